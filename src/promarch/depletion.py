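"""Spike-in normalized differential response to factor depletion.

When a general transcription factor is acutely degraded, total nascent
transcription can fall genome-wide; ordinary library-size normalization
silently rescales that collapse away. Here per-sample size factors are
derived from spike-in read tallies (foreign-genome reads from a constant
admixed cell pool): the spike-to-reference read ratio tracks the inverse of
the sample's transcriptional output, so dividing counts by spike-derived
factors restores absolute (per-cell) comparability.

Down-regulation is called per gene at the conventional thresholds
(fold change > 1.5 down, BH FDR < 0.05) using an exact conditional test:
given the replicate-summed counts n = c + t of a gene, t is Binomial(n, pi0)
under the null, with pi0 the depleted share of the summed size factors; the
two-sided p sums all outcome probabilities not exceeding the observed one.
This is a deliberately simple, fully calibrated stand-in for a negative-
binomial GLM — it shares the normalization entry point and thresholds, and
any external test can be swapped in through the ``test`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2_FOLD_DEFAULT = 1.5
_TIE_REL = 1 + 1e-7   # relative fuzz when comparing outcome probabilities


@dataclass
class CountMatrix:
    """Gene x sample counts plus per-sample condition and spike-in metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame   # index: sample id; columns: condition, replicate,
                            # spike_reads, reference_reads

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample metadata index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        need = {"condition", "spike_reads", "reference_reads"}
        if not need <= set(self.samples.columns):
            raise ValueError(f"sample metadata needs columns {sorted(need)}")
        tot = self.samples["spike_reads"] + self.samples["reference_reads"]
        if (tot <= 0).any():
            raise ValueError("spike + reference reads must be positive per sample")
        for cond in ("control", "depleted"):
            if not (self.samples["condition"] == cond).any():
                raise ValueError(f"no samples in condition {cond!r}")

    def condition_columns(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def write_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, comment="#")
        return cls(counts, samples)


def spike_size_factors(spike_reads: pd.Series,
                       reference_reads: pd.Series | None = None) -> pd.Series:
    """Per-sample size factors from spike-in tallies, geometric mean 1.

    With ``reference_reads`` the factor is proportional to the
    spike/reference read ratio (robust to unequal sequencing depth);
    without, to the raw spike tally. Dividing a sample's counts by its
    factor yields per-cell-comparable values.
    """
    spike = spike_reads.astype(float)
    if (spike <= 0).any():
        raise ValueError("zero spike reads: size factor undefined")
    ratio = spike if reference_reads is None else spike / reference_reads.astype(float)
    factors = ratio / np.exp(np.log(ratio).mean())
    factors.name = "size_factor"
    return factors


def library_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Naive total-count factors (geometric mean 1) — the normalization that
    a global transcriptional collapse defeats."""
    totals = counts.sum(axis=0).astype(float)
    factors = totals / np.exp(np.log(totals).mean())
    factors.name = "size_factor"
    return factors


def exact_ratio_test(c: int, t: int, control_factor_sum: float,
                     depleted_factor_sum: float) -> float:
    """Exact conditional two-sided test of a depleted/control count split.

    Conditional on n = c + t, the depleted total t is Binomial(n, pi0) under
    the null with pi0 = depleted_factor_sum / (control + depleted factor
    sums). The two-sided p sums the probabilities of all outcomes no more
    likely than the observed one. Returns NaN for c = t = 0 (not testable).
    """
    if c < 0 or t < 0:
        raise ValueError("counts must be nonnegative")
    n = c + t
    if n == 0:
        return float("nan")
    pi0 = depleted_factor_sum / (control_factor_sum + depleted_factor_sum)
    pmf = stats.binom.pmf(np.arange(n + 1), n, pi0)
    p_obs = pmf[t]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_REL].sum()))


def bh_fdr(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = pd.Series(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_downregulated(matrix: CountMatrix, factors: pd.Series,
                       fold_threshold: float = LOG2_FOLD_DEFAULT,
                       alpha: float = 0.05, min_norm_total: float = 10.0,
                       test=exact_ratio_test) -> pd.DataFrame:
    """Per-gene depletion response at fold/FDR thresholds.

    log2 fold changes come from size-factor-normalized condition sums with a
    0.5 pseudocount; p-values from the exact conditional test on raw
    replicate-summed counts with the condition factor sums as the expected
    split. Genes whose normalized total is below ``min_norm_total`` are
    reported but marked not testable (NaN p/q, never called down).
    """
    ctrl = matrix.condition_columns("control")
    dep = matrix.condition_columns("depleted")
    factors = factors.reindex(matrix.counts.columns)
    if factors.isna().any():
        raise ValueError("size factors missing for some samples")
    norm = matrix.counts / factors
    ctrl_norm = norm[ctrl].sum(axis=1)
    dep_norm = norm[dep].sum(axis=1)
    log2fc = np.log2((dep_norm + 0.5) / (ctrl_norm + 0.5))
    c_raw = matrix.counts[ctrl].sum(axis=1)
    t_raw = matrix.counts[dep].sum(axis=1)
    f_ctrl = float(factors[ctrl].sum())
    f_dep = float(factors[dep].sum())
    testable = (ctrl_norm + dep_norm) >= min_norm_total
    p = pd.Series(np.nan, index=matrix.counts.index)
    p[testable] = [test(int(c), int(t), f_ctrl, f_dep)
                   for c, t in zip(c_raw[testable], t_raw[testable])]
    q = bh_fdr(p)
    down = (log2fc <= -np.log2(fold_threshold)) & (q < alpha)
    return pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q,
        "testable": testable, "down": down.fillna(False),
    })


# ---------------------------------------------------------------------------
# Fisher motif enrichment


@dataclass
class EnrichmentResult:
    motif: str
    a: int   # down & motif
    b: int   # down & no motif
    c: int   # background (not down) & motif
    d: int   # background & no motif
    odds_ratio: float
    log2_odds_ratio: float
    p: float


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric outcome probabilities not
    exceeding the observed table's probability (margins fixed)."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    k = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_REL].sum()))


def fisher_motif_enrichment(down: set[str], expressed: set[str],
                            flags: pd.DataFrame) -> list[EnrichmentResult]:
    """Motif enrichment of a down-regulated set against an expressed background.

    ``flags`` is the binary promoter x motif table restricted (by reindex) to
    expressed genes. The odds ratio is ad/bc with a Haldane 0.5 correction
    applied only when a cell is zero.
    """
    if not down:
        raise ValueError("empty down-regulated set")
    if not expressed:
        raise ValueError("empty expressed background")
    if not down <= expressed:
        raise ValueError("down set must be a subset of the expressed background")
    flags = flags.reindex(sorted(expressed)).fillna(False).astype(bool)
    rest = expressed - down
    results = []
    for motif in flags.columns:
        pos = set(flags.index[flags[motif]])
        a = len(down & pos)
        b = len(down) - a
        c = len(rest & pos)
        d = len(rest) - c
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        results.append(EnrichmentResult(
            motif, a, b, c, d, orat, float(np.log2(orat)),
            _fisher_two_sided(a, b, c, d)))
    return results


# ---------------------------------------------------------------------------
# ChIP z-scores and intersection of candidate intermediaries


def chip_zscore(chip: pd.DataFrame, nascent: pd.Series, lengths: pd.Series,
                labels: pd.Series) -> tuple[pd.DataFrame, int]:
    """Transcription-normalized ChIP signal summarized as per-factor z-scores
    across promoter classes.

    ``chip`` holds per-promoter coverage (1-kb TSS-centered window) per
    factor; each value is divided by the gene's transcription rate
    (nascent counts / gene length). Promoters with zero nascent signal are
    excluded and tallied. Per factor, class means are z-scored across
    classes (population sd).
    """
    keep = nascent > 0
    n_excluded = int((~keep).sum())
    rate = nascent[keep] / lengths[keep]
    values = chip.loc[keep.index[keep]].div(rate, axis=0)
    values["class"] = labels
    class_means = values.groupby("class").mean()
    if len(class_means) < 2:
        raise ValueError("need at least two promoter classes with data")
    z = (class_means - class_means.mean()) / class_means.std(ddof=0)
    return z, n_excluded


def candidate_intermediaries(bound: dict[str, set[str]],
                             interactors: set[str]) -> dict[str, set[str]]:
    """Per promoter type, the promoter-bound proteins that are also physical
    interactors of the anchor factor."""
    return {ptype: proteins & interactors for ptype, proteins in bound.items()}
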