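"""Positional PWM scoring of promoters and motif-based class assignment.

A promoter's match to a motif is scored on the sense strand at every allowed
motif-start offset inside a TSS-relative search window; the best log-odds
score is rescaled to a percent of the achievable range,

    percent = 100 * (S* - S_min) / (S_max - S_min),

where S_max and S_min sum the per-position maximal and minimal log-odds, so
the motif consensus scores 100 and the worst possible sequence scores 0
regardless of motif length or information content. Percent scores feed three
downstream layers: hard presence thresholds (binary flags), an exclusive
class label per promoter (precedence TCT > TATA > DPE > INR > DRE >
Ohler1/6 — the more position-specific element names the class), and an
unsupervised k-means overview of the raw score matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genomic_io import Genome, revcomp
from .pwm import (PWM, BASE_INDEX, DEFAULT_THRESHOLDS, DEVELOPMENTAL_MOTIFS,
                  HOUSEKEEPING_MOTIFS)

#: Exclusive-label precedence; each label fires if any of its motifs is flagged.
CLASS_PRECEDENCE: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("TCT", ("TCT",)),
    ("TATA", ("TATA",)),
    ("DPE", ("DPE",)),
    ("INR", ("INR",)),
    ("DRE", ("DRE",)),
    ("Ohler1/6", ("Ohler1", "Ohler6")),
)

CLASS_NAMES = tuple(name for name, _ in CLASS_PRECEDENCE)


def logodds_score(seq: str, pwm: PWM) -> float:
    """Log2-odds of a sequence window under the PWM vs background; N scores 0."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.length}")
    lo = pwm.log_odds
    score = 0.0
    for j, base in enumerate(seq.upper()):
        if base == "N":
            continue
        score += lo[j, BASE_INDEX[base]]
    return score


def _offset_scores(seq: str, anchor: int, pwm: PWM,
                   window: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    if lo > hi:
        raise ValueError("empty search window")
    offsets = np.arange(lo, hi + 1)
    scores = np.empty(len(offsets))
    for i, off in enumerate(offsets):
        start = anchor + off
        if start < 0 or start + pwm.length > len(seq):
            raise ValueError(
                f"window offset {off} for {pwm.motif_id} falls outside the sequence")
        scores[i] = logodds_score(seq[start:start + pwm.length], pwm)
    return offsets, scores


def percent_score(seq: str, anchor: int, pwm: PWM,
                  window: tuple[int, int]) -> tuple[float, int]:
    """Best percent-of-optimum match in a TSS-relative window.

    ``seq`` must already be sense-oriented with the TSS at index ``anchor``;
    ``window`` gives allowed motif-start offsets (downstream positive).
    Returns (percent in [0, 100], best offset); ties go to the most upstream
    offset (argmax takes the first).
    """
    offsets, scores = _offset_scores(seq, anchor, pwm, window)
    best = int(np.argmax(scores))
    smin, smax = pwm.min_score, pwm.max_score
    if smax - smin < 1e-12:   # uninformative matrix: every sequence is optimal
        return 100.0, int(offsets[best])
    percent = 100.0 * (scores[best] - smin) / (smax - smin)
    return float(np.clip(percent, 0.0, 100.0)), int(offsets[best])


def count_motif_occurrences(seq: str, anchor: int, pwm: PWM,
                            window: tuple[int, int], threshold: float) -> int:
    """Number of window offsets whose own percent score exceeds the threshold."""
    _offsets, scores = _offset_scores(seq, anchor, pwm, window)
    smin, smax = pwm.min_score, pwm.max_score
    if smax - smin < 1e-12:
        return len(scores)
    percents = 100.0 * (scores - smin) / (smax - smin)
    return int(np.sum(percents > threshold))


def sense_sequence(genome: Genome, contig: str, tss: int, strand: str,
                   up: int, down: int) -> str:
    """Sense-oriented sequence covering offsets -up..+down around the TSS."""
    seq = genome[contig]
    if strand == "+":
        lo, hi = tss - up, tss + down + 1
        if lo < 0 or hi > len(seq):
            raise ValueError("promoter window outside contig")
        return seq[lo:hi]
    lo, hi = tss - down, tss + up + 1
    if lo < 0 or hi > len(seq):
        raise ValueError("promoter window outside contig")
    return revcomp(seq[lo:hi])


@dataclass(frozen=True)
class PromoterAnchor:
    """A promoter identified by its (corrected) TSS."""
    promoter_id: str
    contig: str
    tss: int
    strand: str


def score_promoters(genome: Genome, anchors: list[PromoterAnchor],
                    pwms: dict[str, PWM],
                    windows: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Score every promoter against every motif.

    Returns a DataFrame indexed by promoter id with a two-level column index:
    ('percent', motif) and ('offset', motif).
    """
    up = max(0, -min(w[0] for w in windows.values())) + max(p.length for p in pwms.values())
    down = max(0, max(w[1] + pwms[m].length for m, w in windows.items()))
    rows = {}
    for a in anchors:
        seq = sense_sequence(genome, a.contig, a.tss, a.strand, up, down)
        row = {}
        for motif, pwm in pwms.items():
            pct, off = percent_score(seq, up, pwm, windows[motif])
            row[("percent", motif)] = pct
            row[("offset", motif)] = off
        rows[a.promoter_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def apply_thresholds(percent: pd.DataFrame,
                     thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Binary motif flags: percent strictly greater than the motif threshold."""
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    missing = set(thresholds) - set(percent.columns)
    if missing:
        raise ValueError(f"score table lacks motifs: {sorted(missing)}")
    flags = pd.DataFrame(index=percent.index)
    for motif, thr in thresholds.items():
        flags[motif] = percent[motif] > thr
    return flags


def assign_class(flags: pd.DataFrame) -> pd.Series:
    """One exclusive label per promoter from its binary motif flags."""
    labels = pd.Series("other", index=flags.index, dtype=object)
    assigned = pd.Series(False, index=flags.index)
    for name, motifs in CLASS_PRECEDENCE:
        present = [m for m in motifs if m in flags.columns]
        if not present:
            continue
        fire = flags[present].any(axis=1) & ~assigned
        labels[fire] = name
        assigned |= fire
    return labels


def kmeans_overview(percent: pd.DataFrame, k: int = 9, seed: int = 0,
                    restarts: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """Unsupervised k-means overview of the promoter x motif score matrix.

    Lloyd's algorithm on raw percent scores, best of ``restarts`` random
    initializations by within-cluster sum of squares, deterministic given
    the seed.
    """
    if k > len(percent):
        raise ValueError(f"k={k} exceeds the number of promoters ({len(percent)})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(percent.to_numpy(dtype=float))
    centers = pd.DataFrame(km.cluster_centers_, columns=percent.columns)
    return pd.Series(labels, index=percent.index, name="cluster"), centers


# ---------------------------------------------------------------------------
# prototype selection


@dataclass
class PrototypeRule:
    """Stringent motif co-occurrence rule defining a prototypical promoter.

    ``required`` percent minima must be strictly exceeded (set ``inclusive``
    for a rule demanding a perfect match, where a strict bound at 100 would
    be unsatisfiable); ``forbidden`` maxima must be strictly respected.
    """

    name: str
    required: list[tuple[str, float]] = field(default_factory=list)
    forbidden: list[tuple[str, float]] = field(default_factory=list)
    inclusive: bool = False


def default_prototype_rules() -> list[PrototypeRule]:
    hk90 = [(m, 90.0) for m in HOUSEKEEPING_MOTIFS]
    return [
        PrototypeRule("TATA", [("TATA", 95.0)],
                      [("DPE", 90.0), ("MTE", 90.0)] + hk90),
        PrototypeRule("DPE", [("DPE", 95.0)],
                      [("TATA", 80.0), ("MTE", 90.0)] + hk90),
        PrototypeRule("INR", [("INR", 95.0)],
                      [("TATA", 80.0), ("DPE", 85.0), ("MTE", 85.0)] + hk90),
        PrototypeRule("TCT", [("TCT", 95.0)], []),
        PrototypeRule("Ohler1/6", [("Ohler1", 95.0), ("Ohler6", 95.0)],
                      [("TATA", 80.0), ("INR", 85.0), ("DPE", 85.0),
                       ("MTE", 85.0), ("DRE", 95.0)]),
        PrototypeRule("DRE", [("DRE", 100.0)],
                      [("Ohler1", 85.0), ("Ohler6", 85.0),
                       ("TATA", 80.0), ("DPE", 85.0), ("MTE", 85.0)],
                      inclusive=True),
    ]


def select_prototypes(percent: pd.DataFrame, active: pd.Series,
                      rules: list[PrototypeRule] | None = None) -> dict[str, list[str]]:
    """Promoter ids satisfying each prototype rule among active promoters."""
    rules = default_prototype_rules() if rules is None else rules
    out: dict[str, list[str]] = {}
    for rule in rules:
        for motif, _ in rule.required + rule.forbidden:
            if motif not in percent.columns:
                raise ValueError(f"rule {rule.name} references unknown motif {motif}")
        mask = active.reindex(percent.index, fill_value=False).astype(bool)
        for motif, minp in rule.required:
            mask &= (percent[motif] >= minp) if rule.inclusive else (percent[motif] > minp)
        for motif, maxp in rule.forbidden:
            mask &= percent[motif] < maxp
        out[rule.name] = list(percent.index[mask])
    return out


def cage_tpm(signal, anchors: list[PromoterAnchor], flank: int = 50) -> pd.Series:
    """Promoter activity in tags per million: 5'-end tags within +-flank of
    the TSS, per million tags in the whole track."""
    total = signal.total()
    vals = {}
    for a in anchors:
        w = signal.sense_window(a.contig, a.strand, a.tss, flank, flank)
        vals[a.promoter_id] = w.sum() / total * 1e6 if total > 0 else 0.0
    return pd.Series(vals, name="tpm")
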