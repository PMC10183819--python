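"""Seeded generator of promoter landscapes and the data types read by the
analysis modules: genome + transcript models, 5'-end initiation signal,
nuclease-protected fragments, and two-condition nascent-transcription counts
with spike-in tallies.

The generator encodes the two core-promoter regimes the analyses are built
to distinguish. Developmental classes (TATA, DPE, INR) initiate focused —
one dominant base carries 80% of the tags with a geometric fall-off over
+-3 bp — and their downstream (+1) nucleosome is loosely positioned
(40 bp sd). Housekeeping classes (TCT, DRE, Ohler1/6) initiate dispersed:
tags spread over a ~100-bp window with random per-position weights, anchored
so that the window ends 30 bp upstream of the +1 nucleosome center, which
sits 125 bp downstream of the dominant TSS and is tightly positioned
(10 bp sd). The dominant position of a dispersed promoter carries a fixed
15% of the mass, keeping it the modal TSS without focusing initiation.

All randomness flows from one integer seed; each promoter draws from its own
counter-derived substream so outputs are stable under subsetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depletion import CountMatrix
from .genomic_io import (FragmentSet, Genome, Interval, StrandedBaseSignal,
                         TranscriptModel)
from .pwm import IUPAC, default_embed_offsets, _DEFAULT_MOTIFS

_STREAM_BACKGROUND = 0
_STREAM_EMBED = 10
_STREAM_CAGE = 11
_STREAM_MNASE = 12
_STREAM_COUNTS = 13


@dataclass(frozen=True)
class ClassSpec:
    """One promoter class: motifs to embed and its initiation/chromatin regime."""

    name: str
    motifs: tuple[tuple[str, int], ...]   # (motif id, TSS-relative start offset)
    mode: str                             # 'focused' | 'dispersed'
    focused_width: int = 3
    dispersed_width: int = 100
    nuc_offset: int = 125                 # +1 nucleosome center downstream of dominant TSS
    nuc_sd: float = 10.0

    def __post_init__(self):
        if self.mode not in {"focused", "dispersed"}:
            raise ValueError(f"invalid initiation mode {self.mode!r}")
        if self.focused_width < 1 or self.dispersed_width < 1:
            raise ValueError("initiation widths must be >= 1")


def default_class_specs() -> tuple[ClassSpec, ...]:
    off = default_embed_offsets()
    return (
        ClassSpec("TATA", (("TATA", off["TATA"]), ("INR", off["INR"])),
                  "focused", nuc_sd=40.0),
        ClassSpec("DPE", (("INR", off["INR"]), ("DPE", off["DPE"])),
                  "focused", nuc_sd=40.0),
        ClassSpec("INR", (("INR", off["INR"]),), "focused", nuc_sd=40.0),
        ClassSpec("TCT", (("TCT", off["TCT"]),), "dispersed", nuc_sd=10.0),
        ClassSpec("DRE", (("DRE", off["DRE"]),), "dispersed", nuc_sd=10.0),
        ClassSpec("Ohler1/6", (("Ohler1", off["Ohler1"]), ("Ohler6", off["Ohler6"])),
                  "dispersed", nuc_sd=10.0),
    )


@dataclass(frozen=True)
class DepletionScenario:
    """Condition contrast for the two-condition count simulation.

    Per-gene effects apply ``fold_change`` either to the genes of promoters
    whose class is in ``target_classes`` or, absent class targeting, to a
    random ``affected_fraction`` of genes. ``global_factor`` multiplies every
    gene in the depleted condition — the global-output-collapse scenario that
    only spike-in normalization can detect.
    """

    target_classes: tuple[str, ...] = ()
    fold_change: float = 1.0
    global_factor: float = 1.0
    affected_fraction: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """All simulation constants; defaults are the package's study conditions."""

    n_per_class: int = 100
    classes: tuple[ClassSpec, ...] = field(default_factory=default_class_specs)
    contig: str = "simchr"
    spacing: int = 3000
    margin: int = 1000
    core_length: int = 121
    transcript_length: int = 1000
    annotation_jitter: tuple[int, int] = (0, 0)  # (min, max) |offset| of annotated TSS
    # CAGE
    mean_cage_tags: float = 2000.0
    focused_mass: float = 0.8
    focused_decay: float = 0.5
    dispersed_dominant_weight: float = 0.15
    dispersed_gap: int = 30               # window ends this far upstream of +1 center
    # MNase
    fragments_per_promoter: int = 200
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    fragment_length_bounds: tuple[int, int] = (80, 220)
    # depletion counts
    n_genes: int = 2000
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.0               # NB dispersion phi; 0 = Poisson
    n_replicates: int = 3
    depth: int = 1_000_000
    spike_fraction: float = 0.01
    scenario: DepletionScenario = field(default_factory=DepletionScenario)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 0 or self.n_genes < 0 or self.depth <= 0:
            raise ValueError("counts and depth must be nonnegative/positive")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if not (0 < self.spike_fraction < 1):
            raise ValueError("spike fraction must be in (0, 1)")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Generator ground truth for parameter-recovery tests."""

    promoters: pd.DataFrame
    genes: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None


def _rng(config: SimConfig, stream: int, counter: int | None = None):
    key = [config.seed, stream] if counter is None else [config.seed, stream, counter]
    return np.random.default_rng(key)


def _instantiate_consensus(consensus: str, rng) -> str:
    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b]))
                   for b in consensus)


def simulate_promoter_landscape(
        config: SimConfig) -> tuple[Genome, list[TranscriptModel], SimTruth]:
    """Lay out promoters of each class on one contig with embedded motifs.

    Promoters alternate strand and are spaced ``config.spacing`` apart; each
    promoter's core (121 bp by default, centered on the true dominant TSS)
    carries its class consensus motifs at the programmed offsets on an
    i.i.d.-uniform background. Annotated (transcript-model) TSSs may be
    jittered away from the truth to exercise TSS correction.
    """
    if config.spacing < config.core_length:
        raise ValueError("promoters would overlap at the requested spacing")
    n_prom = config.n_per_class * len(config.classes)
    jlo, jhi = config.annotation_jitter
    margin = max(config.margin, config.transcript_length + jhi + config.core_length)
    length = 2 * margin + max(n_prom, 1) * config.spacing
    seq = _rng(config, _STREAM_BACKGROUND).choice(list("ACGT"), size=length)

    rows = []
    transcripts = []
    i = 0
    for spec in config.classes:
        for _ in range(config.n_per_class):
            rng = _rng(config, _STREAM_EMBED, i)
            strand = "+" if i % 2 == 0 else "-"
            tss = margin + i * config.spacing
            for motif, off in spec.motifs:
                inst = _instantiate_consensus(_DEFAULT_MOTIFS[motif][0], rng)
                for j, base in enumerate(inst):
                    d = off + j          # sense offset
                    pos = tss + d if strand == "+" else tss - d
                    seq[pos] = base if strand == "+" else \
                        {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
            jitter = 0
            if jhi > 0:
                mag = int(rng.integers(jlo, jhi + 1))
                jitter = mag * (1 if rng.random() < 0.5 else -1)
            ann = tss + jitter if strand == "+" else tss - jitter
            if strand == "+":
                iv = Interval(config.contig, ann, ann + config.transcript_length, "+")
            else:
                iv = Interval(config.contig, ann - config.transcript_length + 1,
                              ann + 1, "-")
            gene_id, tx_id = f"g{i:04d}", f"t{i:04d}"
            transcripts.append(TranscriptModel(gene_id, tx_id, iv))
            nuc = tss + spec.nuc_offset if strand == "+" else tss - spec.nuc_offset
            rows.append({
                "promoter_id": f"p{i:04d}", "gene_id": gene_id,
                "transcript_id": tx_id, "class_label": spec.name,
                "contig": config.contig, "strand": strand, "tss": tss,
                "annotated_tss": ann, "nuc_center": nuc,
            })
            i += 1
    genome = Genome({config.contig: "".join(seq)})
    truth = SimTruth(promoters=pd.DataFrame(
        rows, columns=["promoter_id", "gene_id", "transcript_id", "class_label",
                       "contig", "strand", "tss", "annotated_tss", "nuc_center"]))
    return genome, transcripts, truth


def _class_by_name(config: SimConfig) -> dict[str, ClassSpec]:
    return {spec.name: spec for spec in config.classes}


def _initiation_weights(spec: ClassSpec, config: SimConfig, rng):
    """(sense offsets, probabilities) of the per-promoter initiation law."""
    if spec.mode == "focused":
        w = spec.focused_width
        offs = np.arange(-w, w + 1)
        wts = np.array([config.focused_decay ** abs(d) if d != 0 else 0.0
                        for d in offs])
        wts = wts / wts.sum() * (1 - config.focused_mass)
        wts[offs == 0] = config.focused_mass
        return offs, wts
    hi = spec.nuc_offset - config.dispersed_gap      # window end (exclusive)
    offs = np.arange(hi - spec.dispersed_width, hi)
    wts = rng.uniform(0.5, 1.5, len(offs))
    if 0 not in offs:                                # dominant TSS always supported
        offs = np.append(offs, 0)
        wts = np.append(wts, 0.0)
    dom = offs == 0
    wts[dom] = 0.0
    wts = wts / wts.sum() * (1 - config.dispersed_dominant_weight)
    wts[dom] = config.dispersed_dominant_weight
    return offs, wts


def simulate_cage(truth: SimTruth, config: SimConfig) -> StrandedBaseSignal:
    """Per-promoter 5'-end tag counts: Poisson total, multinomial placement."""
    classes = _class_by_name(config)
    signal = StrandedBaseSignal()
    for i, row in truth.promoters.iterrows():
        spec = classes[row["class_label"]]
        rng = _rng(config, _STREAM_CAGE, int(i))
        total = int(rng.poisson(config.mean_cage_tags))
        if total == 0:
            continue
        offs, wts = _initiation_weights(spec, config, rng)
        counts = rng.multinomial(total, wts)
        for d, c in zip(offs, counts):
            if c == 0:
                continue
            pos = row["tss"] + d if row["strand"] == "+" else row["tss"] - d
            signal.add(row["contig"], row["strand"], int(pos), int(c))
    return signal


def simulate_mnase(truth: SimTruth, config: SimConfig) -> FragmentSet:
    """Fragments with centers ~ Normal(true +1 center, class positioning sd).

    Lengths are Normal(147, sd) redrawn until inside the broad bounds
    (default [80, 220]) so a tail of fragments deliberately fails the
    downstream [100, 200] analysis filter.
    """
    classes = _class_by_name(config)
    lo, hi = config.fragment_length_bounds
    frags: list[Interval] = []
    for i, row in truth.promoters.iterrows():
        spec = classes[row["class_label"]]
        rng = _rng(config, _STREAM_MNASE, int(i))
        n = config.fragments_per_promoter
        centers = np.rint(rng.normal(row["nuc_center"], spec.nuc_sd, n)).astype(int)
        lengths = np.rint(rng.normal(config.fragment_length_mean,
                                     config.fragment_length_sd, n)).astype(int)
        bad = (lengths < lo) | (lengths > hi)
        while bad.any():
            lengths[bad] = np.rint(rng.normal(
                config.fragment_length_mean, config.fragment_length_sd,
                int(bad.sum()))).astype(int)
            bad = (lengths < lo) | (lengths > hi)
        for c, ln in zip(centers, lengths):
            start = int(c) - int(ln) // 2
            frags.append(Interval(row["contig"], start, start + int(ln)))
    return FragmentSet(frags)


def simulate_depletion_counts(
        config: SimConfig,
        promoter_truth: SimTruth | None = None) -> tuple[CountMatrix, SimTruth]:
    """Two-condition gene counts with spike-in tallies.

    Baselines are LogNormal(log 200, 1); the depleted-condition mean of gene
    g is ``baseline * fold_g * G``. Counts are negative-binomial around the
    depth-scaled mean (Gamma-Poisson; ``dispersion == 0`` is the Poisson
    limit). Spike reads are Binomial(depth, kappa / (kappa + O_s)) where O_s
    is the sample's total transcriptional output relative to control, so a
    global collapse inflates the spike read share — the signature that makes
    spike normalization load-bearing.
    """
    rng = _rng(config, _STREAM_COUNTS)
    sc = config.scenario
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             config.n_genes)
    fold = np.ones(config.n_genes)
    if sc.target_classes:
        if promoter_truth is None:
            raise ValueError("class-targeted scenario needs promoter truth")
        targets = promoter_truth.promoters.loc[
            promoter_truth.promoters["class_label"].isin(sc.target_classes),
            "gene_id"]
        idx = [gene_ids.index(g) for g in targets if g in set(gene_ids)]
        fold[idx] = sc.fold_change
    elif sc.affected_fraction > 0:
        k = int(round(sc.affected_fraction * config.n_genes))
        idx = rng.choice(config.n_genes, size=k, replace=False)
        fold[idx] = sc.fold_change

    counts = {}
    sample_rows = []
    kappa = config.spike_fraction
    for condition in ("control", "depleted"):
        for rep in range(1, config.n_replicates + 1):
            if condition == "control":
                expr = baseline
            else:
                expr = baseline * fold * sc.global_factor
            output = float(expr.sum() / baseline.sum())
            spike = int(rng.binomial(config.depth, kappa / (kappa + output)))
            fly_depth = config.depth - spike
            mu = fly_depth * expr / expr.sum()
            if config.dispersion > 0:
                lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
            else:
                lam = mu
            name = f"{condition}_{rep}"
            counts[name] = rng.poisson(lam)
            sample_rows.append({"sample": name, "condition": condition,
                                "replicate": rep, "spike_reads": spike,
                                "reference_reads": fly_depth,
                                "output_factor": output})
    counts_df = pd.DataFrame(counts, index=gene_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    cm = CountMatrix(counts_df,
                     samples[["condition", "replicate", "spike_reads",
                              "reference_reads"]])
    truth = SimTruth(
        promoters=(promoter_truth.promoters if promoter_truth is not None
                   else pd.DataFrame()),
        genes=pd.DataFrame({"gene_id": gene_ids, "baseline": baseline,
                            "fold_change": fold}).set_index("gene_id"),
        samples=samples[["condition", "output_factor"]])
    return cm, truth
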