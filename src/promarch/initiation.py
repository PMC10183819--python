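"""Promoter-shape statistics on single-base 5'-end initiation profiles.

A promoter's initiation profile is the vector of tag counts at sense offsets
around an anchor (usually the corrected TSS). From it we take the dominant
TSS (modal position), the dominant fraction (share of all initiation at that
position — high for focused developmental promoters, low for dispersed
housekeeping ones), the number of activated TSSs (positions above a relative
cutoff of the dominant count, by default 20%), and the width of the
initiation region (span of positions with signal). Two activated-TSS
counting modes are kept explicit because both a strict (> 20%) and an
inclusive (>= 20%) reading are in circulation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genomic_io import Genome, StrandedBaseSignal, revcomp


@dataclass
class InitiationProfile:
    """Counts at sense offsets -w_up..+w_down around an anchor position."""

    promoter_id: str
    contig: str
    anchor: int
    strand: str
    w_up: int
    w_down: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.w_up + self.w_down + 1:
            raise ValueError("profile length must equal w_up + w_down + 1")
        if np.any(self.counts < 0):
            raise ValueError("profile counts must be nonnegative")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.w_up, self.w_down + 1)

    @property
    def active(self) -> bool:
        return bool(np.any(self.counts > 0))


@dataclass
class InitiationMetrics:
    promoter_id: str
    dominant_offset: int
    dominant_fraction: float
    n_activated_strict: int
    n_activated_inclusive: int
    width: int


def extract_profile(signal: StrandedBaseSignal, promoter_id: str, contig: str,
                    anchor: int, strand: str, w_up: int,
                    w_down: int) -> InitiationProfile:
    """Windowed sense-oriented profile; minus-strand promoters are flipped so
    downstream is positive."""
    if w_up < 0 or w_down < 0:
        raise ValueError("window extents must be nonnegative")
    counts = signal.sense_window(contig, strand, anchor, w_up, w_down)
    return InitiationProfile(promoter_id, contig, anchor, strand,
                             w_up, w_down, counts)


def _require_active(profile: InitiationProfile) -> None:
    if not profile.active:
        raise ValueError(f"profile {profile.promoter_id} has no signal")


def dominant_tss(profile: InitiationProfile) -> int:
    """Offset of the highest count; ties go to the most upstream position."""
    _require_active(profile)
    return int(profile.offsets[int(np.argmax(profile.counts))])


def dominant_fraction(profile: InitiationProfile) -> float:
    """Share of total initiation at the dominant TSS, in (0, 1]."""
    _require_active(profile)
    return float(profile.counts.max() / profile.counts.sum())


def count_activated_tss(profile: InitiationProfile, rel: float = 0.2,
                        mode: str = "strict") -> int:
    """Positions whose count relative to the dominant exceeds ``rel``.

    ``strict`` counts ratios > rel; ``inclusive`` counts >= rel. The dominant
    position itself always counts, so the result is >= 1.
    """
    _require_active(profile)
    if not (0 < rel <= 1):
        raise ValueError("rel must be in (0, 1]")
    if mode not in {"strict", "inclusive"}:
        raise ValueError(f"unknown mode {mode!r}")
    ratio = profile.counts / profile.counts.max()
    if mode == "strict":
        n = int(np.sum(ratio > rel))
        return max(n, 1)    # rel = 1 would otherwise exclude the dominant
    return int(np.sum((ratio >= rel) & (profile.counts > 0)))


def initiation_width(profile: InitiationProfile, floor: float = 1) -> int:
    """Span in bp of positions with count >= floor, gaps included."""
    _require_active(profile)
    idx = np.nonzero(profile.counts >= floor)[0]
    if len(idx) == 0:
        raise ValueError("no position reaches the count floor")
    return int(idx[-1] - idx[0] + 1)


def profile_metrics(profile: InitiationProfile, rel: float = 0.2,
                    width_floor: float = 1) -> InitiationMetrics:
    return InitiationMetrics(
        promoter_id=profile.promoter_id,
        dominant_offset=dominant_tss(profile),
        dominant_fraction=dominant_fraction(profile),
        n_activated_strict=count_activated_tss(profile, rel, "strict"),
        n_activated_inclusive=count_activated_tss(profile, rel, "inclusive"),
        width=initiation_width(profile, width_floor),
    )


# ---------------------------------------------------------------------------
# -1/+1 dinucleotides


@dataclass
class DinucleotideTable:
    counts: Counter
    skipped: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def dinucleotide_at_tss(genome: Genome,
                        anchors: list[tuple[str, int, str]]) -> DinucleotideTable:
    """Sense-strand dinucleotide spanning the -1/+1 positions of each TSS.

    The +1 base is the TSS itself. Minus-strand promoters are reverse-
    complemented. TSSs at a contig edge or touching an N are skipped and
    tallied.
    """
    counts: Counter = Counter()
    skipped = 0
    for contig, tss, strand in anchors:
        seq = genome[contig]
        if strand == "+":
            if tss - 1 < 0 or tss >= len(seq):
                skipped += 1
                continue
            dinuc = seq[tss - 1:tss + 1]
        else:
            if tss + 1 >= len(seq) or tss < 0:
                skipped += 1
                continue
            dinuc = revcomp(seq[tss:tss + 2])
        if "N" in dinuc:
            skipped += 1
            continue
        counts[dinuc] += 1
    return DinucleotideTable(counts, skipped)


# ---------------------------------------------------------------------------
# anchored metaprofiles


@dataclass
class MetaProfile:
    """Mean sum-normalized signal at offsets around a set of anchors."""

    offsets: np.ndarray
    mean: np.ndarray
    n: int
    n_excluded: int = 0   # failed the single-occurrence filter
    n_empty: int = 0      # no signal in the window


def anchored_metaprofile(signal: StrandedBaseSignal,
                         anchors: list[tuple[str, str, int, str]],
                         flank: int,
                         occurrence_counts: dict[str, int] | None = None
                         ) -> MetaProfile:
    """Average of sum-normalized per-promoter profiles around an anchor.

    ``anchors`` rows are (promoter_id, contig, anchor position, strand); the
    anchor may be a motif position or a +1 nucleosome center. When
    ``occurrence_counts`` is given (promoter id -> number of above-threshold
    motif positions in the search window) only promoters with exactly one
    occurrence contribute; the rest are excluded and tallied, keeping the
    anchor unambiguous.
    """
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(len(offsets))
    n = n_excluded = n_empty = 0
    for pid, contig, anchor, strand in anchors:
        if occurrence_counts is not None and occurrence_counts.get(pid, 0) != 1:
            n_excluded += 1
            continue
        prof = signal.sense_window(contig, strand, anchor, flank, flank)
        s = prof.sum()
        if s <= 0:
            n_empty += 1
            continue
        acc += prof / s
        n += 1
    if n == 0:
        raise ValueError("no eligible promoters for the metaprofile")
    return MetaProfile(offsets, acc / n, n, n_excluded, n_empty)
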