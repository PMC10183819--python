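"""Reassign annotated TSSs to 5'-end-supported positions.

Annotated transcript TSSs are moved to the strongest CAGE position nearby,
searching a primary track first and then any fallback tracks (e.g. other
developmental stages), each within a small window (+-250 bp by default);
only if no track has signal there is the search widened (+-500 bp). A "hit"
is any same-strand position with a positive tag count. The corrected TSS is
the position of maximal count in the winning window; ties go to the position
closest to the annotated TSS, then to the more upstream one. Transcripts
sharing a corrected TSS are collapsed to the longest.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_io import Interval, StrandedBaseSignal, TranscriptModel

PASS_UNCORRECTED = "uncorrected"


@dataclass(frozen=True)
class CorrectionResult:
    transcript_id: str
    original_tss: int
    corrected_tss: int
    pass_label: str   # e.g. 'primary-250', 'fallback-500', 'uncorrected'


def _best_position(signal: StrandedBaseSignal, contig: str, strand: str,
                   tss: int, window: int, min_count: float) -> int | None:
    best_pos, best = None, None
    for pos in range(max(tss - window, 0), tss + window + 1):
        c = signal.count(contig, strand, pos)
        if c < min_count or c <= 0:
            continue
        # rank: count desc, then distance to annotated TSS, then upstream-most
        upstream = (pos - tss) if strand == "+" else (tss - pos)
        rank = (-c, abs(pos - tss), upstream)
        if best is None or rank < best:
            best, best_pos = rank, pos
    return best_pos


def correct_tss(transcripts: list[TranscriptModel],
                primary: StrandedBaseSignal,
                fallbacks: list[StrandedBaseSignal] | None = None,
                w_small: int = 250, w_large: int = 500,
                min_count: float = 1) -> list[CorrectionResult]:
    """Two-window, primary-then-fallback TSS correction.

    Search order: primary at +-w_small, each fallback at +-w_small, then the
    same sequence at +-w_large. Fallback tracks are queried sequentially in
    the given order (not pooled) so each correction is attributable to one
    track. Transcripts with no signal anywhere keep their annotated TSS.
    """
    if not (0 < w_small <= w_large):
        raise ValueError("require 0 < w_small <= w_large")
    fallbacks = fallbacks or []
    stages = []
    for w in (w_small, w_large):
        stages.append((f"primary-{w}", primary, w))
        for i, fb in enumerate(fallbacks):
            label = f"fallback-{w}" if len(fallbacks) == 1 else f"fallback{i + 1}-{w}"
            stages.append((label, fb, w))
    results = []
    for t in transcripts:
        corrected, label = t.tss, PASS_UNCORRECTED
        for stage_label, signal, w in stages:
            pos = _best_position(signal, t.contig, t.strand, t.tss, w, min_count)
            if pos is not None:
                corrected, label = pos, stage_label
                break
        results.append(CorrectionResult(t.transcript_id, t.tss, corrected, label))
    return results


def apply_corrections(transcripts: list[TranscriptModel],
                      results: list[CorrectionResult]) -> list[TranscriptModel]:
    """Rebuild transcript models around their corrected TSSs.

    The transcript span is shifted so the corrected TSS replaces the old one;
    length is preserved.
    """
    by_id = {r.transcript_id: r for r in results}
    out = []
    for t in transcripts:
        r = by_id[t.transcript_id]
        shift = r.corrected_tss - t.tss
        iv = t.interval
        out.append(TranscriptModel(
            t.gene_id, t.transcript_id,
            Interval(iv.contig, iv.start + shift, iv.end + shift, iv.strand)))
    return out


def collapse_by_tss(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Keep the longest transcript per unique (contig, strand, TSS).

    Length ties keep the lexicographically smallest transcript id. Output
    order follows first appearance of each TSS key.
    """
    best: dict[tuple[str, str, int], TranscriptModel] = {}
    for t in transcripts:
        key = (t.contig, t.strand, t.tss)
        cur = best.get(key)
        if cur is None or t.length > cur.length or (
                t.length == cur.length and t.transcript_id < cur.transcript_id):
            best[key] = t
    return list(best.values())
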