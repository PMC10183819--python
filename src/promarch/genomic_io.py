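"""Coordinate conventions, plain-text format I/O, and read-to-signal reduction.

Every interval in this package is 0-based half-open (BED convention), and
every single-base signal is keyed by a 0-based genomic position. Stranded
per-base tracks live on disk as a pair of bedGraph files
(``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``); binary formats
(BAM, bigWig) are deliberately not handled — alignment is upstream of this
package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
UMI_BASES = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# domain types


class Genome:
    """Uppercase nucleotide sequences keyed by contig id, insertion-ordered."""

    def __init__(self, records: Mapping[str, str]):
        self.records: dict[str, str] = {}
        for contig, seq in records.items():
            if contig in self.records:
                raise ValueError(f"duplicate contig id: {contig}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for contig {contig}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases in {contig}: {sorted(bad)}")
            self.records[contig] = seq

    def __getitem__(self, contig: str) -> str:
        return self.records[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.records == other.records


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval; strand '.' means strandless."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its strand-aware TSS (start if '+', end-1 if '-')."""

    gene_id: str
    transcript_id: str
    interval: Interval

    def __post_init__(self):
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("transcript must be stranded")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def length(self) -> int:
        return self.interval.length


class StrandedBaseSignal:
    """Sparse per-base stranded counts: (contig, strand, pos) -> value > 0.

    The common currency for CAGE / reporter-initiation 5' ends, nascent-RNA
    active sites, and fragment-center tracks. Values are positive; integer
    counts stay integers, scaled tracks may hold floats.
    """

    def __init__(self, entries: Mapping[tuple[str, str, int], float] | None = None):
        self._d: dict[tuple[str, str, int], float] = {}
        self.meta: dict = {}
        if entries:
            for key, val in entries.items():
                self.add(*key, val)

    def add(self, contig: str, strand: str, pos: int, value: float = 1) -> None:
        if strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {strand!r}")
        if pos < 0:
            raise ValueError("negative position")
        if value <= 0:
            raise ValueError("signal values must be positive")
        key = (contig, strand, pos)
        self._d[key] = self._d.get(key, 0) + value

    def count(self, contig: str, strand: str, pos: int) -> float:
        return self._d.get((contig, strand, pos), 0)

    def window(self, contig: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense value array over [start, end) in genomic orientation."""
        out = np.zeros(end - start, dtype=float)
        for pos in range(max(start, 0), end):
            v = self._d.get((contig, strand, pos))
            if v:
                out[pos - start] = v
        return out

    def sense_window(self, contig: str, strand: str, anchor: int,
                     up: int, down: int) -> np.ndarray:
        """Values at sense offsets -up..+down relative to an anchor.

        Index 0 of the result is offset -up; downstream is positive in the
        direction of transcription (genomic positions decrease with offset on
        the minus strand).
        """
        n = up + down + 1
        out = np.zeros(n, dtype=float)
        for i, off in enumerate(range(-up, down + 1)):
            pos = anchor + off if strand == "+" else anchor - off
            if pos >= 0:
                v = self._d.get((contig, strand, pos))
                if v:
                    out[i] = v
        return out

    def entries(self) -> Iterator[tuple[tuple[str, str, int], float]]:
        return iter(sorted(self._d.items()))

    def total(self) -> float:
        return sum(self._d.values())

    def __len__(self) -> int:
        return len(self._d)

    def __eq__(self, other) -> bool:
        return isinstance(other, StrandedBaseSignal) and self._d == other._d

    def __bool__(self) -> bool:
        return bool(self._d)


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned read carrying a UMI of 8-10 nt over {A,C,G,T,N}."""

    contig: str
    start: int
    end: int
    strand: str
    umi: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("read start must precede end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (8 <= len(self.umi) <= 10):
            raise ValueError("UMI length must be 8-10 nt")
        if set(self.umi) - UMI_BASES:
            raise ValueError(f"invalid UMI {self.umi!r}")


@dataclass
class FragmentSet:
    """Strandless fragments, e.g. nuclease-protected fragments from MNase."""

    fragments: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        for f in self.fragments:
            if f.length < 1:
                raise ValueError("fragment length must be >= 1")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.fragments)


# ---------------------------------------------------------------------------
# FASTA / BED / GTF

def parse_fasta(path) -> Genome:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate contig id: {rec.id}")
        records[rec.id] = str(rec.seq)
    g = Genome({})
    g.records = {}
    for contig, seq in records.items():
        # route through Genome validation while preserving order
        g.records.update(Genome({contig: seq}).records)
    return g


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.records.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _transcript_from_bed12(fields: Sequence[str], lineno: int) -> TranscriptModel:
    if len(fields) != 12:
        raise ValueError(f"BED12 line {lineno}: expected 12 columns, got {len(fields)}")
    contig, start, end, name, _score, strand = fields[:6]
    if strand not in {"+", "-"}:
        raise ValueError(f"BED12 line {lineno}: transcript strand must be + or -")
    gene_id, _, transcript_id = name.partition("|")
    if not transcript_id:
        gene_id = transcript_id = name
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        interval=Interval(contig, int(start), int(end), strand),
    )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _transcript_from_gtf(fields: Sequence[str], lineno: int) -> TranscriptModel | None:
    if len(fields) != 9:
        raise ValueError(f"GTF line {lineno}: expected 9 columns, got {len(fields)}")
    contig, _src, feature, start, end, _score, strand, _frame, attrs = fields
    if feature != "transcript":
        return None
    if strand not in {"+", "-"}:
        raise ValueError(f"GTF line {lineno}: transcript strand must be + or -")
    d = dict(_GTF_ATTR.findall(attrs))
    if "transcript_id" not in d:
        raise ValueError(f"GTF line {lineno}: missing transcript_id")
    # GTF is 1-based inclusive on disk
    return TranscriptModel(
        gene_id=d.get("gene_id", d["transcript_id"]),
        transcript_id=d["transcript_id"],
        interval=Interval(contig, int(start) - 1, int(end), strand),
    )


def load_transcripts(path, dialect: str = "bed12") -> list[TranscriptModel]:
    if dialect not in {"bed12", "gtf"}:
        raise ValueError(f"unsupported dialect {dialect!r}")
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed12":
                out.append(_transcript_from_bed12(fields, lineno))
            else:
                t = _transcript_from_gtf(fields, lineno)
                if t is not None:
                    out.append(t)
    return out


def write_transcripts_bed12(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            name = f"{t.gene_id}|{t.transcript_id}"
            fh.write("\t".join(map(str, [
                iv.contig, iv.start, iv.end, name, 0, iv.strand,
                iv.start, iv.end, "0,0,0", 1, iv.length, 0,
            ])) + "\n")


def read_fragments_bed(path) -> FragmentSet:
    frags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 columns")
            frags.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return FragmentSet(frags)


def write_fragments_bed(fragments: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\n")


# ---------------------------------------------------------------------------
# nascent-RNA (PRO-seq) read reduction


def proseq_read_to_active_site(read: AlignedRead) -> tuple[str, str, int]:
    """Map an aligned nascent-RNA read to its polymerase active-site base.

    The run-on protocol sequences the reverse complement of the nascent RNA,
    so the transcript strand is the opposite of the alignment strand, and the
    active site — the 3'-most engaged base of the transcript — is the read's
    5' alignment coordinate (``start`` for a plus alignment, ``end - 1`` for
    a minus alignment).
    """
    if read.strand == "+":
        return read.contig, "-", read.start
    if read.strand == "-":
        return read.contig, "+", read.end - 1
    raise ValueError("cannot place an unstranded read")


def umi_collapse(reads: Iterable[AlignedRead]) -> StrandedBaseSignal:
    """Collapse reads to unique UMIs per active-site position.

    The count at each (contig, transcript-strand, position) key is the number
    of distinct UMIs observed there; reads whose UMI contains N are dropped
    and tallied in ``signal.meta['umi_dropped']``.
    """
    seen: dict[tuple[str, str, int], set[str]] = {}
    dropped = 0
    for read in reads:
        if "N" in read.umi:
            dropped += 1
            continue
        key = proseq_read_to_active_site(read)
        seen.setdefault(key, set()).add(read.umi)
    signal = StrandedBaseSignal()
    for key, umis in seen.items():
        signal.add(*key, len(umis))
    signal.meta["umi_dropped"] = dropped
    return signal


def read_reads_tsv(path) -> list[AlignedRead]:
    """Read aligned reads from a TSV with header contig/start/end/strand/umi."""
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            reads.append(AlignedRead(
                contig=f[idx["contig"]], start=int(f[idx["start"]]),
                end=int(f[idx["end"]]), strand=f[idx["strand"]],
                umi=f[idx["umi"]]))
    return reads


# ---------------------------------------------------------------------------
# stranded bedGraph pairs


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _write_bedgraph(entries: list[tuple[str, int, float]], path) -> None:
    with open(path, "w") as fh:
        run_contig, run_start, run_end, run_val = None, None, None, None
        for contig, pos, val in entries:
            if (contig == run_contig and pos == run_end and val == run_val):
                run_end += 1
                continue
            if run_contig is not None:
                fh.write(f"{run_contig}\t{run_start}\t{run_end}\t{_format_value(run_val)}\n")
            run_contig, run_start, run_end, run_val = contig, pos, pos + 1, val
        if run_contig is not None:
            fh.write(f"{run_contig}\t{run_start}\t{run_end}\t{_format_value(run_val)}\n")


def write_stranded_track(signal: StrandedBaseSignal, prefix,
                         per_million: bool = False) -> tuple[Path, Path]:
    """Write a signal as a `.plus.bedgraph` / `.minus.bedgraph` file pair.

    With ``per_million`` every value is multiplied by 1e6 / total signal,
    the usual browser-track scaling; the unscaled form round-trips exactly.
    """
    prefix = Path(prefix)
    scale = 1.0
    if per_million:
        total = signal.total()
        if total <= 0:
            raise ValueError("cannot scale an empty signal per million")
        scale = 1e6 / total
    by_strand: dict[str, list[tuple[str, int, float]]] = {"+": [], "-": []}
    for (contig, strand, pos), val in signal.entries():
        if strand not in by_strand:
            raise ValueError("bedGraph pairs require stranded signal")
        by_strand[strand].append((contig, pos, val * scale))
    paths = (prefix.with_suffix(prefix.suffix + ".plus.bedgraph"),
             prefix.with_suffix(prefix.suffix + ".minus.bedgraph"))
    _write_bedgraph(by_strand["+"], paths[0])
    _write_bedgraph(by_strand["-"], paths[1])
    return paths


def _read_bedgraph(path, strand: str, signal: StrandedBaseSignal) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path} line {lineno}: expected 4 columns")
            contig, start, end, val = fields
            start, end, val = int(start), int(end), float(val)
            if end <= start:
                raise ValueError(f"{path} line {lineno}: end <= start")
            if val < 0:
                raise ValueError(f"{path} line {lineno}: negative value")
            if val == 0:
                continue
            if val.is_integer():
                val = int(val)
            for pos in range(start, end):
                signal.add(contig, strand, pos, val)


def read_stranded_track(prefix) -> StrandedBaseSignal:
    prefix = Path(prefix)
    signal = StrandedBaseSignal()
    _read_bedgraph(prefix.with_suffix(prefix.suffix + ".plus.bedgraph"), "+", signal)
    _read_bedgraph(prefix.with_suffix(prefix.suffix + ".minus.bedgraph"), "-", signal)
    return signal


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
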