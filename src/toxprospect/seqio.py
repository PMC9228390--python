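"""Sequence records, FASTA I/O, assembly statistics and ORF extraction.

Contigs from a de novo transcriptome assembly arrive as FASTA; downstream
stages need basic quality numbers (contig counts above/below a length
threshold, GC content, N50, total assembled bases) and, per contig, the
single longest complete open reading frame (Met-initiated, stop-terminated,
any of the six frames) as a deterministic structural-annotation step.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "AssemblyStats",
    "OrfRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "partition_by_length",
    "assembly_stats",
    "assembly_stats_tsv",
    "longest_complete_orf",
]

_STOPS = {"TAA", "TAG", "TGA"}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited token of the header).
    seq : str
        Residue string; the alphabet (nucleotide vs protein) is the
        caller's declared kind and is not auto-detected.
    source : str or None
        Optional label naming the originating assembler or set.
    """

    id: str
    seq: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblyStats:
    """Basic assembly statistics over the kept (>= threshold) partition."""

    n_ge_threshold: int
    n_lt_threshold: int
    gc_percent: float
    n50: int
    total_nt: int
    empty: bool = False  # true when no contig reached the threshold


@dataclass(frozen=True)
class OrfRecord:
    """A complete ORF: Met-initiated protein plus its coding span.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand and include the stop codon; ``frame`` is +1..+3 for the
    forward strand and -1..-3 for the reverse complement.
    """

    parent_id: str
    protein: str
    frame: int
    start: int
    end: int


def read_fasta(path: str | Path | io.TextIOBase, *, source: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Record ids are the first whitespace-delimited token of each header.
    Duplicate ids, empty sequences and sequence data before the first
    header raise :class:`FastaParseError` naming the line, so that the
    downstream redundancy accounting stays exact.
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path)
        close = True
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"empty sequence for record {cur_id!r} (header at line {cur_line})")
        records.append(SequenceRecord(cur_id, seq, source=source))

    try:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
                cur_id = header.split()[0]
                if cur_id in seen:
                    raise FastaParseError(f"duplicate FASTA id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
                cur_line = lineno
                chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(f"sequence data before first header at line {lineno}")
                chunks.append(line)
        _flush()
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path | io.TextIOBase, *, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path, "w")
        close = True
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def partition_by_length(
    records: Sequence[SequenceRecord], threshold_bp: int = 200
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, short) at a length threshold.

    A record is kept when ``len >= threshold_bp`` (boundary-length records
    stay available to downstream completeness analyses). Order is
    preserved and the two lists partition the input.
    """
    if threshold_bp < 1:
        raise ValueError("threshold_bp must be >= 1")
    kept = [r for r in records if len(r) >= threshold_bp]
    short = [r for r in records if len(r) < threshold_bp]
    return kept, short


def assembly_stats(records: Sequence[SequenceRecord], threshold_bp: int = 200) -> AssemblyStats:
    """Compute contig counts, GC%, N50 and total bases.

    GC, N50 and total_nt are computed over the kept (>= threshold)
    partition only. N50 is the largest contig length L such that contigs
    of length >= L together cover at least half of total_nt.
    """
    kept, short = partition_by_length(records, threshold_bp)
    if not kept:
        return AssemblyStats(0, len(short), 0.0, 0, 0, empty=True)
    total = sum(len(r) for r in kept)
    gc = sum(r.seq.upper().count("G") + r.seq.upper().count("C") for r in kept)
    gc_percent = 100.0 * gc / total
    lengths = sorted((len(r) for r in kept), reverse=True)
    acc = 0
    n50 = lengths[-1]
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            n50 = length
            break
    return AssemblyStats(len(kept), len(short), gc_percent, n50, total)


def assembly_stats_tsv(named_stats: dict[str, AssemblyStats], threshold_bp: int = 200) -> str:
    """Render per-assembly stats as a TSV table (assemblies as columns)."""
    names = list(named_stats)
    rows = [
        (f"Number of contigs > {threshold_bp} bp", lambda s: str(s.n_ge_threshold)),
        (f"Number of contigs < {threshold_bp} bp", lambda s: str(s.n_lt_threshold)),
        ("%GC", lambda s: f"{s.gc_percent:.2f}"),
        ("N50", lambda s: str(s.n50)),
        ("Number of nt", lambda s: str(s.total_nt)),
    ]
    lines = ["\t" + "\t".join(names)]
    for label, fmt in rows:
        lines.append(label + "\t" + "\t".join(fmt(named_stats[n]) for n in names))
    return "\n".join(lines) + "\n"


def _forward_orfs(seq: str, parent_id: str, frame_sign: int, length: int) -> list[OrfRecord]:
    """All complete ORFs on one strand of ``seq`` (already oriented 5'->3')."""
    orfs: list[OrfRecord] = []
    for offset in range(3):
        frame = frame_sign * (offset + 1)
        codons = [(i, seq[i : i + 3]) for i in range(offset, len(seq) - 2, 3)]
        start: int | None = None
        for i, codon in codons:
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                end = i + 3
                protein = str(Seq(seq[start:i]).translate())
                if frame_sign > 0:
                    fstart, fend = start, end
                else:
                    fstart, fend = length - end, length - start
                orfs.append(OrfRecord(parent_id, protein, frame, fstart, fend))
                start = None
    return orfs


def longest_complete_orf(contig: SequenceRecord) -> OrfRecord | None:
    """Find the longest Met-initiated, stop-terminated ORF over six frames.

    Equal-length ties break by frame order +1, +2, +3, -1, -2, -3, then by
    leftmost start on the scanned strand. Returns ``None`` when no complete
    ORF exists. Non-ACGT characters are rejected.
    """
    seq = contig.seq.upper()
    bad = sorted(set(seq) - set("ACGT"))
    if bad:
        raise ValueError(f"non-ACGT characters in {contig.id!r}: {', '.join(bad)}")
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    candidates = _forward_orfs(seq, contig.id, +1, length) + _forward_orfs(rc, contig.id, -1, length)
    if not candidates:
        return None
    frame_rank = {f: i for i, f in enumerate([1, 2, 3, -1, -2, -3])}

    def scan_start(o: OrfRecord) -> int:
        # leftmost start on the strand the ORF was read from
        return o.start if o.frame > 0 else length - o.end

    return min(candidates, key=lambda o: (-len(o.protein), frame_rank[o.frame], scan_start(o)))
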