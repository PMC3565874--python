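"""Shared coordinate/sequence data model and genome access.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF/GTF
readers and writers convert at the boundary (those formats are 1-based,
inclusive).  Strand is a property of features; sequence fetches apply the
reverse complement so downstream code always sees transcript-sense
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pyfaidx

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene's transcript/exon/CDS structure on a genome.

    ``exons`` maps transcript id to the ordered (genome-forward) list of
    exon intervals; ``cds`` likewise for coding segments.  ``protein`` is
    the translated product when one is attached.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    cds: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    protein: str | None = None

    def __post_init__(self) -> None:
        for tid, exs in self.exons.items():
            exs.sort(key=lambda iv: iv.start)
            for a, b in zip(exs, exs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping exons in transcript {tid} of {self.gene_id}"
                    )

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.exons)

    def span(self, transcript_id: str) -> GenomicInterval:
        exs = self.exons[transcript_id]
        return GenomicInterval(self.chrom, exs[0].start, exs[-1].end, self.strand)

    def locus(self) -> GenomicInterval:
        start = min(e[0].start for e in self.exons.values())
        end = max(e[-1].end for e in self.exons.values())
        return GenomicInterval(self.chrom, start, end, self.strand)

    def introns(self, transcript_id: str) -> list[GenomicInterval]:
        """Gaps between consecutive exons, genome-forward order."""
        exs = self.exons[transcript_id]
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(exs, exs[1:])
        ]

    def n_introns(self, transcript_id: str | None = None) -> int:
        if transcript_id is None:
            transcript_id = self.transcript_ids[0]
        return len(self.exons[transcript_id]) - 1

    def cds_span(self, transcript_id: str) -> GenomicInterval | None:
        segs = self.cds.get(transcript_id)
        if not segs:
            return None
        return GenomicInterval(
            self.chrom, segs[0].start, segs[-1].end, self.strand
        )

    def spliced_sequence(self, genome: "Genome", transcript_id: str) -> str:
        """Exon-concatenated (mRNA) sequence in transcript sense."""
        exs = self.exons[transcript_id]
        parts = [genome.fetch_forward(iv.chrom, iv.start, iv.end) for iv in exs]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_sequence(self, genome: "Genome", transcript_id: str) -> str:
        segs = self.cds.get(transcript_id)
        if not segs:
            return ""
        seq = "".join(
            genome.fetch_forward(iv.chrom, iv.start, iv.end) for iv in segs
        )
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class GapRecord:
    """One indel in an alignment.

    ``side`` names the sequence that is *missing* bases ('query' or
    'target'); ``query_pos``/``target_pos`` give the coordinate just
    before the gap on each sequence; ``length`` the number of bases the
    other sequence carries unmatched.
    """

    side: str
    query_pos: int
    target_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.side not in ("query", "target", "retro", "parent"):
            raise ValueError(f"unrecognized gap side: {self.side!r}")
        if self.length <= 0:
            raise ValueError("gap length must be positive")


@dataclass
class AlignmentBlockSet:
    """Co-linear gapped alignment of a query onto a genomic target.

    ``blocks`` is an ordered list of ``((qstart, qend), (tstart, tend))``
    pairs, monotonically increasing on the query; target coordinates
    increase for '+' alignments and decrease for '-'.  Identity is percent
    over aligned columns; coverage is the fraction of the query covered.
    """

    query_id: str
    target: GenomicInterval
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    identity: float
    coverage: float
    gaps: list[GapRecord] = field(default_factory=list)
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of [0,100]: {self.identity}")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage out of [0,1]: {self.coverage}")
        prev_q = None
        for (qs, qe), (ts, te) in self.blocks:
            if qe - qs != abs(te - ts):
                raise ValueError("block lengths differ between query and target")
            if prev_q is not None and qs < prev_q:
                raise ValueError("blocks not monotonic on query")
            prev_q = qe

    @property
    def query_span(self) -> tuple[int, int]:
        return self.blocks[0][0][0], self.blocks[-1][0][1]

    def map_query_to_target(self, qpos: int) -> int | None:
        """Target coordinate aligned to query position, None in a gap."""
        for (qs, qe), (ts, te) in self.blocks:
            if qs <= qpos < qe:
                if ts <= te:
                    return ts + (qpos - qs)
                return ts - (qpos - qs)
        return None


class Genome:
    """Random-access FASTA-backed sequence store."""

    def __init__(self, path: str):
        try:
            self._fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        except Exception as exc:  # pyfaidx raises several flavors
            raise ValueError(f"cannot read FASTA {path}: {exc}") from exc

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        if chrom not in self._fa:
            raise KeyError(f"unknown sequence {chrom!r}")
        return len(self._fa[chrom])

    def fetch_forward(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice with strict bounds checking."""
        if chrom not in self._fa:
            raise KeyError(f"unknown sequence {chrom!r}")
        n = len(self._fa[chrom])
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"slice {chrom}:{start}-{end} outside sequence of length {n}"
            )
        return str(self._fa[chrom][start:end])

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for '-' strand."""
        seq = self.fetch_forward(interval.chrom, interval.start, interval.end)
        return revcomp(seq) if interval.strand == "-" else seq


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
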