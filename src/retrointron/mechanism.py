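"""Retro-parent alignment, mechanism classification and frameshift
accounting for gained introns.

Every gained intron is explained by one of three mechanisms, resolved in
precedence order:

1. ``reverse_orientation`` — the retrogene is transcribed on the strand
   opposite to the orientation in which its locus aligns to the parent
   mRNA, so the splice boundaries only exist on the new strand;
2. ``insertion`` — the intron's sequence has no counterpart in the
   parent (it falls in a parent-side alignment gap);
3. ``intronization`` — the intron aligns to parental exonic sequence
   that was recruited as an intron after retroposition.

Intronization events are sub-classified by splice-site origin:
``substitution`` when at least one base of the boundary dinucleotides
differs from the parental counterpart, ``cryptic`` when both boundary
dinucleotides pre-existed unchanged in the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from retrointron.core import (
    AlignmentBlockSet,
    GapRecord,
    GeneModel,
    Genome,
    GenomicInterval,
    revcomp,
)

logger = logging.getLogger(__name__)

MECHANISMS = ("intronization", "insertion", "reverse_orientation")


# ---------------------------------------------------------------------------
# pairwise alignment engine
# ---------------------------------------------------------------------------

def _make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    if mode == "global-free-ends":
        # tolerate unaligned termini (poly(A) tail, flanks)
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_stats(aln) -> tuple[float, int]:
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    return identity, aligned_cols


@dataclass
class RetroParentAlignment:
    """Gapped alignment of a retrogene locus onto its parent's mRNA.

    ``retro_seq`` is the locus sequence in the retrogene's annotated
    transcript sense; ``parent_seq`` the parent mRNA (or CDS) in sense.
    ``orientation`` is 'same' when the forward retro sequence aligned
    best, 'opposite' when its reverse complement did; in the latter case
    block coordinates refer to the reverse-complemented retro frame and
    :meth:`retro_to_parent` transparently converts.
    """

    retro_seq: str
    parent_seq: str
    orientation: str
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (retro, parent)
    gaps: list[GapRecord] = field(default_factory=list)   # side: retro|parent
    identity: float = 0.0
    score: float = 0.0
    alignable: bool = True

    def _frame_pos(self, retro_pos: int) -> int:
        if self.orientation == "same":
            return retro_pos
        return len(self.retro_seq) - 1 - retro_pos

    def retro_to_parent(self, retro_pos: int) -> int | None:
        """Parent coordinate aligned to a retro (annotated-sense) position."""
        pos = self._frame_pos(retro_pos)
        for (rs, re_), (ps, pe) in self.blocks:
            if rs <= pos < re_:
                return ps + (pos - rs)
        return None

    def parent_base(self, retro_pos: int) -> str | None:
        p = self.retro_to_parent(retro_pos)
        if p is None:
            return None
        base = self.parent_seq[p]
        return revcomp(base) if self.orientation == "opposite" else base


def align_retro_parent(retro_seq: str, parent_seq: str,
                       min_score_frac: float = 0.2,
                       free_end_gaps: bool = False) -> RetroParentAlignment:
    """Global affine alignment, orientation chosen by the higher-scoring
    strand.  Scores below ``min_score_frac`` of the shorter sequence
    length yield an 'unalignable' result.

    End gaps are penalized by default: both inputs are expected to be
    trimmed to homologous spans (annotated transcript region vs. parent
    mRNA), and a true global alignment forces a short terminal exon
    across an inserted intron instead of dropping it.  Pass
    ``free_end_gaps=True`` for untrimmed loci (e.g. with poly(A) tails).
    """
    if not retro_seq or not parent_seq:
        raise ValueError("cannot align empty sequences")
    retro_seq = retro_seq.upper()
    parent_seq = parent_seq.upper()
    aligner = _make_aligner("global-free-ends" if free_end_gaps else "global")
    best = None
    for orientation, rseq in (("same", retro_seq),
                              ("opposite", revcomp(retro_seq))):
        alns = aligner.align(rseq, parent_seq)
        aln = alns[0]
        if best is None or aln.score > best[2]:
            best = (orientation, aln, aln.score)
    orientation, aln, score = best
    floor = min_score_frac * min(len(retro_seq), len(parent_seq))
    identity, _ = _alignment_stats(aln)
    r_blocks, p_blocks = aln.aligned
    blocks = [((int(r[0]), int(r[1])), (int(p[0]), int(p[1])))
              for r, p in zip(r_blocks, p_blocks)]
    gaps: list[GapRecord] = []
    for (b1, b2) in zip(blocks, blocks[1:]):
        (rs1, re1), (ps1, pe1) = b1
        (rs2, re2), (ps2, pe2) = b2
        dr = rs2 - re1
        dp = ps2 - pe1
        if dp > 0:
            gaps.append(GapRecord("retro", re1, pe1, dp))
        if dr > 0:
            gaps.append(GapRecord("parent", re1, pe1, dr))
    return RetroParentAlignment(
        retro_seq=retro_seq, parent_seq=parent_seq,
        orientation=orientation, blocks=blocks, gaps=gaps,
        identity=identity, score=score, alignable=score >= floor,
    )


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

def classify_mechanism(intron_start: int, intron_end: int,
                       alignment: RetroParentAlignment,
                       overlap_threshold: float = 0.8) -> str:
    """Mechanism label for one intron given the retro-parent alignment.

    ``intron_start``/``intron_end`` are 0-based half-open coordinates in
    the retro locus sequence, annotated transcript sense.  Precedence:
    reverse_orientation > insertion > intronization; when none of the
    three conditions is met, 'unclassified' is returned.
    """
    if not alignment.alignable:
        return "unclassified"
    if alignment.orientation == "opposite":
        return "reverse_orientation"
    length = intron_end - intron_start
    if length <= 0:
        raise ValueError("empty intron interval")
    aligned = in_gap = 0
    lo = alignment.blocks[0][0][0] if alignment.blocks else 0
    hi = alignment.blocks[-1][0][1] if alignment.blocks else 0
    for pos in range(intron_start, intron_end):
        p = alignment.retro_to_parent(pos)
        if p is not None:
            aligned += 1
        elif lo <= alignment._frame_pos(pos) < hi:
            in_gap += 1
    if in_gap / length >= overlap_threshold:
        return "insertion"
    if aligned / length >= overlap_threshold:
        return "intronization"
    logger.debug("unclassified intron: aligned=%d gap=%d len=%d",
                 aligned, in_gap, length)
    return "unclassified"


def boundary_dinucleotides(intron_start: int, intron_end: int,
                           retro_seq: str) -> tuple[str, str]:
    """(donor, acceptor) dinucleotides of an intron in a sense sequence."""
    if intron_end - intron_start < 4:
        raise ValueError("intron too short for boundary dinucleotides")
    return (retro_seq[intron_start:intron_start + 2].upper(),
            retro_seq[intron_end - 2:intron_end].upper())


def parental_boundary_dinucleotides(
        intron_start: int, intron_end: int,
        alignment: RetroParentAlignment) -> tuple[str | None, str | None]:
    """Parental counterparts of the donor/acceptor dinucleotides, or None
    for a boundary that falls in an alignment gap.  For opposite-strand
    alignments the counterparts are reported as the reverse complement of
    the parental sense sequence."""
    def dinuc(a: int, b: int) -> str | None:
        b1 = alignment.parent_base(a)
        b2 = alignment.parent_base(b)
        if b1 is None or b2 is None:
            return None
        return (b1 + b2).upper()

    donor = dinuc(intron_start, intron_start + 1)
    acceptor = dinuc(intron_end - 2, intron_end - 1)
    return donor, acceptor


def classify_splice_origin(intron_start: int, intron_end: int,
                           retro_seq: str,
                           alignment: RetroParentAlignment) -> str:
    """'substitution' | 'cryptic' | 'unresolvable' for an intronization.

    Substitution when at least one base of the donor or acceptor
    dinucleotide differs from its parental counterpart; cryptic when both
    dinucleotides are identical to the parent."""
    donor, acceptor = boundary_dinucleotides(intron_start, intron_end, retro_seq)
    p_donor, p_acceptor = parental_boundary_dinucleotides(
        intron_start, intron_end, alignment)
    if p_donor is None or p_acceptor is None:
        return "unresolvable"
    if donor != p_donor or acceptor != p_acceptor:
        return "substitution"
    return "cryptic"


def classify_boundaries(donor: str, acceptor: str) -> str:
    """'canonical GT-AG' or 'noncanonical <donor>-<acceptor>'."""
    d, a = donor.upper(), acceptor.upper()
    if len(d) != 2 or len(a) != 2:
        raise ValueError("boundary dinucleotides must be 2 bases")
    if d == "GT" and a == "AG":
        return "canonical GT-AG"
    return f"noncanonical {d}-{a}"


def is_canonical(donor: str, acceptor: str) -> bool:
    return classify_boundaries(donor, acceptor) == "canonical GT-AG"


# ---------------------------------------------------------------------------
# frameshift accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelRecord:
    """One retro-side indel near an intron.

    ``kind`` is 'insertion' (retro carries extra bases) or 'deletion'
    (retro lacks bases present in the parent); ``offset`` the distance in
    bases from the nearest intron boundary; ``length`` the indel size.
    """

    kind: str
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"indel kind must be insertion/deletion: {self.kind!r}")
        if self.length <= 0:
            raise ValueError("indel length must be positive")
        if self.offset < 0:
            raise ValueError("indel offset cannot be negative")


def frameshift_accounting(intron_length: int,
                          indels: list[IndelRecord] | None = None,
                          region: str = "ORF",
                          window: int = 100) -> tuple[int | None, str]:
    """Net coding-length change and frameshift class for an intronization.

    The intron removes ``intron_length`` bases from the coding sequence;
    nearby compensating indels (within ``window`` bases of the intron in
    the alignment) adjust the net change:

        delta = intron_length - sum(insertions) + sum(deletions)

    The event is non-frameshift iff delta is divisible by three.  Introns
    in untranslated regions are classed 'utr' with no delta.
    """
    if region.upper() == "UTR":
        return None, "utr"
    if intron_length <= 0:
        raise ValueError("intron length must be positive")
    indels = indels or []
    seen_spans: list[IndelRecord] = []
    for ind in indels:
        for other in seen_spans:
            if ind.kind == other.kind and ind.offset == other.offset:
                raise ValueError(f"ambiguous duplicate indel records at "
                                 f"offset {ind.offset}")
        seen_spans.append(ind)
    delta = intron_length
    for ind in indels:
        if ind.offset > window:
            continue
        if ind.kind == "insertion":
            delta -= ind.length
        else:
            delta += ind.length
    cls = "non_frameshift" if delta % 3 == 0 else "frameshift"
    return delta, cls


def indels_near_intron(intron_start: int, intron_end: int,
                       alignment: RetroParentAlignment,
                       window: int = 100) -> list[IndelRecord]:
    """Collect retro-side indels within ``window`` bases of an intron
    from a retro-parent alignment (the intron's own parent-side gap, if
    any, is excluded)."""
    out = []
    a = alignment._frame_pos(intron_start)
    b = alignment._frame_pos(intron_end - 1)
    lo, hi = min(a, b), max(a, b) + 1
    for gap in alignment.gaps:
        pos = gap.query_pos  # retro-frame coordinate of the gap
        if lo <= pos <= hi:
            continue  # the intron itself
        dist = min(abs(pos - lo), abs(pos - hi))
        if dist > window:
            continue
        kind = "insertion" if gap.side == "parent" else "deletion"
        out.append(IndelRecord(kind, dist, gap.length))
    return out


# ---------------------------------------------------------------------------
# seeded genome-wide search (shared with the scan and paralog tracing)
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index of a genome's forward strands."""

    def __init__(self, genome: Genome, k: int = 14):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome.chroms:
            seq = genome.fetch_forward(chrom, 0, genome.length(chrom))
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def hits(self, query: str, step: int = 4):
        for q in range(0, len(query) - self.k + 1, step):
            kmer = query[q:q + self.k].upper()
            for chrom, pos in self._index.get(kmer, ()):
                yield q, chrom, pos


def seed_and_extend(query: str, genome: Genome,
                    index: GenomeIndex | None = None,
                    query_id: str = "query",
                    k: int = 14, min_seeds: int = 2,
                    exclude: GenomicInterval | None = None,
                    margin: int = 300) -> list[AlignmentBlockSet]:
    """Find gapped local alignments of ``query`` genome-wide.

    Seeds exact k-mers on both strands, clusters them by diagonal band,
    and polishes each cluster with the affine local aligner.  Returns one
    :class:`AlignmentBlockSet` per cluster (query coordinates always in
    the original query orientation; target coordinates decrease for '-'
    strand hits).
    """
    if index is None:
        index = GenomeIndex(genome, k)
    query = query.upper()
    split_gap = 400  # seeds further apart than this start a new cluster
    results: list[AlignmentBlockSet] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for qpos, chrom, tpos in index.hits(qseq):
            by_chrom.setdefault(chrom, []).append((tpos, qpos))
        clusters: list[tuple[str, list[tuple[int, int]]]] = []
        for chrom, hits in by_chrom.items():
            hits.sort()
            current: list[tuple[int, int]] = []
            for tpos, qpos in hits:
                if current and tpos - current[-1][1] > split_gap:
                    clusters.append((chrom, current))
                    current = []
                current.append((qpos, tpos))
            if current:
                clusters.append((chrom, current))
        for chrom, seeds in clusters:
            if len(seeds) < min_seeds:
                continue
            tmin = min(t for _q, t in seeds)
            tmax = max(t for _q, t in seeds) + index.k
            lo = max(0, tmin - margin)
            hi = min(genome.length(chrom), tmax + margin)
            hit_iv = GenomicInterval(chrom, lo, hi)
            if exclude is not None and exclude.overlaps(hit_iv):
                continue
            window = genome.fetch_forward(chrom, lo, hi)
            aln = _make_aligner("local").align(window, qseq)[0]
            identity, aligned_cols = _alignment_stats(aln)
            if aligned_cols < index.k:
                continue
            t_blocks, q_blocks = aln.aligned
            if strand == "+":
                blocks = [((int(q[0]), int(q[1])), (lo + int(t[0]), lo + int(t[1])))
                          for t, q in zip(t_blocks, q_blocks)]
            else:
                L = len(query)
                blocks = [((L - int(q[1]), L - int(q[0])),
                           (lo + int(t[1]) - 1, lo + int(t[0]) - 1))
                          for t, q in zip(t_blocks, q_blocks)]
                blocks.reverse()
            q_covered = sum(qe - qs for (qs, qe), _t in blocks)
            if strand == "+":
                span_lo = blocks[0][1][0]
                span_hi = blocks[-1][1][1]
            else:
                # '-' blocks carry descending target coordinates; the
                # stored end is exclusive in the descending direction
                span_lo = min(te for _q, (_ts, te) in blocks) + 1
                span_hi = max(ts for _q, (ts, _te) in blocks) + 1
            target = GenomicInterval(chrom, span_lo, span_hi, strand)
            results.append(AlignmentBlockSet(
                query_id=query_id, target=target, blocks=blocks,
                identity=identity, coverage=q_covered / len(query),
                score=aln.score,
            ))
    # deduplicate overlapping hits, keep best score
    results.sort(key=lambda a: -(a.score or 0))
    kept: list[AlignmentBlockSet] = []
    for aln in results:
        if any(aln.target.overlap_length(k_.target) > 0.5 * len(aln.target)
               for k_ in kept):
            continue
        kept.append(aln)
    return kept


def trace_insertion_origin(insert_seq: str, genome: Genome,
                           annotation: dict[str, GeneModel] | None = None,
                           index: GenomeIndex | None = None,
                           min_identity: float = 95.0,
                           min_coverage: float = 0.70) -> list[dict]:
    """Genome-wide paralog search for an inserted intron sequence.

    Returns hits passing identity > ``min_identity`` and coverage >
    ``min_coverage``, each labelled with whether it overlaps an annotated
    intron (bears on a reverse-splicing origin)."""
    hits = seed_and_extend(insert_seq, genome, index=index,
                           query_id="insert", min_seeds=1)
    intron_ivs: list[GenomicInterval] = []
    for gene in (annotation or {}).values():
        for tid in gene.transcript_ids:
            intron_ivs.extend(gene.introns(tid))
    out = []
    for aln in hits:
        if aln.identity <= min_identity or aln.coverage <= min_coverage:
            continue
        overlaps = any(aln.target.overlaps(iv) for iv in intron_ivs)
        out.append({
            "chrom": aln.target.chrom,
            "start": min(aln.target.start, aln.target.end),
            "end": max(aln.target.start, aln.target.end),
            "strand": aln.target.strand,
            "identity": aln.identity,
            "coverage": aln.coverage,
            "overlaps_annotated_intron": overlaps,
        })
    return out
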