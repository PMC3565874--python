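"""Retrocopy candidate scanning and the filter cascade.

A candidate is a protein/CDS-to-genome alignment (externally supplied or
produced by the built-in seeded aligner).  The cascade retains a
candidate iff, in order:

1. e-value <= threshold (only when an e-value column is present);
2. identity >= 40 %;
3. query coverage >= 70 %;
4. RNA-duplication evidence: more than three parental introns absent,
   OR 1-3 introns absent together with a small Ks (< 2) to the parent or
   a downstream poly(A) tract;
5. repeat overlap of the candidate span < 50 %;
6. candidate flanks not similar to the parental flanks (DNA-duplication
   signature);
7. no candidate sub-region aligning well to a parental intron (second
   DNA-duplication signature).

The first failing step is recorded as the discard reason.  A parental
intron counts as "absent" when its two flanking exons align contiguously
(gap below a small tolerance) in the candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from retrointron.core import (
    AlignmentBlockSet,
    GeneModel,
    Genome,
    GenomicInterval,
    revcomp,
)
from retrointron.kaks import estimate_from_codon_pairs, is_stop
from retrointron.mechanism import GenomeIndex, _alignment_stats, _make_aligner, \
    seed_and_extend

logger = logging.getLogger(__name__)

FILTER_ORDER = (
    "evalue", "identity", "coverage", "duplication-evidence",
    "repeat", "flanking-similarity", "intron-alignment",
)


@dataclass(frozen=True)
class ScanThresholds:
    """Filter cascade thresholds (defaults follow the pipeline's standard
    settings: e-value 1e-10, identity 40 %, coverage 70 %, Ks < 2,
    repeat overlap < 50 %)."""

    evalue_max: float = 1e-10
    identity_min: float = 40.0
    coverage_min: float = 0.70
    introns_absent_strict: int = 3       # "> 3" clause
    ks_max: float = 2.0
    repeat_max: float = 0.5
    polya_window: int = 30
    polya_min_a: int = 12
    contiguity_gap: int = 10
    flank_len: int = 2000
    flank_identity: float = 70.0
    flank_coverage: float = 0.5
    intron_aln_identity: float = 80.0
    intron_aln_len: int = 50


@dataclass
class RetrocopyCandidate:
    """One candidate with its evidence fields and filter verdict."""

    alignment: AlignmentBlockSet
    parent_id: str
    introns_absent: int = 0
    parent_intron_count: int = 0
    ks_to_parent: float | None = None
    polya_evidence: bool = False
    repeat_overlap: float = 0.0
    flanking_similarity: bool = False
    intron_alignment: bool = False
    verdict: str = "pending"

    @property
    def retained(self) -> bool:
        return self.verdict == "retained"

    @property
    def span(self) -> GenomicInterval:
        return self.alignment.target


# ---------------------------------------------------------------------------
# evidence operations
# ---------------------------------------------------------------------------

def detect_polyA(downstream_seq: str, window: int = 30, min_a: int = 12) -> bool:
    """Poly(A) tract test on the transcript-sense sequence immediately
    downstream of the aligned 3' end; a truncated window is evaluated on
    the bases available."""
    window_seq = downstream_seq[:window].upper()
    return window_seq.count("A") >= min_a


def count_missing_introns(alignment: AlignmentBlockSet, parent: GeneModel,
                          transcript_id: str | None = None,
                          gap_tolerance: int = 10) -> int:
    """Number of parental introns absent from the candidate.

    The query is the parent's spliced CDS; an intron is absent when the
    exon junction's two sides map to adjacent target positions (gap <
    ``gap_tolerance``)."""
    tid = transcript_id or parent.transcript_ids[0]
    segs = parent.cds.get(tid) or parent.exons[tid]
    lens = [len(iv) for iv in segs]
    if parent.strand == "-":
        lens = lens[::-1]
    junctions = []
    acc = 0
    for ln in lens[:-1]:
        acc += ln
        junctions.append(acc)
    # probe a small window across each junction: gap placement at exon
    # boundaries is ambiguous by a few bases, so sampling only the two
    # adjacent positions would misread a slightly shifted intron gap
    w = 5
    absent = 0
    for j in junctions:
        left = alignment.map_query_to_target(j - w)
        right = alignment.map_query_to_target(j + w - 1)
        if left is None or right is None:
            continue
        if abs(right - left) - (2 * w - 1) < gap_tolerance:
            absent += 1
    return absent


def repeat_overlap_fraction(span: GenomicInterval,
                            repeats: list[GenomicInterval]) -> float:
    """Fraction of the candidate span covered by repeat intervals."""
    if len(span) == 0:
        return 0.0
    segs = sorted(
        (max(span.start, r.start), min(span.end, r.end))
        for r in repeats if r.overlaps(span)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(span)


def _local_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    if not seq_a or not seq_b:
        return 0.0, 0
    aln = _make_aligner("local").align(seq_a, seq_b)
    if len(seq_a) * len(seq_b) == 0:
        return 0.0, 0
    best = aln[0]
    return _alignment_stats(best)


def flanking_similarity(genome: Genome, span: GenomicInterval,
                        parent: GeneModel,
                        flank_len: int = 2000,
                        min_identity: float = 70.0,
                        min_coverage: float = 0.5) -> bool:
    """Flag candidates whose genomic flanks resemble the parental flanks
    (a DNA-duplication signature)."""
    locus = parent.locus()
    for side in ("left", "right"):
        if side == "left":
            c_iv = (max(0, span.start - flank_len), span.start)
            p_iv = (max(0, locus.start - flank_len), locus.start)
        else:
            c_iv = (span.end, min(genome.length(span.chrom), span.end + flank_len))
            p_iv = (locus.end, min(genome.length(locus.chrom), locus.end + flank_len))
        c_seq = genome.fetch_forward(span.chrom, *c_iv)
        p_seq = genome.fetch_forward(locus.chrom, *p_iv)
        if min(len(c_seq), len(p_seq)) < 100:
            continue
        identity, aligned = _local_identity(c_seq, p_seq)
        ref_len = min(len(c_seq), len(p_seq))
        if identity >= min_identity and aligned >= min_coverage * ref_len:
            return True
    return False


def intron_alignment_flag(genome: Genome, span: GenomicInterval,
                          parent: GeneModel,
                          min_identity: float = 80.0,
                          min_len: int = 50) -> bool:
    """Flag candidates containing a region that aligns well to a
    parental intron (another DNA-duplication signature)."""
    cand_seq = genome.fetch_forward(span.chrom, span.start, span.end)
    tid = parent.transcript_ids[0]
    for intron in parent.introns(tid):
        iseq = genome.fetch_forward(intron.chrom, intron.start, intron.end)
        if len(iseq) < min_len:
            continue
        for probe in (iseq, revcomp(iseq)):
            identity, aligned = _local_identity(cand_seq, probe)
            if identity >= min_identity and aligned >= min_len:
                return True
    return False


def ks_to_parent(alignment: AlignmentBlockSet, parent_cds: str,
                 genome: Genome) -> float | None:
    """Ks of the candidate against the parent CDS over gap-free,
    frame-consistent codon columns of the alignment."""
    pairs = []
    strand = alignment.target.strand
    for qstart in range(0, len(parent_cds) - 2, 3):
        tpos = [alignment.map_query_to_target(qstart + o) for o in range(3)]
        if any(t is None for t in tpos):
            continue
        step = -1 if strand == "-" else 1
        if tpos[1] - tpos[0] != step or tpos[2] - tpos[1] != step:
            continue
        if strand == "-":
            lo, hi = tpos[2], tpos[0] + 1
            t_codon = revcomp(genome.fetch_forward(alignment.target.chrom, lo, hi))
        else:
            t_codon = genome.fetch_forward(alignment.target.chrom,
                                           tpos[0], tpos[2] + 1)
        q_codon = parent_cds[qstart:qstart + 3].upper()
        if any(b not in "ACGT" for b in q_codon + t_codon):
            continue
        if is_stop(q_codon) or is_stop(t_codon):
            continue
        pairs.append((q_codon, t_codon))
    if len(pairs) < 10:
        return None
    try:
        return estimate_from_codon_pairs(pairs).ks
    except ValueError:
        return None


def downstream_sequence(alignment: AlignmentBlockSet, genome: Genome,
                        window: int = 30) -> str:
    """Transcript-sense sequence immediately downstream of the aligned
    3' end (truncated at the contig boundary)."""
    t = alignment.target
    if t.strand == "+":
        end = min(genome.length(t.chrom), t.end + window)
        return genome.fetch_forward(t.chrom, t.end, end)
    start = max(0, t.start - window)
    return revcomp(genome.fetch_forward(t.chrom, start, t.start))


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def apply_filters(candidate: RetrocopyCandidate,
                  thresholds: ScanThresholds = ScanThresholds()) -> str:
    """Evaluate the cascade in order; sets and returns the verdict."""
    t = thresholds
    aln = candidate.alignment
    verdict = "retained"
    if aln.evalue is not None and aln.evalue > t.evalue_max:
        verdict = "discarded:evalue"
    elif aln.identity < t.identity_min:
        verdict = "discarded:identity"
    elif aln.coverage < t.coverage_min:
        verdict = "discarded:coverage"
    else:
        n_absent = candidate.introns_absent
        if n_absent > t.introns_absent_strict:
            evidence_ok = True
        elif n_absent >= 1:
            ks_ok = (candidate.ks_to_parent is not None
                     and candidate.ks_to_parent < t.ks_max)
            evidence_ok = ks_ok or candidate.polya_evidence
        else:
            evidence_ok = False
        if not evidence_ok:
            verdict = "discarded:duplication-evidence"
        elif candidate.repeat_overlap >= t.repeat_max:
            verdict = "discarded:repeat"
        elif candidate.flanking_similarity:
            verdict = "discarded:flanking-similarity"
        elif candidate.intron_alignment:
            verdict = "discarded:intron-alignment"
    candidate.verdict = verdict
    return verdict


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def scan_retrocopies(genome: Genome, parents: dict[str, GeneModel],
                     thresholds: ScanThresholds = ScanThresholds(),
                     alignments: list[AlignmentBlockSet] | None = None,
                     repeats: list[GenomicInterval] | None = None,
                     index: GenomeIndex | None = None,
                     min_span: int = 100) -> list[RetrocopyCandidate]:
    """Identify retrocopy candidates of each parent and filter them.

    When ``alignments`` is None the built-in seeded aligner maps each
    parent's CDS onto the genome (the parent's own locus is excluded);
    otherwise the supplied (e.g. tBLASTn-derived) table is used, with
    query ids matching parent gene ids.
    """
    repeats = repeats or []
    candidates: list[RetrocopyCandidate] = []
    if alignments is None:
        if index is None:
            index = GenomeIndex(genome)
        alignments = []
        for gid, parent in parents.items():
            tid = parent.transcript_ids[0]
            cds = parent.cds_sequence(genome, tid) or \
                parent.spliced_sequence(genome, tid)
            hits = seed_and_extend(cds, genome, index=index, query_id=gid,
                                   exclude=parent.locus())
            alignments.extend(hits)
    for aln in alignments:
        parent = parents.get(aln.query_id)
        if parent is None:
            logger.warning("alignment query %s matches no parent — skipped",
                           aln.query_id)
            continue
        span = aln.target
        if abs(span.end - span.start) < min_span:
            continue
        tid = parent.transcript_ids[0]
        cds = parent.cds_sequence(genome, tid) or \
            parent.spliced_sequence(genome, tid)
        cand = RetrocopyCandidate(
            alignment=aln,
            parent_id=parent.gene_id,
            parent_intron_count=parent.n_introns(tid),
        )
        cand.introns_absent = count_missing_introns(
            aln, parent, tid, thresholds.contiguity_gap)
        cand.polya_evidence = detect_polyA(
            downstream_sequence(aln, genome, thresholds.polya_window),
            thresholds.polya_window, thresholds.polya_min_a)
        cand.ks_to_parent = ks_to_parent(aln, cds, genome)
        norm_span = GenomicInterval(span.chrom, min(span.start, span.end),
                                    max(span.start, span.end))
        cand.repeat_overlap = repeat_overlap_fraction(norm_span, repeats)
        cand.flanking_similarity = flanking_similarity(
            genome, norm_span, parent, thresholds.flank_len,
            thresholds.flank_identity, thresholds.flank_coverage)
        cand.intron_alignment = intron_alignment_flag(
            genome, norm_span, parent, thresholds.intron_aln_identity,
            thresholds.intron_aln_len)
        apply_filters(cand, thresholds)
        candidates.append(cand)
    return candidates
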