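"""Gained-intron detection inside retroposed spans, with transcript
(EST/mRNA junction) support.

Annotated introns overlapping a retained candidate's span are reported
per transcript (multi-transcript retrogenes yield one row per transcript
variant; variants are not collapsed).  A transcript alignment supports
an intron iff one of its junctions matches both intron boundaries
exactly and the transcript maps uniquely to the retrogene locus (its
best alignment is there, with the next-best locus at least two identity
points worse — BED12 scores are read as 10x percent identity).
"""

from __future__ import annotations

from dataclasses import dataclass

from retrointron.core import GeneModel, GenomicInterval
from retrointron.io import Bed12Record
from retrointron.scan import RetrocopyCandidate

UNIQUENESS_MARGIN = 20  # BED12 score units = 2 identity percentage points


@dataclass
class RetrogeneIntron:
    """One annotated intron inside a retroposed span."""

    retro_id: str
    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    within_retroposed_span: bool
    region: str                     # 'ORF' | 'UTR'
    transcript_support: int = 0


def _intron_region(intron: GenomicInterval, gene: GeneModel,
                   transcript_id: str) -> str:
    cds_span = gene.cds_span(transcript_id)
    if cds_span is not None and cds_span.start <= intron.start \
            and intron.end <= cds_span.end:
        return "ORF"
    return "UTR"


def find_gained_introns(candidates: list[RetrocopyCandidate],
                        annotation: dict[str, GeneModel],
                        parent_ids: set[str] | None = None
                        ) -> list[RetrogeneIntron]:
    """Report every annotated intron overlapping a retained candidate.

    ``annotation`` is the full gene set; parents themselves (and any ids
    listed in ``parent_ids``) are never reported as retrogenes.
    """
    skip = set(parent_ids or ())
    skip.update(c.parent_id for c in candidates)
    out: list[RetrogeneIntron] = []
    for cand in candidates:
        if not cand.retained:
            continue
        span = cand.span
        norm = GenomicInterval(span.chrom, min(span.start, span.end),
                               max(span.start, span.end))
        for gid, gene in annotation.items():
            if gid in skip or gene.chrom != norm.chrom:
                continue
            if not gene.locus().overlaps(norm):
                continue
            # every intron of an overlapping transcript is reported; the
            # within_retroposed_span flag records containment (a short
            # terminal exon can leave an inserted intron just outside
            # the aligned span)
            for tid in gene.transcript_ids:
                for intron in gene.introns(tid):
                    out.append(RetrogeneIntron(
                        retro_id=gid,
                        interval=intron,
                        transcript_id=tid,
                        gene_id=gid,
                        within_retroposed_span=norm.contains(intron),
                        region=_intron_region(intron, gene, tid),
                    ))
    return out


def transcript_support(intron: RetrogeneIntron,
                       transcripts: list[Bed12Record],
                       uniqueness_margin: int = UNIQUENESS_MARGIN) -> int:
    """Count uniquely mapped transcripts whose junctions match the intron
    boundaries exactly.

    Multiple BED12 records sharing a name are alternative loci of the
    same transcript; only the best-scoring locus counts, and only when
    the runner-up is at least ``uniqueness_margin`` score units worse.
    Single-block records carry no junctions and contribute nothing.
    """
    by_name: dict[str, list[Bed12Record]] = {}
    for rec in transcripts:
        by_name.setdefault(rec.name, []).append(rec)
    count = 0
    for name, records in by_name.items():
        records = sorted(records, key=lambda r: -r.score)
        best = records[0]
        if len(records) > 1 and records[1].score > best.score - uniqueness_margin:
            continue  # ambiguous mapping
        if best.chrom != intron.interval.chrom:
            continue
        for donor, acceptor in best.junctions:
            if donor == intron.interval.start and acceptor == intron.interval.end:
                count += 1
                break
    return count


def annotate_support(introns: list[RetrogeneIntron],
                     transcripts: list[Bed12Record]) -> None:
    for intron in introns:
        intron.transcript_support = transcript_support(intron, transcripts)
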