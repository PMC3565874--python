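"""Statistical comparisons, summary tables and the pipeline orchestrator.

``run_pipeline`` ties the stages together: scan -> gained-intron
detection -> mechanism classification -> frameshift accounting ->
region rate estimates -> summary report.  The statistics layer provides
the two-sample proportion test (chi-square with continuity correction,
Fisher's exact always co-reported) and the Wilcoxon rank-sum test (exact
distribution for small tie-free samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from retrointron.core import GeneModel, Genome, GenomicInterval
from retrointron.introns import (
    RetrogeneIntron,
    annotate_support,
    find_gained_introns,
)
from retrointron.kaks import CodonAlignment, kaks
from retrointron.mechanism import (
    GenomeIndex,
    RetroParentAlignment,
    align_retro_parent,
    boundary_dinucleotides,
    classify_boundaries,
    classify_mechanism,
    classify_splice_origin,
    frameshift_accounting,
    indels_near_intron,
    parental_boundary_dinucleotides,
)
from retrointron.scan import RetrocopyCandidate, ScanThresholds, scan_retrocopies

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are groups, columns are outcome yes/no."""

    a_yes: int
    a_no: int
    b_yes: int
    b_no: int
    group_labels: tuple[str, str] = ("group_a", "group_b")
    outcome_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        if min(self.a_yes, self.a_no, self.b_yes, self.b_no) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def matrix(self) -> list[list[int]]:
        return [[self.a_yes, self.a_no], [self.b_yes, self.b_no]]


def proportion_test(table: ContingencyTable) -> dict:
    """Two-sided two-sample proportion test.

    Chi-square with continuity correction is the headline p-value;
    Fisher's exact is always co-reported and flagged as preferred when
    any expected cell count is below 5."""
    m = np.asarray(table.matrix)
    if m.sum(axis=1).min() == 0 or m.sum(axis=0).min() == 0:
        raise ValueError("zero-margin contingency table")
    chi2, p_chi2, _dof, expected = stats.chi2_contingency(m, correction=True)
    _odds, p_fisher = stats.fisher_exact(m, alternative="two-sided")
    n1, n2 = m[0].sum(), m[1].sum()
    return {
        "p_chi2": float(p_chi2),
        "p_fisher": float(p_fisher),
        "prop_a": table.a_yes / n1,
        "prop_b": table.b_yes / n2,
        "min_expected": float(expected.min()),
        "prefer_fisher": bool(expected.min() < 5),
    }


def wilcoxon_rank_sum(sample_a, sample_b) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when the combined sample size is <= 20 and
    tie-free; otherwise the normal approximation with midrank tie
    handling."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "method": method,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


# ---------------------------------------------------------------------------
# classified introns
# ---------------------------------------------------------------------------

@dataclass
class GainedIntron:
    """Fully characterized gained intron."""

    intron: RetrogeneIntron
    mechanism: str
    splice_origin: str            # substitution | cryptic | n/a | unresolvable
    donor: str
    acceptor: str
    parental_donor: str | None
    parental_acceptor: str | None
    boundary_label: str
    delta: int | None
    frameshift_class: str


def classify_retrogene_introns(
        genome: Genome,
        retro_gene: GeneModel,
        parent: GeneModel,
        introns: list[RetrogeneIntron],
        frameshift_window: int = 100,
) -> tuple[list[GainedIntron], RetroParentAlignment]:
    """Classify every gained intron of one retrogene against its parent."""
    tid = retro_gene.transcript_ids[0]
    span = retro_gene.span(tid)
    sense = GenomicInterval(span.chrom, span.start, span.end, retro_gene.strand)
    retro_seq = genome.fetch(sense)
    ptid = parent.transcript_ids[0]
    parent_mrna = parent.cds_sequence(genome, ptid) or \
        parent.spliced_sequence(genome, ptid)
    alignment = align_retro_parent(retro_seq, parent_mrna)
    out: list[GainedIntron] = []
    for intron in introns:
        iv = intron.interval
        if retro_gene.strand == "+":
            a, b = iv.start - span.start, iv.end - span.start
        else:
            a, b = span.end - iv.end, span.end - iv.start
        mech = classify_mechanism(a, b, alignment)
        donor, acceptor = boundary_dinucleotides(a, b, retro_seq)
        p_donor, p_acceptor = parental_boundary_dinucleotides(a, b, alignment)
        origin = "n/a"
        if mech == "intronization":
            origin = classify_splice_origin(a, b, retro_seq, alignment)
        delta, fclass = (None, "utr")
        if intron.region == "ORF":
            indels = indels_near_intron(a, b, alignment, frameshift_window) \
                if mech == "intronization" else []
            delta, fclass = frameshift_accounting(
                b - a, indels, region="ORF", window=frameshift_window)
        out.append(GainedIntron(
            intron=intron, mechanism=mech, splice_origin=origin,
            donor=donor, acceptor=acceptor,
            parental_donor=p_donor, parental_acceptor=p_acceptor,
            boundary_label=classify_boundaries(donor, acceptor),
            delta=delta, frameshift_class=fclass,
        ))
    return out, alignment


def region_rates(alignment: RetroParentAlignment,
                 intron_frames: list[tuple[int, int]]) -> dict:
    """NG86 estimates for the intronic vs. exonic parts of a retro-parent
    alignment (frames are retro coordinates in the alignment frame)."""
    def subalign(lo: int, hi: int):
        retro_chars, parent_chars = [], []
        p_start = None
        pos = lo
        for (rs, re_), (ps, pe) in alignment.blocks:
            if re_ <= lo or rs >= hi:
                continue
            s = max(rs, lo)
            e = min(re_, hi)
            if p_start is None:
                p_start = ps + (s - rs)
            retro_chars.append(alignment_retro[s:e])
            parent_chars.append(alignment.parent_seq[ps + (s - rs):ps + (e - rs)])
        return "".join(retro_chars), "".join(parent_chars), p_start

    from retrointron.core import revcomp as _rc
    alignment_retro = alignment.retro_seq if alignment.orientation == "same" \
        else _rc(alignment.retro_seq)

    intronic = sorted(intron_frames)
    span_lo = alignment.blocks[0][0][0]
    span_hi = alignment.blocks[-1][0][1]
    exonic_frames = []
    cursor = span_lo
    for lo, hi in intronic:
        if lo > cursor:
            exonic_frames.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < span_hi:
        exonic_frames.append((cursor, span_hi))

    out = {}
    for label, frames in (("intronic-region", intronic),
                          ("exonic-region", exonic_frames)):
        r_all, p_all, p0 = "", "", None
        for lo, hi in frames:
            r, p, ps = subalign(lo, hi)
            if p0 is None:
                p0 = ps
            r_all += r
            p_all += p
        if not r_all or p0 is None:
            out[label] = None
            continue
        frame = (3 - p0 % 3) % 3
        try:
            out[label] = kaks(CodonAlignment(p_all, r_all, frame=frame,
                                             region=label))
        except ValueError:
            out[label] = None
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def summarize_intron_table(df: pd.DataFrame) -> dict:
    """Derived fractions from a per-intron table.

    Expects columns ``retrogene``, ``mechanism`` and optionally
    ``region``, ``boundary``, ``frameshift_class``.  All fractions are
    recomputed from the table's own counts."""
    total = len(df)
    summary: dict = {"total_gained_introns": total}
    if total == 0:
        return summary
    mech = df["mechanism"].str.replace("intronization_.*", "intronization",
                                       regex=True)
    n_intronized = int((mech == "intronization").sum())
    summary["intronization_count"] = n_intronized
    summary["intronization_share_pct"] = 100.0 * n_intronized / total
    summary["mechanism_counts"] = mech.value_counts().to_dict()
    sub = df[mech == "intronization"]
    if "region" in df.columns and len(sub):
        n_orf = int((sub["region"] == "ORF").sum())
        summary["orf_count_of_intronized"] = n_orf
        summary["orf_share_pct"] = 100.0 * n_orf / len(sub)
    if "boundary" in df.columns:
        canon = df["boundary"].str.startswith("canonical")
        summary["canonical_count"] = int(canon.sum())
        summary["noncanonical_pairs"] = sorted(
            df.loc[~canon, "boundary"].str.replace("noncanonical ", "").tolist())
    if "frameshift_class" in df.columns and len(sub):
        orf_sub = sub[sub["frameshift_class"] != "utr"]
        if len(orf_sub):
            n_nf = int((orf_sub["frameshift_class"] == "non_frameshift").sum())
            summary["non_frameshift_count"] = n_nf
            summary["non_frameshift_share_pct"] = 100.0 * n_nf / len(orf_sub)
    return summary


@dataclass
class PipelineReport:
    candidates: list[RetrocopyCandidate]
    gained_introns: list[GainedIntron]
    intron_table: pd.DataFrame
    retrogene_table: pd.DataFrame
    rate_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_pipeline(genome: Genome,
                 parents: dict[str, GeneModel],
                 annotation: dict[str, GeneModel],
                 transcripts=None,
                 repeats=None,
                 thresholds: ScanThresholds = ScanThresholds(),
                 alignments=None,
                 compute_rates: bool = True) -> PipelineReport:
    """Execute scan -> introns -> classify -> rates -> report."""
    index = None
    if alignments is None:
        index = GenomeIndex(genome)
    candidates = scan_retrocopies(genome, parents, thresholds,
                                  alignments=alignments, repeats=repeats,
                                  index=index)
    retained = [c for c in candidates if c.retained]
    retro_annotation = {gid: g for gid, g in annotation.items()
                        if gid not in parents}
    introns = find_gained_introns(retained, retro_annotation,
                                  parent_ids=set(parents))
    if transcripts:
        annotate_support(introns, transcripts)

    # map retro gene -> parent via the retained candidate overlapping it
    def candidate_for(gene: GeneModel) -> RetrocopyCandidate | None:
        locus = gene.locus()
        best, best_ov = None, 0
        for cand in retained:
            s = cand.span
            norm = GenomicInterval(s.chrom, min(s.start, s.end),
                                   max(s.start, s.end))
            ov = locus.overlap_length(norm)
            if ov > best_ov:
                best, best_ov = cand, ov
        return best

    by_gene: dict[str, list[RetrogeneIntron]] = {}
    for intron in introns:
        by_gene.setdefault(intron.gene_id, []).append(intron)

    gained: list[GainedIntron] = []
    rate_rows = []
    for gid, gene_introns in by_gene.items():
        gene = retro_annotation[gid]
        cand = candidate_for(gene)
        if cand is None:
            continue
        parent = parents[cand.parent_id]
        classified, alignment = classify_retrogene_introns(
            genome, gene, parent, gene_introns)
        gained.extend(classified)
        if compute_rates and alignment.alignable:
            frames = []
            span = gene.span(gene.transcript_ids[0])
            for intron in gene_introns:
                iv = intron.interval
                if gene.strand == "+":
                    a, b = iv.start - span.start, iv.end - span.start
                else:
                    a, b = span.end - iv.end, span.end - iv.start
                fa = alignment._frame_pos(a)
                fb = alignment._frame_pos(b - 1)
                frames.append((min(fa, fb), max(fa, fb) + 1))
            rates = region_rates(alignment, frames)
            row = {"retrogene": gid, "parent": parent.gene_id}
            for label, est in rates.items():
                key = "intronic" if label.startswith("intronic") else "exonic"
                row[f"ka_{key}"] = est.ka if est else None
                row[f"ks_{key}"] = est.ks if est else None
                row[f"kaks_{key}"] = est.omega if est else None
                row[f"p_{key}"] = est.p_value if est else None
                row[f"len_{key}"] = est.n_codons * 3 if est else None
            rate_rows.append(row)

    intron_table = pd.DataFrame([
        {
            "retrogene": g.intron.gene_id,
            "transcript": g.intron.transcript_id,
            "chrom": g.intron.interval.chrom,
            "start": g.intron.interval.start,
            "end": g.intron.interval.end,
            "region": g.intron.region,
            "support": g.intron.transcript_support,
            "mechanism": g.mechanism,
            "splice_origin": g.splice_origin,
            "boundary": g.boundary_label,
            "donor": g.donor,
            "acceptor": g.acceptor,
            "delta": g.delta,
            "frameshift_class": g.frameshift_class,
        }
        for g in gained
    ])

    retro_rows = []
    for cand in candidates:
        s = cand.span
        retro_rows.append({
            "query": cand.alignment.query_id,
            "parent": cand.parent_id,
            "chrom": s.chrom,
            "start": min(s.start, s.end),
            "end": max(s.start, s.end),
            "strand": s.strand,
            "identity": cand.alignment.identity,
            "coverage": cand.alignment.coverage,
            "introns_absent": cand.introns_absent,
            "ks_to_parent": cand.ks_to_parent,
            "polya": cand.polya_evidence,
            "repeat_overlap": cand.repeat_overlap,
            "verdict": cand.verdict,
        })
    retrogene_table = pd.DataFrame(retro_rows)
    rate_table = pd.DataFrame(rate_rows)

    summary = summarize_intron_table(intron_table) if len(intron_table) else {
        "total_gained_introns": 0}
    summary["n_candidates"] = len(candidates)
    summary["n_retained"] = len(retained)
    if len(rate_table) >= 2:
        for metric in ("ka", "ks"):
            a = rate_table[f"{metric}_intronic"].dropna().tolist()
            b = rate_table[f"{metric}_exonic"].dropna().tolist()
            if len(a) >= 2 and len(b) >= 2:
                summary[f"{metric}_region_contrast"] = wilcoxon_rank_sum(a, b)
    return PipelineReport(
        candidates=candidates, gained_introns=gained,
        intron_table=intron_table, retrogene_table=retrogene_table,
        rate_table=rate_table, summary=summary,
    )


# ---------------------------------------------------------------------------
# truth benchmarking (for synthetic fixtures)
# ---------------------------------------------------------------------------

def benchmark_against_truth(report: PipelineReport,
                            truth: pd.DataFrame) -> dict:
    """Recall/accuracy of a pipeline run against a simulator truth table.

    Retrocopy recall: fraction of injected (non-decoy) retrocopies whose
    locus overlaps a retained candidate.  Mechanism accuracy: fraction of
    injected intron-gain events whose reported mechanism matches the
    truth label (intronization sub-modes collapse onto 'intronization').
    Decoy rejection: fraction of DNA-duplication decoys NOT retained.
    """
    retained_spans = []
    for cand in report.candidates:
        if not cand.retained:
            continue
        s = cand.span
        retained_spans.append(GenomicInterval(
            s.chrom, min(s.start, s.end), max(s.start, s.end)))

    def hit(row) -> bool:
        iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        return any(iv.overlap_length(s) > 0.5 * len(s) for s in retained_spans)

    real = truth[~truth["is_decoy"]]
    decoys = truth[truth["is_decoy"]]
    recall = float(real.apply(hit, axis=1).mean()) if len(real) else float("nan")
    decoy_reject = float((~decoys.apply(hit, axis=1)).mean()) if len(decoys) \
        else float("nan")

    events = truth[(~truth["is_decoy"]) & (truth["mechanism"] != "none")]
    n_correct = 0
    for _, row in events.iterrows():
        want = row["mechanism"]
        if want.startswith("intronization"):
            want = "intronization"
        got = None
        for g in report.gained_introns:
            iv = g.intron.interval
            if iv.chrom == row["chrom"] and iv.start == row["intron_start"] \
                    and iv.end == row["intron_end"]:
                got = g.mechanism
                break
        if got == want:
            n_correct += 1
    accuracy = n_correct / len(events) if len(events) else float("nan")
    return {
        "retrocopy_recall": recall,
        "decoy_rejection": decoy_reject,
        "mechanism_accuracy": accuracy,
        "n_events": int(len(events)),
        "n_retrocopies": int(len(real)),
        "n_decoys": int(len(decoys)),
    }
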