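"""Splice-signal scoring: 5'SS, 3'SS, branch site (BS) and
polypyrimidine tract (PPT), with percentile conversion.

Each new intron is scored twice with the same model: once in the
retrogene context ("after" retroposition) and once over the
corresponding region of the parental gene ("before" retroposition).
Splice sites are scored as log-odds of a position-weight model against a
uniform background; the BS score is the maximum of a 7-mer weight model
over a search window upstream of the acceptor; the PPT score is a
weighted pyrimidine content/run statistic.  Raw scores are converted to
percentiles against a reference distribution of constitutive introns via
the empirical CDF (ties counted half), and the before/after comparison
operates on the sum of the four percentiles.

The shipped weight matrices are editable TSV files
(:mod:`retrointron.data`); they are declared approximations of the
splice-signal models used by percentile-scoring web services, not
reproductions of any particular calibration set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from retrointron.core import GeneModel, Genome

SIGNALS = ("bs", "ppt", "donor", "acceptor")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _load_matrix(path_or_name) -> np.ndarray:
    df = pd.read_csv(str(path_or_name), sep="\t", comment="#")
    mat = df[["A", "C", "G", "T"]].to_numpy(float)
    rows = mat.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=0.02):
        raise ValueError("weight-matrix rows must each sum to ~1")
    return mat / rows[:, None]


def _pwm_score(pwm: np.ndarray, seq: str, background: float = 0.25) -> float:
    """Sum of per-position log2 odds; non-ACGT bases contribute zero."""
    if len(seq) != pwm.shape[0]:
        raise ValueError(f"context length {len(seq)} != model width {pwm.shape[0]}")
    score = 0.0
    for i, base in enumerate(seq.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            continue
        score += math.log2(max(pwm[i, j], 1e-6) / background)
    return score


@dataclass
class SignalModel:
    """Weight models and search windows for the four splicing signals.

    ``bs_window`` and ``ppt_window`` are (near, far) distances upstream of
    the acceptor (3' end of the intron), in bases.
    """

    donor_pwm: np.ndarray
    acceptor_pwm: np.ndarray
    branch_pwm: np.ndarray
    donor_exonic: int = 3      # exonic positions of the donor model
    acceptor_exonic: int = 3   # exonic positions of the acceptor model
    bs_window: tuple[int, int] = (15, 45)
    ppt_window: tuple[int, int] = (5, 45)
    ppt_weights: dict = field(default_factory=lambda: {"T": 1.0, "C": 0.75})

    @classmethod
    def default(cls) -> "SignalModel":
        data = resources.files("retrointron.data")
        return cls(
            donor_pwm=_load_matrix(data / "donor.tsv"),
            acceptor_pwm=_load_matrix(data / "acceptor.tsv"),
            branch_pwm=_load_matrix(data / "branch.tsv"),
        )

    @classmethod
    def from_directory(cls, matrix_dir: str) -> "SignalModel":
        import os
        return cls(
            donor_pwm=_load_matrix(os.path.join(matrix_dir, "donor.tsv")),
            acceptor_pwm=_load_matrix(os.path.join(matrix_dir, "acceptor.tsv")),
            branch_pwm=_load_matrix(os.path.join(matrix_dir, "branch.tsv")),
        )

    # -- raw scores --------------------------------------------------------

    def donor_score(self, upstream_exon: str, intron: str) -> float | None:
        n_ex = self.donor_exonic
        n_in = self.donor_pwm.shape[0] - n_ex
        if len(upstream_exon) < n_ex or len(intron) < n_in:
            return None
        return _pwm_score(self.donor_pwm, upstream_exon[-n_ex:] + intron[:n_in])

    def acceptor_score(self, intron: str, downstream_exon: str) -> float | None:
        n_ex = self.acceptor_exonic
        n_in = self.acceptor_pwm.shape[0] - n_ex
        if len(intron) < n_in or len(downstream_exon) < n_ex:
            return None
        return _pwm_score(self.acceptor_pwm, intron[-n_in:] + downstream_exon[:n_ex])

    def branch_score(self, intron: str) -> float | None:
        """Max of the branch model over the search window (truncated when
        the intron is shorter than the far edge of the window)."""
        k = self.branch_pwm.shape[0]
        near, far = self.bs_window
        lo = max(0, len(intron) - far)
        hi = len(intron) - near
        if hi - lo < k:
            hi = min(len(intron), lo + k)  # truncated window fallback
        if hi - lo < k:
            return None
        return max(
            _pwm_score(self.branch_pwm, intron[s:s + k])
            for s in range(lo, hi - k + 1)
        )

    def ppt_score(self, intron: str) -> float | None:
        near, far = self.ppt_window
        window = intron[max(0, len(intron) - far): len(intron) - near].upper()
        if not window:
            return None
        w = self.ppt_weights
        content = sum(w.get(b, 0.0) for b in window) / len(window)
        run = best = 0
        for b in window:
            run = run + 1 if b in w else 0
            best = max(best, run)
        return content + best / len(window)


def score_signals(upstream_exon: str, intron: str, downstream_exon: str,
                  model: SignalModel) -> dict[str, float | None]:
    """Raw scores of the four signals for one intron with its flanks.

    All sequences are transcript-sense.  Unavailable windows propagate as
    ``None``.
    """
    return {
        "bs": model.branch_score(intron),
        "ppt": model.ppt_score(intron),
        "donor": model.donor_score(upstream_exon, intron),
        "acceptor": model.acceptor_score(intron, downstream_exon),
    }


# ---------------------------------------------------------------------------
# percentile machinery
# ---------------------------------------------------------------------------

def percentile_transform(raw: float, reference) -> float:
    """Empirical-CDF percentile in [0, 1]: fraction of reference scores
    strictly below the query, ties counted half."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    below = np.count_nonzero(ref < raw)
    equal = np.count_nonzero(ref == raw)
    return (below + 0.5 * equal) / ref.size


def build_reference(genes: dict[str, GeneModel], genome: Genome,
                    model: SignalModel) -> pd.DataFrame:
    """Raw-score table over all (constitutive) introns of a gene set."""
    rows = []
    for gene in genes.values():
        for tid in gene.transcript_ids:
            for idx in range(gene.n_introns(tid)):
                up, intron, down = intron_context(gene, tid, idx, genome)
                raw = score_signals(up, intron, down, model)
                if all(v is not None for v in raw.values()):
                    rows.append(raw)
    return pd.DataFrame(rows, columns=list(SIGNALS))


@dataclass
class SpliceSignalScores:
    """Percentile-scored signals for one intron in one context."""

    intron_id: str
    context: str                      # 'before' or 'after'
    raw: dict[str, float | None]
    percentiles: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.percentiles.values())


def percentile_scores(intron_id: str, context: str,
                      raw: dict[str, float | None],
                      reference: pd.DataFrame) -> SpliceSignalScores:
    pct = {}
    for sig in SIGNALS:
        if raw.get(sig) is None:
            pct[sig] = 0.0
        else:
            pct[sig] = percentile_transform(raw[sig], reference[sig].to_numpy())
    return SpliceSignalScores(intron_id, context, raw, pct)


def compare_before_after(sum_after: float, sum_before: float,
                         tol: float = 1e-9) -> str:
    """Verdict on the percentile sums of the two contexts."""
    diff = sum_after - sum_before
    if abs(diff) < tol:
        return "unchanged"
    return "increased" if diff > 0 else "decreased"


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

def intron_context(gene: GeneModel, transcript_id: str, intron_index: int,
                   genome: Genome, max_flank: int = 100) -> tuple[str, str, str]:
    """(upstream exon, intron, downstream exon) in transcript sense.

    ``intron_index`` counts introns 5'->3' along the transcript.
    """
    exons = list(gene.exons[transcript_id])
    introns = gene.introns(transcript_id)
    if gene.strand == "-":
        exons = exons[::-1]
        introns = introns[::-1]
    if not (0 <= intron_index < len(introns)):
        raise IndexError(f"transcript {transcript_id} has {len(introns)} introns")
    up_iv = exons[intron_index]
    dn_iv = exons[intron_index + 1]
    iv = introns[intron_index]
    up = genome.fetch(GenomicIntervalSense(up_iv, gene.strand))[-max_flank:]
    dn = genome.fetch(GenomicIntervalSense(dn_iv, gene.strand))[:max_flank]
    intron = genome.fetch(GenomicIntervalSense(iv, gene.strand))
    return up, intron, dn


def GenomicIntervalSense(iv, strand):
    """Interval re-stranded to the transcript sense."""
    from retrointron.core import GenomicInterval
    return GenomicInterval(iv.chrom, iv.start, iv.end, strand)


def neighbor_intron_contrast(gene: GeneModel, genome: Genome,
                             target_region, model: SignalModel,
                             reference: pd.DataFrame,
                             transcript_id: str | None = None,
                             flank: int = 50) -> dict:
    """Contrast a candidate (exonic) region's signal sum against the
    gene's real introns.

    Returns the target's percentile sum alongside the min and median of
    the real introns' sums.  Raises if the gene has no introns.
    """
    tid = transcript_id or gene.transcript_ids[0]
    n = gene.n_introns(tid)
    if n == 0:
        raise ValueError(f"gene {gene.gene_id} has no introns to contrast")
    sums = []
    for idx in range(n):
        up, intron, dn = intron_context(gene, tid, idx, genome)
        raw = score_signals(up, intron, dn, model)
        sums.append(percentile_scores(f"{tid}.i{idx}", "real", raw, reference).total)

    from retrointron.core import GenomicInterval
    chrom = target_region.chrom
    if gene.strand == "+":
        up_iv = GenomicInterval(chrom, max(0, target_region.start - flank),
                                target_region.start, "+")
        dn_iv = GenomicInterval(chrom, target_region.end,
                                min(genome.length(chrom), target_region.end + flank),
                                "+")
        up, dn = genome.fetch(up_iv), genome.fetch(dn_iv)
    else:
        up_iv = GenomicInterval(chrom, target_region.end,
                                min(genome.length(chrom), target_region.end + flank),
                                "-")
        dn_iv = GenomicInterval(chrom, max(0, target_region.start - flank),
                                target_region.start, "-")
        up, dn = genome.fetch(up_iv), genome.fetch(dn_iv)
    target_seq = genome.fetch(GenomicIntervalSense(target_region, gene.strand))
    raw = score_signals(up, target_seq, dn, model)
    target_sum = percentile_scores("target", "candidate", raw, reference).total
    srt = sorted(sums)
    return {
        "target_sum": target_sum,
        "intron_min": srt[0],
        "intron_median": float(np.median(srt)),
        "intron_sums": sums,
    }
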