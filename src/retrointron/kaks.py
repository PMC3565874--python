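"""Nei-Gojobori (NG86) Ka/Ks estimation on codon alignments.

The method counts, per codon, the expected numbers of synonymous (S) and
nonsynonymous (N) sites from the nine possible single-base mutations
(mutations to stop codons are excluded from numerator and denominator),
and per codon pair the observed synonymous/nonsynonymous differences
(Sd, Nd) averaged over all minimal mutational pathways that avoid stop
codons.  Proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with the one-parameter Jukes-Cantor formula

    d = -(3/4) * ln(1 - 4p/3),

undefined at saturation (p >= 3/4).  Significance of Ka != Ks uses a
normal approximation on the difference of the corrected rates, with
binomial sampling variances propagated through the correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from scipy import stats

BASES = "ACGT"

# standard genetic code, stops as '*'
from Bio.Data import CodonTable as _CodonTable

_std = _CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_std.forward_table)
for _stop in _std.stop_codons:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def is_stop(codon: str) -> bool:
    return GENETIC_CODE.get(codon.upper()) == "*"


def ng86_site_count(codon: str) -> tuple[float, float]:
    """(synonymous sites S, nonsynonymous sites N) for one codon.

    Codons containing ambiguous bases contribute zero sites.
    """
    codon = codon.upper()
    if any(b not in BASES for b in codon):
        return 0.0, 0.0
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no defined site counts")
    aa = GENETIC_CODE[codon]
    syn = nonsyn = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if is_stop(mutant):
                continue  # excluded from the denominator
            if GENETIC_CODE[mutant] == aa:
                syn += 1
            else:
                nonsyn += 1
    total = syn + nonsyn
    if total == 0:
        return 0.0, 0.0
    return 3.0 * syn / total, 3.0 * nonsyn / total


def ng86_diff_count(codon1: str, codon2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal pathways.

    For k differing positions all k! substitution orders are enumerated;
    pathways passing through a stop codon are excluded.  If every pathway
    hits a stop (possible only for some 2-3-step pairs), the average is
    taken over all pathways instead so the pair still contributes.
    """
    c1, c2 = codon1.upper(), codon2.upper()
    if any(b not in BASES for b in c1 + c2):
        return 0.0, 0.0
    if is_stop(c1) or is_stop(c2):
        raise ValueError("stop codons are not comparable")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0
        cur = c1
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if is_stop(nxt):
                hit_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur] and not is_stop(nxt) \
                    and not is_stop(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn, hit_stop

    valid, fallback = [], []
    for order in itertools.permutations(diff_pos):
        syn, nonsyn, hit_stop = walk(order)
        fallback.append((syn, nonsyn))
        if not hit_stop:
            valid.append((syn, nonsyn))
    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class CodonAlignment:
    """Two gap-aligned coding sequences read in a common frame."""

    seq1: str
    seq2: str
    frame: int = 0
    region: str = "exonic-region"

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences must have equal length")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Gap-free, unambiguous, non-stop codon column pairs."""
        s1 = self.seq1.upper()[self.frame:]
        s2 = self.seq2.upper()[self.frame:]
        pairs = []
        for i in range(0, len(s1) - 2, 3):
            c1, c2 = s1[i:i + 3], s2[i:i + 3]
            if len(c1) < 3:
                break
            if "-" in c1 or "-" in c2:
                continue
            if any(b not in BASES for b in c1 + c2):
                continue
            if is_stop(c1) or is_stop(c2):
                continue
            pairs.append((c1, c2))
        return pairs

    @property
    def length(self) -> int:
        return len(self.seq1)


@dataclass
class RateEstimate:
    """NG86 estimates for one aligned region."""

    ka: float | None
    ks: float | None
    omega: float | None            # Ka/Ks; None when Ks undefined or 0
    p_value: float | None          # test of Ka = Ks
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    region: str = ""


def _rate_variance(p: float, sites: float) -> float:
    """Sampling variance of the JC-corrected rate (delta method)."""
    if sites <= 0 or p >= 0.75:
        return float("nan")
    var_p = p * (1.0 - p) / sites
    deriv = 1.0 / (1.0 - 4.0 * p / 3.0)
    return var_p * deriv * deriv


def kaks(alignment: CodonAlignment) -> RateEstimate:
    """NG86 Ka, Ks, Ka/Ks and a normal-approximation test of Ka = Ks."""
    return estimate_from_codon_pairs(alignment.codon_pairs(),
                                     region=alignment.region)


def estimate_from_codon_pairs(pairs, region: str = "") -> RateEstimate:
    """NG86 estimate from an explicit list of aligned codon pairs."""
    if not pairs:
        raise ValueError("no usable codon columns in alignment")
    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        s1, n1 = ng86_site_count(c1)
        s2, n2 = ng86_site_count(c2)
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = ng86_diff_count(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS) if S > 0 else None
    ka = jukes_cantor(pN) if N > 0 else None

    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks

    p_value = None
    if ka is not None and ks is not None:
        var = _rate_variance(pN, N) + _rate_variance(pS, S)
        if var > 0 and math.isfinite(var):
            z = (ka - ks) / math.sqrt(var)
            p_value = 2.0 * stats.norm.sf(abs(z))
        elif ka == ks:
            p_value = 1.0
    return RateEstimate(
        ka=ka, ks=ks, omega=omega, p_value=p_value,
        n_sites=N, s_sites=S, nd=Nd, sd=Sd,
        n_codons=len(pairs), region=region,
    )


def region_contrast(values_a, values_b, label_a="intronic-region",
                    label_b="exonic-region") -> dict:
    """Two-sided Wilcoxon rank-sum comparison of per-gene rate columns."""
    a = [v for v in values_a if v is not None]
    b = [v for v in values_b if v is not None]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 estimates per region")
    method = "exact" if len(a) + len(b) <= 20 else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "mean_" + label_a: sum(a) / len(a),
        "mean_" + label_b: sum(b) / len(b),
        "p_value": float(res.pvalue),
        "n_" + label_a: len(a),
        "n_" + label_b: len(b),
    }
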