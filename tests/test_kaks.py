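"""NG86 engine against an independent brute-force oracle."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from retrointron.kaks import (
    CodonAlignment,
    SENSE_CODONS,
    jukes_cantor,
    kaks,
    ng86_diff_count,
    ng86_site_count,
    region_contrast,
)

# ---------------------------------------------------------------------------
# oracle: classify every mutation / pathway by translating with Bio.Seq
# ---------------------------------------------------------------------------


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_count(codon):
    syn = nonsyn = 0
    for pos, alt in itertools.product(range(3), "ACGT"):
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1:]
        if _aa(mutant) == "*":
            continue
        if _aa(mutant) == _aa(codon):
            syn += 1
        else:
            nonsyn += 1
    total = syn + nonsyn
    if total == 0:
        return 0.0, 0.0
    return 3 * syn / total, 3 * nonsyn / total


def oracle_diff_count(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid, fallback = [], []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, stopped = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                stopped = True
            if _aa(nxt) == _aa(cur) and _aa(nxt) != "*" and _aa(cur) != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        fallback.append((syn, nonsyn))
        if not stopped:
            valid.append((syn, nonsyn))
    paths = valid or fallback
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


# ---------------------------------------------------------------------------
# frozen examples (computed with the oracle above)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("codon, s_expected, n_expected", [
    ("TTT", 1 / 3, 8 / 3),     # Phe: only third-position T->C is synonymous
    ("ATG", 0.0, 3.0),         # Met: every mutation changes the amino acid
    ("GGG", 1.0, 2.0),         # Gly: four-fold degenerate third position
])
def test_site_counts_match_enumeration(codon, s_expected, n_expected):
    s, n = ng86_site_count(codon)
    assert s == pytest.approx(s_expected)
    assert n == pytest.approx(n_expected)
    s_o, n_o = oracle_site_count(codon)
    assert (s, n) == pytest.approx((s_o, n_o))


def test_single_synonymous_difference():
    assert ng86_diff_count("TTT", "TTC") == pytest.approx((1.0, 0.0))


def test_identical_codons_no_differences():
    assert ng86_diff_count("GCT", "GCT") == (0.0, 0.0)


def test_two_difference_pair_averages_pathways():
    # TTT -> GTA: via GTT (nonsyn) then GTA (syn), or TTA (nonsyn) then
    # GTA (nonsyn); average of (1,1) and (0,2)
    got = ng86_diff_count("TTT", "GTA")
    assert got == pytest.approx(oracle_diff_count("TTT", "GTA"))


def test_diff_counts_match_oracle_on_sample():
    rng = np.random.default_rng(42)
    idx = rng.integers(0, len(SENSE_CODONS), size=(120, 2))
    for i, j in idx:
        c1, c2 = SENSE_CODONS[i], SENSE_CODONS[j]
        assert ng86_diff_count(c1, c2) == pytest.approx(
            oracle_diff_count(c1, c2)), (c1, c2)


def test_site_counts_match_oracle_for_all_sense_codons():
    for codon in SENSE_CODONS:
        assert ng86_site_count(codon) == pytest.approx(
            oracle_site_count(codon)), codon


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def test_identical_sequences_have_zero_rates():
    est = kaks(CodonAlignment("ATGGCTAAG", "ATGGCTAAG"))
    assert est.ka == 0.0 and est.ks == 0.0


def test_saturation_is_undefined():
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None
    assert jukes_cantor(0.0) == 0.0


def test_jukes_cantor_closed_form():
    p = 0.2
    assert jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))


def test_symmetry():
    a = "ATGGCTAAGTTTGGGCCC"
    b = "ATGGCAAAATTCGGACCA"
    e1 = kaks(CodonAlignment(a, b))
    e2 = kaks(CodonAlignment(b, a))
    assert e1.ka == pytest.approx(e2.ka)
    assert e1.ks == pytest.approx(e2.ks)


def test_gapped_columns_dropped_pairwise():
    est = kaks(CodonAlignment("ATG---AAG", "ATGGCTAAG"))
    assert est.n_codons == 2


def test_no_usable_codons_errors():
    with pytest.raises(ValueError):
        kaks(CodonAlignment("---", "ATG"))


def test_parameter_recovery_under_neutrality():
    from retrointron.simulate import simulate_codon_divergence
    rng = np.random.default_rng(7)
    a, b = simulate_codon_divergence(1000, 0.2, 1.0, rng)
    est = kaks(CodonAlignment(a, b))
    assert est.omega == pytest.approx(1.0, rel=0.2)


def test_region_contrast_identical_columns():
    vals = [0.1, 0.2, 0.3, 0.4]
    res = region_contrast(vals, vals)
    assert res["p_value"] == pytest.approx(1.0)


def test_region_contrast_reports_means():
    res = region_contrast([0.5, 0.6, 0.7], [0.1, 0.2, 0.3])
    assert res["mean_intronic-region"] == pytest.approx(0.6)
    assert res["mean_exonic-region"] == pytest.approx(0.2)
    assert res["p_value"] == pytest.approx(0.1, abs=1e-9)  # exact rank-sum


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

codon_strategy = st.sampled_from(SENSE_CODONS)


@settings(derandomize=True, max_examples=200)
@given(codon_strategy)
def test_site_counts_bounded_and_complementary(codon):
    """S + N == 3 minus the stop-excluded fraction, each non-negative."""
    s, n = ng86_site_count(codon)
    assert 0.0 <= s <= 3.0 and 0.0 <= n <= 3.0
    assert s + n <= 3.0 + 1e-12
    # S + N equals 3 exactly when no mutation reaches a stop codon
    stop_reachable = any(
        _aa(codon[:pos] + alt + codon[pos + 1:]) == "*"
        for pos in range(3) for alt in "ACGT" if alt != codon[pos])
    if not stop_reachable:
        assert s + n == pytest.approx(3.0)


@settings(derandomize=True, max_examples=200)
@given(codon_strategy, codon_strategy)
def test_diff_counts_symmetric_and_bounded(c1, c2):
    """Sd + Nd equals the number of differing positions; the count is
    symmetric in its arguments."""
    sd, nd = ng86_diff_count(c1, c2)
    k = sum(a != b for a, b in zip(c1, c2))
    assert sd + nd == pytest.approx(k)
    assert ng86_diff_count(c2, c1) == pytest.approx((sd, nd))
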