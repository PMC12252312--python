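"""Panel QC tests: HWE exact test vs an enumeration oracle, allele
frequencies, composite LD r², univariate logistic association, and the
clump-and-threshold pipeline against a brute-force rule check."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from lipidprs import (
    QcThresholds,
    allele_frequency,
    clump_and_threshold,
    hwe_exact_test,
    ld_r2,
    snp_association,
)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration over all heterozygote configurations."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        aa = (na - h) // 2
        bb = (nb - h) // 2
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(na) * math.factorial(nb),
            math.factorial(aa) * math.factorial(h) * math.factorial(bb)
            * math.factorial(2 * n),
        )

    hs = range(min(na, nb) % 2, min(na, nb) + 1, 2)
    p_obs = prob(n_ab)
    return float(sum(prob(h) for h in hs if prob(h) <= p_obs))


def test_modal_configuration_gives_p_one():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_extreme_heterozygote_deficit():
    assert hwe_exact_test(50, 0, 50) < 1e-12


@pytest.mark.parametrize(
    "counts",
    [(10, 10, 10), (3, 7, 2), (0, 5, 20), (40, 20, 40), (1, 0, 1), (7, 0, 0)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=70),
    st.integers(min_value=0, max_value=70),
    st.integers(min_value=0, max_value=60),
)
def test_hwe_oracle_agreement_property(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
        hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
    )


def test_hwe_rejects_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# Allele frequency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dosages, freq, maf",
    [
        ([0, 0, 0, 0], 0.0, 0.0),
        ([2, 2, 2, 2], 1.0, 0.0),
        ([0, 1, 2, 1, np.nan], 0.5, 0.5),
        ([2, 2, 1, 1], 0.75, 0.25),
    ],
)
def test_allele_frequency(dosages, freq, maf):
    f, m = allele_frequency(dosages)
    assert f == pytest.approx(freq)
    assert m == pytest.approx(maf)


def test_allele_frequency_all_missing_rejected():
    with pytest.raises(ValueError, match="missing"):
        allele_frequency([np.nan, np.nan])


# ---------------------------------------------------------------------------
# LD r²
# ---------------------------------------------------------------------------

def test_r2_identical_vectors():
    assert ld_r2([0, 1, 2, 0, 1], [0, 1, 2, 0, 1]) == pytest.approx(1.0)


def test_r2_sign_invariance():
    assert ld_r2([0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]) == pytest.approx(1.0)


def test_r2_matches_correlation_oracle():
    a = [0, 1, 2, 0, 1, 2]
    b = [0, 2, 1, 1, 0, 2]
    assert ld_r2(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)


def test_r2_pairwise_complete():
    a = [0, 1, 2, np.nan, 1]
    b = [0, 1, 2, 2, np.nan]
    assert ld_r2(a, b) == pytest.approx(1.0)


def test_r2_zero_variance_flagged_as_zero():
    assert ld_r2([1, 1, 1, 1], [0, 1, 2, 1]) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=2), min_size=4, max_size=30),
    st.data(),
)
def test_r2_symmetric_and_bounded(a, data):
    b = data.draw(st.lists(st.integers(min_value=0, max_value=2),
                           min_size=len(a), max_size=len(a)))
    r2_ab = ld_r2(a, b)
    assert r2_ab == pytest.approx(ld_r2(b, a), abs=1e-12)
    assert -1e-12 <= r2_ab <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Univariate logistic association
# ---------------------------------------------------------------------------

def test_association_type_one_error_under_null():
    rng = np.random.default_rng(11)
    n_rep, rejections = 1000, 0
    for _ in range(n_rep):
        d = rng.binomial(2, 0.3, 5000).astype(float)
        y = rng.binomial(1, 0.3, 5000)
        _, p = snp_association(d, y)
        rejections += p < 0.05
    rate = rejections / n_rep
    band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < band


def test_association_recovers_planted_log_or():
    rng = np.random.default_rng(21)
    n = 5584
    d = rng.binomial(2, 0.3, n).astype(float)
    y = rng.binomial(1, expit(-0.8 + 0.5 * d))
    beta, p = snp_association(d, y)
    # Wald SE of the fitted beta at this n is ~0.04
    assert abs(beta - 0.5) < 2 * 0.05
    assert p < 1e-10


def test_association_constant_dosage_flagged():
    y = np.array([0, 1] * 10)
    beta, p = snp_association(np.ones(20), y)
    assert np.isnan(beta) and p == 1.0


def test_association_single_class_rejected():
    with pytest.raises(ValueError, match="single class"):
        snp_association(np.arange(20) % 3, np.zeros(20))


def test_association_too_few_subjects_rejected():
    with pytest.raises(ValueError, match="10"):
        snp_association([0, 1, 2], [0, 1, 0])


# ---------------------------------------------------------------------------
# Clump and threshold
# ---------------------------------------------------------------------------

def _five_snp_fixture(seed=9, n=4000):
    """Constructed fixture exercising every exclusion rule."""
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, 0.3, n).astype(float)
    b = np.where(rng.random(n) < 0.95, a, rng.binomial(2, 0.3, n)).astype(float)
    ind = rng.binomial(2, 0.4, n).astype(float)
    null = rng.binomial(2, 0.25, n).astype(float)
    rare = rng.binomial(2, 0.005, n).astype(float)
    het = np.ones(n)  # every subject heterozygous: gross HWE violation
    y = rng.binomial(1, expit(-0.8 + 0.5 * a + 0.6 * ind))
    geno = pd.DataFrame({"rs_a": a, "rs_b": b, "rs_ind": ind,
                         "rs_null": null, "rs_rare": rare, "rs_het": het})
    return geno, y


def _brute_force_check(geno, y, records, thresholds):
    """Re-verify every record's status from its fields and the raw data."""
    by_id = {r.rsid: r for r in records}
    for r in records:
        d = geno[r.rsid].to_numpy()
        counts = [int((d == k).sum()) for k in (0, 1, 2)]
        assert r.hwe_p == pytest.approx(hwe_exact_test(*counts), abs=1e-12)
        assert r.maf == pytest.approx(allele_frequency(d)[1], abs=1e-12)
        if r.reason == "hwe":
            assert r.hwe_p < thresholds.hwe_p_min
        elif r.reason == "maf":
            assert r.hwe_p >= thresholds.hwe_p_min
            assert r.maf < thresholds.maf_min
        elif r.reason == "pvalue":
            assert r.maf >= thresholds.maf_min
            assert (not np.isfinite(r.assoc_beta)
                    or r.assoc_p >= thresholds.assoc_p_max)
        elif r.reason == "ld":
            # must be in high LD with a retained SNP of better (p, rsid) rank
            partners = [
                s for s in records
                if s.status == "retained"
                and (s.assoc_p, s.rsid) < (r.assoc_p, r.rsid)
                and ld_r2(geno[s.rsid], geno[r.rsid]) >= thresholds.ld_r2_max
            ]
            assert partners, f"{r.rsid} excluded as ld without a retained partner"
        else:
            assert r.status == "retained"
            for s in records:
                if s.status == "retained" and s.rsid != r.rsid:
                    assert ld_r2(geno[s.rsid], geno[r.rsid]) < thresholds.ld_r2_max


def test_clump_fixture_exercises_every_rule():
    geno, y = _five_snp_fixture()
    thresholds = QcThresholds()
    records = clump_and_threshold(geno, y, thresholds)
    status = {r.rsid: (r.status, r.reason) for r in records}
    assert status["rs_rare"] == ("excluded", "maf")
    assert status["rs_null"] == ("excluded", "pvalue")
    assert status["rs_het"] == ("excluded", "hwe")
    assert status["rs_ind"] == ("retained", None)
    # exactly one of the LD pair survives — the better-ranked member
    pair = {status["rs_a"], status["rs_b"]}
    assert ("retained", None) in pair and ("excluded", "ld") in pair
    assert sum(1 for r in records if r.status == "retained") == 2
    _brute_force_check(geno, y, records, thresholds)


def test_clump_order_invariance():
    geno, y = _five_snp_fixture()
    records_fwd = clump_and_threshold(geno, y)
    shuffled = geno[list(reversed(geno.columns))]
    records_rev = clump_and_threshold(shuffled, y)
    fwd = {r.rsid: (r.status, r.reason) for r in records_fwd}
    rev = {r.rsid: (r.status, r.reason) for r in records_rev}
    assert fwd == rev


def test_all_independent_associated_snps_retained():
    rng = np.random.default_rng(31)
    n = 4000
    cols = {f"rs{i}": rng.binomial(2, 0.2 + 0.1 * i, n).astype(float)
            for i in range(4)}
    geno = pd.DataFrame(cols)
    eta = -1.0 + sum(0.4 * geno[c] for c in geno.columns)
    y = rng.binomial(1, expit(eta))
    records = clump_and_threshold(geno, y)
    assert all(r.status == "retained" for r in records)


def test_tie_broken_by_rsid():
    # identical dosage columns: identical p; lexicographically first retained
    rng = np.random.default_rng(41)
    d = rng.binomial(2, 0.3, 3000).astype(float)
    y = rng.binomial(1, expit(-0.5 + 0.5 * d))
    geno = pd.DataFrame({"rs_bbb": d.copy(), "rs_aaa": d.copy()})
    records = {r.rsid: r for r in clump_and_threshold(geno, y)}
    assert records["rs_aaa"].status == "retained"
    assert records["rs_bbb"].reason == "ld"


def test_thresholds_validated():
    with pytest.raises(ValueError, match="maf_min"):
        QcThresholds(maf_min=0.0)
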