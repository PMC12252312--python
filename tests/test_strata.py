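"""Stratified-comparison tests: Mann-Whitney exact/asymptotic paths,
chi-square, the two-axis gene-environment tables, and descriptive
summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from lipidprs import (
    ExposureEffect,
    ScoreSet,
    build_strata_table,
    chi_square_test,
    default_simspec,
    descriptive_table,
    mann_whitney_u,
    simulate_cohort,
    stratify,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mw_enumeration_oracle(x, y):
    """Two-sided exact p by full enumeration over group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    n = len(pooled)
    ranks = rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2

    mid = nx * (n - nx) / 2
    u_obs = u_of(range(nx))
    dist = abs(u_obs - mid)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(u_of(idx) - mid) >= dist - 1e-9:
            count += 1
    return count / total


def test_identical_multisets():
    x = [1.0, 2.0, 3.0, 4.0]
    U, p = mann_whitney_u(x, list(x))
    assert U == pytest.approx(len(x) * len(x) / 2)
    assert p > 0.9


def test_complete_separation_exact():
    U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert U == 0
    assert p == pytest.approx(0.1, abs=1e-12)  # 2 of C(6,3)=20 assignments


@pytest.mark.parametrize(
    "x, y",
    [
        ([1.5, 2.5, 9.0], [3.0, 4.0, 5.0, 6.0]),
        ([10.0, 20.0], [1.0, 2.0, 3.0, 30.0, 40.0]),
        ([1.0, 8.0, 9.0, 10.0], [2.0, 3.0, 4.0, 5.0]),
        ([5.0], [1.0, 2.0, 3.0]),
    ],
)
def test_exact_path_matches_enumeration_oracle(x, y):
    _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)


def test_asymptotic_path_matches_permutation_oracle():
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 1.0, 200)
    y = rng.normal(0.15, 1.0, 200)
    _, p = mann_whitney_u(x, y)
    ranks = rankdata(np.concatenate([x, y]))
    obs = ranks[:200].sum()
    mid = ranks.sum() * 200 / 400
    n_perm, count = 100_000, 0
    for _ in range(10):
        perm = rng.permuted(np.tile(ranks, (10_000, 1)), axis=1)
        s = perm[:, :200].sum(axis=1)
        count += int((np.abs(s - mid) >= abs(obs - mid) - 1e-9).sum())
    assert abs(p - count / n_perm) < 0.005


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def test_perfect_independence():
    stat, p = chi_square_test([[25, 25], [25, 25]])
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_hand_formula():
    # margins 30/30 x 30/30 -> every expected count 15
    stat, _ = chi_square_test([[10, 20], [20, 10]])
    assert stat == pytest.approx(20.0 / 3.0, abs=1e-9)


def test_type_one_error_on_null_tables():
    rng = np.random.default_rng(5)
    n_rep, rejections = 2000, 0
    for _ in range(n_rep):
        table = rng.multinomial(400, [0.25] * 4).reshape(2, 2)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        _, p = chi_square_test(table)
        rejections += p < 0.05
    band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rejections / n_rep - 0.05) < band


def test_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_test([[0, 0], [5, 5]])


def test_low_expected_count_warned():
    with pytest.warns(UserWarning, match="expected"):
        chi_square_test([[1, 9], [2, 8]])


def test_yates_correction_available():
    stat_plain, _ = chi_square_test([[10, 20], [20, 10]])
    stat_corr, _ = chi_square_test([[10, 20], [20, 10]], correction=True)
    assert stat_corr < stat_plain


# ---------------------------------------------------------------------------
# Strata tables
# ---------------------------------------------------------------------------

def _true_scores(cohort, trait):
    return stratify(ScoreSet(scores=cohort[f"score_true_{trait}"], trait_tag=trait))


def test_global_null_p_values_mostly_nonsignificant():
    spec = default_simspec(
        n_subjects=4000, seed=51,
        score_effect_hdl=0.0, score_effect_tg=0.0, exposure_effects=[],
    )
    _, cohort = simulate_cohort(spec)
    table = build_strata_table(cohort, _true_scores(cohort, "tg"), "tg")
    pvals = table.comparisons["p"].dropna()
    # ~5% of null comparisons fall below 0.05
    assert (pvals < 0.05).mean() < 0.2


def test_amplified_obesity_pattern_recovered(cohort_amplified):
    cohort, table = cohort_amplified
    comp = table.comparisons.set_index(["exposure", "axis", "context"])
    assert comp.loc[("obesity", "b", "high"), "p"] < 0.05
    assert comp.loc[("obesity", "b", "low"), "p"] < 0.05
    cells = table.cells.set_index(["exposure", "level", "risk_group"])
    # obesity raises TG in both strata, more in the high-risk stratum
    hi_gap = (cells.loc[("obesity", "BMI>=30", "high"), "mean"]
              - cells.loc[("obesity", "BMI<30", "high"), "mean"])
    lo_gap = (cells.loc[("obesity", "BMI>=30", "low"), "mean"]
              - cells.loc[("obesity", "BMI<30", "low"), "mean"])
    assert hi_gap > lo_gap > 0
    assert (cells.loc[("obesity", "BMI>=30", "high"), "mean"]
            > cells.loc[("obesity", "BMI>=30", "low"), "mean"])


def test_ceiling_smoking_pattern_recovered(cohort_amplified):
    # smoking planted with a ceiling: shifts TG only in the low stratum
    _, table = cohort_amplified
    comp = table.comparisons.set_index(["exposure", "axis", "context"])
    assert comp.loc[("smoking", "b", "low"), "p"] < 0.05
    assert comp.loc[("smoking", "b", "high"), "p"] > 0.05


@pytest.fixture(scope="module")
def cohort_amplified():
    effects = [
        ExposureEffect.amplified("tg", "obesity", 22.0, 38.0),
        ExposureEffect.ceiling("tg", "smoking", 14.0),
    ]
    spec = default_simspec(n_subjects=5584, seed=52, exposure_effects=effects)
    _, cohort = simulate_cohort(spec)
    table = build_strata_table(cohort, _true_scores(cohort, "tg"), "tg")
    return cohort, table


def test_cells_partition_cohort(cohort5584):
    _, cohort = cohort5584
    table = build_strata_table(cohort, _true_scores(cohort, "tg"), "tg")
    for exposure, group in table.cells.groupby("exposure"):
        assert group["n"].sum() == len(cohort), exposure


def test_table_invariant_to_row_order(cohort5584):
    _, cohort = cohort5584
    scores = _true_scores(cohort, "tg")
    t1 = build_strata_table(cohort, scores, "tg")
    shuffled = cohort.sample(frac=1.0, random_state=1)
    t2 = build_strata_table(shuffled, scores, "tg")
    pd.testing.assert_frame_equal(
        t1.cells.sort_values(["exposure", "level", "risk_group"]).reset_index(drop=True),
        t2.cells.sort_values(["exposure", "level", "risk_group"]).reset_index(drop=True),
    )


def test_empty_cell_marked_undefined():
    cohort = pd.DataFrame({
        "tg": np.arange(20, dtype=float) + 100,
        "smoking": [0] * 20,  # nobody smokes: smoker cells empty
        "sex": ["F"] * 20,
    })
    scores = stratify(ScoreSet(scores=pd.Series(np.arange(20, dtype=float))))
    from lipidprs import Exposure

    table = build_strata_table(
        cohort, scores, "tg",
        [Exposure("smoking", "smoking", {0: "non-smoker", 1: "smoker"})],
    )
    comp = table.comparisons.set_index(["exposure", "axis", "context"])
    assert np.isnan(comp.loc[("smoking", "a", "smoker"), "p"])
    assert "undefined" in comp.loc[("smoking", "a", "smoker"), "note"]


def test_missing_exposure_level_explicit():
    cohort = pd.DataFrame({
        "tg": np.arange(30, dtype=float) + 100,
        "wine": [0, 1, np.nan] * 10,
    })
    scores = stratify(ScoreSet(scores=pd.Series(np.arange(30, dtype=float))))
    from lipidprs import Exposure

    table = build_strata_table(
        cohort, scores, "tg",
        [Exposure("wine", "wine", {0: "none", 1: "1-3 drinks/week"})],
    )
    assert "missing" in set(table.cells["level"])
    assert table.cells["n"].sum() == 30


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------

def test_single_group_percentages_sum_to_100(cohort5584):
    _, cohort = cohort5584
    table = descriptive_table(cohort, categorical=["sex", "smoking"])
    for var, group in table.groupby("variable"):
        assert group["overall_pct"].sum() == pytest.approx(100.0)


def test_counts_match_hand_counts():
    cohort = pd.DataFrame({
        "sex": ["F", "F", "F", "M"],
        "tg": [100.0, 110.0, 120.0, 130.0],
    })
    table = descriptive_table(cohort, continuous=["tg"], categorical=["sex"])
    f_row = table[(table["variable"] == "sex") & (table["level"] == "F")].iloc[0]
    assert f_row["overall_n"] == 3
    assert f_row["overall_pct"] == pytest.approx(75.0)
    tg_row = table[table["variable"] == "tg"].iloc[0]
    assert tg_row["overall_mean"] == pytest.approx(115.0)


def test_female_fraction_on_flowchart_replica_cohort(cohort5584):
    _, cohort = cohort5584
    table = descriptive_table(cohort, categorical=["sex"])
    f_pct = table[(table["variable"] == "sex")
                  & (table["level"] == "F")]["overall_pct"].iloc[0]
    assert round(f_pct, 1) == 69.1


def test_grouped_descriptive_has_tests(cohort5584):
    _, cohort = cohort5584
    scores = _true_scores(cohort, "tg")
    table = descriptive_table(
        cohort, scores, continuous=["tg", "hdl"], categorical=["sex"]
    )
    assert set(table["test"]) <= {"mann-whitney", "chi-square", "undefined"}
    assert table["p"].notna().all()
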