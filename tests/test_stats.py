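"""Statistical battery: outlier rule, omnibus tests, pairwise contrasts,
categorical association, change scores, reliability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eddx.stats import (association_magnitude, cap_and_gap_delete,
                        chi_square, cohen_d_magnitude, cohens_d,
                        cronbach_alpha, eta_squared_magnitude,
                        fisher_exact_2x2, games_howell_contrasts,
                        gated_contrasts, one_way_anova, pairwise_categorical,
                        residual_gain, scheffe_contrasts, select_omnibus,
                        welch_anova)


# --- outlier rule -----------------------------------------------------------

def test_cap_then_gap_delete_worked_example():
    cleaned, log = cap_and_gap_delete({"g": [1, 2, 3, 50]}, cap=30)
    assert cleaned["g"].tolist() == [1, 2, 3]
    assert ("g", "capped", 30.0, 1) in log
    assert ("g", "deleted", 30.0, 1) in log


def test_gap_delete_identity_when_gap_small():
    values = [1, 2, 3, 4, 5]
    cleaned, log = cap_and_gap_delete({"g": values}, cap=100)
    assert cleaned["g"].tolist() == values and log == []


def test_gap_delete_constant_group_unchanged():
    cleaned, _ = cap_and_gap_delete({"g": [5, 5, 5, 5]}, cap=30)
    assert cleaned["g"].tolist() == [5, 5, 5, 5]


def test_gap_delete_removes_tied_block():
    cleaned, log = cap_and_gap_delete({"g": [1, 1, 2, 2, 3, 40, 40]}, cap=60)
    assert cleaned["g"].max() < 40
    assert ("g", "deleted", 40.0, 2) in log


def test_small_group_skipped_with_warning():
    with pytest.warns(UserWarning):
        cleaned, _ = cap_and_gap_delete({"g": [1, 99]}, cap=50)
    assert cleaned["g"].tolist() == [1, 50]


# --- omnibus ----------------------------------------------------------------

def test_two_group_anova_equals_pooled_t_squared(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1, 22)
    t, p = sps.ttest_ind(a, b)
    res = one_way_anova([a, b])
    assert res.statistic == pytest.approx(t ** 2, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)


def test_two_group_welch_equals_welch_t_squared(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 3, 15)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    res = welch_anova([a, b])
    assert res.statistic == pytest.approx(t ** 2, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)


def test_welch_matches_reference_implementation(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(0.5, 2.5, 25),
              "c": rng.normal(1, 0.5, 9)}
    df = pd.DataFrame([(k, v) for k, vs in groups.items() for v in vs],
                      columns=["g", "y"])
    ref = pg.welch_anova(dv="y", between="g", data=df)
    res = welch_anova(groups)
    assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), abs=1e-9)
    assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-9)


def test_identical_groups_give_null_result():
    g = [1.0, 2.0, 3.0, 4.0]
    res = one_way_anova([g, g, g])
    assert res.statistic == pytest.approx(0.0)
    assert res.effect == pytest.approx(0.0)


def test_eta_squared_magnitude_labels():
    assert eta_squared_magnitude(0.174) == "large"
    assert eta_squared_magnitude(0.07) == "medium"
    assert eta_squared_magnitude(0.042) == "small"
    assert eta_squared_magnitude(0.005) == "negligible"


def test_welch_trigger_selects_method(rng):
    hetero = {"a": rng.normal(0, 0.2, 12), "b": rng.normal(0, 4, 200),
              "c": rng.normal(0, 0.2, 14)}
    assert select_omnibus(hetero).method == "welch"
    homo = {"a": rng.normal(0, 1, 200), "b": rng.normal(0, 1, 210),
            "c": rng.normal(0, 1, 190)}
    assert select_omnibus(homo).method == "anova"
    assert select_omnibus(hetero, force="anova").method == "anova"


# --- pairwise contrasts -----------------------------------------------------

def test_identical_pair_not_significant():
    g = list(np.linspace(0, 1, 20))
    for contrast in scheffe_contrasts([g, g, list(np.array(g) + 5)]):
        if contrast.group_a == "0" and contrast.group_b == "1":
            assert contrast.p_value > 0.99
            assert contrast.cohens_d == pytest.approx(0.0)
            assert not contrast.passes_gate


def test_cohens_d_formula():
    rng = np.random.default_rng(0)
    a = rng.normal(3, 2, 50)
    b = rng.normal(2, 2, 50)
    a = (a - a.mean()) / a.std(ddof=1) * 2 + 3     # exact moments
    b = (b - b.mean()) / b.std(ddof=1) * 2 + 2
    assert cohens_d(a, b) == pytest.approx(0.5)
    assert cohens_d(a, a) == pytest.approx(0.0)
    assert cohen_d_magnitude(0.5) == "medium"


def test_cohens_d_zero_pooled_sd_errors():
    with pytest.raises(ValueError):
        cohens_d([1, 1, 1], [2, 2, 2])


def test_games_howell_matches_reference_implementation(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(0.8, 2.5, 25),
              "c": rng.normal(1.5, 0.5, 9)}
    df = pd.DataFrame([(k, v) for k, vs in groups.items() for v in vs],
                      columns=["g", "y"])
    ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
    mine = games_howell_contrasts(groups)
    for contrast, (_, row) in zip(mine, ref.iterrows()):
        assert (contrast.group_a, contrast.group_b) == (row["A"], row["B"])
        assert contrast.p_value == pytest.approx(float(row["pval"]),
                                                 abs=1e-6)


def test_scheffe_never_beats_unadjusted_pairwise_f(rng):
    groups = [rng.normal(m, 1, 20) for m in (0.0, 0.4, 1.0, 1.1)]
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n_tot - k)
    for c in scheffe_contrasts(groups):
        i, j = int(c.group_a), int(c.group_b)
        f_pair = c.mean_diff ** 2 / (msw * (1 / len(groups[i])
                                            + 1 / len(groups[j])))
        p_unadj = sps.f.sf(f_pair, 1, n_tot - k)
        assert c.p_value >= p_unadj - 1e-12


def test_dual_gate_blocks_small_effects(rng):
    # Massive n makes tiny differences significant; the d-gate must hold.
    a = rng.normal(0.00, 1, 20000)
    b = rng.normal(0.08, 1, 20000)
    c = rng.normal(0.16, 1, 20000)
    for contrast in gated_contrasts({"a": a, "b": b, "c": c}):
        assert abs(contrast.cohens_d) >= 0.5     # none should pass
    assert gated_contrasts({"a": a, "b": b, "c": c}) == []


# --- categorical ------------------------------------------------------------

@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.lists(st.integers(1, 40), min_size=2, max_size=5),
                min_size=2, max_size=4).filter(
                    lambda t: len({len(r) for r in t}) == 1))
def test_chi_square_matches_brute_force(table):
    obs = np.array(table, dtype=float)
    res = chi_square(obs)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert res.statistic == pytest.approx(
        float(((obs - expected) ** 2 / expected).sum()), rel=1e-12)
    assert res.n == int(obs.sum())


def test_chi_square_identical_proportions_zero():
    assert chi_square([[10, 20, 30], [20, 40, 60]]).statistic \
        == pytest.approx(0.0)


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError):
        chi_square([[0, 5], [0, 7]])


def test_phi_identity_on_2x2():
    table = [[30, 10], [15, 25]]
    res = chi_square(table)
    assert res.effect == pytest.approx(math.sqrt(res.statistic / res.n))


def test_fisher_requires_2x2():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


def test_pairwise_categorical_phi_and_fisher_fallback():
    # presence/absence x 3 groups; the last pair has tiny expected counts
    table = np.array([[40, 25, 1], [60, 75, 9]])
    results = pairwise_categorical(table, ["A", "B", "C"])
    assert len(results) == 3
    for r in results:
        pair = {r.group_a, r.group_b}
        sub_cols = [i for i, g in enumerate("ABC") if g in pair]
        sub = table[:, sub_cols]
        assert r.phi == pytest.approx(
            math.sqrt(chi_square(sub).statistic / sub.sum()), rel=1e-12)
        if "C" in pair:
            assert r.method == "fisher"
    assert results[0].omnibus_std_residuals.shape == (2, 3)


def test_balanced_2x2_phi_zero_negligible():
    table = np.array([[10, 10, 10], [10, 10, 10]])
    for r in pairwise_categorical(table, ["A", "B", "C"]):
        assert r.phi == pytest.approx(0.0)
        assert r.magnitude == "negligible"
        assert not r.significant


@pytest.mark.parametrize("v,label", [
    (0.05, "negligible"), (0.10, "weak"), (0.26, "moderate"),
    (0.40, "relatively strong"), (0.50, "relatively strong"),
    (0.60, "strong"), (1.0, "very strong"),
])
def test_association_magnitude_bins(v, label):
    assert association_magnitude(v) == label


def test_association_magnitude_negative_rejected():
    with pytest.raises(ValueError):
        association_magnitude(-0.1)


# --- change scores and reliability ------------------------------------------

def test_residual_gain_properties(rng):
    base = rng.normal(3, 1, 80)
    follow = 0.6 * base + rng.normal(0, 0.5, 80)
    res = residual_gain(base, follow)
    assert res.sum() == pytest.approx(0.0, abs=1e-9)
    assert np.dot(res, base) == pytest.approx(0.0, abs=1e-7)
    # exact linear relation leaves zero residuals
    assert np.allclose(residual_gain(base, 2 * base), 0.0)


def test_residual_gain_zero_baseline_variance_errors():
    with pytest.raises(ValueError):
        residual_gain([2, 2, 2, 2], [1, 2, 3, 4])


def test_residual_gain_anova_type_one_error(rng):
    """Under a no-group-effect change model, group ANOVA on residual gains
    rejects at close to the nominal 1% rate."""
    reps, hits = 400, 0
    for _ in range(reps):
        base = rng.normal(0, 1, 90)
        follow = 0.5 * base + rng.normal(0, 1, 90)
        res = residual_gain(base, follow)
        groups = [res[:30], res[30:60], res[60:]]
        if one_way_anova(groups).p_value < 0.01:
            hits += 1
    assert hits / reps < 0.035


def test_cronbach_alpha_limits(rng):
    x = rng.normal(0, 1, 300)
    assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)
    noise = rng.normal(0, 1, (2000, 4))
    assert abs(cronbach_alpha(noise)) < 0.1


def test_cronbach_alpha_parallel_items_spearman_brown(rng):
    lam, k, n = 0.7, 5, 40000
    factor = rng.normal(0, 1, n)
    items = np.column_stack([
        lam * factor + math.sqrt(1 - lam ** 2) * rng.normal(0, 1, n)
        for _ in range(k)])
    expected = k * lam ** 2 / (1 + (k - 1) * lam ** 2)
    assert cronbach_alpha(items) == pytest.approx(expected, abs=0.01)


def test_cronbach_alpha_degenerate_inputs():
    with pytest.raises(ValueError):
        cronbach_alpha([[1, 2]])
    with pytest.raises(ValueError):
        cronbach_alpha(np.ones((10, 3)))
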