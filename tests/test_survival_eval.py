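import numpy as np
import pandas as pd
import pytest

from insmark.survival_eval import (
    CoxSpec, _cnri_idi_point, _risk_to_probability, cnri_idi, compare_c,
    cox_model, harrell_c, km_estimate, random_split, rcs_basis,
    rcs_dose_response, screen_biomarkers, select_top2_per_group,
    time_dependent_auc,
)
from insmark.biomarkers import compute_panel
from insmark.synthetic import SimConfig, simulate_cohort

from conftest import random_censored_dataset


# ------------------------------------------------------------- oracles

def brute_force_c(times, events, risk):
    """O(n^2) pair enumeration: usable iff shorter time is an event."""
    conc = disc = ties = 0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = times[i], times[j]
            if ti == tj:
                if events[i] == events[j]:
                    continue  # both died together or both censored: excluded
                # tied time, one censored: the censored subject outlived the
                # event, so the event subject should carry the higher risk
                short, lng = (i, j) if events[i] else (j, i)
            else:
                short, lng = (i, j) if ti < tj else (j, i)
                if not events[short]:
                    continue
            if risk[short] > risk[lng]:
                conc += 1
            elif risk[short] < risk[lng]:
                disc += 1
            else:
                ties += 1
    return (conc + 0.5 * ties) / (conc + disc + ties)


def binary_cnri_idi(y, p_old, p_new):
    """Textbook continuous NRI and IDI for a fully observed binary outcome."""
    ev, ne = y == 1, y == 0
    up, down = p_new > p_old, p_new < p_old
    cnri = (up[ev].mean() - down[ev].mean()) + (down[ne].mean() - up[ne].mean())
    idi = (p_new[ev] - p_old[ev]).mean() - (p_new[ne] - p_old[ne]).mean()
    return cnri, idi


# ------------------------------------------------------------ Kaplan-Meier

def test_km_no_events_is_flat_one():
    km = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
    assert np.all(km.survival == 1.0)
    assert km.at(100.0) == 1.0


def test_km_four_deaths_product_limit():
    km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    assert km.at(1.0) == pytest.approx(0.75)
    assert km.at(2.0) == pytest.approx(0.50)
    assert km.at(3.5) == pytest.approx(0.25)
    assert km.at(4.0) == pytest.approx(0.0)


def test_km_hand_computed_mixed_censoring():
    # deaths at 1,3,4,6; censored at 2,5:
    # S = 5/6, 5/8, 5/12, 0 at the event times
    km = km_estimate([1.0, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
    assert km.at(1) == pytest.approx(5 / 6)
    assert km.at(3) == pytest.approx(5 / 8)
    assert km.at(4) == pytest.approx(5 / 12)
    assert km.at(6) == pytest.approx(0.0)
    assert km.at(3.99) == pytest.approx(5 / 8)  # right-continuity
    assert km.at(4, left=True) == pytest.approx(5 / 8)


def test_km_order_invariant_and_nonincreasing():
    rng = np.random.default_rng(0)
    times = rng.exponential(10, 50)
    events = (rng.random(50) > 0.3).astype(int)
    km1 = km_estimate(times, events)
    perm = rng.permutation(50)
    km2 = km_estimate(times[perm], events[perm])
    np.testing.assert_allclose(km1.survival, km2.survival)
    assert np.all(np.diff(km1.survival) <= 1e-12)


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        km_estimate([-1.0, 2.0], [1, 1])


# ------------------------------------------------------------ Harrell's C

def test_c_perfect_inverse_ordering_is_one():
    times = np.array([1.0, 2, 3, 4, 5])
    risk = np.array([5.0, 4, 3, 2, 1])
    assert harrell_c(times, np.ones(5, int), risk).c == 1.0


def test_c_constant_risk_is_half():
    times = np.array([1.0, 2, 3, 4])
    assert harrell_c(times, np.ones(4, int), np.zeros(4)).c == 0.5


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_c_equals_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    times, events, risk = random_censored_dataset(rng, 60)
    if events.sum() == 0:
        events[0] = 1
    fast = harrell_c(times, events, risk).c
    assert fast == pytest.approx(brute_force_c(times, events, risk), rel=1e-12)


def test_c_requires_events():
    with pytest.raises(ValueError):
        harrell_c([1.0, 2.0], [0, 0], [1.0, 2.0])


def test_c_bootstrap_ci_contains_point_estimate():
    rng = np.random.default_rng(5)
    times, events, risk = random_censored_dataset(rng, 120)
    res = harrell_c(times, events, risk, ci=True, n_bootstrap=100, seed=1)
    assert res.ci[0] <= res.c <= res.ci[1]


# ------------------------------------------------------------ compare_c

def test_compare_identical_scores_zero_delta_large_p():
    rng = np.random.default_rng(2)
    times, events, risk = random_censored_dataset(rng, 100)
    res = compare_c(times, events, risk, risk, n_bootstrap=100, seed=3)
    assert res.delta == 0.0
    assert res.p_value > 0.5


def test_compare_antisymmetry():
    rng = np.random.default_rng(3)
    times, events, risk = random_censored_dataset(rng, 100)
    other = risk + rng.normal(0, 0.5, 100)
    ab = compare_c(times, events, risk, other, n_bootstrap=50, seed=1)
    ba = compare_c(times, events, other, risk, n_bootstrap=50, seed=1)
    assert ab.delta == pytest.approx(-ba.delta, abs=1e-12)


def test_compare_added_signal_improves_c():
    """A score incorporating extra true signal wins in most replicates."""
    rng = np.random.default_rng(4)
    wins = 0
    reps = 40
    for _ in range(reps):
        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        lp = 0.5 * x1 + 0.7 * x2
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(1.5, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        res = compare_c(times, events, x1, x1 + 1.4 * x2,
                        n_bootstrap=10, seed=0)
        wins += res.delta > 0
    assert wins >= 0.9 * reps


def test_compare_mismatched_lengths():
    with pytest.raises(ValueError):
        compare_c([1.0, 2], [1, 1], [1.0, 2], [1.0])


# ------------------------------------------------------------- cNRI / IDI

def test_cnri_idi_identical_scores_are_zero():
    rng = np.random.default_rng(6)
    n = 200
    times = rng.exponential(40, n)
    events = (rng.random(n) > 0.3).astype(int)
    risk = rng.normal(size=n)
    res = cnri_idi(times, events, risk, risk, horizon=20.0)
    assert res.cnri == pytest.approx(0.0, abs=1e-12)
    assert res.idi == pytest.approx(0.0, abs=1e-12)


def test_cnri_idi_uncensored_reduces_to_binary_form():
    rng = np.random.default_rng(7)
    n = 300
    times = rng.exponential(30, n)
    events = np.ones(n, int)  # fully observed
    horizon = float(np.median(times))
    r_old = rng.normal(size=n)
    r_new = r_old + rng.normal(0, 1, n)
    p_old = _risk_to_probability(times, events, r_old, horizon)
    p_new = _risk_to_probability(times, events, r_new, horizon)
    got_cnri, got_idi = _cnri_idi_point(times, events, p_old, p_new, horizon)
    y = (times <= horizon).astype(int)
    exp_cnri, exp_idi = binary_cnri_idi(y, p_old, p_new)
    assert got_cnri == pytest.approx(exp_cnri, rel=1e-10)
    assert got_idi == pytest.approx(exp_idi, rel=1e-10)


def test_cnri_idi_better_model_positive_idi():
    rng = np.random.default_rng(8)
    pos = 0
    reps = 30
    for _ in range(reps):
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        lp = 0.4 * x1 + 0.8 * x2
        t = 30 * rng.exponential(np.exp(-lp))
        c = rng.uniform(10, 80, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        res = cnri_idi(times, events, x1, x1 + 2 * x2, horizon=25.0)
        pos += res.idi > 0
    assert pos >= 0.95 * reps


def test_cnri_idi_horizon_beyond_followup_rejected():
    with pytest.raises(ValueError, match="horizon"):
        cnri_idi([1.0, 2, 3], [1, 1, 1], [1.0, 2, 3], [3.0, 2, 1], horizon=10.0)


# ----------------------------------------------------- time-dependent AUC

def test_auc_perfect_separation_is_one():
    times = np.array([1.0, 2, 3, 50, 60, 70])
    events = np.array([1, 1, 1, 0, 0, 0])
    risk = np.array([10.0, 9, 8, 1, 2, 3])
    assert time_dependent_auc(times, events, risk, 10.0) == pytest.approx(1.0)


def test_auc_uncensored_equals_plain_rank_auc():
    rng = np.random.default_rng(9)
    n = 250
    times = rng.exponential(30, n)
    events = np.ones(n, int)
    risk = -times + rng.normal(0, 10, n)
    t = float(np.median(times))
    got = time_dependent_auc(times, events, risk, t)
    cases, controls = risk[times <= t], risk[times > t]
    cmp_ = (cases[:, None] > controls[None, :]) + 0.5 * (
        cases[:, None] == controls[None, :])
    assert got == pytest.approx(cmp_.mean(), rel=1e-12)


def test_auc_independent_risk_near_half():
    rng = np.random.default_rng(10)
    n = 1000
    times = rng.exponential(30, n)
    events = (rng.random(n) > 0.25).astype(int)
    risk = rng.normal(size=n)
    auc = time_dependent_auc(times, events, risk, 20.0)
    assert abs(auc - 0.5) < 0.06


def test_auc_matches_sksurv_cumulative_dynamic():
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv
    rng = np.random.default_rng(11)
    n = 400
    lp = rng.normal(size=n)
    t = 30 * rng.exponential(np.exp(-lp))
    c = rng.uniform(10, 90, n)
    times, events = np.minimum(t, c), (t <= c).astype(bool)
    y = Surv.from_arrays(event=events, time=times)
    ref, _ = cumulative_dynamic_auc(y, y, lp, [25.0])
    got = time_dependent_auc(times, events.astype(int), lp, 25.0)
    assert got == pytest.approx(float(ref[0]), abs=0.02)


def test_auc_requires_cases_and_controls():
    with pytest.raises(ValueError):
        time_dependent_auc([50.0, 60], [0, 0], [1.0, 2], 10.0)


# ------------------------------------------------------------------- Cox

def test_cox_binary_exposure_recovery():
    rng = np.random.default_rng(12)
    n = 2000
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-np.log(2.0) * x) * 40)
    c = rng.uniform(10, 120, n)
    df = pd.DataFrame({"os_time": np.minimum(t, c), "event": (t <= c).astype(int),
                       "stratum": x})
    rep = cox_model(df, CoxSpec(exposure="stratum", reference=0.0))
    hr = rep.hr_table.loc[1.0, "HR"]
    assert 1.7 < hr < 2.3
    assert rep.p_trend < 1e-6


def test_cox_adjustment_removes_confounding():
    rng = np.random.default_rng(13)
    n = 3000
    confounder = rng.normal(size=n)
    exposure = (confounder + rng.normal(0, 0.7, n) > 0).astype(float)
    # true exposure effect null; confounder drives hazard
    t = rng.exponential(np.exp(-0.9 * confounder) * 40)
    c = rng.uniform(10, 120, n)
    df = pd.DataFrame({"os_time": np.minimum(t, c),
                       "event": (t <= c).astype(int),
                       "stratum": exposure, "age": confounder})
    crude = cox_model(df, CoxSpec(reference=0.0)).hr_table.loc[1.0, "HR"]
    adj = cox_model(df, CoxSpec(reference=0.0, adjustment=["age"])
                    ).hr_table.loc[1.0, "HR"]
    assert abs(np.log(adj)) < abs(np.log(crude))
    assert abs(np.log(adj)) < 0.15


def test_cox_constant_exposure_rejected():
    df = pd.DataFrame({"os_time": [1.0, 2, 3], "event": [1, 1, 1],
                       "stratum": [1, 1, 1]})
    with pytest.raises(ValueError, match="constant"):
        cox_model(df)


def test_cox_few_events_warns():
    rng = np.random.default_rng(14)
    n = 40
    df = pd.DataFrame({"os_time": rng.exponential(10, n),
                       "event": np.r_[np.ones(5, int), np.zeros(n - 5, int)],
                       "stratum": (rng.random(n) > 0.5).astype(float)})
    with pytest.warns(UserWarning, match="events"):
        cox_model(df, CoxSpec(reference=0.0))


# ------------------------------------------------------------------- RCS

def test_rcs_basis_has_k_minus_one_columns():
    x = np.linspace(0, 10, 50)
    assert rcs_basis(x, [1.0, 5.0, 9.0]).shape == (50, 2)
    assert rcs_basis(x, [1.0, 3.0, 6.0, 9.0]).shape == (50, 3)


def test_rcs_basis_linear_tails():
    # below the first knot every nonlinear column is exactly zero
    x = np.linspace(-5, 0.5, 20)
    B = rcs_basis(x, [1.0, 5.0, 9.0])
    np.testing.assert_allclose(B[:, 1], 0.0, atol=1e-12)


def test_rcs_detects_u_shaped_effect():
    rng = np.random.default_rng(15)
    hits = 0
    reps = 10
    for _ in range(reps):
        n = 2000
        x = rng.uniform(-2, 2, n)
        lp = 0.8 * x ** 2
        t = rng.exponential(np.exp(-lp) * 30)
        c = rng.uniform(5, 90, n)
        res = rcs_dose_response(x, np.minimum(t, c), (t <= c).astype(int))
        hits += res.p_nonlinear < 0.05
    assert hits >= 0.8 * reps


def test_rcs_too_few_distinct_values():
    with pytest.raises(ValueError, match="distinct"):
        rcs_dose_response([1.0, 1.0, 2.0], [1.0, 2, 3], [1, 1, 1])


def test_rcs_curve_zero_at_median():
    rng = np.random.default_rng(16)
    n = 500
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.5 * x) * 30)
    c = rng.uniform(5, 90, n)
    res = rcs_dose_response(x, np.minimum(t, c), (t <= c).astype(int))
    at_med = np.interp(np.median(x), res.grid, res.log_hr)
    assert abs(at_med) < 1e-3  # grid interpolation accuracy


# ------------------------------------------------------------- screening

def test_screen_correlation_symmetric_unit_diagonal(medium_cohort):
    cohort, _ = medium_cohort
    panel = compute_panel(cohort)
    res = screen_biomarkers(panel, cohort.data["os_time"], cohort.data["event"],
                            use_lasso=False)
    corr = res.correlation
    np.testing.assert_allclose(np.diag(corr), 1.0)
    np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
    assert set(res.c_table["group"]) == {"inflammation", "nutrition"}


def test_screen_signal_biomarker_ranks_first():
    rng = np.random.default_rng(17)
    firsts = 0
    reps = 20
    for _ in range(reps):
        n = 300
        signal = rng.normal(size=n)
        noise = rng.normal(size=(n, 3))
        t = rng.exponential(np.exp(-signal) * 30)
        c = rng.uniform(5, 90, n)
        panel = pd.DataFrame(np.column_stack([signal, noise]),
                             columns=["sig", "n1", "n2", "n3"])
        res = screen_biomarkers(panel, np.minimum(t, c), (t <= c).astype(int),
                                groups={k: "inflammation" for k in panel},
                                use_lasso=False)
        firsts += res.c_table["c"].idxmax() == "sig"
    assert firsts >= 0.95 * reps


def test_lasso_drops_duplicated_column():
    rng = np.random.default_rng(18)
    n = 500
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.8 * x) * 30)
    c = rng.uniform(5, 90, n)
    panel = pd.DataFrame({"a": x, "a_copy": x, "z": z})
    res = screen_biomarkers(panel, np.minimum(t, c), (t <= c).astype(int),
                            groups={k: "inflammation" for k in panel},
                            use_lasso=True, seed=0)
    assert sum(name in res.lasso_retained for name in ("a", "a_copy")) <= 1


def test_all_missing_biomarker_excluded_with_warning():
    rng = np.random.default_rng(19)
    n = 200
    panel = pd.DataFrame({"a": rng.normal(size=n), "b": np.nan,
                          "c": rng.normal(size=n)})
    t = rng.exponential(30, n)
    with pytest.warns(UserWarning, match="entirely missing"):
        res = screen_biomarkers(panel, t, np.ones(n, int),
                                groups={k: "nutrition" for k in panel},
                                use_lasso=False)
    assert "b" not in res.c_table.index


# ----------------------------------------------------------- top-2 / split

def _ctable(rows):
    return pd.DataFrame(rows).set_index("index")


def test_select_top2_mirrors_reported_ordering():
    rows = [
        {"index": "LCR", "group": "inflammation", "c": 0.652},
        {"index": "CAR", "group": "inflammation", "c": 0.649},
        {"index": "NLR", "group": "inflammation", "c": 0.623},
        {"index": "ALI", "group": "nutrition", "c": 0.643},
        {"index": "NRI", "group": "nutrition", "c": 0.623},
        {"index": "PNI", "group": "nutrition", "c": 0.620},
    ]
    assert set(select_top2_per_group(_ctable(rows))) == {"LCR", "CAR", "ALI", "NRI"}


def test_select_top2_tie_falls_back_to_registry_order():
    rows = [{"index": n, "group": "inflammation", "c": 0.6}
            for n in ("NLR", "LCR", "CAR")]
    rows += [{"index": n, "group": "nutrition", "c": 0.6}
             for n in ("PNI", "ALI")]
    with pytest.warns(UserWarning, match="tied"):
        sel = select_top2_per_group(_ctable(rows))
    assert sel == ("LCR", "CAR", "ALI", "PNI")  # registry order breaks ties


def test_select_top2_exactly_two_per_group_returns_all():
    rows = [{"index": "LCR", "group": "inflammation", "c": 0.6},
            {"index": "CAR", "group": "inflammation", "c": 0.5},
            {"index": "ALI", "group": "nutrition", "c": 0.7},
            {"index": "NRI", "group": "nutrition", "c": 0.4}]
    assert set(select_top2_per_group(_ctable(rows))) == {"LCR", "CAR", "ALI", "NRI"}


def test_select_top2_requires_two_per_group():
    rows = [{"index": "LCR", "group": "inflammation", "c": 0.6},
            {"index": "ALI", "group": "nutrition", "c": 0.7}]
    with pytest.raises(ValueError, match="fewer than 2"):
        select_top2_per_group(_ctable(rows))


def test_random_split_sizes_and_partition(small_cohort):
    cohort, _ = small_cohort
    a, b = random_split(cohort, ratio=0.7, seed=5)
    assert len(a) == round(0.7 * len(cohort))
    assert len(a) + len(b) == len(cohort)
    ids_a, ids_b = set(a.data["patient_id"]), set(b.data["patient_id"])
    assert not (ids_a & ids_b)
    assert ids_a | ids_b == set(cohort.data["patient_id"])


def test_random_split_reproducible(small_cohort):
    cohort, _ = small_cohort
    a1, _ = random_split(cohort, seed=9)
    a2, _ = random_split(cohort, seed=9)
    assert (a1.data["patient_id"] == a2.data["patient_id"]).all()


def test_random_split_ten_patients():
    cohort, _ = simulate_cohort(SimConfig(n=10), seed=1)
    a, b = random_split(cohort, ratio=0.7, seed=0)
    assert (len(a), len(b)) == (7, 3)
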