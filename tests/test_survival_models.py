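"""Cox partial likelihood, Kaplan-Meier, log-rank, PH diagnostics."""

import numpy as np
import pandas as pd
import pytest

from albumin_mr.survival_models import (
    CoxConvergenceError,
    CoxRankError,
    SurvivalData,
    adjusted_survival_curves,
    fit_cox,
    kaplan_meier,
    log_rank_test,
    ph_supremum_test,
)
from albumin_mr.calibration import (
    KM_FIXTURE,
    _km_longhand,
    _logrank_longhand,
    brute_force_cox_1d,
)


def _random_survival(n=400, seed=1, b=(-0.5, 0.3), grid=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"x": rng.normal(size=n), "z": rng.binomial(1, 0.4, n).astype(float)}
    )
    t = rng.exponential(10.0, n) * np.exp(-(b[0] * X["x"] + b[1] * X["z"]))
    e = rng.random(n) < 0.7
    if grid:
        t = np.ceil(t / grid) * grid
    return pd.DataFrame({"t": t, "e": e.astype(int)}).join(X)


# ---------------------------------------------------------------------------
# Cox fitting

def test_cox_matches_brute_force_partial_likelihood():
    rng = np.random.default_rng(3)
    for _ in range(3):
        n = 10
        x = np.round(rng.normal(size=n), 3)
        t = np.round(rng.exponential(10, n) * np.exp(-0.5 * x), 3)
        e = rng.random(n) < 0.7
        if not e.any():
            e[0] = True
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        fit = fit_cox(df, "t", "e", ["x"], ties="breslow")
        oracle = brute_force_cox_1d(t, e, x, "breslow")
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-4)


def test_breslow_equals_efron_without_ties():
    df = _random_survival(seed=4)
    assert len(np.unique(df["t"])) == len(df)
    fb = fit_cox(df, "t", "e", ["x", "z"], ties="breslow")
    fe = fit_cox(df, "t", "e", ["x", "z"], ties="efron")
    np.testing.assert_allclose(fb.coef, fe.coef, atol=1e-10)
    np.testing.assert_allclose(fb.se, fe.se, atol=1e-10)


def test_cox_agrees_with_lifelines_on_tied_grid_data():
    """Independent cross-check: lifelines implements the Efron
    approximation, which our Efron path must reproduce on heavily tied
    visit-grid times."""
    from lifelines import CoxPHFitter

    df = _random_survival(n=500, seed=5, grid=5.0)
    ours = fit_cox(df, "t", "e", ["x", "z"], ties="efron")
    cph = CoxPHFitter().fit(df[["t", "e", "x", "z"]], "t", "e")
    np.testing.assert_allclose(ours.coef, cph.params_.values, atol=1e-6)
    np.testing.assert_allclose(ours.se, cph.standard_errors_.values, atol=1e-6)
    ci = ours.ci
    np.testing.assert_allclose(ci[:, 0], np.exp(ours.coef - 1.959964 * ours.se))


def test_cox_local_maximum_property():
    df = _random_survival(seed=6)
    data = SurvivalData.from_frame(df, "t", "e", ["x", "z"])
    fit = fit_cox(data)
    from albumin_mr.survival_models import _cox_quantities, _prepare

    X = data.covariates.to_numpy() - fit.cov_means
    time, event, Xs, _ = _prepare(data.time, data.event, X)
    ll_hat, _, _ = _cox_quantities(fit.coef, time, event, Xs, "breslow")
    for eps in (1e-3, -1e-3):
        for j in range(2):
            beta = fit.coef.copy()
            beta[j] += eps
            ll, _, _ = _cox_quantities(beta, time, event, Xs, "breslow")
            assert ll <= ll_hat + 1e-12


def test_cox_affine_rescaling_of_covariates():
    df = _random_survival(seed=7)
    f1 = fit_cox(df, "t", "e", ["x"], ties="breslow")
    df2 = df.assign(x=df["x"] * 10.0 + 3.0)
    f2 = fit_cox(df2, "t", "e", ["x"], ties="breslow")
    assert f2.coef[0] == pytest.approx(f1.coef[0] / 10.0, rel=1e-8)


def test_cox_monotone_likelihood_diverges():
    df = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 0], "x": [1.0, 0.0]})
    with pytest.raises(CoxConvergenceError):
        fit_cox(df, "t", "e", ["x"])


def test_cox_constant_covariate_rank_error():
    df = _random_survival(seed=8).assign(const=1.0)
    with pytest.raises(CoxRankError):
        fit_cox(df, "t", "e", ["x", "const"])


def test_cox_parameter_recovery_simulation():
    """Mean coefficient over replicates is close to the generating
    log-hazard ratio."""
    betas = []
    for seed in range(25):
        df = _random_survival(n=4000, seed=100 + seed)
        betas.append(fit_cox(df, "t", "e", ["x", "z"]).coef)
    mean = np.mean(betas, axis=0)
    assert mean[0] == pytest.approx(-0.5, rel=0.05)
    assert mean[1] == pytest.approx(0.3, rel=0.08)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

def test_km_no_censoring_steps():
    curves = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    np.testing.assert_allclose(curves[0].survival, [0.75, 0.5, 0.25, 0.0])
    np.testing.assert_array_equal(curves[0].at_risk, [4, 3, 2, 1])


def test_km_all_censored_stays_at_one():
    curves = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
    assert curves[0].times.size == 0  # no drops: survival identically 1


def test_km_interleaved_censoring_matches_longhand():
    t = np.array([1.0, 2.0, 2.5, 3.0, 3.5, 5.0, 6.0, 7.0])
    e = np.array([1, 0, 1, 1, 0, 1, 0, 1], dtype=bool)
    want = _km_longhand(t, e)
    got = kaplan_meier(t, e)[0]
    for tu, s in want.items():
        assert got.survival[np.searchsorted(got.times, tu)] == pytest.approx(s)
    assert np.all(np.diff(got.survival) <= 1e-12)  # non-increasing
    assert np.all(got.greenwood_var >= 0)


def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0] * 2
    e = [1, 0, 1, 1] * 2
    g = [0] * 4 + [1] * 4
    chi2, df, p = log_rank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 1 and p == pytest.approx(1.0)


def test_logrank_matches_longhand_oracle():
    df = KM_FIXTURE
    chi2, _, _ = log_rank_test(df["time"], df["event"].astype(bool), df["group"])
    want, _ = _logrank_longhand(df["time"], df["event"].astype(bool), df["group"])
    assert chi2 == pytest.approx(want, abs=1e-8)


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError):
        log_rank_test([1.0, 2.0], [1, 1], [0, 0])


def test_logrank_asymptotic_p_consistent_with_permutation():
    rng = np.random.default_rng(9)
    n = 80
    g = rng.binomial(1, 0.5, n)
    t = rng.exponential(10, n) * np.exp(-0.45 * g)
    e = rng.random(n) < 0.8
    chi2, _, p_asym = log_rank_test(t, e, g)
    n_perm = 400
    hits = 0
    for _ in range(n_perm):
        stat, _, _ = log_rank_test(t, e, rng.permutation(g))
        hits += stat >= chi2
    p_perm = (hits + 1) / (n_perm + 1)
    mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(p_perm - p_asym) < 3 * mc_se + 0.02


# ---------------------------------------------------------------------------
# proportional-hazards supremum test

def test_ph_supremum_seed_determinism_and_validation():
    df = _random_survival(n=200, seed=10)
    data = SurvivalData.from_frame(df, "t", "e", ["x", "z"])
    fit = fit_cox(data)
    p1 = ph_supremum_test(fit, data, n_resample=200, seed=5)
    p2 = ph_supremum_test(fit, data, n_resample=200, seed=5)
    pd.testing.assert_frame_equal(p1, p2)
    with pytest.raises(ValueError):
        ph_supremum_test(fit, data, n_resample=50, seed=5)


def test_ph_supremum_size_under_proportional_hazards():
    rejections = 0
    n_reps = 30
    for seed in range(n_reps):
        df = _random_survival(n=250, seed=200 + seed)
        data = SurvivalData.from_frame(df, "t", "e", ["x", "z"])
        fit = fit_cox(data)
        res = ph_supremum_test(fit, data, n_resample=200, seed=seed)
        rejections += (res["p"] < 0.05).any()
    # two covariates tested per dataset; allow the familywise level
    assert rejections <= np.ceil(0.10 * 2 * n_reps) + 2


def test_ph_supremum_detects_crossing_effect():
    """A covariate whose effect reverses over time violates PH and should
    be flagged."""
    hits = 0
    n_reps = 20
    for seed in range(n_reps):
        rng = np.random.default_rng(300 + seed)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        # piecewise hazard: strong positive effect early, negative late
        t = np.where(
            x == 1, rng.exponential(4.0, n), rng.exponential(8.0, n)
        )
        late = t > 6.0
        t = np.where(late & (x == 1), 6.0 + rng.exponential(20.0, n), t)
        t = np.where(late & (x == 0), 6.0 + rng.exponential(4.0, n), t)
        e = t < 30.0
        time = np.minimum(t, 30.0)
        data = SurvivalData(time, e, pd.DataFrame({"x": x}))
        fit = fit_cox(data)
        res = ph_supremum_test(fit, data, n_resample=200, seed=seed)
        hits += res["p"].iloc[0] < 0.05
    assert hits >= 0.6 * n_reps


# ---------------------------------------------------------------------------
# adjusted survival curves

def test_adjusted_curves_contract_and_ordering():
    df = _random_survival(n=500, seed=11)
    data = SurvivalData.from_frame(df, "t", "e", ["x", "z"])
    fit = fit_cox(data)
    curves = adjusted_survival_curves(fit, {"lo": {"x": -1.0}, "hi": {"x": 1.0}})
    for label in ("lo", "hi"):
        c = curves[curves["stratum"] == label]
        assert c["survival"].iloc[0] == 1.0
        assert (np.diff(c["survival"]) <= 1e-12).all()
    lo = curves[curves["stratum"] == "lo"]["survival"].to_numpy()
    hi = curves[curves["stratum"] == "hi"]["survival"].to_numpy()
    sign = np.sign(fit.coef[fit.names.index("x")])
    if sign < 0:  # negative coefficient: higher x -> lower hazard
        assert (hi >= lo - 1e-12).all()
    else:
        assert (hi <= lo + 1e-12).all()
    with pytest.raises(ValueError):
        adjusted_survival_curves(fit, {"bad": {"nope": 1.0}})


def test_adjusted_curve_reduces_to_nelson_aalen_when_effect_null():
    """With a no-effect covariate the Breslow baseline is the Nelson-Aalen
    estimator, so the mean-covariate curve is exp(-NA)."""
    rng = np.random.default_rng(12)
    n = 4000
    x = rng.normal(size=n)  # unrelated to the hazard
    t = rng.exponential(10.0, n)
    e = rng.random(n) < 0.7
    data = SurvivalData(t, e, pd.DataFrame({"x": x}))
    fit = fit_cox(data)
    curves = adjusted_survival_curves(fit, {"mean": {}})
    surv = curves[curves["stratum"] == "mean"]
    # longhand Nelson-Aalen
    order = np.argsort(t)
    ts, es = t[order], e[order]
    na = {}
    acc = 0.0
    for tu in np.unique(ts[es]):
        acc += ((ts == tu) & es).sum() / (ts >= tu).sum()
        na[tu] = acc
    times = surv["time"].to_numpy()[1:]
    got = surv["survival"].to_numpy()[1:]
    want = np.exp(-np.array([na[tu] for tu in times]))
    np.testing.assert_allclose(got, want, atol=0.01)
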