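import numpy as np
import pandas as pd
import pytest

from phenosink import SimulationConfig, noise_free
from phenosink.inference import (
    FitError,
    ModelResult,
    ModelSpec,
    bootstrap_ci,
    effect_tests,
    endpoint_spec,
    fit_lmm,
    longitudinal_spec,
    prune_interactions,
    r2_mixed,
    recovery_study,
)


def _frame(n_per_block=12, n_blocks=6, sigma=0.0, block_sd=0.0, seed=0,
           beta_leaf=0.1, beta_bud=-0.05, beta_int=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, n_blocks + 1):
        re_b = rng.normal(0, block_sd) if block_sd > 0 else 0.0
        for _ in range(n_per_block):
            leaf = rng.choice([0, 25, 50, 75])
            bud = rng.choice([0, 25, 50, 75])
            y = (2.0 + beta_leaf * leaf + beta_bud * bud
                 + beta_int * leaf * bud + re_b)
            if sigma > 0:
                y += rng.normal(0, sigma)
            rows.append((b, leaf, bud, y))
    return pd.DataFrame(rows, columns=["block_id", "leaf_pct", "bud_pct", "y"])


# -- spec -------------------------------------------------------------------

def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(response="y", transform="cube")
    with pytest.raises(ValueError):
        ModelSpec(response="y", random_terms=())
    spec = endpoint_spec("y")
    assert spec.formula == "_response ~ leaf_pct + bud_pct + leaf_pct:bud_pct"
    assert spec.drop_term("leaf_pct:bud_pct").fixed_terms == ("leaf_pct", "bud_pct")
    assert "tree_id" in longitudinal_spec().random_terms


def test_fit_requires_columns():
    with pytest.raises(FitError, match="lacks columns"):
        fit_lmm(endpoint_spec("y"), pd.DataFrame({"y": [1.0, 2.0]}))


# -- noiseless oracle -------------------------------------------------------

def test_noiseless_fit_equals_least_squares():
    data = _frame(sigma=0.0, block_sd=0.0)
    res = fit_lmm(endpoint_spec("y"), data)
    X = np.column_stack([
        np.ones(len(data)), data["leaf_pct"], data["bud_pct"],
        data["leaf_pct"] * data["bud_pct"],
    ])
    beta, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
    np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)
    assert res.converged and not res.flagged
    assert res.variance_components["residual"] == 0.0
    assert (res.bse == 0).all()


def test_noisy_fit_recovers_coefficients():
    data = _frame(n_per_block=40, n_blocks=8, sigma=0.5, block_sd=1.0, seed=3)
    res = fit_lmm(endpoint_spec("y"), data)
    assert res.converged
    assert res.params["leaf_pct"] == pytest.approx(0.1, abs=0.01)
    assert res.params["bud_pct"] == pytest.approx(-0.05, abs=0.01)
    assert res.variance_components["block_id"] > 0
    assert res.variance_components["residual"] == pytest.approx(0.25, rel=0.5)


# -- tests and pruning ------------------------------------------------------

def test_effect_tests_power_and_df():
    data = _frame(n_per_block=40, n_blocks=8, sigma=0.5, block_sd=0.5,
                  beta_bud=0.0, seed=4)
    res = fit_lmm(endpoint_spec("y"), data)
    tests = effect_tests(res)
    assert list(tests.index) == ["leaf_pct", "bud_pct", "leaf_pct:bud_pct"]
    assert (tests["df"] == 1).all()  # continuous covariates carry 1 df
    assert tests.loc["leaf_pct", "p"] < 0.05
    assert tests.loc["bud_pct", "p"] > 0.05


def test_prune_drops_null_interaction_keeps_main_effects():
    data = _frame(n_per_block=30, n_blocks=8, sigma=0.5, block_sd=0.5,
                  beta_bud=0.0, beta_int=0.0, seed=5)
    spec, log = prune_interactions(endpoint_spec("y"), data)
    assert spec.fixed_terms == ("leaf_pct", "bud_pct")  # bud stays despite null
    assert [t for t, _ in log] == ["leaf_pct:bud_pct"]
    assert all(p >= 0.05 for _, p in log)


def test_prune_keeps_significant_interaction():
    data = _frame(n_per_block=30, n_blocks=8, sigma=0.5, block_sd=0.5,
                  beta_int=0.01, seed=6)
    spec, log = prune_interactions(endpoint_spec("y"), data)
    assert "leaf_pct:bud_pct" in spec.fixed_terms
    assert log == []


# -- R2 ---------------------------------------------------------------------

def test_r2_known_variance_split():
    # fixed : random : residual variance = 1 : 1 : 2
    rng = np.random.default_rng(0)
    exog = rng.normal(size=(4000, 1))
    exog = (exog - exog.mean()) / exog.std()  # unit variance predictor
    res = ModelResult(
        spec=ModelSpec(response="y", fixed_terms=("x",), random_terms=("g",)),
        params=pd.Series({"x": 1.0}), bse=pd.Series({"x": 0.0}),
        pvalues=pd.Series({"x": 0.0}),
        variance_components={"g": 1.0, "residual": 2.0},
        converged=True, flagged=False, _exog=exog,
    )
    marginal, conditional = r2_mixed(res)
    assert marginal == pytest.approx(0.25, abs=1e-9)
    assert conditional == pytest.approx(0.5, abs=1e-9)


def test_r2_clamps_negative_variance():
    res = ModelResult(
        spec=ModelSpec(response="y", fixed_terms=("x",), random_terms=("g",)),
        params=pd.Series({"x": 1.0}), bse=pd.Series({"x": 0.0}),
        pvalues=pd.Series({"x": 0.0}),
        variance_components={"g": -0.5, "residual": 1.0},
        converged=True, flagged=True, _exog=np.ones((10, 1)),
    )
    with pytest.warns(UserWarning):
        marginal, conditional = r2_mixed(res)
    assert marginal == 0.0 and conditional == 0.0


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_deterministic_and_sane():
    data = _frame(n_per_block=12, n_blocks=6, sigma=0.5, block_sd=0.5, seed=7)
    res = fit_lmm(endpoint_spec("y"), data)
    a = bootstrap_ci(res, n_sim=60, seed=11)
    b = bootstrap_ci(res, n_sim=60, seed=11)
    pd.testing.assert_frame_equal(a, b)
    assert (a["upper95"] >= a["lower95"]).all()
    assert (a["se_boot"] > 0).all()
    assert a.attrs["n_failed"] <= 6
    assert list(a.attrs["param_draws"].columns) == list(res.params.index)


def test_bootstrap_zero_variance_width_zero():
    data = _frame(sigma=0.0, block_sd=0.0)
    res = fit_lmm(endpoint_spec("y"), data)
    ci = bootstrap_ci(res, n_sim=50, seed=1)
    assert (ci["se_boot"] == 0).all()
    np.testing.assert_allclose(ci["lower95"], ci["fit"])
    np.testing.assert_allclose(ci["upper95"], ci["fit"])


def test_bootstrap_width_scales_with_residual_sd():
    narrow = fit_lmm(endpoint_spec("y"),
                     _frame(n_per_block=20, sigma=0.3, block_sd=0.0, seed=8))
    wide = fit_lmm(endpoint_spec("y"),
                   _frame(n_per_block=20, sigma=1.2, block_sd=0.0, seed=8))
    ci_n = bootstrap_ci(narrow, n_sim=80, seed=2)
    ci_w = bootstrap_ci(wide, n_sim=80, seed=2)
    assert ci_w["se_boot"].mean() > 2 * ci_n["se_boot"].mean()


def test_log_transform_monotone_back_transform():
    data = _frame(sigma=0.0, block_sd=0.0, beta_leaf=0.01, beta_bud=0.0)
    res = fit_lmm(ModelSpec(response="y", transform="log"), data)
    ci = bootstrap_ci(res, n_sim=20, seed=3)
    ordered = ci.sort_values(["leaf_pct", "bud_pct"])
    by_leaf = ordered.groupby("leaf_pct")["fit"].mean()
    assert by_leaf.is_monotonic_increasing
    assert (ci["fit"] > 0).all()


def test_log_transform_rejects_nonpositive():
    data = _frame(sigma=0.0, beta_leaf=-1.0)
    with pytest.raises(FitError, match="positive"):
        fit_lmm(ModelSpec(response="y", transform="log"), data)


# -- recovery ---------------------------------------------------------------

def test_recovery_noise_free_hits_truth():
    cfg = noise_free(SimulationConfig())
    study = recovery_study(cfg, n_reps=2, seed=0)
    assert set(study) >= {"replicates", "leaf_slope", "delay_75pct",
                          "photo_effect_pct"}
    assert len(study["replicates"]) == 2
    # noise-free replicates deviate from truth only by interpolation error
    assert study["leaf_slope"]["mean"] == pytest.approx(
        cfg.true_senescence_delay_per_pct, abs=0.01)
    assert study["photo_effect_pct"]["mean"] == pytest.approx(14.0, abs=0.2)


def test_recovery_null_truth():
    cfg = noise_free(SimulationConfig(), true_senescence_delay_per_pct=0.0)
    study = recovery_study(cfg, n_reps=2, seed=0)
    assert study["leaf_slope"]["mean"] == pytest.approx(0.0, abs=0.01)
    assert study["leaf_slope"]["truth"] == 0.0
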