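"""WAIC, model weights, HPDI and posterior predictions."""

import numpy as np
import pytest

from ewalearn.compare import WAICResult, compare_models, compute_waic, hpdi, posterior_predict
from ewalearn.core import ModelSpec
from ewalearn.design import build_design
from ewalearn.inference import HierarchicalModel, PosteriorSamples


# -- WAIC --------------------------------------------------------------------

def test_waic_zero_variance_limit():
    ll = np.full((4, 1), -1.7)
    r = compute_waic(ll)
    assert r.p_waic == pytest.approx(0.0, abs=1e-12)
    assert r.waic == pytest.approx(-2 * -1.7)


def test_waic_matches_direct_formula():
    """Brute-force evaluation of the deviance-scale formula on a fixture."""
    rng = np.random.default_rng(0)
    ll = rng.normal(-1.0, 0.3, size=(50, 7))
    r = compute_waic(ll)
    # independent direct computation
    lppd = np.log(np.exp(ll).mean(axis=0))
    p = ll.var(axis=0, ddof=1)
    waic_e = -2 * (lppd - p)
    assert r.waic == pytest.approx(waic_e.sum(), abs=1e-8)
    assert r.p_waic == pytest.approx(p.sum(), abs=1e-8)
    assert r.se == pytest.approx(np.sqrt(7 * waic_e.var(ddof=1)), abs=1e-8)


def test_waic_agrees_with_arviz():
    import arviz as az

    rng = np.random.default_rng(1)
    ll = rng.normal(-1.2, 0.4, size=(2, 100, 9))  # chains x draws x events
    idata = az.from_dict(log_likelihood={"obs": ll})
    ref = az.waic(idata, scale="deviance")
    r = compute_waic(ll.reshape(-1, 9))
    # arviz computes p_waic with the population variance (ddof=0); we use the
    # sample variance (ddof=1).  Convert before comparing.
    S = 200
    p_ref = float(ref.p_waic) * S / (S - 1)
    assert r.p_waic == pytest.approx(p_ref, abs=1e-8)
    assert r.waic == pytest.approx(float(ref.elpd_waic) + 2 * (p_ref - float(ref.p_waic)), abs=1e-8)


def test_waic_additivity():
    rng = np.random.default_rng(2)
    ll = rng.normal(-1.0, 0.2, size=(30, 4))
    const = np.full((30, 1), -2.3)
    r0 = compute_waic(ll)
    r1 = compute_waic(np.hstack([ll, const]))
    assert r1.waic == pytest.approx(r0.waic + 2 * 2.3, abs=1e-10)


def test_waic_rejects_single_draw():
    with pytest.raises(ValueError, match="single draw"):
        compute_waic(np.full((1, 5), -1.0))


# -- comparison table --------------------------------------------------------

def _res(waic, n=100):
    return WAICResult(waic=waic, se=1.0, p_waic=1.0, n_events=n)


def test_equal_waic_splits_weight():
    table = compare_models([("a", _res(10.0)), ("b", _res(10.0))])
    assert np.allclose(table["weight"], 0.5)
    assert np.allclose(table["dwaic"], 0.0)


def test_large_dwaic_gives_zero_weight():
    table = compare_models([("social", _res(4707.71)), ("asocial", _res(4707.71 + 49.18))])
    assert table.loc["social", "weight"] == pytest.approx(1.0, abs=1e-4)
    assert table.loc["asocial", "weight"] == pytest.approx(0.0, abs=1e-4)
    assert table.loc["asocial", "dwaic"] == pytest.approx(49.18)


def test_three_model_weights():
    table = compare_models([("a", _res(10.0)), ("b", _res(12.0)), ("c", _res(14.0))])
    w = np.exp([-0.0, -1.0, -2.0])
    assert np.allclose(table["weight"], w / w.sum(), atol=5e-4)
    # ordering by waic equals ordering by weight, descending
    assert list(table["weight"]) == sorted(table["weight"], reverse=True)


def test_compare_requires_matching_event_sets():
    with pytest.raises(ValueError, match="different event counts"):
        compare_models([("a", _res(10.0, n=100)), ("b", _res(11.0, n=99))])
    with pytest.raises(ValueError, match=">= 2"):
        compare_models([("a", _res(10.0))])


# -- HPDI --------------------------------------------------------------------

def test_hpdi_degenerate_distribution():
    assert hpdi(np.full(50, 3.3)) == (3.3, 3.3)


def test_hpdi_exhaustive_scan_uniform_grid():
    draws = np.arange(1.0, 101.0)
    lo, hi = hpdi(draws, 0.89)
    assert hi - lo == 88.0
    assert lo == 1.0  # tie broken toward the lowest lower bound


def test_hpdi_mass_bounds():
    draws = np.arange(10.0)
    with pytest.raises(ValueError):
        hpdi(draws, 1.0)
    assert hpdi(draws, 0.9999) == (0.0, 9.0)


def test_hpdi_agrees_with_arviz_on_smooth_samples():
    import arviz as az

    rng = np.random.default_rng(3)
    draws = rng.normal(0, 1, 4000)
    lo, hi = hpdi(draws, 0.89)
    ref = az.hdi(draws, hdi_prob=0.89)
    assert lo == pytest.approx(ref[0], abs=0.05)
    assert hi == pytest.approx(ref[1], abs=0.05)


# -- posterior prediction ----------------------------------------------------

@pytest.fixture(scope="module")
def degenerate_samples(small_sim):
    """A posterior with every draw at the same point, for consistency checks."""
    design = build_design(small_sim.log, small_sim.config.window)
    model = HierarchicalModel(design, ModelSpec("payoff_bias"))
    th = 0.2 * np.random.default_rng(4).standard_normal(model.dim)
    theta = np.tile(th, (2, 3, 1))
    pw = np.tile(model.pointwise_loglik(th), (6, 1))
    return PosteriorSamples(
        spec=model.spec, model=model, theta=theta, pointwise_loglik=pw, diagnostics={}, seed=0
    )


def test_per_bout_predictions_equal_forward_probs(degenerate_samples):
    model = degenerate_samples.model
    th = degenerate_samples.flat()[0]
    expected = model.choice_probs(th)
    df = posterior_predict(degenerate_samples, "per-bout")
    K = model.design.K
    got = df.sort_values(["event_index", "technique"])
    for k, tech in enumerate(model.design.techniques):
        sub = got[got.technique == tech].sort_values("event_index")
        assert np.allclose(sub["mean"].to_numpy(), expected[:, k], atol=1e-12)
        # degenerate posterior: HPDI collapses onto the mean
        assert np.allclose(sub["hpdi_lo"], sub["mean"], atol=1e-12)


def test_population_daily_rows_sum_to_one(degenerate_samples):
    df = posterior_predict(degenerate_samples, "population-daily")
    sums = df.groupby(["group", "date"])["mean"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    raw_sums = df.groupby(["group", "date"])["raw_freq"].sum()
    assert np.allclose(raw_sums, 1.0, atol=1e-9)


def test_individual_daily_resolution_and_errors(degenerate_samples):
    df = posterior_predict(degenerate_samples, "individual-daily")
    assert {"actor_id", "date", "technique", "mean"} <= set(df.columns)
    sums = df.groupby(["actor_id", "date"])["mean"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="resolution"):
        posterior_predict(degenerate_samples, "hourly")
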