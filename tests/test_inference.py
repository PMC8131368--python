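"""Hierarchical inference: transforms, gradients, consistency and determinism."""

import numpy as np
import pytest

from ewalearn.core import LearningParameters, ModelSpec, sequence_loglik
from ewalearn.design import build_design
from ewalearn.inference import (
    HierarchicalModel,
    HierarchicalSpec,
    PriorConfig,
    corr_chol_backward,
    corr_chol_forward,
    fit_model,
    inv_link,
    load_fit,
    natural_scale,
)

from conftest import make_log


@pytest.fixture(scope="module")
def small_design(small_sim):
    return build_design(small_sim.log, small_sim.config.window)


# -- correlation-factor transform -------------------------------------------

@pytest.mark.parametrize("P", [2, 4, 6])
def test_corr_chol_produces_valid_correlation(P):
    rng = np.random.default_rng(P)
    y = rng.normal(0, 1.2, P * (P - 1) // 2)
    L, _ = corr_chol_forward(y, P, eta=4.0)
    R = L @ L.T
    assert np.allclose(np.diag(R), 1.0, atol=1e-12)
    assert np.allclose(R, R.T)
    assert np.linalg.eigvalsh(R).min() > 0
    assert np.allclose(np.triu(L, 1), 0.0)


@pytest.mark.parametrize("P", [2, 4])
def test_corr_chol_backward_matches_finite_differences(P):
    rng = np.random.default_rng(10 + P)
    y = rng.normal(0, 0.8, P * (P - 1) // 2)
    W = rng.normal(0, 1, (P, P))  # arbitrary external gradient on L

    def scalar(yv):
        L, logp = corr_chol_forward(yv, P, eta=4.0)
        return logp + np.sum(np.tril(W) * L)

    g = corr_chol_backward(y, P, eta=4.0, gL=np.tril(W))
    eps = 1e-6
    for i in range(len(y)):
        yp, ym = y.copy(), y.copy()
        yp[i] += eps
        ym[i] -= eps
        fd = (scalar(yp) - scalar(ym)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


# -- design -----------------------------------------------------------------

def test_design_alignment_and_indexing(small_sim, small_design):
    d = small_design
    assert d.n_events == small_sim.log.n_events
    assert d.actor.max() < d.n_individuals
    assert d.choice.max() < d.K
    assert set(np.unique(d.group)) <= set(range(d.n_groups))
    # empty-window events are flagged for the individual-only fallback
    assert (~d.social_any).sum() > 0
    assert np.array_equal(d.social_any, d.N.sum(axis=1) > 0)


def test_design_excludes_individuals_without_events():
    log = make_log(
        [("A", "G", "F", "adult", 1.0), ("B", "G", "M", "juvenile", 0.0)],
        {("S1", "d"): [(1.0, "A", "CMS", "success", {"B"})]},
    )
    with pytest.warns(UserWarning, match="zero manipulation events"):
        d = build_design(log)
    assert d.individual_ids == ("A",)


# -- links and priors --------------------------------------------------------

def test_inverse_link_identities():
    assert inv_link(np.array(0.0), "logit") == pytest.approx(0.5)
    assert inv_link(np.array(0.0), "log") == pytest.approx(1.0)


def test_natural_parameters_respect_bounds(small_design):
    """Any unconstrained draw maps to lambda, fc > 0 and phi, gamma in [0,1]."""
    model = HierarchicalModel(small_design, ModelSpec("global"))
    rng = np.random.default_rng(0)
    for _ in range(20):
        nat = model.natural(rng.normal(0, 2, model.dim))
        cols = dict(zip(model.param_names, nat.T))
        assert (cols["lambda"] > 0).all() and (cols["fc"] > 0).all()
        assert ((cols["phi"] >= 0) & (cols["phi"] <= 1)).all()
        assert ((cols["gamma"] >= 0) & (cols["gamma"] <= 1)).all()


# -- posterior gradient and likelihood consistency ---------------------------

@pytest.mark.parametrize("spec_name", ["individual", "payoff_bias", "global"])
def test_posterior_gradient_matches_finite_differences(small_design, spec_name):
    model = HierarchicalModel(small_design, ModelSpec(spec_name))
    rng = np.random.default_rng(3)
    th = 0.3 * rng.standard_normal(model.dim)
    lp, g = model.logp_grad(th)
    assert np.isfinite(lp)
    for i in rng.choice(model.dim, size=min(25, model.dim), replace=False):
        eps = 1e-6
        tp, tm = th.copy(), th.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=2e-4, abs=1e-6)


def test_hierarchical_likelihood_equals_forward_model(small_sim, small_design):
    """Kernel pointwise log-lik equals the pure-python recursion at a draw."""
    model = HierarchicalModel(small_design, ModelSpec("global"))
    rng = np.random.default_rng(8)
    th = 0.4 * rng.standard_normal(model.dim)
    nat = model.natural(th)
    params = {}
    for j, iid in enumerate(small_design.individual_ids):
        kw = dict(zip(model.param_names, nat[j]))
        params[iid] = LearningParameters(
            lam=kw["lambda"],
            phi=kw["phi"],
            gamma=kw["gamma"],
            fc=kw["fc"],
            beta={k.split("_", 1)[1]: v for k, v in kw.items() if k.startswith("beta_")},
        )
    ref = sequence_loglik(small_sim.log, params, ModelSpec("global"), window=small_sim.config.window)
    got = model.pointwise_loglik(th)
    assert np.allclose(got, ref, atol=1e-10)


# -- fitting ------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_fit(small_design):
    return fit_model(
        small_design,
        ModelSpec("payoff_bias"),
        chains=2,
        warmup=150,
        draws=150,
        seed=5,
    )


def test_fit_is_deterministic_under_seed(small_design, tiny_fit):
    again = fit_model(
        small_design, ModelSpec("payoff_bias"), chains=2, warmup=150, draws=150, seed=5
    )
    assert np.array_equal(tiny_fit.theta, again.theta)
    assert np.array_equal(tiny_fit.pointwise_loglik, again.pointwise_loglik)


def test_fit_reports_diagnostics_and_shapes(small_design, tiny_fit):
    assert tiny_fit.theta.shape[:2] == (2, 150)
    assert tiny_fit.pointwise_loglik.shape == (300, small_design.n_events)
    for key in ("max_rhat", "min_ess", "divergences", "accept_rate"):
        assert key in tiny_fit.diagnostics
    assert np.isfinite(tiny_fit.pointwise_loglik).all()


def test_fit_requires_two_chains(small_design):
    with pytest.raises(ValueError, match="2 chains"):
        fit_model(small_design, ModelSpec("individual"), chains=1)


def test_natural_scale_selectors(small_design, tiny_fit):
    pop = natural_scale(tiny_fit, "population")
    assert set(pop.index) == {"lambda", "phi", "gamma", "beta_pay"}
    assert (pop.loc["phi"], pop.loc["gamma"])  # present
    assert 0 <= pop.loc["gamma", "mean"] <= 1
    assert (pop["hpdi_lo"] <= pop["mean"]).all() and (pop["mean"] <= pop["hpdi_hi"]).all()
    for who in ("adult", "juvenile", "female", "male"):
        df = natural_scale(tiny_fit, who)
        assert 0 <= df.loc["phi", "mean"] <= 1
    ind = small_design.individual_ids[0]
    df_ind = natural_scale(tiny_fit, ind)
    assert df_ind.loc["lambda", "mean"] > 0
    with pytest.raises(KeyError):
        natural_scale(tiny_fit, "no-such-unit")


def test_fit_round_trips_through_disk(tmp_path, small_design, tiny_fit):
    tiny_fit.save(tmp_path / "fit")
    back = load_fit(tmp_path / "fit", small_design)
    assert np.allclose(back.flat(), tiny_fit.flat())
    assert np.allclose(back.pointwise_loglik, tiny_fit.pointwise_loglik)
    assert back.spec.name == "payoff_bias"
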