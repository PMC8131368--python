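"""Hierarchical Bayesian estimation of EWA learning parameters.

Each learning parameter gets a link-scale linear predictor per individual:

    eta[j, p] = mu[p] + a[p] * adult_j + s[p] * male_j + u[j, p] + v[group(j), p]

with log links for lambda and f_c, logit links for phi and gamma, and the
identity for the cue coefficients beta.  ``u`` (per individual) and ``v``
(per group) are correlated zero-mean varying effects parameterised
non-centredly through a scale vector sigma and the Cholesky factor of a
correlation matrix (LKJ prior).  Priors are regularising: standard normal on
means and offsets, unit-rate exponential on sigma, LKJ(4) on correlations.

The posterior is explored with the in-package Hamiltonian Monte Carlo sampler
(:mod:`ewalearn.hmc`); the likelihood and its analytic gradient come from the
numba kernel (:mod:`ewalearn.kernel`), with all chain rules through links,
varying effects and the correlation-factor transform applied here.  Group
varying effects are dropped automatically when the design contains a single
group (they would be unidentifiable against the population mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ewalearn.core import ModelSpec
from ewalearn.cues import CUE_NAMES
from ewalearn.design import Design, build_design  # noqa: F401  (re-exported)
from ewalearn.hmc import sample_chain
from ewalearn.kernel import ewa_choice_probs, ewa_loglik_grad

_LINKS = {"lambda": "log", "phi": "logit", "gamma": "logit", "fc": "log"}


def _link_of(param: str) -> str:
    return _LINKS.get(param, "identity")


def inv_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "log":
        return np.exp(eta)
    if link == "logit":
        from scipy.special import expit

        return expit(eta)
    return np.asarray(eta)


def _dinv_link(nat: np.ndarray, link: str) -> np.ndarray:
    """d(natural)/d(eta) expressed through the natural value."""
    if link == "log":
        return nat
    if link == "logit":
        return nat * (1.0 - nat)
    return np.ones_like(nat)


@dataclass(frozen=True)
class HierarchicalSpec:
    """Which varying-effect blocks to include.

    All free learning parameters of the fitted model spec co-vary within each
    block (one correlation matrix per block).
    """

    individual_effects: bool = True
    group_effects: bool = True


@dataclass(frozen=True)
class PriorConfig:
    """Regularising prior hyperparameters (link scale).

    Population means get normal(0, 1.5) priors: on the log scale this spans
    sensitivities lambda (and frequency exponents) from ~0.05 to ~20 at 95%
    prior mass, and on the logit scale recency/social weights from ~0.01 to
    ~0.99 -- wide enough to cover the parameter magnitudes reported for
    field diffusion experiments of this kind while still shrinking extreme
    values.  Age/sex offsets keep tighter standard-normal priors.
    """

    mean_sd: float = 1.5
    offset_sd: float = 1.0
    sigma_rate: float = 1.0
    lkj_eta: float = 4.0

    def __post_init__(self) -> None:
        if min(self.mean_sd, self.offset_sd, self.sigma_rate, self.lkj_eta) <= 0:
            raise ValueError("prior hyperparameters must be positive")


# ---------------------------------------------------------------------------
# correlation-factor transform (unconstrained y -> Cholesky factor L)
# ---------------------------------------------------------------------------

def corr_chol_forward(y: np.ndarray, P: int, eta: float) -> tuple[np.ndarray, float]:
    """Map unconstrained y (len P(P-1)/2) to a correlation Cholesky factor.

    Returns (L, logp) where logp is the LKJ log-density plus the log |Jacobian|
    of the transform (canonical partial-correlation construction, tanh
    squashing), up to a constant.
    """
    z = np.tanh(y)
    L = np.zeros((P, P))
    L[0, 0] = 1.0
    logp = 0.0
    idx = 0
    # at extreme y the construction degenerates (log of 0 -> -inf logp); the
    # sampler then rejects, so the warnings are suppressed
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(1, P):
            c = 1.0
            for j in range(i):
                zij = z[idx]
                s = np.sqrt(c)
                L[i, j] = zij * s
                logp += np.log1p(-zij * zij) + 0.5 * np.log(c)
                c -= L[i, j] ** 2
                idx += 1
            L[i, i] = np.sqrt(c)
            logp += (P - i + 2.0 * eta - 3.0) * np.log(L[i, i])
    return L, logp


def corr_chol_backward(y: np.ndarray, P: int, eta: float, gL: np.ndarray) -> np.ndarray:
    """Gradient of (logp + <gL, L>) with respect to y.

    At numerically extreme y the construction can underflow to a degenerate
    row; the resulting non-finite gradient makes the sampler reject the
    proposal, so warnings are suppressed here.
    """
    z = np.tanh(y)
    gy = np.zeros_like(y)
    idx = 0
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        for i in range(1, P):
            cj = np.empty(i + 1)
            cj[0] = 1.0
            Lrow = np.empty(i)
            for j in range(i):
                zij = z[idx + j]
                Lrow[j] = zij * np.sqrt(cj[j])
                cj[j + 1] = cj[j] - Lrow[j] ** 2
            Lii = np.sqrt(cj[i])
            gc = np.zeros(i + 1)
            gc[i] = (gL[i, i] + (P - i + 2.0 * eta - 3.0) / Lii) * 0.5 / Lii
            for j in range(i - 1, -1, -1):
                zij = z[idx + j]
                s = np.sqrt(cj[j])
                gLij = gL[i, j] - 2.0 * Lrow[j] * gc[j + 1]
                gc[j] = gc[j + 1] + 0.5 / cj[j] + gLij * zij * 0.5 / s
                gy[idx + j] = gLij * s * (1.0 - zij * zij) - 2.0 * zij
            idx += i
    return gy


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class HierarchicalModel:
    """Unconstrained-vector view of the hierarchical EWA posterior."""

    def __init__(
        self,
        design: Design,
        spec: ModelSpec,
        priors: PriorConfig = PriorConfig(),
        hspec: HierarchicalSpec = HierarchicalSpec(),
    ):
        self.design = design
        self.spec = spec
        self.priors = priors
        self.hspec = hspec
        self.param_names = spec.param_names
        P, J, G = len(self.param_names), design.n_individuals, design.n_groups
        self.P, self.J, self.G = P, J, G
        self.include_ind = hspec.individual_effects
        self.include_grp = hspec.group_effects and G >= 2
        self.n_corr = P * (P - 1) // 2

        offset = 0

        def block(size: int) -> slice:
            nonlocal offset
            sl = slice(offset, offset + size)
            offset += size
            return sl

        self.s_mu = block(P)
        self.s_age = block(P)
        self.s_sex = block(P)
        if self.include_ind:
            self.s_tau_i = block(P)
            self.s_y_i = block(self.n_corr)
            self.s_z_i = block(J * P)
        if self.include_grp:
            self.s_tau_g = block(P)
            self.s_y_g = block(self.n_corr)
            self.s_z_g = block(G * P)
        self.dim = offset

        # kernel constants
        self.active = np.zeros(5, dtype=np.uint8)
        for k, cue in enumerate(CUE_NAMES):
            if cue in spec.active_betas:
                self.active[k] = 1
        self.use_social = spec.social
        self.fc_free = spec.fc_free
        self._social_any = design.social_any.astype(np.uint8)
        self._links = [_link_of(p) for p in self.param_names]
        self._col = {p: i for i, p in enumerate(self.param_names)}

    # -- parameter assembly --------------------------------------------
    def _eta(self, theta: np.ndarray) -> tuple[np.ndarray, dict]:
        """Linear predictor [J, P] and a cache of intermediates.

        Overflow at numerically extreme proposals yields a non-finite
        log-density, which the sampler rejects; warnings are suppressed.
        """
        d = self.design
        cache: dict = {}
        with np.errstate(over="ignore", invalid="ignore"):
            mu = theta[self.s_mu]
            a = theta[self.s_age]
            s = theta[self.s_sex]
            eta = mu[None, :] + np.outer(d.adult, a) + np.outer(d.male, s)
            if self.include_ind:
                sigma_i = np.exp(theta[self.s_tau_i])
                L_i, lkj_i = corr_chol_forward(theta[self.s_y_i], self.P, self.priors.lkj_eta)
                Z_i = theta[self.s_z_i].reshape(self.J, self.P)
                DL_i = sigma_i[:, None] * L_i
                U = Z_i @ DL_i.T
                eta = eta + U
                cache.update(sigma_i=sigma_i, L_i=L_i, lkj_i=lkj_i, Z_i=Z_i, DL_i=DL_i, U=U)
            if self.include_grp:
                sigma_g = np.exp(theta[self.s_tau_g])
                L_g, lkj_g = corr_chol_forward(theta[self.s_y_g], self.P, self.priors.lkj_eta)
                Z_g = theta[self.s_z_g].reshape(self.G, self.P)
                DL_g = sigma_g[:, None] * L_g
                V = Z_g @ DL_g.T
                eta = eta + V[d.group]
                cache.update(sigma_g=sigma_g, L_g=L_g, lkj_g=lkj_g, Z_g=Z_g, DL_g=DL_g, V=V)
        return eta, cache

    def natural(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale per-individual parameters [J, P]."""
        eta, _ = self._eta(theta)
        nat = np.empty_like(eta)
        for p, link in enumerate(self._links):
            nat[:, p] = inv_link(eta[:, p], link)
        return nat

    def _kernel_params(self, nat: np.ndarray):
        J = self.J
        lam = nat[:, self._col["lambda"]].copy()
        phi = nat[:, self._col["phi"]].copy()
        gam = nat[:, self._col["gamma"]].copy() if "gamma" in self._col else np.zeros(J)
        fc = nat[:, self._col["fc"]].copy() if "fc" in self._col else np.ones(J)
        beta = np.zeros((5, J))
        for k, cue in enumerate(CUE_NAMES):
            name = f"beta_{cue}"
            if name in self._col:
                beta[k] = nat[:, self._col[name]]
        return lam, phi, gam, fc, beta

    # -- posterior density ----------------------------------------------
    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.design
        pr = self.priors
        eta, cache = self._eta(theta)
        nat = np.empty_like(eta)
        with np.errstate(over="ignore", invalid="ignore"):
            for p, link in enumerate(self._links):
                nat[:, p] = inv_link(eta[:, p], link)
        lam, phi, gam, fc, beta = self._kernel_params(nat)
        total, _, glam, gphi, ggam, gfc, gbeta = ewa_loglik_grad(
            d.actor, d.choice, d.payoff, d.N, d.kappa, self._social_any,
            lam, phi, gam, fc, beta,
            self.use_social, self.fc_free, self.active, True,
        )
        if not np.isfinite(total):
            return -np.inf, np.zeros(self.dim)

        # gradient wrt natural params -> eta
        g_nat = np.zeros_like(eta)
        g_nat[:, self._col["lambda"]] = glam
        g_nat[:, self._col["phi"]] = gphi
        if "gamma" in self._col:
            g_nat[:, self._col["gamma"]] = ggam
        if "fc" in self._col:
            g_nat[:, self._col["fc"]] = gfc
        for k, cue in enumerate(CUE_NAMES):
            name = f"beta_{cue}"
            if name in self._col:
                g_nat[:, self._col[name]] = gbeta[k]
        g_eta = np.empty_like(g_nat)
        for p, link in enumerate(self._links):
            g_eta[:, p] = g_nat[:, p] * _dinv_link(nat[:, p], link)

        grad = np.zeros(self.dim)
        logp = total

        mu = theta[self.s_mu]
        a = theta[self.s_age]
        s = theta[self.s_sex]
        grad[self.s_mu] = g_eta.sum(axis=0) - mu / pr.mean_sd**2
        grad[self.s_age] = d.adult @ g_eta - a / pr.offset_sd**2
        grad[self.s_sex] = d.male @ g_eta - s / pr.offset_sd**2
        logp += -0.5 * np.sum(mu**2) / pr.mean_sd**2
        logp += -0.5 * (np.sum(a**2) + np.sum(s**2)) / pr.offset_sd**2

        if self.include_ind:
            sigma, L, Z, DL = cache["sigma_i"], cache["L_i"], cache["Z_i"], cache["DL_i"]
            tau = theta[self.s_tau_i]
            gU = g_eta  # u enters eta additively, one row per individual
            gZ = gU @ DL - Z
            gDL = gU.T @ Z
            g_sigma = np.sum(gDL * L, axis=1)
            gL = sigma[:, None] * gDL
            gy = corr_chol_backward(theta[self.s_y_i], self.P, pr.lkj_eta, gL)
            grad[self.s_tau_i] = g_sigma * sigma + (1.0 - pr.sigma_rate * sigma)
            grad[self.s_y_i] = gy
            grad[self.s_z_i] = gZ.ravel()
            logp += cache["lkj_i"]
            logp += np.sum(tau - pr.sigma_rate * sigma)  # exponential prior + log-Jacobian
            logp += -0.5 * np.sum(Z**2)

        if self.include_grp:
            sigma, L, Z, DL = cache["sigma_g"], cache["L_g"], cache["Z_g"], cache["DL_g"]
            tau = theta[self.s_tau_g]
            gV = np.zeros((self.G, self.P))
            np.add.at(gV, self.design.group, g_eta)
            gZ = gV @ DL - Z
            gDL = gV.T @ Z
            g_sigma = np.sum(gDL * L, axis=1)
            gL = sigma[:, None] * gDL
            gy = corr_chol_backward(theta[self.s_y_g], self.P, pr.lkj_eta, gL)
            grad[self.s_tau_g] = g_sigma * sigma + (1.0 - pr.sigma_rate * sigma)
            grad[self.s_y_g] = gy
            grad[self.s_z_g] = gZ.ravel()
            logp += cache["lkj_g"]
            logp += np.sum(tau - pr.sigma_rate * sigma)
            logp += -0.5 * np.sum(Z**2)

        return float(logp), grad

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        d = self.design
        lam, phi, gam, fc, beta = self._kernel_params(self.natural(theta))
        _, pointwise, *_ = ewa_loglik_grad(
            d.actor, d.choice, d.payoff, d.N, d.kappa, self._social_any,
            lam, phi, gam, fc, beta,
            self.use_social, self.fc_free, self.active, False,
        )
        return pointwise

    def choice_probs(self, theta: np.ndarray) -> np.ndarray:
        d = self.design
        lam, phi, gam, fc, beta = self._kernel_params(self.natural(theta))
        return ewa_choice_probs(
            d.actor, d.choice, d.payoff, d.N, d.kappa, self._social_any,
            lam, phi, gam, fc, beta,
            self.use_social, self.fc_free, self.active,
        )


# ---------------------------------------------------------------------------
# posterior container and fitting
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Labelled posterior draws plus pointwise log-likelihood and diagnostics."""

    spec: ModelSpec
    model: HierarchicalModel
    theta: np.ndarray  # [chains, draws, dim]
    pointwise_loglik: np.ndarray  # [chains*draws, n_events]
    diagnostics: dict
    seed: int

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def flat(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def population_natural(self, param: str) -> np.ndarray:
        """Natural-scale draws of the population mean for one parameter."""
        p = self.model._col[param]
        mu = self.flat()[:, self.model.s_mu][:, p]
        return inv_link(mu, _link_of(param))

    def monitored(self) -> dict[str, np.ndarray]:
        """Population-level scalars as {name: [chains, draws]} for diagnostics."""
        out: dict[str, np.ndarray] = {}
        names = self.model.param_names
        for p, name in enumerate(names):
            out[f"mu_{name}"] = self.theta[:, :, self.model.s_mu][:, :, p]
            out[f"age_{name}"] = self.theta[:, :, self.model.s_age][:, :, p]
            out[f"sex_{name}"] = self.theta[:, :, self.model.s_sex][:, :, p]
            if self.model.include_ind:
                out[f"tau_ind_{name}"] = self.theta[:, :, self.model.s_tau_i][:, :, p]
            if self.model.include_grp:
                out[f"tau_grp_{name}"] = self.theta[:, :, self.model.s_tau_g][:, :, p]
        return out

    def save(self, out_dir: str | Path) -> None:
        """Persist draws and pointwise log-likelihood (parquet + JSON sidecar)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        C, D, dim = self.theta.shape
        pd.DataFrame(
            self.flat(), columns=[f"theta_{i}" for i in range(dim)]
        ).assign(chain=np.repeat(np.arange(C), D)).to_parquet(out / "draws.parquet")
        pd.DataFrame(self.pointwise_loglik).to_parquet(out / "pointwise_loglik.parquet")
        sidecar = {
            "spec": self.spec.name,
            "seed": self.seed,
            "param_names": list(self.param_names),
            "chains": C,
            "draws_per_chain": D,
            "priors": vars(self.model.priors),
            "diagnostics": {
                k: (float(v) if np.isscalar(v) else v) for k, v in self.diagnostics.items()
            },
        }
        (out / "fit.json").write_text(json.dumps(sidecar, indent=2, default=float))


def _diagnostics(theta: np.ndarray, samples_monitored: dict[str, np.ndarray]) -> dict:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in samples_monitored.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    rhat_vals = {k: float(rhat[k].values) for k in samples_monitored}
    ess_vals = {k: float(ess[k].values) for k in samples_monitored}
    return {
        "max_rhat": max(rhat_vals.values()),
        "min_ess": min(ess_vals.values()),
        "rhat": rhat_vals,
        "ess": ess_vals,
    }


def fit_model(
    design: Design,
    spec: ModelSpec,
    priors: PriorConfig = PriorConfig(),
    hspec: HierarchicalSpec = HierarchicalSpec(),
    chains: int = 2,
    warmup: int = 500,
    draws: int = 500,
    seed: int = 0,
    target_accept: float = 0.85,
    max_leapfrog: int = 48,
    max_init_tries: int = 20,
    rhat_retry_threshold: float = 1.1,
    max_retries: int = 2,
) -> PosteriorSamples:
    """Sample the hierarchical posterior for one model spec.

    Reproducible under a fixed (seed, chains) pair; chains use independent
    deterministic substreams.  With fewer than 2 chains split-R-hat cannot be
    computed, so ``chains >= 2`` is required.

    If split-R-hat over the population-level scalars exceeds
    ``rhat_retry_threshold`` (a stuck or maladapted chain), the fit is
    automatically retried with a stiffer configuration — longer warmup and a
    higher acceptance target, the same idiom as raising ``adapt_delta`` in
    Stan — up to ``max_retries`` times, deterministically.  The best attempt
    is returned.
    """
    if chains < 2:
        raise ValueError("at least 2 chains are required for convergence diagnostics")
    model = HierarchicalModel(design, spec, priors, hspec)

    def run_once(attempt: int, warmup_a: int, ta: float) -> PosteriorSamples:
        all_draws = np.empty((chains, draws, model.dim))
        divergences = 0
        accepts = []
        for c in range(chains):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7000 + c, attempt]))
            theta0 = None
            for _ in range(max_init_tries):
                cand = 0.1 * rng.standard_normal(model.dim)
                lp, _ = model.logp_grad(cand)
                if np.isfinite(lp):
                    theta0 = cand
                    break
            if theta0 is None:
                raise FloatingPointError(
                    f"could not find a finite initial point in {max_init_tries} tries"
                )
            res = sample_chain(
                model.logp_grad,
                theta0,
                n_warmup=warmup_a,
                n_draws=draws,
                rng=rng,
                target_accept=ta,
                max_leapfrog=max_leapfrog,
            )
            all_draws[c] = res.draws
            divergences += res.divergences
            accepts.append(res.accept_rate)

        flat = all_draws.reshape(-1, model.dim)
        pointwise = np.empty((flat.shape[0], design.n_events))
        for i, th in enumerate(flat):
            pointwise[i] = model.pointwise_loglik(th)

        samples = PosteriorSamples(
            spec=spec,
            model=model,
            theta=all_draws,
            pointwise_loglik=pointwise,
            diagnostics={},
            seed=seed,
        )
        diag = _diagnostics(all_draws, samples.monitored())
        diag["divergences"] = divergences
        diag["accept_rate"] = float(np.mean(accepts))
        diag["attempt"] = attempt
        diag["target_accept"] = ta
        samples.diagnostics = diag
        return samples

    best = None
    warmup_a, ta = warmup, target_accept
    for attempt in range(max_retries + 1):
        samples = run_once(attempt, warmup_a, ta)
        if best is None or samples.diagnostics["max_rhat"] < best.diagnostics["max_rhat"]:
            best = samples
        if samples.diagnostics["max_rhat"] <= rhat_retry_threshold:
            break
        warmup_a = int(warmup_a * 1.5)
        ta = min(0.95, ta + 0.05)
    if best.diagnostics["max_rhat"] > rhat_retry_threshold:
        warnings.warn(
            f"split R-hat {best.diagnostics['max_rhat']:.2f} still above "
            f"{rhat_retry_threshold} after {max_retries + 1} attempts",
            stacklevel=2,
        )
    if best.diagnostics["divergences"] > 0:
        warnings.warn(
            f"{best.diagnostics['divergences']} divergent transitions after warmup",
            stacklevel=2,
        )
    return best


def load_fit(fit_dir: str | Path, design: Design) -> PosteriorSamples:
    """Reload a persisted fit against a freshly rebuilt design.

    The design must be rebuilt from the same event log and window the fit was
    produced with (the sidecar records spec, seed and parameter names).
    """
    fit_dir = Path(fit_dir)
    sidecar = json.loads((fit_dir / "fit.json").read_text())
    spec = ModelSpec(sidecar["spec"])
    priors = PriorConfig(**sidecar["priors"])
    model = HierarchicalModel(design, spec, priors)
    df = pd.read_parquet(fit_dir / "draws.parquet")
    C = int(df["chain"].max()) + 1
    theta = df.drop(columns="chain").to_numpy().reshape(C, -1, model.dim)
    pointwise = pd.read_parquet(fit_dir / "pointwise_loglik.parquet").to_numpy()
    return PosteriorSamples(
        spec=spec,
        model=model,
        theta=theta,
        pointwise_loglik=pointwise,
        diagnostics=sidecar.get("diagnostics", {}),
        seed=int(sidecar["seed"]),
    )


# ---------------------------------------------------------------------------
# natural-scale reporting
# ---------------------------------------------------------------------------

def _class_weights(design: Design, condition: np.ndarray) -> list[tuple[float, float, float]]:
    """Empirical (weight, adult, male) cells under a boolean condition."""
    sel = condition.astype(bool)
    if sel.sum() == 0:
        return [(1.0, 0.0, 0.0)]
    cells: dict[tuple[float, float], int] = {}
    for ad, ma in zip(design.adult[sel], design.male[sel]):
        cells[(ad, ma)] = cells.get((ad, ma), 0) + 1
    n = sum(cells.values())
    return [(cnt / n, ad, ma) for (ad, ma), cnt in sorted(cells.items())]


def natural_scale(samples: PosteriorSamples, who: str, hpdi_mass: float = 0.89) -> pd.DataFrame:
    """Natural-scale posterior summaries (mean + HPDI) for a selector.

    Selectors: ``population`` (baseline juvenile female), ``adult`` /
    ``juvenile`` / ``female`` / ``male`` (marginal over the empirical
    distribution of the other factor), a group name, or an individual id.
    """
    from ewalearn.compare import hpdi

    model = samples.model
    design = model.design
    flat = samples.flat()
    S, P = flat.shape[0], model.P
    mu = flat[:, model.s_mu]
    a = flat[:, model.s_age]
    s = flat[:, model.s_sex]

    def cells_value(cells: list[tuple[float, float, float]], extra: np.ndarray | None = None) -> np.ndarray:
        vals = np.zeros((S, P))
        for w, ad, ma in cells:
            eta = mu + ad * a + ma * s
            if extra is not None:
                eta = eta + extra
            for p, name in enumerate(model.param_names):
                vals[:, p] += w * inv_link(eta[:, p], _link_of(name))
        return vals

    if who == "population":
        vals = np.column_stack(
            [inv_link(mu[:, p], _link_of(name)) for p, name in enumerate(model.param_names)]
        )
    elif who in ("adult", "juvenile"):
        cond = design.adult == (1.0 if who == "adult" else 0.0)
        cells = _class_weights(design, cond)
        # fix the age indicator, average over empirical sex distribution
        cells = [(w, 1.0 if who == "adult" else 0.0, ma) for w, _, ma in cells]
        vals = cells_value(cells)
    elif who in ("female", "male"):
        cond = design.male == (1.0 if who == "male" else 0.0)
        cells = _class_weights(design, cond)
        cells = [(w, ad, 1.0 if who == "male" else 0.0) for w, ad, _ in cells]
        vals = cells_value(cells)
    elif who in design.group_names:
        if not model.include_grp:
            vals = cells_value(_class_weights(design, design.group == design.group_names.index(who)))
        else:
            g = design.group_names.index(who)
            V = np.empty((S, P))
            for i, th in enumerate(flat):
                sigma = np.exp(th[model.s_tau_g])
                L, _ = corr_chol_forward(th[model.s_y_g], P, model.priors.lkj_eta)
                Z = th[model.s_z_g].reshape(model.G, P)
                V[i] = sigma * (L @ Z[g])
            vals = cells_value(_class_weights(design, design.group == g), extra=V)
    elif who in design.individual_ids:
        j = design.individual_ids.index(who)
        eta = mu + design.adult[j] * a + design.male[j] * s
        if model.include_ind:
            U = np.empty((S, P))
            for i, th in enumerate(flat):
                sigma = np.exp(th[model.s_tau_i])
                L, _ = corr_chol_forward(th[model.s_y_i], P, model.priors.lkj_eta)
                Z = th[model.s_z_i].reshape(model.J, P)
                U[i] = sigma * (L @ Z[j])
            eta = eta + U
        if model.include_grp:
            g = design.group[j]
            V = np.empty((S, P))
            for i, th in enumerate(flat):
                sigma = np.exp(th[model.s_tau_g])
                L, _ = corr_chol_forward(th[model.s_y_g], P, model.priors.lkj_eta)
                Z = th[model.s_z_g].reshape(model.G, P)
                V[i] = sigma * (L @ Z[g])
            eta = eta + V
        vals = np.column_stack(
            [inv_link(eta[:, p], _link_of(name)) for p, name in enumerate(model.param_names)]
        )
    else:
        raise KeyError(f"unknown selector {who!r}")

    rows = []
    for p, name in enumerate(model.param_names):
        lo, hi = hpdi(vals[:, p], hpdi_mass)
        rows.append({"parameter": name, "mean": vals[:, p].mean(), "hpdi_lo": lo, "hpdi_hi": hi})
    return pd.DataFrame(rows).set_index("parameter")


__all__ = [
    "Design",
    "HierarchicalModel",
    "HierarchicalSpec",
    "PosteriorSamples",
    "PriorConfig",
    "build_design",
    "corr_chol_backward",
    "corr_chol_forward",
    "fit_model",
    "inv_link",
    "natural_scale",
]
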