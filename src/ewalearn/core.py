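"""Deterministic forward mathematics of the experience-weighted attraction model.

Per individual ``j`` and technique ``i`` an attraction score ``A_ij`` tracks a
memory-weighted average of personally experienced payoffs:

    A_ij,t+1 = (1 - phi_j) * A_ij,t + phi_j * pi_ij,t

with ``phi`` the weight of recent experience (only the chosen technique is
updated each bout).  Individual choice is multinomial-logistic in the
attractions with sensitivity ``lambda``:

    I_i = exp(lambda * A_i) / sum_k exp(lambda * A_k)

Social choice follows a multinomial with frequency exponent ``f_c`` and a
log-linear combination of windowed cue means:

    S_i  propto  N_i ** f_c * exp( sum_k beta_k * kappa_k,i )

(``f_c = 1`` is unbiased, proportional imitation; ``f_c > 1`` conformity;
``f_c < 1`` anti-conformity; unobserved techniques get zero social support).
The realised choice probability is the convex combination

    Pr(i) = (1 - gamma) * I_i + gamma * S_i

falling back to ``I`` alone when no demonstration was observed in the window
(``S`` is then undefined).  Attractions start at 0 for all techniques, so the
first choice is uniform under any lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ewalearn.cues import CUE_NAMES, CueSet, CueWindowConfig, cues_for_log
from ewalearn.events import EventLog

MODEL_NAMES = (
    "individual",
    "freq_dep",
    "female_bias",
    "kin_bias",
    "payoff_bias",
    "rank_bias",
    "sex_bias",
    "global",
)

_SINGLE_BIAS_BETA = {
    "female_bias": "fem",
    "kin_bias": "kin",
    "payoff_bias": "pay",
    "rank_bias": "rank",
    "sex_bias": "sex",
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the eight learning-strategy variants.

    ``individual`` has no social component; ``freq_dep`` uses only observation
    frequencies with a free exponent; the five single-bias models use one cue
    with ``f_c`` fixed at 1; ``global`` activates every cue and frees ``f_c``.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model spec {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def social(self) -> bool:
        return self.name != "individual"

    @property
    def fc_free(self) -> bool:
        return self.name in ("freq_dep", "global")

    @property
    def active_betas(self) -> tuple[str, ...]:
        if self.name == "global":
            return CUE_NAMES
        if self.name in _SINGLE_BIAS_BETA:
            return (_SINGLE_BIAS_BETA[self.name],)
        return ()

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free learning parameters of this spec, in canonical order."""
        names = ["lambda", "phi"]
        if self.social:
            names.append("gamma")
            if self.fc_free:
                names.append("fc")
            names.extend(f"beta_{k}" for k in self.active_betas)
        return tuple(names)


@dataclass
class LearningParameters:
    """Natural-scale learning parameters for one individual.

    lambda >= 0 (attraction sensitivity), phi in [0,1] (recency weight),
    gamma in [0,1] (social-information weight), fc > 0 (frequency exponent),
    beta: cue coefficients keyed by cue name, unconstrained.
    """

    lam: float = 1.0
    phi: float = 0.5
    gamma: float = 0.0
    fc: float = 1.0
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.fc <= 0:
            raise ValueError(f"fc must be > 0, got {self.fc}")

    def beta_value(self, cue: str) -> float:
        return self.beta.get(cue, 0.0)


@dataclass
class AttractionState:
    """Per-individual x technique attraction scores, initialised at zero."""

    individuals: tuple[str, ...]
    techniques: tuple[str, ...]
    A: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.A is None:
            self.A = np.zeros((len(self.individuals), len(self.techniques)))
        self._row = {ind: j for j, ind in enumerate(self.individuals)}
        self._col = {t: i for i, t in enumerate(self.techniques)}

    def row(self, individual: str) -> np.ndarray:
        return self.A[self._row[individual]]

    def update(self, individual: str, technique: str, phi: float, payoff: float) -> None:
        j, i = self._row[individual], self._col[technique]
        self.A[j, i] = update_attraction(self.A[j, i], phi, payoff)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def update_attraction(A_prev: float, phi: float, payoff: float) -> float:
    """Memory-weighted attraction update for the chosen technique."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return (1.0 - phi) * A_prev + phi * payoff


def individual_choice_probs(A_row: np.ndarray, lam: float) -> np.ndarray:
    """Multinomial-logistic choice over attractions (overflow-safe softmax)."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    z = lam * np.asarray(A_row, dtype=float)
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def social_choice_probs(
    cues: CueSet, params: LearningParameters, spec: ModelSpec
) -> np.ndarray | None:
    """Social choice probabilities, or None when no demonstration was observed.

    Techniques unobserved in the window get probability 0 (``0^fc = 0`` for
    ``fc > 0``); with zero support everywhere the social distribution is
    undefined and the caller must fall back to individual choice.
    """
    if not spec.social:
        raise ValueError(f"spec {spec.name!r} has no social component")
    if params.fc <= 0:
        raise ValueError(f"fc must be > 0, got {params.fc}")
    N = np.asarray(cues.N, dtype=float)
    if N.sum() == 0:
        return None
    fc = params.fc if spec.fc_free else 1.0
    defined = N > 0
    B = np.zeros_like(N)
    for k in spec.active_betas:
        kappa = cues.cue(k)
        B[defined] += params.beta_value(k) * kappa[defined]
    # normalise in log space over the observed techniques for stability
    logw = np.full_like(N, -np.inf)
    logw[defined] = fc * np.log(N[defined]) + B[defined]
    logw_max = logw[defined].max()
    w = np.zeros_like(N)
    w[defined] = np.exp(logw[defined] - logw_max)
    return w / w.sum()


def combined_choice_probs(
    I: np.ndarray, S: np.ndarray | None, gamma: float
) -> np.ndarray:
    """Convex combination of individual and social choice distributions."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if S is None:
        return np.asarray(I, dtype=float)
    return (1.0 - gamma) * np.asarray(I, dtype=float) + gamma * np.asarray(S, dtype=float)


# ---------------------------------------------------------------------------
# sequence likelihood
# ---------------------------------------------------------------------------

def event_choice_probs(
    log: EventLog,
    params: dict[str, LearningParameters],
    spec: ModelSpec,
    cues_per_choice: list[CueSet] | None = None,
    window: CueWindowConfig = CueWindowConfig(),
) -> np.ndarray:
    """Forward one-step-ahead choice-probability vectors, one row per event.

    Iterates events chronologically; for each event computes the actor's full
    choice distribution from its current attractions and windowed cues, then
    updates the chosen technique's attraction with the realised payoff.
    Attractions evolve independently per individual and persist across
    sessions.
    """
    if cues_per_choice is None:
        cues_per_choice = cues_for_log(log, window)
    state = AttractionState(tuple(log.individuals), log.techniques)
    out = np.empty((log.n_events, len(log.techniques)))
    for idx, (e, cs) in enumerate(zip(log.events(), cues_per_choice)):
        p = params[e.actor]
        I = individual_choice_probs(state.row(e.actor), p.lam)
        if spec.social:
            S = social_choice_probs(cs, p, spec)
            prob = combined_choice_probs(I, S, p.gamma)
        else:
            prob = I
        out[idx] = prob
        state.update(e.actor, e.technique, p.phi, e.payoff)
    return out


def sequence_loglik(
    log: EventLog,
    params: dict[str, LearningParameters],
    spec: ModelSpec,
    cues_per_choice: list[CueSet] | None = None,
    window: CueWindowConfig = CueWindowConfig(),
) -> np.ndarray:
    """Pointwise log-likelihood of the observed sequence (one entry per event).

    Events whose observed technique receives probability zero contribute
    ``-inf`` (possible only in the pure-social limit ``gamma = 1``; the
    individual softmax component is strictly positive).
    """
    probs = event_choice_probs(log, params, spec, cues_per_choice, window)
    tech_index = {t: i for i, t in enumerate(log.techniques)}
    chosen = np.array([tech_index[e.technique] for e in log.events()], dtype=int)
    p_chosen = probs[np.arange(len(chosen)), chosen]
    with np.errstate(divide="ignore"):
        return np.log(p_chosen)


def export_pointwise_loglik(
    log: EventLog,
    params: dict[str, LearningParameters],
    spec: ModelSpec,
    path,
    window: CueWindowConfig = CueWindowConfig(),
) -> None:
    """Audit export: per-event probability of the observed choice and its log."""
    import pandas as pd

    probs = event_choice_probs(log, params, spec, window=window)
    tech_index = {t: i for i, t in enumerate(log.techniques)}
    rows = []
    for idx, e in enumerate(log.events()):
        p = probs[idx, tech_index[e.technique]]
        rows.append(
            {
                "event_index": idx,
                "actor_id": e.actor,
                "technique": e.technique,
                "probability": p,
                "loglik": np.log(p) if p > 0 else -np.inf,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


__all__ = [
    "MODEL_NAMES",
    "AttractionState",
    "LearningParameters",
    "ModelSpec",
    "combined_choice_probs",
    "event_choice_probs",
    "export_pointwise_loglik",
    "individual_choice_probs",
    "sequence_loglik",
    "social_choice_probs",
    "update_attraction",
]
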