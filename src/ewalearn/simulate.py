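"""Agent-based generator of open-diffusion event logs.

The generator is the forward twin of the fitted model: agents accumulate
attraction scores from their own payoffs and weigh windowed social cues from
the demonstrations they attend, exactly as the likelihood assumes.  On top of
that it emulates the observational structure of a field open-diffusion
experiment:

* two social groups of unequal size, each tested over its own multi-session
  schedule (defaults mirror a 34- and a 19-member group over 11 and 10
  sessions of ~45 min);
* rank-skewed participation (actor sampled with probability proportional to
  ``rank ** participation_rank_skew``, so the lowest rankers may never act);
* per-event attendance sets, with the probability of watching scaled by the
  demonstrator's rank;
* technique-specific Bernoulli success probabilities (defaults 0.47 / 0.08 /
  0.05, the observed success shares of the three techniques in the larger
  group of the motivating experiment).

Every event's full choice-probability vector is recorded in a ledger, so the
likelihood code can be checked against the generator draw-for-draw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ewalearn.core import (
    AttractionState,
    LearningParameters,
    ModelSpec,
    combined_choice_probs,
    individual_choice_probs,
    social_choice_probs,
)
from ewalearn.cues import CueWindowConfig, compute_cues
from ewalearn.events import EventLog, Individual, ManipulationEvent, Session, write_event_log

_LINKS = {"lam": "log", "phi": "logit", "gamma": "logit", "fc": "log"}


def _link(value: float, link: str) -> float:
    if link == "log":
        return math.log(max(value, 1e-300))
    if link == "logit":
        value = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(value / (1 - value))
    return value


def _inv_link(value: float, link: str) -> float:
    if link == "log":
        return math.exp(value)
    if link == "logit":
        return 1.0 / (1.0 + math.exp(-value))
    return value


@dataclass(frozen=True)
class GroupConfig:
    """Composition of one social group (infants are folded into juveniles)."""

    name: str
    n_adult_f: int
    n_adult_m: int
    n_juv_f: int
    n_juv_m: int
    n_sessions: int | None = None
    bouts_per_session: float | None = None

    @property
    def size(self) -> int:
        return self.n_adult_f + self.n_adult_m + self.n_juv_f + self.n_juv_m


@dataclass
class TrueParameters:
    """Ground-truth learning parameters: population values plus link-scale offsets.

    ``adult_offset`` / ``male_offset`` shift the link-scale linear predictor
    for adults / males; ``sigma_individual`` adds i.i.d. normal link-scale
    heterogeneity per individual (0 = all individuals share class values).
    """

    population: LearningParameters = field(
        default_factory=lambda: LearningParameters(lam=8.0, phi=0.06, gamma=0.3, beta={"pay": 1.0})
    )
    adult_offset: dict[str, float] = field(default_factory=dict)
    male_offset: dict[str, float] = field(default_factory=dict)
    sigma_individual: dict[str, float] = field(default_factory=dict)

    def for_individual(self, ind: Individual, rng: np.random.Generator) -> LearningParameters:
        values: dict[str, float] = {}
        pop = self.population
        fields = {"lam": pop.lam, "phi": pop.phi, "gamma": pop.gamma, "fc": pop.fc}
        for name, pop_val in fields.items():
            link = _LINKS[name]
            eta = _link(pop_val, link)
            if ind.age_class == "adult":
                eta += self.adult_offset.get(name, 0.0)
            if ind.sex == "M":
                eta += self.male_offset.get(name, 0.0)
            sd = self.sigma_individual.get(name, 0.0)
            if sd > 0:
                eta += sd * rng.standard_normal()
            values[name] = _inv_link(eta, link)
        beta = {}
        for cue, b in pop.beta.items():
            eta = b
            if ind.age_class == "adult":
                eta += self.adult_offset.get(f"beta_{cue}", 0.0)
            if ind.sex == "M":
                eta += self.male_offset.get(f"beta_{cue}", 0.0)
            sd = self.sigma_individual.get(f"beta_{cue}", 0.0)
            if sd > 0:
                eta += sd * rng.standard_normal()
            beta[cue] = eta
        return LearningParameters(lam=values["lam"], phi=values["phi"], gamma=values["gamma"], fc=values["fc"], beta=beta)


def _default_groups() -> tuple[GroupConfig, ...]:
    # study-scale defaults: a 34-member and a 19-member group (infants counted
    # with juveniles), on 11- and 10-session schedules
    return (
        GroupConfig("NH", n_adult_f=9, n_adult_m=6, n_juv_f=8, n_juv_m=11, n_sessions=11, bouts_per_session=300.0),
        GroupConfig("KB", n_adult_f=6, n_adult_m=1, n_juv_f=6, n_juv_m=6, n_sessions=10, bouts_per_session=15.0),
    )


@dataclass
class SimulationConfig:
    """Full specification of one synthetic open-diffusion experiment."""

    groups: tuple[GroupConfig, ...] = field(default_factory=_default_groups)
    n_sessions: int = 11
    session_length_min: float = 46.0
    bouts_per_session: float = 160.0
    technique_success_probs: dict[str, float] = field(
        default_factory=lambda: {"CMS": 0.47, "CMT": 0.08, "CH": 0.05}
    )
    attendance_base: float = 0.4
    rank_attention: float = 1.0
    participation_rank_skew: float = 1.0
    true_params: TrueParameters = field(default_factory=TrueParameters)
    spec: ModelSpec = field(default_factory=lambda: ModelSpec("payoff_bias"))
    window: CueWindowConfig = field(default_factory=CueWindowConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for t, p in self.technique_success_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"success probability for {t!r} outside [0, 1]: {p}")
        if not 0.0 <= self.attendance_base <= 1.0:
            raise ValueError(f"attendance base probability outside [0, 1]: {self.attendance_base}")
        if self.rank_attention < 0 or self.participation_rank_skew < 0:
            raise ValueError("rank exponents must be >= 0")
        if self.n_sessions <= 0 or self.session_length_min <= 0 or self.bouts_per_session <= 0:
            raise ValueError("session counts and durations must be positive")

    @property
    def techniques(self) -> tuple[str, ...]:
        return tuple(self.technique_success_probs)


@dataclass
class SimulatedDataset:
    """A generated log together with its ground truth and probability ledger."""

    log: EventLog
    truth: dict[str, LearningParameters]
    spec: ModelSpec
    prob_ledger: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        paths = write_event_log(self.log, out)
        truth = {
            "spec": self.spec.name,
            "seed": self.config.seed,
            "window_min": self.config.window.width_min,
            "parameters": {
                ind: {
                    "lambda": p.lam,
                    "phi": p.phi,
                    "gamma": p.gamma,
                    "fc": p.fc,
                    "beta": p.beta,
                }
                for ind, p in self.truth.items()
            },
        }
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=2))
        ledger_path = out / "prob_ledger.csv"
        self.prob_ledger.to_csv(ledger_path, index=False)
        paths.update({"truth": truth_path, "ledger": ledger_path})
        return paths


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> tuple[dict[str, Individual], pd.DataFrame]:
    """Generate individuals and the pedigree-rule relatedness matrix.

    Juveniles are attached to a random adult female of their group (mother,
    r = 0.5); individuals sharing a matriline otherwise have r = 0.25; members
    of different matrilines (and all adult males, who are modelled as
    immigrants) have r = 0.  Ranks are distinct values spanning [0, 1] within
    each group, with adults biased toward the top of the order.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    individuals: dict[str, Individual] = {}
    mothers: dict[str, str] = {}
    for g in cfg.groups:
        members: list[tuple[str, str, str]] = []  # (id, sex, age_class)
        counter = 1
        for sex, age, n in (
            ("F", "adult", g.n_adult_f),
            ("M", "adult", g.n_adult_m),
            ("F", "juvenile", g.n_juv_f),
            ("M", "juvenile", g.n_juv_m),
        ):
            for _ in range(n):
                members.append((f"{g.name}{counter:02d}", sex, age))
                counter += 1
        # ranks: a random order, distinct, spanning [0, 1]; age classes mix
        # through the hierarchy (juveniles were major participants and fast
        # first-succeeders in field open-diffusion experiments of this kind)
        scores = rng.random(len(members))
        order = np.argsort(scores)  # ascending: position 0 = lowest rank
        ranks = np.zeros(len(members))
        if len(members) > 1:
            ranks[order] = np.linspace(0.0, 1.0, len(members))
        else:
            ranks[:] = 1.0
        adult_females = [m[0] for m in members if m[1] == "F" and m[2] == "adult"]
        matriline_of: dict[str, str] = {}
        for k, af in enumerate(adult_females):
            matriline_of[af] = f"{g.name}-M{k + 1}"
        solo = len(adult_females)
        for ind_id, sex, age in members:
            if age == "adult" and sex == "F":
                mat = matriline_of[ind_id]
            elif age == "juvenile" and adult_females:
                mother = adult_females[rng.integers(len(adult_females))]
                mothers[ind_id] = mother
                mat = matriline_of[mother]
            else:
                solo += 1
                mat = f"{g.name}-M{solo}"
            individuals[ind_id] = Individual(
                id=ind_id,
                group=g.name,
                sex=sex,
                age_class=age,
                rank=float(ranks[[m[0] for m in members].index(ind_id)]),
                matriline=mat,
            )
    ids = list(individuals)
    kin = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        kin.loc[a, a] = 1.0
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            ia, ib = individuals[a], individuals[b]
            if ia.matriline != ib.matriline or ia.group != ib.group:
                continue
            if mothers.get(a) == b or mothers.get(b) == a:
                r = 0.5
            else:
                r = 0.25
            kin.loc[a, b] = kin.loc[b, a] = r
    return individuals, kin


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def simulate_diffusion(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the forward model over the configured session schedule.

    All randomness flows from ``cfg.seed`` through deterministic sub-streams
    (population, parameters, schedule, choices), so re-running with the same
    config is byte-identical.
    """
    pop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    par_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    sched_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    choice_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 404]))

    individuals, kin = generate_population(cfg, pop_rng)
    truth = {ind_id: cfg.true_params.for_individual(ind, par_rng) for ind_id, ind in individuals.items()}
    techniques = cfg.techniques
    tech_idx = {t: i for i, t in enumerate(techniques)}

    log = EventLog(individuals=individuals, kin=kin, sessions=[], techniques=techniques)
    state = AttractionState(tuple(individuals), techniques)
    ledger_rows = []
    event_index = 0

    day = 0
    for g in cfg.groups:
        members = [ind for ind in individuals.values() if ind.group == g.name]
        ranks = np.array([m.rank for m in members])
        weights = ranks**cfg.participation_rank_skew if cfg.participation_rank_skew > 0 else np.ones(len(members))
        if weights.sum() == 0:
            weights = np.ones(len(members))
        weights = weights / weights.sum()
        n_sessions = g.n_sessions if g.n_sessions is not None else cfg.n_sessions
        for s in range(n_sessions):
            day += 1
            session = Session(id=f"{g.name}-S{s + 1:02d}", date=f"2018-05-{day:02d}" if day <= 28 else f"2018-06-{day - 28:02d}")
            log.sessions.append(session)
            bout_rate = g.bouts_per_session if g.bouts_per_session is not None else cfg.bouts_per_session
            n_bouts = int(sched_rng.poisson(bout_rate))
            times = np.sort(sched_rng.uniform(0.0, cfg.session_length_min, size=n_bouts))
            for t in times:
                actor = members[int(choice_rng.choice(len(members), p=weights))]
                # windowed social information for the actor
                lo = t - cfg.window.width_min
                window = [
                    e
                    for e in session.events
                    if lo <= e.time < t
                    and (
                        (e.actor == actor.id and cfg.window.include_own_events)
                        or (e.actor != actor.id and actor.id in e.observers)
                    )
                ]
                cs = compute_cues(window, log, actor.id)
                p = truth[actor.id]
                I = individual_choice_probs(state.row(actor.id), p.lam)
                if cfg.spec.social:
                    S = social_choice_probs(cs, p, cfg.spec)
                    prob = combined_choice_probs(I, S, p.gamma)
                else:
                    S = None
                    prob = I
                chosen = int(choice_rng.choice(len(techniques), p=prob / prob.sum()))
                technique = techniques[chosen]
                success = bool(choice_rng.random() < cfg.technique_success_probs[technique])
                payoff = 1.0 if success else 0.0
                # attendance set: eligible groupmates watch with rank-scaled probability
                p_att = min(1.0, cfg.attendance_base * actor.rank**cfg.rank_attention)
                observers = frozenset(
                    m.id for m in members if m.id != actor.id and choice_rng.random() < p_att
                )
                session.events.append(
                    ManipulationEvent(
                        session_id=session.id,
                        time=float(t),
                        actor=actor.id,
                        technique=technique,
                        outcome="success" if success else "failure",
                        observers=observers,
                    )
                )
                ledger_rows.append(
                    {
                        "event_index": event_index,
                        "session_id": session.id,
                        "time_min": float(t),
                        "actor_id": actor.id,
                        "technique": technique,
                        "outcome": "success" if success else "failure",
                        "social_defined": bool(cs.total > 0) and cfg.spec.social,
                        **{f"p_{tech}": float(prob[i]) for tech, i in tech_idx.items()},
                        "p_chosen": float(prob[chosen]),
                    }
                )
                event_index += 1
                state.update(actor.id, technique, p.phi, payoff)
    log.validate()
    return SimulatedDataset(
        log=log,
        truth=truth,
        spec=cfg.spec,
        prob_ledger=pd.DataFrame(ledger_rows),
        config=cfg,
    )


__all__ = [
    "GroupConfig",
    "SimulatedDataset",
    "SimulationConfig",
    "TrueParameters",
    "generate_population",
    "simulate_diffusion",
]
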