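"""Fitting-ready array bundle: integer-indexed events, cues and covariates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ewalearn.cues import CUE_NAMES, CueWindowConfig, cues_for_log
from ewalearn.events import EventLog


@dataclass
class Design:
    """Aligned arrays for the likelihood kernel.

    One row per manipulation event, in chronological order.  Individuals with
    zero events as actor are excluded (they can still appear as demonstrators
    inside the precomputed cue arrays).  ``kappa`` is ``nan``-free: cue means
    of unobserved techniques are stored as 0 but carry no weight because the
    social kernel gives zero support wherever ``N == 0``.
    """

    techniques: tuple[str, ...]
    individual_ids: tuple[str, ...]
    group_names: tuple[str, ...]
    actor: np.ndarray  # int32 [E] index into individual_ids
    choice: np.ndarray  # int32 [E] index into techniques
    payoff: np.ndarray  # float64 [E]
    N: np.ndarray  # float64 [E, K] attended demonstration counts
    kappa: np.ndarray  # float64 [5, E, K] cue means (pay, rank, kin, fem, sex)
    social_any: np.ndarray  # bool [E] any demonstration in window
    adult: np.ndarray  # float64 [J] 1 if adult
    male: np.ndarray  # float64 [J] 1 if male
    group: np.ndarray  # int32 [J] index into group_names
    session_date: np.ndarray  # object [E] session date per event (for daily summaries)
    window_min: float

    @property
    def n_events(self) -> int:
        return len(self.actor)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def K(self) -> int:
        return len(self.techniques)


def build_design(log: EventLog, window: CueWindowConfig = CueWindowConfig()) -> Design:
    """Precompute cue arrays and integer indices for the whole log."""
    cues = cues_for_log(log, window)
    events = list(log.events())
    actors_seen = {e.actor for e in events}
    skipped = sorted(set(log.individuals) - actors_seen)
    if skipped:
        warnings.warn(
            f"excluding {len(skipped)} individual(s) with zero manipulation events: {skipped}",
            stacklevel=2,
        )
    ids = tuple(i for i in log.individuals if i in actors_seen)
    ind_index = {i: j for j, i in enumerate(ids)}
    groups = tuple(dict.fromkeys(log.individuals[i].group for i in ids))
    group_index = {g: k for k, g in enumerate(groups)}
    tech_index = {t: i for i, t in enumerate(log.techniques)}

    E, K = len(events), len(log.techniques)
    actor = np.empty(E, dtype=np.int32)
    choice = np.empty(E, dtype=np.int32)
    payoff = np.empty(E)
    N = np.zeros((E, K))
    kappa = np.zeros((5, E, K))
    dates = np.empty(E, dtype=object)
    session_date = {s.id: s.date for s in log.sessions}
    for e_idx, (ev, cs) in enumerate(zip(events, cues)):
        actor[e_idx] = ind_index[ev.actor]
        choice[e_idx] = tech_index[ev.technique]
        payoff[e_idx] = ev.payoff
        N[e_idx] = cs.N
        dates[e_idx] = session_date[ev.session_id]
        for k, name in enumerate(CUE_NAMES):
            vals = cs.cue(name)
            kappa[k, e_idx] = np.where(cs.N > 0, np.nan_to_num(vals), 0.0)

    adult = np.array([1.0 if log.individuals[i].age_class == "adult" else 0.0 for i in ids])
    male = np.array([1.0 if log.individuals[i].sex == "M" else 0.0 for i in ids])
    group = np.array([group_index[log.individuals[i].group] for i in ids], dtype=np.int32)
    return Design(
        techniques=log.techniques,
        individual_ids=ids,
        group_names=groups,
        actor=actor,
        choice=choice,
        payoff=payoff,
        N=N,
        kappa=kappa,
        social_any=N.sum(axis=1) > 0,
        adult=adult,
        male=male,
        group=group,
        session_date=dates,
        window_min=window.width_min,
    )


__all__ = ["Design", "build_design"]
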