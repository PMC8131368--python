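"""Windowed social-cue construction.

For each focal choice the social information available to the actor is taken
from the manipulation events it attended in a sliding time window (default
20 min, alternatives 5/10/30) immediately preceding the choice.  Per candidate
technique ``i`` the cue set holds the attended demonstration count ``N_i`` and
the mean value of each demonstrator/behaviour cue over those demonstrations:

====================  =====================================================
``paybar``            mean observed payoff (success share) of technique i
``rank``              mean normalised dominance rank of its demonstrators
``kin``               mean relatedness r(observer, demonstrator)
``fem``               share of demonstrations given by adult females
``samesex``           share of demonstrations by same-sex demonstrators
====================  =====================================================

Cue means are undefined for techniques never observed in the window
(``N_i = 0``); downstream models give those techniques zero social support.
The window is half-open, ``[t - W, t)``: an event never informs itself, and
by default an individual's own past manipulations are excluded from its
social cues (they act through its attraction scores instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ewalearn.events import EventLog, ManipulationEvent

CUE_NAMES = ("pay", "rank", "kin", "fem", "sex")


@dataclass(frozen=True)
class CueWindowConfig:
    """Width (minutes) of the social-information window and self-inclusion flag."""

    width_min: float = 20.0
    include_own_events: bool = False

    def __post_init__(self) -> None:
        if self.width_min <= 0:
            raise ValueError(f"window width must be positive, got {self.width_min}")


@dataclass
class CueSet:
    """Per-technique observation counts and cue means for one focal choice.

    ``N[i]`` counts attended demonstrations of technique ``i`` in the window;
    cue means are ``nan`` where ``N[i] == 0`` (undefined, not zero).
    """

    techniques: tuple[str, ...]
    N: np.ndarray
    paybar: np.ndarray
    rank: np.ndarray
    kin: np.ndarray
    fem: np.ndarray
    samesex: np.ndarray

    @property
    def total(self) -> int:
        return int(self.N.sum())

    @property
    def defined(self) -> np.ndarray:
        return self.N > 0

    def cue(self, name: str) -> np.ndarray:
        """Cue-mean vector by short name ('pay', 'rank', 'kin', 'fem', 'sex')."""
        return {
            "pay": self.paybar,
            "rank": self.rank,
            "kin": self.kin,
            "fem": self.fem,
            "sex": self.samesex,
        }[name]


def attended_events(
    log: EventLog,
    observer: str,
    t: float,
    session_id: str,
    cfg: CueWindowConfig = CueWindowConfig(),
) -> list[ManipulationEvent]:
    """Events the observer attended in ``[t - width, t)`` of the given session.

    The focal event itself (time exactly ``t``) is never included; the
    observer's own manipulations are excluded unless configured otherwise.
    """
    session = next((s for s in log.sessions if s.id == session_id), None)
    if session is None:
        raise KeyError(f"unknown session {session_id!r}")
    lo = t - cfg.width_min
    out = []
    for e in session.events:
        if e.time >= t:
            break
        if e.time < lo:
            continue
        if e.actor == observer:
            if not cfg.include_own_events:
                continue
            out.append(e)
        elif observer in e.observers:
            out.append(e)
    return out


def compute_cues(events: list[ManipulationEvent], log: EventLog, observer: str) -> CueSet:
    """Aggregate a window's attended events into per-technique cue means."""
    K = len(log.techniques)
    tech_index = {t: i for i, t in enumerate(log.techniques)}
    N = np.zeros(K, dtype=int)
    sums = {name: np.zeros(K) for name in ("pay", "rank", "kin", "fem", "sex")}
    obs_sex = log.individuals[observer].sex
    for e in events:
        i = tech_index[e.technique]
        demo = log.individuals[e.actor]
        N[i] += 1
        sums["pay"][i] += e.payoff
        sums["rank"][i] += demo.rank
        sums["kin"][i] += log.relatedness(observer, e.actor)
        sums["fem"][i] += 1.0 if demo.is_adult_female else 0.0
        sums["sex"][i] += 1.0 if demo.sex == obs_sex else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = {name: np.where(N > 0, s / np.maximum(N, 1), np.nan) for name, s in sums.items()}
    return CueSet(
        techniques=log.techniques,
        N=N,
        paybar=means["pay"],
        rank=means["rank"],
        kin=means["kin"],
        fem=means["fem"],
        samesex=means["sex"],
    )


def cues_for_log(log: EventLog, cfg: CueWindowConfig = CueWindowConfig()) -> list[CueSet]:
    """One CueSet per event (for its actor at its time), in log order.

    This is the cue stream consumed by the likelihood: for each manipulation
    event the actor's windowed social information immediately before acting.
    Uses a per-session sweep so construction is linear in events per window.
    """
    out: list[CueSet] = []
    for session in log.sessions:
        events = session.events
        lo_idx = 0
        for k, focal in enumerate(events):
            # advance window start (events sorted by time within session)
            while lo_idx < len(events) and events[lo_idx].time < focal.time - cfg.width_min:
                lo_idx += 1
            window = []
            for e in events[lo_idx:k]:
                if e.time >= focal.time:
                    continue
                if e.actor == focal.actor:
                    if cfg.include_own_events:
                        window.append(e)
                elif focal.actor in e.observers:
                    window.append(e)
            out.append(compute_cues(window, log, focal.actor))
    return out


def cue_table(log: EventLog, cfg: CueWindowConfig = CueWindowConfig()) -> pd.DataFrame:
    """Tidy audit table: one row per focal choice x technique."""
    rows = []
    cues = cues_for_log(log, cfg)
    for idx, (e, cs) in enumerate(zip(log.events(), cues)):
        for i, tech in enumerate(log.techniques):
            rows.append(
                {
                    "event_index": idx,
                    "session_id": e.session_id,
                    "time_min": e.time,
                    "actor_id": e.actor,
                    "chosen": e.technique,
                    "technique": tech,
                    "N": int(cs.N[i]),
                    "paybar": cs.paybar[i],
                    "rank": cs.rank[i],
                    "kin": cs.kin[i],
                    "fem": cs.fem[i],
                    "samesex": cs.samesex[i],
                }
            )
    return pd.DataFrame(rows)


def write_cue_table(log: EventLog, path: str | Path, cfg: CueWindowConfig = CueWindowConfig()) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cue_table(log, cfg).to_csv(path, index=False)
    return path


__all__ = [
    "CUE_NAMES",
    "CueSet",
    "CueWindowConfig",
    "attended_events",
    "compute_cues",
    "cue_table",
    "cues_for_log",
    "write_cue_table",
]
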