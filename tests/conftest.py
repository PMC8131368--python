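"""Shared fixtures: a hand-built toy log and a small simulated diffusion."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewalearn.core import LearningParameters, ModelSpec
from ewalearn.events import EventLog, Individual, ManipulationEvent, Session
from ewalearn.simulate import GroupConfig, SimulationConfig, TrueParameters, simulate_diffusion


def make_log(individuals, events_by_session, techniques=("CMS", "CMT", "CH"), kin=None):
    """Build a validated EventLog from terse tuples.

    individuals: list of (id, group, sex, age_class, rank[, matriline])
    events_by_session: {(session_id, date): [(time, actor, technique, outcome, observers), ...]}
    """
    inds = {}
    for tup in individuals:
        iid, group, sex, age, rank = tup[:5]
        mat = tup[5] if len(tup) > 5 else None
        inds[iid] = Individual(id=iid, group=group, sex=sex, age_class=age, rank=rank, matriline=mat)
    ids = list(inds)
    if kin is None:
        kin = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    sessions = []
    for (sid, date), evs in events_by_session.items():
        session = Session(id=sid, date=date)
        for time, actor, tech, outcome, observers in evs:
            session.events.append(
                ManipulationEvent(
                    session_id=sid,
                    time=time,
                    actor=actor,
                    technique=tech,
                    outcome=outcome,
                    observers=frozenset(observers),
                )
            )
        sessions.append(session)
    return EventLog(individuals=inds, kin=kin, sessions=sessions, techniques=techniques)


@pytest.fixture
def toy_log():
    """Two individuals, three events in one session."""
    return make_log(
        [("A", "G", "F", "adult", 1.0), ("B", "G", "M", "juvenile", 0.0)],
        {
            ("S1", "2018-05-01"): [
                (1.0, "A", "CMS", "success", {"B"}),
                (5.0, "A", "CMT", "failure", {"B"}),
                (9.0, "B", "CMS", "failure", set()),
            ]
        },
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 12-agent, ~240-bout payoff-bias diffusion used across test modules."""
    cfg = SimulationConfig(
        groups=(GroupConfig("G", 3, 3, 3, 3, n_sessions=4),),
        bouts_per_session=60.0,
        seed=11,
        spec=ModelSpec("payoff_bias"),
        true_params=TrueParameters(
            population=LearningParameters(lam=8.0, phi=0.06, gamma=0.3, beta={"pay": 1.0})
        ),
    )
    return simulate_diffusion(cfg)
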