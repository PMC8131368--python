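"""Event-log data model: individuals, manipulation events, attendance, summaries.

The unit of analysis is the *manipulation event*: one individual (the actor)
handles the novel food item with one technique and either succeeds or fails,
while a set of conspecifics (the attendance set) watches.  Events are grouped
into experimental sessions; sessions are separated by hours-to-days, so all
windowed social information is within-session by construction.

Age coding follows the two-level convention used by the learning models:
infants are merged into ``juvenile`` at load time (the raw age string is kept
for provenance in :attr:`Individual.raw_age_class`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_TECHNIQUES: tuple[str, ...] = ("CMS", "CMT", "CH")

SEXES = ("F", "M")
AGE_CLASSES = ("adult", "juvenile")
OUTCOMES = ("success", "failure")


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass(frozen=True)
class Individual:
    """One study subject.

    ``rank`` is the normalised dominance rank in [0, 1] with 1 the highest
    ranking individual; it arrives precomputed (e.g. from an I&SI ordering).
    """

    id: str
    group: str
    sex: str
    age_class: str
    rank: float
    matriline: str | None = None
    raw_age_class: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"individual {self.id!r}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise SchemaError(
                f"individual {self.id!r}: age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )
        if not 0.0 <= self.rank <= 1.0:
            raise SchemaError(f"individual {self.id!r}: rank {self.rank} outside [0, 1]")

    @property
    def is_adult_female(self) -> bool:
        return self.sex == "F" and self.age_class == "adult"


@dataclass(frozen=True)
class ManipulationEvent:
    """One manipulation bout: actor, technique, outcome and its audience."""

    session_id: str
    time: float
    actor: str
    technique: str
    outcome: str
    observers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise SchemaError(f"event at t={self.time}: time must be >= 0")
        if self.outcome not in OUTCOMES:
            raise SchemaError(f"event by {self.actor!r}: outcome must be in {OUTCOMES}, got {self.outcome!r}")
        if self.actor in self.observers:
            raise SchemaError(f"event by {self.actor!r} at t={self.time}: actor cannot observe itself")

    @property
    def payoff(self) -> int:
        """Binary payoff: 1 for a success, 0 for a failed attempt."""
        return 1 if self.outcome == "success" else 0


@dataclass
class Session:
    """An ordered run of events recorded on one experimental day."""

    id: str
    date: str
    events: list[ManipulationEvent] = field(default_factory=list)

    @property
    def duration(self) -> float:
        """Elapsed session time in minutes, taken as the last event time."""
        return max((e.time for e in self.events), default=0.0)

    def groups(self, individuals: dict[str, Individual]) -> set[str]:
        return {individuals[e.actor].group for e in self.events}


@dataclass
class EventLog:
    """Validated collection of individuals, relatedness and ordered sessions."""

    individuals: dict[str, Individual]
    kin: pd.DataFrame
    sessions: list[Session]
    techniques: tuple[str, ...] = DEFAULT_TECHNIQUES

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers -------------------------------------------------
    def events(self) -> Iterator[ManipulationEvent]:
        """All events in chronological (session, time) order."""
        for session in self.sessions:
            yield from session.events

    @property
    def n_events(self) -> int:
        return sum(len(s.events) for s in self.sessions)

    def relatedness(self, a: str, b: str) -> float:
        return float(self.kin.loc[a, b])

    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self.individuals.values():
            seen.setdefault(ind.group, None)
        return tuple(seen)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if len(self.techniques) < 2:
            raise SchemaError("technique alphabet must have at least 2 entries")
        ids = set(self.individuals)
        kin = self.kin
        if set(kin.index) != ids or set(kin.columns) != ids:
            raise SchemaError("kin matrix ids do not match individual ids")
        arr = kin.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise SchemaError("kin matrix is not symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-9):
            raise SchemaError("kin matrix diagonal must be 1")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise SchemaError("kin entries must lie in [0, 1]")
        for session in self.sessions:
            times = [e.time for e in session.events]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                warnings.warn(
                    f"session {session.id!r}: events out of time order; repairing by sorting",
                    stacklevel=2,
                )
                session.events.sort(key=lambda e: e.time)
            for i, e in enumerate(session.events):
                if e.actor not in ids:
                    raise SchemaError(f"session {session.id!r} row {i}: unknown actor id {e.actor!r}")
                unknown = set(e.observers) - ids
                if unknown:
                    raise SchemaError(
                        f"session {session.id!r} row {i}: unknown observer id(s) {sorted(unknown)}"
                    )
                if e.technique not in self.techniques:
                    raise SchemaError(
                        f"session {session.id!r} row {i}: technique {e.technique!r} "
                        f"not in alphabet {self.techniques}"
                    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_observers(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


def _coerce_age(raw: str, ind_id: str) -> tuple[str, str]:
    """Map the three-level field coding onto the two-level model coding."""
    age = str(raw).strip().lower()
    if age not in ("adult", "juvenile", "infant"):
        raise SchemaError(f"individual {ind_id!r}: age_class {raw!r} not in (adult, juvenile, infant)")
    return ("juvenile" if age == "infant" else age), age


def read_individuals(path: str | Path) -> dict[str, Individual]:
    df = pd.read_csv(path, dtype=str)
    required = {"id", "group", "sex", "age_class", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    individuals: dict[str, Individual] = {}
    for i, row in df.iterrows():
        ind_id = str(row["id"]).strip()
        if ind_id in individuals:
            raise SchemaError(f"{path} row {i}: duplicate id {ind_id!r}")
        age_class, raw_age = _coerce_age(row["age_class"], ind_id)
        matriline = row.get("matriline")
        if matriline is not None and (pd.isna(matriline) or not str(matriline).strip()):
            matriline = None
        individuals[ind_id] = Individual(
            id=ind_id,
            group=str(row["group"]).strip(),
            sex=str(row["sex"]).strip().upper(),
            age_class=age_class,
            rank=float(row["rank"]),
            matriline=None if matriline is None else str(matriline).strip(),
            raw_age_class=raw_age,
        )
    return individuals


def read_kin(path: str | Path) -> pd.DataFrame:
    kin = pd.read_csv(path, index_col=0)
    kin.index = kin.index.astype(str)
    kin.columns = kin.columns.astype(str)
    return kin.astype(float)


def read_event_log(
    events_path: str | Path,
    individuals_path: str | Path,
    kin_path: str | Path,
    techniques: Sequence[str] = DEFAULT_TECHNIQUES,
) -> EventLog:
    """Read and validate the three-file CSV representation of an event log.

    ``events.csv`` columns: session_id, date, time_min, actor_id, technique,
    outcome, observers (semicolon-separated, possibly empty).
    """
    individuals = read_individuals(individuals_path)
    kin = read_kin(kin_path)
    df = pd.read_csv(events_path, dtype={"session_id": str, "actor_id": str, "observers": str})
    required = {"session_id", "date", "time_min", "actor_id", "technique", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{events_path}: missing columns {sorted(missing)}")

    sessions: dict[str, Session] = {}
    for i, row in df.iterrows():
        sid = str(row["session_id"])
        if sid not in sessions:
            sessions[sid] = Session(id=sid, date=str(row["date"]))
        actor = str(row["actor_id"]).strip()
        if actor not in individuals:
            raise SchemaError(f"{events_path} row {i}: unknown actor id {actor!r}")
        sessions[sid].events.append(
            ManipulationEvent(
                session_id=sid,
                time=float(row["time_min"]),
                actor=actor,
                technique=str(row["technique"]).strip(),
                outcome=str(row["outcome"]).strip().lower(),
                observers=_parse_observers(row.get("observers")),
            )
        )
    ordered = sorted(sessions.values(), key=lambda s: (s.date, s.id))
    return EventLog(individuals=individuals, kin=kin, sessions=ordered, techniques=tuple(techniques))


def write_event_log(log: EventLog, out_dir: str | Path) -> dict[str, Path]:
    """Write ``events.csv``, ``individuals.csv`` and ``kin.csv`` under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev_rows = []
    for session in log.sessions:
        for e in session.events:
            ev_rows.append(
                {
                    "session_id": session.id,
                    "date": session.date,
                    "time_min": e.time,
                    "actor_id": e.actor,
                    "technique": e.technique,
                    "outcome": e.outcome,
                    "observers": ";".join(sorted(e.observers)),
                }
            )
    paths = {
        "events": out / "events.csv",
        "individuals": out / "individuals.csv",
        "kin": out / "kin.csv",
    }
    pd.DataFrame(
        ev_rows,
        columns=["session_id", "date", "time_min", "actor_id", "technique", "outcome", "observers"],
    ).to_csv(paths["events"], index=False)
    ind_rows = [
        {
            "id": ind.id,
            "group": ind.group,
            "sex": ind.sex,
            "age_class": ind.raw_age_class or ind.age_class,
            "rank": ind.rank,
            "matriline": ind.matriline or "",
        }
        for ind in log.individuals.values()
    ]
    pd.DataFrame(ind_rows).to_csv(paths["individuals"], index=False)
    log.kin.to_csv(paths["kin"])
    return paths


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def summarize_log(log: EventLog) -> pd.DataFrame:
    """Per-individual participation summary.

    Returns one row per individual that appears as an actor, with success and
    attempt counts, the latency of first success (cumulative exposure minutes
    across that individual's group sessions; NaN if never successful), and
    per-technique success proportions of that individual's own manipulations.
    """
    rows: dict[str, dict] = {}
    # cumulative exposure bookkeeping per group
    exposure: dict[str, float] = {}
    for session in log.sessions:
        session_groups = session.groups(log.individuals)
        for e in session.events:
            ind = log.individuals[e.actor]
            rec = rows.setdefault(
                e.actor,
                {
                    "id": e.actor,
                    "group": ind.group,
                    "sex": ind.sex,
                    "age_class": ind.age_class,
                    "rank": ind.rank,
                    "n_success": 0,
                    "n_attempt": 0,
                    "latency_first_success": np.nan,
                    **{f"n_{t}": 0 for t in log.techniques},
                    **{f"n_success_{t}": 0 for t in log.techniques},
                },
            )
            rec[f"n_{e.technique}"] += 1
            if e.outcome == "success":
                rec["n_success"] += 1
                rec[f"n_success_{e.technique}"] += 1
                if np.isnan(rec["latency_first_success"]):
                    rec["latency_first_success"] = exposure.get(ind.group, 0.0) + e.time
            else:
                rec["n_attempt"] += 1
        for g in session_groups:
            exposure[g] = exposure.get(g, 0.0) + session.duration

    if not rows:
        return pd.DataFrame(
            columns=["id", "group", "sex", "age_class", "rank", "n_success", "n_attempt", "n_manipulation"]
        ).set_index("id")

    df = pd.DataFrame(list(rows.values())).set_index("id")
    df["n_manipulation"] = df["n_success"] + df["n_attempt"]
    for t in log.techniques:
        with np.errstate(invalid="ignore"):
            df[f"prop_success_{t}"] = df[f"n_success_{t}"] / df[f"n_{t}"].replace(0, np.nan)
    return df.sort_index()


def group_success_rates(log: EventLog) -> pd.DataFrame:
    """Per-group technique success shares over *all* of the group's manipulations.

    The share for technique ``i`` is (successes with ``i``) / (all manipulation
    events in the group), so shares over techniques sum to the group's overall
    success proportion.
    """
    records: dict[str, dict] = {}
    for e in log.events():
        g = log.individuals[e.actor].group
        rec = records.setdefault(g, {"group": g, "n_manipulation": 0, **{f"n_success_{t}": 0 for t in log.techniques}})
        rec["n_manipulation"] += 1
        if e.outcome == "success":
            rec[f"n_success_{e.technique}"] += 1
    df = pd.DataFrame(list(records.values())).set_index("group")
    for t in log.techniques:
        df[f"success_share_{t}"] = df[f"n_success_{t}"] / df["n_manipulation"]
    return df.sort_index()


__all__ = [
    "DEFAULT_TECHNIQUES",
    "EventLog",
    "Individual",
    "ManipulationEvent",
    "SchemaError",
    "Session",
    "group_success_rates",
    "read_event_log",
    "read_individuals",
    "read_kin",
    "summarize_log",
    "write_event_log",
]
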