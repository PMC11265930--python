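"""Event-log domain model: trials, solvers, box state, social condition.

The raw substrate is an RFID/video event log: timestamped detections,
door openings (with door id, latch type, work time and an exploratory
diversity count scored from video) and re-baiting events, per site and
testing night. This module turns that log into the analysis units:

* a **trial** — one individual's contiguous visit to the box; a new trial
  begins after the individual is absent for at least one minute;
* a **solver** — an individual that opened at least three doors of the
  same latch type across all its trials (a *flexible* solver solved two
  or more latch types);
* the **social condition** of each trial — *unrestricted* (first solver
  to arrive at a freshly baited, unopened box and not joined by another
  solver) versus *competitive* (another solver present and/or the box
  possibly partially solved on arrival).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import pandas as pd

from .sequences import ALPHABET, LatchSequence

logger = logging.getLogger(__name__)

UNKNOWN_ID = "UNKNOWN"

__all__ = [
    "UNKNOWN_ID",
    "EventLog",
    "Opening",
    "Trial",
    "SolverStatus",
    "SequenceFilters",
    "BoxState",
    "segment_trials",
    "classify_solvers",
    "track_box_state",
    "classify_conditions",
    "bin_work_time",
    "extract_latch_sequences",
    "final_trials_subset",
    "latch_preference_counts",
]


@dataclass
class EventLog:
    """A validated, chronologically sorted event table.

    ``df`` has columns timestamp (datetime64), site_id, box_id, night_id,
    individual_id (``UNKNOWN`` when unidentified), event_type
    (detection | door_open | rebait), door_id, latch_type, work_time_s,
    exploratory_diversity. Rows are sorted by (site_id, night_id,
    timestamp) and retain their original file line numbers in
    ``df["source_line"]`` when read from disk.
    """

    df: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class Opening:
    """One door opening inside a trial."""

    door_id: int
    latch_type: str
    work_time_s: float | None
    work_time_bin: int | None
    exploratory_diversity: int | None


@dataclass
class Trial:
    """One individual's contiguous visit to a box."""

    individual_id: str
    site_id: str
    box_id: int
    night_id: str
    trial_index: int
    start: pd.Timestamp
    end: pd.Timestamp
    openings: list[Opening]
    condition: str = "undetermined"
    first_arrival: bool | None = None
    doors_opened_to_date: int = 0
    first_trial_diversity: int | None = None

    @property
    def latch_states(self) -> tuple[str, ...]:
        return tuple(o.latch_type for o in self.openings)

    @property
    def n_openings(self) -> int:
        return len(self.openings)


@dataclass
class SolverStatus:
    """Per-individual cumulative latch counts and solver/flexible flags."""

    individual_id: str
    latch_counts: dict[str, int]
    solved_latches: frozenset[str]
    is_solver: bool
    is_flexible: bool


def bin_work_time(seconds: float) -> int:
    """Ordinal work-time bin: 1 (<5 s), 2 (5-15 s), 3 (16-30 s), 4 (>=31 s).

    The half-open intervals [5, 16) and [16, 31) close the fractional
    gaps left open by integer-second bin edges.
    """
    if seconds < 0:
        raise ValueError(f"work time must be non-negative, got {seconds}")
    if seconds < 5:
        return 1
    if seconds < 16:
        return 2
    if seconds < 31:
        return 3
    return 4


def segment_trials(
    log: EventLog, absence_threshold: float = 60.0
) -> list[Trial]:
    """Split each identified individual's events into trials.

    Within a (site, box, night), maximal runs of an individual's events
    whose inter-event gaps are strictly below ``absence_threshold`` seconds
    form one trial; a gap of at least the threshold (absence for >= 1 min
    at the default) starts a new trial. Trial indices are assigned
    chronologically per individual across the whole log, and
    ``doors_opened_to_date`` counts the individual's openings in strictly
    earlier trials. Events of unidentified (UNKNOWN) individuals are not
    segmented into trials.
    """
    if absence_threshold <= 0:
        raise ValueError("absence_threshold must be positive")
    df = log.df
    trials: list[Trial] = []
    mask = (df["individual_id"] != UNKNOWN_ID) & (
        df["event_type"].isin(["detection", "door_open"])
    )
    for (ind, site, box, night), grp in df[mask].groupby(
        ["individual_id", "site_id", "box_id", "night_id"], sort=False
    ):
        grp = grp.sort_values("timestamp", kind="stable")
        gaps = grp["timestamp"].diff().dt.total_seconds()
        new_trial = (gaps >= absence_threshold) | gaps.isna()
        for _, sub in grp.groupby(new_trial.cumsum()):
            openings = []
            diversity = None
            for _, row in sub.iterrows():
                if diversity is None and pd.notna(
                    row["exploratory_diversity"]
                ):
                    diversity = int(row["exploratory_diversity"])
                if row["event_type"] == "door_open":
                    wt = (
                        float(row["work_time_s"])
                        if pd.notna(row["work_time_s"])
                        else None
                    )
                    ed = (
                        int(row["exploratory_diversity"])
                        if pd.notna(row["exploratory_diversity"])
                        else None
                    )
                    openings.append(
                        Opening(
                            door_id=int(row["door_id"]),
                            latch_type=str(row["latch_type"]),
                            work_time_s=wt,
                            work_time_bin=(
                                bin_work_time(wt) if wt is not None else None
                            ),
                            exploratory_diversity=ed,
                        )
                    )
            trials.append(
                Trial(
                    individual_id=ind,
                    site_id=site,
                    box_id=int(box),
                    night_id=night,
                    trial_index=0,
                    start=sub["timestamp"].iloc[0],
                    end=sub["timestamp"].iloc[-1],
                    openings=openings,
                    first_trial_diversity=diversity,
                )
            )
    # chronological trial indices and cumulative openings per individual
    trials.sort(key=lambda t: (t.start, t.individual_id))
    counters: dict[str, int] = {}
    opened: dict[str, int] = {}
    for t in trials:
        counters[t.individual_id] = counters.get(t.individual_id, 0) + 1
        t.trial_index = counters[t.individual_id]
        t.doors_opened_to_date = opened.get(t.individual_id, 0)
        opened[t.individual_id] = t.doors_opened_to_date + t.n_openings
    return trials


def classify_solvers(
    trials: list[Trial], min_doors: int = 3
) -> dict[str, SolverStatus]:
    """Cumulative per-latch counts and solver flags per individual.

    An individual solves a latch type once it has opened at least
    ``min_doors`` doors of that type across all its trials; a solver of
    two or more latch types is flexible.
    """
    counts: dict[str, dict[str, int]] = {}
    for t in trials:
        c = counts.setdefault(
            t.individual_id, {a: 0 for a in ALPHABET}
        )
        for o in t.openings:
            c[o.latch_type] = c.get(o.latch_type, 0) + 1
    out: dict[str, SolverStatus] = {}
    for ind, c in counts.items():
        solved = frozenset(a for a, n in c.items() if n >= min_doors)
        out[ind] = SolverStatus(
            individual_id=ind,
            latch_counts=c,
            solved_latches=solved,
            is_solver=bool(solved),
            is_flexible=len(solved) >= 2,
        )
    return out


@dataclass
class BoxState:
    """Open-door state of each box through time, reset at every rebait.

    ``states_before[i]`` is the set of open doors of the box concerned by
    log row position ``i`` immediately *before* that row's event applies.
    A box with no prior rebait record is all-closed by convention.
    ``event_times`` / ``states_after`` hold, per (site, box, night), the
    box's event timestamps in order and the open-door set after each.
    """

    states_before: list[frozenset[int]]
    event_times: dict[tuple[str, int, str], list[pd.Timestamp]]
    states_after: dict[tuple[str, int, str], list[frozenset[int]]]
    rebait_times: dict[tuple[str, int, str], list[pd.Timestamp]]
    warnings: list[str] = field(default_factory=list)

    def state_at(
        self, site_id: str, box_id: int, night_id: str, when: pd.Timestamp
    ) -> frozenset[int]:
        """Open-door set of a box strictly before ``when``."""
        key = (site_id, box_id, night_id)
        times = self.event_times.get(key, [])
        idx = bisect.bisect_left(times, when)
        if idx == 0:
            return frozenset()
        return self.states_after[key][idx - 1]

    def last_rebait(
        self, site_id: str, box_id: int, night_id: str, when: pd.Timestamp
    ) -> pd.Timestamp | None:
        """Most recent rebait of the box at or before ``when`` (None if never)."""
        times = self.rebait_times.get((site_id, box_id, night_id), [])
        idx = bisect.bisect_right(times, when)
        return times[idx - 1] if idx else None


def track_box_state(log: EventLog) -> BoxState:
    """Walk the log computing the open-door set of every box per event.

    Rebait events close all doors of their box; a door_open for an
    already-open door leaves the state unchanged with a logged warning.
    """
    df = log.df.sort_values(
        ["site_id", "night_id", "timestamp"], kind="stable"
    )
    states: dict[tuple[str, int, str], set[int]] = {}
    times: dict[tuple[str, int, str], list[pd.Timestamp]] = {}
    after: dict[tuple[str, int, str], list[frozenset[int]]] = {}
    rebaits: dict[tuple[str, int, str], list[pd.Timestamp]] = {}
    warns: list[str] = []
    per_row: dict[int, frozenset[int]] = {}
    for row in df.itertuples():
        key = (row.site_id, int(row.box_id), row.night_id)
        state = states.setdefault(key, set())
        per_row[row.Index] = frozenset(state)
        if row.event_type == "rebait":
            rebaits.setdefault(key, []).append(row.timestamp)
            state.clear()
        elif row.event_type == "door_open":
            door = int(row.door_id)
            if door in state:
                msg = (
                    f"door {door} at {key} opened while already open "
                    f"(t={row.timestamp})"
                )
                warns.append(msg)
                logger.warning(msg)
            else:
                state.add(door)
        times.setdefault(key, []).append(row.timestamp)
        after.setdefault(key, []).append(frozenset(state))
    before = [per_row[i] for i in log.df.index]
    return BoxState(
        states_before=before,
        event_times=times,
        states_after=after,
        rebait_times=rebaits,
        warnings=warns,
    )


def classify_conditions(
    log: EventLog,
    trials: list[Trial],
    solvers: dict[str, SolverStatus],
    box_state: BoxState | None = None,
    unknown_counts_as_competitor: bool = False,
) -> list[Trial]:
    """Label every trial unrestricted or competitive, in place.

    A trial is *unrestricted* iff the box was unopened (all doors closed)
    at its start, the focal individual was the first solver to arrive
    since the last rebait, and no other solver's events fall within
    [start, end]. Anything else is *competitive*. Conditions are computed
    for non-solver trials too; downstream sequence filters drop them.
    Presence is inferred from temporal overlap of logged events at the
    same box; unidentified individuals count as competitors only when
    ``unknown_counts_as_competitor`` is set.
    """
    if box_state is None:
        box_state = track_box_state(log)
    df = log.df
    competitor_ids = {s for s, st in solvers.items() if st.is_solver}
    for t in trials:
        others = competitor_ids - {t.individual_id}
        if unknown_counts_as_competitor:
            others = others | {UNKNOWN_ID}
        at_box = df[
            (df["site_id"] == t.site_id)
            & (df["box_id"] == t.box_id)
            & (df["night_id"] == t.night_id)
            & (df["individual_id"].isin(others))
            & (df["event_type"].isin(["detection", "door_open"]))
        ]
        state_before = box_state.state_at(
            t.site_id, t.box_id, t.night_id, t.start
        )
        unopened = len(state_before) == 0
        rebait = box_state.last_rebait(
            t.site_id, t.box_id, t.night_id, t.start
        )
        window_start = rebait if rebait is not None else pd.Timestamp.min
        arrived_first = not (
            (at_box["timestamp"] >= window_start)
            & (at_box["timestamp"] < t.start)
        ).any()
        joined = (
            (at_box["timestamp"] >= t.start)
            & (at_box["timestamp"] <= t.end)
        ).any()
        t.first_arrival = unopened and arrived_first
        t.condition = (
            "unrestricted"
            if (unopened and arrived_first and not joined)
            else "competitive"
        )
    return trials


@dataclass
class SequenceFilters:
    """Inclusion rules for the sequence analyses.

    Defaults reproduce the analysis subset used for the dissimilarity
    and complexity analyses: solver trials only, sequences of at least six
    openings, at least six doors opened before the trial starts (so the
    individual had qualified as a solver), restricted to each individual's
    first test year, both social conditions retained.
    """

    solver_only: bool = True
    min_length: int = 6
    min_doors_to_date: int = 6
    first_year_only: bool = True
    condition: str = "both"  # unrestricted | competitive | both


def extract_latch_sequences(
    trials: list[Trial],
    solvers: dict[str, SolverStatus],
    filters: SequenceFilters | None = None,
) -> list[LatchSequence]:
    """One latch sequence per qualifying trial, with metadata attached.

    The first-year filter keeps trials from the earliest calendar year in
    which the individual appears in the log.
    """
    f = filters or SequenceFilters()
    first_year: dict[str, int] = {}
    for t in trials:
        y = t.start.year
        first_year[t.individual_id] = min(
            first_year.get(t.individual_id, y), y
        )
    out: list[LatchSequence] = []
    n_dropped = 0
    for t in trials:
        if f.solver_only and not (
            t.individual_id in solvers
            and solvers[t.individual_id].is_solver
        ):
            n_dropped += 1
            continue
        if t.n_openings < f.min_length:
            n_dropped += 1
            continue
        if t.doors_opened_to_date < f.min_doors_to_date:
            n_dropped += 1
            continue
        if f.first_year_only and t.start.year != first_year[t.individual_id]:
            n_dropped += 1
            continue
        if f.condition != "both" and t.condition != f.condition:
            n_dropped += 1
            continue
        out.append(
            LatchSequence(
                states=t.latch_states,
                individual_id=t.individual_id,
                trial_index=t.trial_index,
                condition=t.condition,
            )
        )
    logger.info(
        "extract_latch_sequences: kept %d of %d trials (%d filtered)",
        len(out), len(trials), n_dropped,
    )
    if not out:
        logger.warning(
            "sequence filters eliminated all %d trials", len(trials)
        )
    return out


def final_trials_subset(
    trials: list[Trial],
    solvers: dict[str, SolverStatus],
    k: int = 5,
    require_first_arrival: bool = True,
    require_solitude: bool = False,
) -> list[Trial]:
    """Per solver, the final ``k`` chronological trials with openings.

    Used for the latch-preference tests: by their final trials solvers
    have learnt every latch they will ever learn. When
    ``require_first_arrival`` is set, only trials where the solver was
    first to arrive at an unopened box qualify (all doors available);
    ``require_solitude`` additionally demands the whole trial was
    unrestricted (no other solver joined). Solvers with fewer than ``k``
    qualifying trials contribute all of them, with a logged warning.
    """
    out: list[Trial] = []
    for ind, st in solvers.items():
        if not st.is_solver:
            continue
        qual = [
            t
            for t in trials
            if t.individual_id == ind
            and t.n_openings > 0
            and (not require_first_arrival or t.first_arrival)
            and (not require_solitude or t.condition == "unrestricted")
        ]
        qual.sort(key=lambda t: t.trial_index)
        if len(qual) < k:
            logger.warning(
                "solver %s has only %d qualifying trials (< %d)",
                ind, len(qual), k,
            )
        out.extend(qual[-k:])
    return out


def latch_preference_counts(
    subset: list[Trial], alphabet: tuple[str, ...] = ALPHABET
) -> tuple[dict[str, int], dict[str, int]]:
    """First-opened and total latch counts over a trial subset."""
    first = {a: 0 for a in alphabet}
    total = {a: 0 for a in alphabet}
    for t in subset:
        if t.openings:
            first[t.openings[0].latch_type] += 1
            for o in t.openings:
                total[o.latch_type] += 1
    return first, total
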