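"""Reading and writing event logs, rosters and derived tables.

File schemas
------------
``events.csv``
    timestamp (ISO 8601), site_id, box_id, night_id, individual_id,
    event_type (detection | door_open | rebait), door_id, latch_type
    (H | R | V | S), work_time_s, exploratory_diversity. door_id and
    latch_type are required for door_open rows and empty otherwise;
    rebait rows carry no individual.
``individuals.csv``
    individual_id, sex (male | female | unknown), age (adult | juvenile |
    unknown), first_test_year, and optionally prior_knowledge
    (naive | knowledgeable) with respect to the horizontal latch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .events import UNKNOWN_ID, EventLog, Trial
from .sequences import ALPHABET

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "timestamp", "site_id", "box_id", "night_id", "individual_id",
    "event_type", "door_id", "latch_type", "work_time_s",
    "exploratory_diversity",
]
ROSTER_COLUMNS = ["individual_id", "sex", "age", "first_test_year"]
EVENT_TYPES = {"detection", "door_open", "rebait"}


class EventLogError(ValueError):
    """A malformed event-log file; the message names the offending line."""


def read_event_log(path) -> EventLog:
    """Parse and validate an events CSV into a sorted :class:`EventLog`.

    Rows are validated one by one so errors can name the file line
    (header = line 1). Unknown individuals are retained under the id
    ``UNKNOWN``; out-of-order timestamps are sorted with a logged warning.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise EventLogError(
            f"{path}: missing required columns {missing}"
        )
    warnings: list[str] = []
    rows = []
    for pos, row in enumerate(raw.itertuples(index=False)):
        line = pos + 2  # header is line 1
        r = dict(zip(raw.columns, row))
        ts = pd.to_datetime(r["timestamp"], errors="coerce")
        if pd.isna(ts):
            raise EventLogError(
                f"{path} line {line}: unparseable timestamp "
                f"{r['timestamp']!r}"
            )
        etype = r["event_type"]
        if etype not in EVENT_TYPES:
            raise EventLogError(
                f"{path} line {line}: unknown event_type {etype!r}"
            )
        door_id = np.nan
        latch = None
        wt = np.nan
        ed = np.nan
        if etype == "door_open":
            try:
                door_id = int(r["door_id"])
            except ValueError:
                raise EventLogError(
                    f"{path} line {line}: door_open needs an integer "
                    f"door_id, got {r['door_id']!r}"
                ) from None
            latch = r["latch_type"]
            if latch not in ALPHABET:
                raise EventLogError(
                    f"{path} line {line}: unknown latch code "
                    f"{latch!r} (expected one of {ALPHABET})"
                )
        if r["work_time_s"] != "":
            wt = float(r["work_time_s"])
            if wt < 0:
                raise EventLogError(
                    f"{path} line {line}: negative work_time_s {wt}"
                )
        if r["exploratory_diversity"] != "":
            ed = int(r["exploratory_diversity"])
            if ed < 0:
                raise EventLogError(
                    f"{path} line {line}: negative exploratory_diversity"
                )
        ind = r["individual_id"].strip()
        if etype == "rebait":
            ind = ""
        if ind == "" and etype != "rebait":
            ind = UNKNOWN_ID
        box_id = int(r["box_id"]) if r["box_id"] != "" else 1
        rows.append(
            {
                "timestamp": ts,
                "site_id": r["site_id"],
                "box_id": box_id,
                "night_id": r["night_id"],
                "individual_id": ind,
                "event_type": etype,
                "door_id": door_id,
                "latch_type": latch,
                "work_time_s": wt,
                "exploratory_diversity": ed,
                "source_line": line,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=EVENT_COLUMNS + ["source_line"],
    )
    n_unknown = int(
        (
            (df["individual_id"] == UNKNOWN_ID)
            & (df["event_type"] != "rebait")
        ).sum()
    )
    if n_unknown:
        msg = f"{n_unknown} events from unidentified individuals retained"
        warnings.append(msg)
        logger.info(msg)
    sorted_df = df.sort_values(
        ["site_id", "night_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    if not sorted_df["source_line"].equals(
        df["source_line"].reset_index(drop=True)
    ):
        msg = "events were out of chronological order and have been sorted"
        warnings.append(msg)
        logger.warning(msg)
    return EventLog(df=sorted_df, warnings=warnings)


def write_event_log(log: EventLog, path) -> None:
    """Write an event log back to CSV in the documented schema."""
    out = log.df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.loc[out["event_type"] == "rebait", "individual_id"] = ""
    out["door_id"] = out["door_id"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["exploratory_diversity"] = out["exploratory_diversity"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["work_time_s"] = out["work_time_s"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out["latch_type"] = out["latch_type"].fillna("")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    """Read the individual roster; individual ids must be unique."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"{path}: missing roster columns {missing}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"]
        raise EventLogError(
            f"{path}: duplicate individual_id values {sorted(set(dup))}"
        )
    if "prior_knowledge" not in df.columns:
        df["prior_knowledge"] = "naive"
    return df


def write_roster(df: pd.DataFrame, path) -> None:
    cols = ROSTER_COLUMNS + (
        ["prior_knowledge"] if "prior_knowledge" in df.columns else []
    )
    df[cols].to_csv(path, index=False)


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """One row per trial: condition, first arrival, sequence, latch counts."""
    rows = []
    for t in trials:
        seq = "".join(t.latch_states)
        counts = {f"n_{a}": seq.count(a) for a in ALPHABET}
        rows.append(
            {
                "individual_id": t.individual_id,
                "site_id": t.site_id,
                "box_id": t.box_id,
                "night_id": t.night_id,
                "trial_index": t.trial_index,
                "start": t.start.strftime("%Y-%m-%dT%H:%M:%S"),
                "end": t.end.strftime("%Y-%m-%dT%H:%M:%S"),
                "n_openings": t.n_openings,
                "doors_opened_to_date": t.doors_opened_to_date,
                "condition": t.condition,
                "first_arrival": t.first_arrival,
                "sequence": seq,
                **counts,
            }
        )
    return pd.DataFrame(rows)
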