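"""Trial segmentation, solver classification, box state and conditions."""

import pandas as pd
import pytest

from latchseq.events import (
    SequenceFilters,
    bin_work_time,
    classify_conditions,
    classify_solvers,
    extract_latch_sequences,
    final_trials_subset,
    latch_preference_counts,
    segment_trials,
    track_box_state,
)
from latchseq.io import read_event_log

BASE = pd.Timestamp("2016-08-01T21:00:00")


def ts(seconds: float, days: int = 0) -> str:
    return (
        BASE + pd.Timedelta(days=days, seconds=seconds)
    ).strftime("%Y-%m-%dT%H:%M:%S")


def det(t, ind, night="N1", ed="", days=0):
    return f"{ts(t, days)},s1,1,{night},{ind},detection,,,,{ed}"


def opening(t, ind, door, latch, night="N1", wt="", ed="", days=0):
    return f"{ts(t, days)},s1,1,{night},{ind},door_open,{door},{latch},{wt},{ed}"


def rebait(t, night="N1", days=0):
    return f"{ts(t, days)},s1,1,{night},,rebait,,,,"


# ------------------------------------------------------------- segmentation


def test_gap_of_70_seconds_splits_trials(write_events):
    log = read_event_log(
        write_events([det(0, "A"), det(30, "A"), det(100, "A")])
    )
    trials = segment_trials(log, absence_threshold=60)
    assert len(trials) == 2
    assert trials[0].end - trials[0].start == pd.Timedelta(seconds=30)
    assert trials[1].start == BASE + pd.Timedelta(seconds=100)
    assert [t.trial_index for t in trials] == [1, 2]


def test_single_event_is_one_trial(write_events):
    log = read_event_log(write_events([det(0, "A")]))
    trials = segment_trials(log)
    assert len(trials) == 1
    assert trials[0].start == trials[0].end


def test_gap_of_exactly_60_seconds_splits(write_events):
    log = read_event_log(write_events([det(0, "A"), det(60, "A")]))
    assert len(segment_trials(log, absence_threshold=60)) == 2


def test_empty_log_gives_no_trials(write_events):
    log = read_event_log(write_events([rebait(0)]))
    assert segment_trials(log) == []


def test_segmentation_partitions_all_identified_events(write_events):
    rows = [
        det(0, "A"), opening(10, "A", 1, "H"), det(200, "A"),
        det(5, "B"), opening(400, "B", 2, "R"),
        rebait(300),
    ]
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    # every identified detection/door_open belongs to exactly one trial
    total_in_trials = 0
    for t in trials:
        span = log.df[
            (log.df["individual_id"] == t.individual_id)
            & (log.df["timestamp"] >= t.start)
            & (log.df["timestamp"] <= t.end)
        ]
        total_in_trials += len(span)
    identified = log.df[
        (log.df["individual_id"].isin(["A", "B"]))
    ]
    assert total_in_trials == len(identified)


def test_doors_opened_to_date_counts_strictly_earlier_trials(write_events):
    rows = [
        opening(0, "A", 1, "H"), opening(20, "A", 2, "H"),
        opening(200, "A", 3, "S"),
    ]
    log = read_event_log(write_events(rows))
    t1, t2 = segment_trials(log)
    assert t1.doors_opened_to_date == 0
    assert t2.doors_opened_to_date == 2


# ------------------------------------------------------------------ solvers


def test_three_same_latch_doors_across_trials_make_a_solver(write_events):
    rows = [
        opening(0, "A", 1, "H"), opening(20, "A", 2, "H"),
        opening(200, "A", 3, "H"),
    ]
    trials = segment_trials(read_event_log(write_events(rows)))
    status = classify_solvers(trials)["A"]
    assert status.is_solver
    assert status.solved_latches == frozenset({"H"})
    assert not status.is_flexible


def test_two_plus_two_openings_do_not_qualify(write_events):
    rows = [
        opening(0, "A", 1, "H"), opening(20, "A", 2, "H"),
        opening(40, "A", 13, "S"), opening(60, "A", 14, "S"),
    ]
    trials = segment_trials(read_event_log(write_events(rows)))
    assert not classify_solvers(trials)["A"].is_solver


def test_three_latch_types_give_flexible_solver(write_events):
    rows = []
    t = 0
    for latch, doors in (("H", (1, 2, 3)), ("S", (10, 11, 12)),
                         ("V", (7, 8, 9))):
        for d in doors:
            rows.append(opening(t, "A", d, latch))
            t += 20
    trials = segment_trials(read_event_log(write_events(rows)))
    status = classify_solvers(trials)["A"]
    assert status.is_flexible and len(status.solved_latches) == 3


def test_latch_counts_sum_to_total_openings(write_events):
    rows = [
        opening(0, "A", 1, "H"), opening(20, "A", 10, "S"),
        opening(300, "B", 2, "H"),
    ]
    trials = segment_trials(read_event_log(write_events(rows)))
    solvers = classify_solvers(trials)
    total = sum(
        sum(s.latch_counts.values()) for s in solvers.values()
    )
    assert total == 3


# ---------------------------------------------------------------- box state


def test_box_state_tracks_openings_and_rebait_reset(write_events):
    rows = [
        rebait(0), opening(30, "A", 5, "H"),
        rebait(100), det(150, "A"),
    ]
    log = read_event_log(write_events(rows))
    bs = track_box_state(log)
    assert bs.state_at("s1", 1, "N1", BASE + pd.Timedelta(seconds=50)) == {5}
    # after the second rebait the box is unopened again
    assert bs.state_at("s1", 1, "N1", BASE + pd.Timedelta(seconds=150)) == frozenset()


def test_box_state_all_closed_without_rebait(write_events):
    log = read_event_log(write_events([det(0, "A")]))
    bs = track_box_state(log)
    assert bs.state_at("s1", 1, "N1", BASE) == frozenset()
    assert bs.last_rebait("s1", 1, "N1", BASE) is None


def test_reopening_an_open_door_warns_and_keeps_state(write_events):
    rows = [rebait(0), opening(10, "A", 5, "H"), opening(20, "B", 5, "H")]
    bs = track_box_state(read_event_log(write_events(rows)))
    assert len(bs.warnings) == 1
    assert bs.state_at("s1", 1, "N1", BASE + pd.Timedelta(seconds=30)) == {5}


# ----------------------------------------------------------- work-time bins


@pytest.mark.parametrize(
    "seconds, expected",
    [(0, 1), (3, 1), (4.999, 1), (5, 2), (15.5, 2), (16, 3), (30.5, 3),
     (31, 4), (120, 4)],
)
def test_work_time_bins(seconds, expected):
    assert bin_work_time(seconds) == expected


def test_negative_work_time_rejected():
    with pytest.raises(ValueError):
        bin_work_time(-1)


# --------------------------------------------------------------- conditions


def _solver_rows(ind, t0, doors, latch, night="N1"):
    rows = [det(t0, ind, night=night)]
    for k, d in enumerate(doors):
        rows.append(opening(t0 + 10 + 15 * k, ind, d, latch, night=night))
    return rows


def test_lone_solver_at_fresh_box_is_unrestricted(write_events):
    rows = [rebait(0)] + _solver_rows("A", 20, (1, 2, 3), "H")
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    assert trials[0].condition == "unrestricted"
    assert trials[0].first_arrival is True


def test_arriving_at_partially_solved_box_is_competitive(write_events):
    rows = (
        [rebait(0)]
        + _solver_rows("A", 20, (1, 2, 3), "H")
        # B arrives 200 s later, after A opened doors; box not rebaited
        + _solver_rows("B", 200, (10, 11, 12), "S")
    )
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    by_ind = {t.individual_id: t for t in trials}
    assert by_ind["B"].condition == "competitive"
    assert by_ind["B"].first_arrival is False
    # A was alone on a fresh box for the whole trial
    assert by_ind["A"].condition == "unrestricted"


def test_overlapping_solver_trials_are_both_competitive(write_events):
    rows = (
        [rebait(0)]
        + _solver_rows("A", 20, (1, 2, 3), "H")
        + _solver_rows("B", 35, (10, 11, 12), "S")  # joins during A's trial
    )
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    assert all(t.condition == "competitive" for t in trials)


def test_nonsolver_presence_does_not_disturb_unrestricted(write_events):
    rows = (
        [rebait(0)]
        + _solver_rows("A", 20, (1, 2, 3), "H")
        + [det(40, "C")]  # scrounger: C never opens a door
    )
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    a = next(t for t in trials if t.individual_id == "A")
    assert a.condition == "unrestricted"


# ------------------------------------------------------------------ filters


def _qualifying_rows():
    """A solver with 3 trials: warm-up (6 doors), then two 6-door trials."""
    rows = [rebait(0)] + _solver_rows("A", 20, (1, 2, 3, 4, 5, 6), "H")
    rows.append(rebait(400))
    rows += _solver_rows("A", 420, (1, 2, 3, 7, 8, 9), "H")
    rows.append(rebait(900))
    rows += _solver_rows("A", 920, (1, 2, 3, 4), "H")
    return rows


def test_sequence_filters_drop_short_and_inexperienced(write_events):
    log = read_event_log(write_events(_qualifying_rows()))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    seqs = extract_latch_sequences(trials, solvers)
    # trial 1 fails min_doors_to_date, trial 3 fails min_length
    assert len(seqs) == 1
    assert seqs[0].trial_index == 2
    assert str(seqs[0]) == "HHHHHH"


def test_first_year_filter_drops_second_year_trials(write_events):
    rows = _qualifying_rows()
    rows.append(rebait(0, days=366))
    rows.append(det(20, "A", days=366))
    rows += [
        opening(30 + 15 * k, "A", d, "H", days=366)
        for k, d in enumerate((1, 2, 3, 7, 8, 9))
    ]
    log = read_event_log(write_events(rows))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    first_only = extract_latch_sequences(trials, solvers)
    both_years = extract_latch_sequences(
        trials, solvers, SequenceFilters(first_year_only=False)
    )
    assert len(both_years) == len(first_only) + 1


def test_filters_can_eliminate_everything(write_events):
    log = read_event_log(write_events([det(0, "A")]))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    assert extract_latch_sequences(trials, solvers) == []


# --------------------------------------------------------------- final five


def _many_trials_rows(n_trials: int, ind="A"):
    rows = []
    t = 0
    for k in range(n_trials):
        rows.append(rebait(t))
        rows += _solver_rows(ind, t + 20, (1, 2, 3), "H")
        t += 400
    return rows


def test_final_five_takes_last_k_qualifying_trials(write_events):
    log = read_event_log(write_events(_many_trials_rows(9)))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    sub = final_trials_subset(trials, solvers, k=5)
    assert sorted(t.trial_index for t in sub) == [5, 6, 7, 8, 9]


def test_final_five_with_too_few_trials_returns_all(write_events):
    log = read_event_log(write_events(_many_trials_rows(3)))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    sub = final_trials_subset(trials, solvers, k=5)
    assert sorted(t.trial_index for t in sub) == [1, 2, 3]


def test_latch_preference_tabulation(write_events):
    log = read_event_log(write_events(_many_trials_rows(5)))
    trials = segment_trials(log)
    solvers = classify_solvers(trials)
    classify_conditions(log, trials, solvers)
    sub = final_trials_subset(trials, solvers, k=5)
    first, total = latch_preference_counts(sub)
    assert first == {"H": 5, "R": 0, "V": 0, "S": 0}
    assert total == {"H": 15, "R": 0, "V": 0, "S": 0}
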