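"""Seeded generator of puzzle-box event logs with known latent structure.

The generator emulates the statistical features the downstream analyses
assume about nightly visitation at a 24-door, four-latch puzzle box:

* a population in which a fraction of individuals are solvers;
* per-individual latch preferences drawn from a Dirichlet distribution
  centred on shared latch-difficulty weights (small concentration =
  strong individuality);
* *sticky* Markovian latch switching — with probability ``stickiness``
  a solver repeats the previous latch, otherwise it samples its
  preference vector;
* *competition sharpening* — during competitive trials preferences are
  raised to ``1 / competition_sharpening`` and renormalised, so
  behaviour concentrates on the individual's favourite latch;
* a work-time learning curve — log-normal work times whose log-mean
  declines linearly in cumulative doors opened;
* naive solvers that start with a single-latch repertoire and expand it
  across trials, versus knowledgeable solvers with the full repertoire;
* non-solvers that visit and scrounge (detection events only).

Every latent parameter is written to ``truth.json`` so recovery tests
are self-describing, and the whole dataset is a deterministic function
of the seed (nights draw from independent counter-derived substreams,
so adding nights never perturbs earlier ones).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import ALPHABET

__all__ = [
    "SyntheticConfig",
    "Population",
    "generate_population",
    "simulate_night",
    "generate_dataset",
    "sharpen_preferences",
    "DOOR_LATCH_MAP",
]

#: Door layout of the multi-solution box: 24 doors on two working sides
#: (1-12 and 13-24), three doors of each latch type per side.
DOOR_LATCH_MAP: dict[int, str] = {
    d: ALPHABET[((d - 1) % 12) // 3] for d in range(1, 25)
}
SIDE_DOORS: tuple[tuple[int, ...], tuple[int, ...]] = (
    tuple(range(1, 13)), tuple(range(13, 25))
)
_LATCH_DOORS: dict[str, list[int]] = {
    a: [d for d, l in DOOR_LATCH_MAP.items() if l == a] for a in ALPHABET
}


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generative model.

    Defaults mirror the field conditions of the multi-solution
    experiment: 31 individuals tested over 31 nights with roughly a
    quarter of them solvers, latch-difficulty weights ordered
    swivel > horizontal > vertical > rod.
    """

    n_individuals: int = 31
    prop_juvenile: float = 0.5
    prop_solvers: float = 0.23
    #: Dirichlet concentration of per-individual latch preferences;
    #: small values give strongly individual profiles.
    preference_concentration: float = 2.0
    #: Probability of repeating the previous latch type.
    stickiness: float = 0.4
    #: Preferences are raised to 1/tau during competitive trials;
    #: tau = 1 leaves them unchanged.
    competition_sharpening: float = 0.5
    #: Per-opening decline of the expected log work time (log-seconds).
    learning_slope: float = 0.05
    nights: int = 31
    #: Inclusive (low, high) bounds on a solver's trials per night.
    trials_per_night: tuple[int, int] = (1, 2)
    #: Inclusive (low, high) bounds on openings per trial.
    openings_per_trial: tuple[int, int] = (4, 12)
    #: Shared latch-difficulty weights (easiest first); must sum to 1.
    latch_difficulty: dict[str, float] = field(
        default_factory=lambda: {
            "S": 0.295, "H": 0.269, "V": 0.262, "R": 0.174
        }
    )
    #: Fraction of solvers with prior knowledge of the horizontal latch
    #: (full repertoire from the start); the rest are naive.
    prop_knowledgeable: float = 0.5
    #: A naive solver adds one latch to its repertoire every this many trials.
    repertoire_expand_every: int = 2
    #: Bait cycles per night; each starts with a rebait event.
    rebaits_per_night: int = 4
    #: Probability that a bait cycle is visited by two solvers at once
    #: (a competitive trial for both).
    p_joint: float = 0.5
    #: Per-cycle visit probability of each non-solver (scrounging presence).
    p_scrounger_visit: float = 0.15
    #: Baseline log work time (log-seconds) and its spread.
    work_time_mu0: float = math.log(18.0)
    work_time_sigma: float = 0.8
    #: Per-opening decline in the expected exploratory-diversity count.
    diversity_decline: float = 0.05
    site_id: str = "site1"
    box_id: int = 1
    first_year: int = 2016
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("prop_juvenile", "prop_solvers", "stickiness",
                     "prop_knowledgeable", "p_joint", "p_scrounger_visit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.preference_concentration <= 0:
            raise ValueError("preference_concentration must be > 0")
        if not 0.0 < self.competition_sharpening <= 1.0:
            raise ValueError("competition_sharpening must be in (0, 1]")
        if self.learning_slope < 0:
            raise ValueError("learning_slope must be >= 0")
        for name in ("trials_per_night", "openings_per_trial"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= low <= high")
        if set(self.latch_difficulty) != set(ALPHABET):
            raise ValueError(
                "latch_difficulty must weight exactly the latches "
                f"{ALPHABET}"
            )
        if not math.isclose(sum(self.latch_difficulty.values()), 1.0,
                            abs_tol=1e-9):
            raise ValueError("latch_difficulty weights must sum to 1")
        if self.nights < 1 or self.rebaits_per_night < 1:
            raise ValueError("nights and rebaits_per_night must be >= 1")


@dataclass
class _IndividualState:
    """Latent traits plus mutable simulation state of one individual."""

    individual_id: str
    sex: str
    age: str
    is_solver: bool
    knowledgeable: bool
    theta: np.ndarray  # preference over ALPHABET
    kappa: float
    first_trial_diversity: int
    diversity_base: float
    repertoire: list[str] = field(default_factory=list)
    cum_openings: int = 0
    trials_done: int = 0
    emitted_first_diversity: bool = False


@dataclass
class Population:
    """Roster table plus per-individual latent traits and state."""

    roster: pd.DataFrame
    individuals: dict[str, _IndividualState]

    @property
    def solvers(self) -> list[str]:
        return [
            i for i, s in self.individuals.items() if s.is_solver
        ]

    @property
    def non_solvers(self) -> list[str]:
        return [
            i for i, s in self.individuals.items() if not s.is_solver
        ]


def sharpen_preferences(theta: np.ndarray, tau: float) -> np.ndarray:
    """Raise preferences to ``1/tau`` and renormalise; identity at tau = 1."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    if tau == 1.0:
        return theta
    p = np.power(theta, 1.0 / tau)
    return p / p.sum()


def generate_population(cfg: SyntheticConfig) -> Population:
    """Draw the roster and latent traits; deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    weights = np.array([cfg.latch_difficulty[a] for a in ALPHABET])
    rows = []
    individuals: dict[str, _IndividualState] = {}
    for i in range(cfg.n_individuals):
        ind = f"R{i + 1:02d}"
        sex = "female" if rng.random() < 0.5 else "male"
        age = "juvenile" if rng.random() < cfg.prop_juvenile else "adult"
        solver = rng.random() < cfg.prop_solvers
        knowledgeable = solver and (
            rng.random() < cfg.prop_knowledgeable
        )
        theta = rng.dirichlet(cfg.preference_concentration * weights)
        juv = age == "juvenile"
        ed_first = 1 + rng.poisson(3 + 4 * solver + 2 * juv)
        ed_base = 4.0 + 3.0 * solver + 1.5 * juv
        if knowledgeable:
            repertoire = list(ALPHABET)
        else:
            repertoire = [ALPHABET[int(np.argmax(theta))]]
        individuals[ind] = _IndividualState(
            individual_id=ind,
            sex=sex,
            age=age,
            is_solver=solver,
            knowledgeable=knowledgeable,
            theta=theta,
            kappa=cfg.stickiness,
            first_trial_diversity=int(ed_first),
            diversity_base=ed_base,
            repertoire=repertoire,
        )
        rows.append(
            {
                "individual_id": ind,
                "sex": sex,
                "age": age,
                "first_test_year": cfg.first_year,
                "prior_knowledge": (
                    "knowledgeable" if knowledgeable else "naive"
                ),
            }
        )
    return Population(roster=pd.DataFrame(rows), individuals=individuals)


def _expand_repertoire(st: _IndividualState, cfg: SyntheticConfig) -> None:
    """Naive solvers add their next-preferred latch every few trials."""
    if len(st.repertoire) >= len(ALPHABET):
        return
    due = st.trials_done // cfg.repertoire_expand_every + 1
    order = [ALPHABET[j] for j in np.argsort(-st.theta)]
    for a in order:
        if len(st.repertoire) >= min(due, len(ALPHABET)):
            break
        if a not in st.repertoire:
            st.repertoire.append(a)


def _draw_sequence(
    st: _IndividualState,
    n_openings: int,
    competitive: bool,
    available: set[int],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> list[tuple[int, str]]:
    """Sticky Markov chain over the repertoire, constrained to closed doors."""
    theta = st.theta
    if competitive:
        theta = sharpen_preferences(theta, cfg.competition_sharpening)
    openings: list[tuple[int, str]] = []
    prev: str | None = None
    for _ in range(n_openings):
        open_latches = [
            a for a in st.repertoire
            if any(d in available for d in _LATCH_DOORS[a])
        ]
        if not open_latches:
            break
        if prev in open_latches and rng.random() < st.kappa:
            latch = prev
        else:
            w = np.array(
                [theta[ALPHABET.index(a)] for a in open_latches]
            )
            latch = open_latches[
                int(rng.choice(len(open_latches), p=w / w.sum()))
            ]
        doors = [d for d in _LATCH_DOORS[latch] if d in available]
        door = int(doors[int(rng.integers(len(doors)))])
        available.discard(door)
        openings.append((door, latch))
        prev = latch
    return openings


def _draw_work_time(
    st: _IndividualState, cfg: SyntheticConfig, rng: np.random.Generator
) -> float:
    mu = cfg.work_time_mu0 - cfg.learning_slope * st.cum_openings
    wt = float(np.exp(rng.normal(mu, cfg.work_time_sigma)))
    return round(min(max(wt, 0.5), 300.0), 1)


def _draw_diversity(
    st: _IndividualState, cfg: SyntheticConfig, rng: np.random.Generator
) -> int:
    rate = max(0.3, st.diversity_base
               - cfg.diversity_decline * st.cum_openings)
    return int(rng.poisson(rate))


def simulate_night(
    population: Population,
    night_index: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[dict], list[dict]]:
    """Simulate one testing night: rebaited bait cycles with visits.

    Each bait cycle opens with a rebait event; either one solver visits
    alone (an unrestricted trial) or, with probability ``p_joint``, two
    solvers overlap (competitive trials for both). Non-solvers appear as
    detection-only scrounging visits. Returns ``(events, truth_trials)``
    where ``truth_trials`` records the intended condition labels.
    Mutates per-individual learning state in ``population``.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1 + night_index])
    night_id = f"N{night_index + 1:02d}"
    base = pd.Timestamp(
        year=cfg.first_year, month=8, day=1, hour=21
    ) + pd.Timedelta(days=night_index)
    t = base
    events: list[dict] = []
    truth: list[dict] = []
    lo, hi = cfg.trials_per_night
    quota = {
        ind: int(rng.integers(lo, hi + 1)) for ind in population.solvers
    }

    def emit(ts, ind, etype, door_id=None, latch=None, wt=None, ed=None):
        events.append(
            {
                "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                "site_id": cfg.site_id,
                "box_id": cfg.box_id,
                "night_id": night_id,
                "individual_id": ind or "",
                "event_type": etype,
                "door_id": "" if door_id is None else door_id,
                "latch_type": "" if latch is None else latch,
                "work_time_s": "" if wt is None else wt,
                "exploratory_diversity": "" if ed is None else ed,
            }
        )

    for cycle in range(cfg.rebaits_per_night):
        emit(t, None, "rebait")
        eligible = [i for i in population.solvers if quota[i] > 0]
        n_vis = 0
        if eligible:
            n_vis = (
                2 if len(eligible) >= 2 and rng.random() < cfg.p_joint
                else 1
            )
        visitors = [
            eligible[j]
            for j in rng.choice(len(eligible), size=n_vis, replace=False)
        ] if n_vis else []
        competitive = n_vis >= 2
        cycle_end = t
        # every visitor works one side of the box (three doors per latch);
        # joint visitors take opposite sides, so the door constraint is
        # identical across social conditions
        first_side = int(rng.integers(2))
        sides = [set(SIDE_DOORS[first_side]), set(SIDE_DOORS[1 - first_side])]
        # schedule solver visits; the second arrives mid-way through the
        # first's trial so their events overlap in time
        arrivals = [t + pd.Timedelta(seconds=int(rng.integers(20, 40)))]
        if competitive:
            # 15-25 s after the first arrival: inside the first trial's
            # window whenever that trial has at least two openings
            arrivals.append(
                arrivals[0] + pd.Timedelta(seconds=int(rng.integers(15, 26)))
            )
        for v, (ind, t_arr) in enumerate(zip(visitors, arrivals)):
            st = population.individuals[ind]
            quota[ind] -= 1
            lo_o, hi_o = cfg.openings_per_trial
            n_open = int(rng.integers(lo_o, hi_o + 1))
            ed_arr = None
            if not st.emitted_first_diversity:
                ed_arr = st.first_trial_diversity
                st.emitted_first_diversity = True
            emit(t_arr, ind, "detection", ed=ed_arr)
            seq = _draw_sequence(
                st, n_open, competitive, sides[v], cfg, rng
            )
            ts = t_arr
            for door, latch in seq:
                ts = ts + pd.Timedelta(seconds=int(rng.integers(10, 40)))
                wt = _draw_work_time(st, cfg, rng)
                ed = _draw_diversity(st, cfg, rng)
                emit(ts, ind, "door_open", door_id=door, latch=latch,
                     wt=wt, ed=ed)
                st.cum_openings += 1
            st.trials_done += 1
            if st.is_solver and not st.knowledgeable:
                _expand_repertoire(st, cfg)
            cycle_end = max(cycle_end, ts)
            truth.append(
                {
                    "individual_id": ind,
                    "night_id": night_id,
                    "cycle": cycle,
                    "condition": (
                        "competitive" if competitive else "unrestricted"
                    ),
                    "n_openings": len(seq),
                    "sequence": "".join(l for _, l in seq),
                }
            )
        # detection-only scrounging visits by non-solvers, placed after
        # the solver trials so they never overlap an unrestricted trial
        scrounge_t = cycle_end + pd.Timedelta(seconds=90)
        for ind in population.non_solvers:
            if rng.random() < cfg.p_scrounger_visit:
                st = population.individuals[ind]
                ed_arr = None
                if not st.emitted_first_diversity:
                    ed_arr = st.first_trial_diversity
                    st.emitted_first_diversity = True
                emit(scrounge_t, ind, "detection", ed=ed_arr)
                scrounge_t = scrounge_t + pd.Timedelta(
                    seconds=int(rng.integers(5, 20))
                )
        # at least a minute of silence before the next bait cycle so
        # consecutive visits by the same individual segment into trials
        t = max(cycle_end, scrounge_t) + pd.Timedelta(
            seconds=int(rng.integers(120, 180))
        )
    return events, truth


def generate_dataset(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write ``events.csv``, ``individuals.csv`` and ``truth.json``.

    Byte-identical across runs with the same config and seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    population = generate_population(cfg)
    all_events: list[dict] = []
    all_truth: list[dict] = []
    for night in range(cfg.nights):
        ev, tr = simulate_night(population, night, cfg)
        all_events.extend(ev)
        all_truth.extend(tr)
    events_path = outdir / "events.csv"
    roster_path = outdir / "individuals.csv"
    truth_path = outdir / "truth.json"
    events_df = pd.DataFrame(
        all_events,
        columns=[
            "timestamp", "site_id", "box_id", "night_id", "individual_id",
            "event_type", "door_id", "latch_type", "work_time_s",
            "exploratory_diversity",
        ],
    )
    events_df = events_df.sort_values(
        ["site_id", "night_id", "timestamp"], kind="stable"
    )
    events_df.to_csv(events_path, index=False)
    population.roster.to_csv(roster_path, index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["trials_per_night"] = list(cfg.trials_per_night)
    cfg_dict["openings_per_trial"] = list(cfg.openings_per_trial)
    truth = {
        "config": cfg_dict,
        "individuals": {
            ind: {
                "is_solver": st.is_solver,
                "knowledgeable": st.knowledgeable,
                "theta": {
                    a: float(st.theta[i]) for i, a in enumerate(ALPHABET)
                },
                "kappa": st.kappa,
                "sex": st.sex,
                "age": st.age,
                "first_trial_diversity": st.first_trial_diversity,
            }
            for ind, st in population.individuals.items()
        },
        "n_solvers": len(population.solvers),
        "trials": all_truth,
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "events": events_path,
        "roster": roster_path,
        "truth": truth_path,
    }
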