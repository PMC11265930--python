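"""End-to-end analysis pipeline: event log -> trials -> sequences -> stats.

``run_pipeline`` chains every stage on a single events/roster pair and
writes the full artifact set:

* ``trials.csv`` — segmented trials with condition and latch counts;
* ``sequences.csv`` — qualifying latch sequences per filter profile;
* ``complexity.csv`` — entropy, transitions and complexity per sequence;
* ``distances.csv`` — long-format pairwise normalised OM distances;
* ``doors.csv`` — per-door work-time-bin and diversity series for
  external learning-curve models;
* ``stats_report.json`` — every test and the model-competition table;
* ``summary.txt`` — a human-readable digest.

Outputs are pure functions of (inputs, config, seed); each report is
stamped with a config hash so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import io as lio
from . import sequences as sq
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of every analysis threshold and filter.

    The defaults form the standard analysis profile: trials split by a
    one-minute absence, solvers need three same-latch doors, sequence
    analyses keep unrestricted-and-competitive solver sequences of at
    least six openings from individuals with at least six doors opened
    to date in their first test year, and latch preferences are tested
    on the final five first-arrival trials per solver.
    """

    events_path: str = "events.csv"
    roster_path: str = "individuals.csv"
    out_dir: str = "results"
    absence_threshold: float = 60.0
    solver_min_doors: int = 3
    min_sequence_length: int = 6
    min_doors_to_date: int = 6
    final_trials_k: int = 5
    normalization: str = "longest"  # longest | sum | none
    cost_pooling: str = "pooled"  # pooled | per_condition
    condition_filter: str = "both"  # both | unrestricted | competitive
    first_year_only: bool = True
    unknown_counts_as_competitor: bool = False
    trial_block_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.absence_threshold <= 0:
            raise ValueError("absence_threshold must be positive")
        for name in ("solver_min_doors", "min_sequence_length",
                     "min_doors_to_date", "final_trials_k",
                     "trial_block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.normalization not in ("longest", "sum", "none"):
            raise ValueError(
                f"unknown normalization {self.normalization!r}"
            )
        if self.cost_pooling not in ("pooled", "per_condition"):
            raise ValueError(f"unknown cost_pooling {self.cost_pooling!r}")
        if self.condition_filter not in (
            "both", "unrestricted", "competitive"
        ):
            raise ValueError(
                f"unknown condition_filter {self.condition_filter!r}"
            )

    def content_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        params = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("events_path", "roster_path", "out_dir")
        }
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Paths to artifacts plus the in-memory objects stages produced."""

    paths: dict[str, Path]
    trials: list[ev.Trial]
    solvers: dict[str, ev.SolverStatus]
    sequences: list[sq.LatchSequence]
    report: dict


def _condition_analysis(
    seqs: list[sq.LatchSequence],
    condition: str,
    sc: sq.SubstitutionCostMatrix | None,
    cfg: PipelineConfig,
) -> tuple[dict, pd.DataFrame, np.ndarray]:
    """Distances, intra/inter partition and rank test for one condition."""
    sub = [s for s in seqs if s.condition == condition]
    if len(sub) < 2:
        return (
            {"skipped": f"fewer than 2 {condition} sequences"},
            pd.DataFrame(),
            np.array([]),
        )
    if sc is None:  # per-condition cost estimation
        sc = sq.trate_costs(sq.estimate_transition_rates(sub))
    dm = sq.pairwise_distances(
        sub, sc, normalize=True, method=cfg.normalization
    )
    intra, inter = sq.partition_dissimilarities(dm)
    rows = []
    m = len(sub)
    for k in range(m):
        for l in range(k + 1, m):
            same = dm.labels[k][0] == dm.labels[l][0]
            rows.append(
                {
                    "id1": dm.labels[k][0],
                    "trial1": dm.labels[k][1],
                    "id2": dm.labels[l][0],
                    "trial2": dm.labels[l][1],
                    "condition": condition,
                    "d": dm.d[k, l],
                    "d_norm": dm.d_norm[k, l],
                    "pair_type": "intra" if same else "inter",
                }
            )
    long = pd.DataFrame(rows)
    block: dict = {
        "n_sequences": m,
        "n_intra_pairs": int(intra.size),
        "n_inter_pairs": int(inter.size),
        "median_intra": float(np.median(intra)) if intra.size else None,
        "median_inter": float(np.median(inter)) if inter.size else None,
    }
    if intra.size and inter.size:
        block["intra_vs_inter"] = st.mann_whitney(intra, inter).as_dict()
    return block, long, intra


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write the full artifact bundle."""
    cfg.validate()
    for p in (cfg.events_path, cfg.roster_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log = lio.read_event_log(cfg.events_path)
    roster = lio.read_roster(cfg.roster_path)

    trials = ev.segment_trials(log, cfg.absence_threshold)
    solvers = ev.classify_solvers(trials, cfg.solver_min_doors)
    box_state = ev.track_box_state(log)
    ev.classify_conditions(
        log, trials, solvers, box_state,
        unknown_counts_as_competitor=cfg.unknown_counts_as_competitor,
    )

    paths: dict[str, Path] = {}
    trials_df = lio.trials_to_frame(trials)
    paths["trials"] = out / "trials.csv"
    trials_df.to_csv(paths["trials"], index=False)

    filters = ev.SequenceFilters(
        solver_only=True,
        min_length=cfg.min_sequence_length,
        min_doors_to_date=cfg.min_doors_to_date,
        first_year_only=cfg.first_year_only,
        condition=cfg.condition_filter,
    )
    seqs = ev.extract_latch_sequences(trials, solvers, filters)
    seq_df = pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "trial_index": s.trial_index,
                "condition": s.condition,
                "sequence": str(s),
            }
            for s in seqs
        ]
    )
    paths["sequences"] = out / "sequences.csv"
    seq_df.to_csv(paths["sequences"], index=False)

    # --- complexity ----------------------------------------------------
    prior = dict(
        zip(roster["individual_id"], roster.get("prior_knowledge", ""))
    )
    comp_rows = []
    for s in seqs:
        c = sq.complexity_index(s)
        comp_rows.append(
            {
                "individual_id": s.individual_id,
                "trial_index": s.trial_index,
                "condition": s.condition,
                "prior_knowledge": prior.get(s.individual_id, "unknown"),
                "h": c.h,
                "q": c.q,
                "C": c.C,
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    paths["complexity"] = out / "complexity.csv"
    comp_df.to_csv(paths["complexity"], index=False)

    complexity_block: dict = {"skipped": "no qualifying sequences"}
    if len(comp_df):
        # per-individual sequence order defines trial blocks (1-3, 4-6, ...)
        comp_df = comp_df.sort_values(
            ["individual_id", "trial_index"], kind="stable"
        )
        comp_df["seq_rank"] = comp_df.groupby("individual_id").cumcount() + 1
        comp_df["trial_block"] = (
            (comp_df["seq_rank"] - 1) // cfg.trial_block_size + 1
        )
        blocks = {}
        for (pk, blk), grp in comp_df.groupby(
            ["prior_knowledge", "trial_block"]
        ):
            blocks[f"{pk}_block{blk}"] = {
                "median_C": float(grp["C"].median()),
                "n": int(len(grp)),
            }
        complexity_block = {
            "median_C_overall": float(comp_df["C"].median()),
            "per_group_block": blocks,
        }

    # --- dissimilarity --------------------------------------------------
    sc = None
    if cfg.cost_pooling == "pooled" and len(seqs) >= 1:
        try:
            sc = sq.trate_costs(sq.estimate_transition_rates(seqs))
        except ValueError:
            sc = None
    dissim: dict = {}
    longs = []
    intra_by_cond: dict[str, np.ndarray] = {}
    for condition in ("unrestricted", "competitive"):
        if cfg.condition_filter not in ("both", condition):
            continue
        block, long, intra = _condition_analysis(seqs, condition, sc, cfg)
        dissim[condition] = block
        intra_by_cond[condition] = intra
        if len(long):
            longs.append(long)
    if (
        intra_by_cond.get("unrestricted", np.array([])).size
        and intra_by_cond.get("competitive", np.array([])).size
    ):
        dissim["intra_unrestricted_vs_competitive"] = st.mann_whitney(
            intra_by_cond["unrestricted"], intra_by_cond["competitive"]
        ).as_dict()
    paths["distances"] = out / "distances.csv"
    (
        pd.concat(longs, ignore_index=True)
        if longs
        else pd.DataFrame(
            columns=["id1", "trial1", "id2", "trial2", "condition",
                     "d", "d_norm", "pair_type"]
        )
    ).to_csv(paths["distances"], index=False)

    # --- latch preferences (final trials per solver) --------------------
    final = ev.final_trials_subset(
        trials, solvers, k=cfg.final_trials_k, require_first_arrival=True
    )
    first_counts, total_counts = ev.latch_preference_counts(final)
    preference: dict = {
        "first_opened_counts": first_counts,
        "total_opened_counts": total_counts,
        "n_trials": len(final),
    }
    if sum(first_counts.values()) > 0:
        preference["chisq_first"] = st.chisq_uniform_gof(
            list(first_counts.values())
        ).as_dict()
        preference["chisq_total"] = st.chisq_uniform_gof(
            list(total_counts.values())
        ).as_dict()
    else:
        preference["skipped"] = "no qualifying final trials"

    # --- predictors of solving success ----------------------------------
    glm_block: dict = {"skipped": "insufficient data"}
    first_div = {}
    first_bin = {}
    for t in sorted(trials, key=lambda t: t.trial_index):
        if t.individual_id not in first_div:
            if t.first_trial_diversity is not None:
                first_div[t.individual_id] = t.first_trial_diversity
        if t.individual_id not in first_bin:
            bins = [
                o.work_time_bin for o in t.openings
                if o.work_time_bin is not None
            ]
            if bins:
                first_bin[t.individual_id] = bins[0]
    rows = []
    for _, r in roster.iterrows():
        ind = r["individual_id"]
        if ind not in first_div:
            continue
        rows.append(
            {
                "individual_id": ind,
                "age": r["age"],
                "sex": r["sex"],
                "first_diversity": first_div[ind],
                "first_work_bin": first_bin.get(ind, np.nan),
                "solver": int(
                    ind in solvers and solvers[ind].is_solver
                ),
            }
        )
    glm_df = pd.DataFrame(rows)
    if len(glm_df) >= 10 and glm_df["solver"].nunique() == 2:
        candidates = ["age", "sex", "first_diversity"]
        if glm_df["first_work_bin"].notna().all():
            candidates.append("first_work_bin")
        try:
            comparison = st.forward_stepwise(
                glm_df[candidates], glm_df["solver"].to_numpy(),
                candidates=candidates,
            )
            glm_block = {
                "selected": comparison.selected,
                "table": comparison.table.to_dict(orient="records"),
                "steps": comparison.steps,
                "fits": [f.as_dict() for f in comparison.fits],
                "n": int(len(glm_df)),
            }
        except (st.SeparationError, ValueError) as e:
            glm_block = {"skipped": f"model fitting failed: {e}"}

    # --- per-door learning series ---------------------------------------
    door_rows = []
    for t in sorted(trials, key=lambda t: (t.individual_id, t.trial_index)):
        base = t.doors_opened_to_date
        for j, o in enumerate(t.openings, start=1):
            door_rows.append(
                {
                    "individual_id": t.individual_id,
                    "trial_index": t.trial_index,
                    "door_number": base + j,
                    "latch_type": o.latch_type,
                    "work_time_s": o.work_time_s,
                    "work_time_bin": o.work_time_bin,
                    "exploratory_diversity": o.exploratory_diversity,
                }
            )
    doors_df = pd.DataFrame(door_rows)
    paths["doors"] = out / "doors.csv"
    doors_df.to_csv(paths["doors"], index=False)

    # --- report ----------------------------------------------------------
    n_ind = len({t.individual_id for t in trials})
    n_solvers = sum(s.is_solver for s in solvers.values())
    n_flexible = sum(s.is_flexible for s in solvers.values())
    report = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "counts": {
            "n_events": len(log),
            "n_individuals_tested": n_ind,
            "n_trials": len(trials),
            "n_solvers": n_solvers,
            "prop_solvers": (n_solvers / n_ind) if n_ind else None,
            "n_flexible_solvers": n_flexible,
            "n_sequences": len(seqs),
        },
        "latch_preference": preference,
        "complexity": complexity_block,
        "dissimilarity": dissim,
        "success_models": glm_block,
    }
    paths["stats_report"] = out / "stats_report.json"
    paths["stats_report"].write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )

    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(_summarize(report))
    return PipelineResult(
        paths=paths, trials=trials, solvers=solvers, sequences=seqs,
        report=report,
    )


def _fmt(v, nd=3):
    return "NA" if v is None else f"{v:.{nd}f}"


def _summarize(report: dict) -> str:
    c = report["counts"]
    lines = [
        "latchseq pipeline summary",
        f"config_hash={report['config_hash']} seed={report['seed']}",
        "",
        f"individuals tested: {c['n_individuals_tested']}  "
        f"trials: {c['n_trials']}  events: {c['n_events']}",
        f"solvers: {c['n_solvers']} "
        f"({_fmt(c['prop_solvers'], 2)} of tested), "
        f"flexible: {c['n_flexible_solvers']}",
        "",
    ]
    pref = report["latch_preference"]
    if "chisq_first" in pref:
        lines += [
            "latch preference (final trials per solver):",
            f"  first opened: {pref['first_opened_counts']}  "
            f"chi2={pref['chisq_first']['statistic']:.3f} "
            f"p={pref['chisq_first']['p_value']:.2e}",
            f"  total opened: {pref['total_opened_counts']}  "
            f"chi2={pref['chisq_total']['statistic']:.3f} "
            f"p={pref['chisq_total']['p_value']:.2e}",
        ]
    else:
        lines.append("latch preference: SKIPPED")
    comp = report["complexity"]
    if "skipped" in comp:
        lines.append("complexity: SKIPPED")
    else:
        lines.append(
            f"complexity median (all sequences): "
            f"{_fmt(comp['median_C_overall'])}"
        )
        for key, blk in sorted(comp["per_group_block"].items()):
            lines.append(
                f"  {key}: median C={_fmt(blk['median_C'])} (n={blk['n']})"
            )
    lines.append("")
    for cond in ("unrestricted", "competitive"):
        blk = report["dissimilarity"].get(cond)
        if blk is None or "skipped" in blk:
            lines.append(f"dissimilarity [{cond}]: SKIPPED")
            continue
        t = blk.get("intra_vs_inter", {})
        lines.append(
            f"dissimilarity [{cond}]: median intra="
            f"{_fmt(blk['median_intra'])} inter={_fmt(blk['median_inter'])}"
            + (
                f"  W={t['statistic']:.1f} p={t['p_value']:.2e}"
                if t else ""
            )
        )
    cross = report["dissimilarity"].get(
        "intra_unrestricted_vs_competitive"
    )
    if cross:
        lines.append(
            "intra unrestricted vs competitive: "
            f"W={cross['statistic']:.1f} p={cross['p_value']:.2e}"
        )
    lines.append("")
    glm = report["success_models"]
    if "skipped" in glm:
        lines.append(f"success models: SKIPPED ({glm['skipped']})")
    else:
        lines.append(f"success models (n={glm['n']}): best = {glm['selected']}")
        for row in glm["table"]:
            lines.append(
                f"  {row['model']}: AICc={row['AICc']:.2f} "
                f"dAICc={row['delta_AICc']:.2f} w={row['weight']:.2f}"
            )
    return "\n".join(lines) + "\n"
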