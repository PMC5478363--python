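"""End-to-end analysis pipeline: events and scans in, ranked models out.

Stage order mirrors how the results are reported: dominance scores and
their stability first, then perch position, then model selection over
the developmental predictors for each response.  Every stage logs its
record counts so filter effects (discarded scans, substitute-bird
exclusions) are auditable, and all outputs are plain CSV keyed by bird
id.  Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    Bird,
    DisplacementEvent,
    read_birds,
    read_displacements,
    read_scans,
    sort_events,
)
from .dominance import davids_weekly_and_overall, elo_sequence, elo_stability
from .model_selection import (
    dtl_comparison,
    enumerate_main_candidates,
    fit_candidates,
    mediator_comparison,
    rank_models,
)
from .perch import average_perch_position
from .repeatability import icc_oneway, pearson_with_ci
from .synthetic_data import SimulationConfig, generate_cohort, generate_displacements, generate_scans

__all__ = ["RunConfig", "analysis_frame", "stability_report", "run_full_analysis"]

logger = logging.getLogger("domhier")


@dataclass
class RunConfig:
    """Inputs and options for one full analysis run.

    Either the three CSV paths or a :class:`SimulationConfig` must be
    given.  ``out_dir`` receives all output tables; ``None`` keeps the
    results in memory only.
    """

    birds_csv: str | None = None
    displacements_csv: str | None = None
    scans_csv: str | None = None
    simulation: SimulationConfig | None = None
    out_dir: str | None = None
    elo_start: float = 1000.0
    elo_k: float = 100.0
    expectation: str = "normal"
    retention_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.retention_threshold <= 0:
            raise ValueError("retention threshold must be > 0")
        has_files = all(p is not None for p in (self.birds_csv, self.displacements_csv, self.scans_csv))
        if not has_files and self.simulation is None:
            raise ValueError("provide either the three input CSVs or a simulation config")


def analysis_frame(birds: Sequence[Bird], ds_table: pd.DataFrame, perch_table: pd.DataFrame) -> pd.DataFrame:
    """One row per non-substitute bird, ready for model fitting.

    Columns: family, sex, amount, effort, tarsus, weight, delta_tl,
    davids_overall, perch_overall; indexed by bird id.
    """
    ds_overall = ds_table[ds_table["scope"] == "overall"].set_index("bird")["ds"]
    perch_overall = perch_table[perch_table["scope"] == "overall"].set_index("bird")["score"]
    rows = {}
    for b in birds:
        if b.is_substitute:
            continue
        rows[b.id] = {
            "family": b.family,
            "sex": b.sex,
            "amount": b.amount,
            "effort": b.effort,
            "tarsus": np.nan if b.tarsus is None else b.tarsus,
            "weight": np.nan if b.weight is None else b.weight,
            "delta_tl": np.nan if b.delta_tl is None else b.delta_tl,
            "davids_overall": ds_overall.get(b.id, np.nan),
            "perch_overall": perch_overall.get(b.id, np.nan),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "bird"
    return df


def _scope_matrix(table: pd.DataFrame, value: str, scopes: Sequence[str]) -> pd.DataFrame:
    wide = table.pivot(index="bird", columns="scope", values=value)[list(scopes)]
    return wide.dropna()


def stability_report(
    birds: Sequence[Bird],
    events: Sequence[DisplacementEvent],
    ds_table: pd.DataFrame,
    perch_table: pd.DataFrame,
    elo_final: pd.Series,
    elo_stab: pd.DataFrame,
    weeks: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """All stability statistics in one tidy frame.

    Pairwise weekly (and weekly-vs-overall) Pearson correlations with
    Fisher-z CIs for David's scores and perch scores; the one-way ICC
    treating the weekly + overall scores as repeated measures of one
    quantity; the final-Elo vs overall-DS correlation; the DS vs perch
    correlation; and each family's Elo stability statistic.
    """
    scopes = [f"week{w}" for w in weeks] + ["overall"]
    rows: list[dict] = []

    def corr_rows(measure: str, wide: pd.DataFrame) -> None:
        for a, b in combinations(wide.columns, 2):
            sub = wide[[a, b]].dropna()
            if len(sub) >= 4 and sub[a].std() > 0 and sub[b].std() > 0:
                c = pearson_with_ci(sub[a], sub[b])
                rows.append({"measure": measure, "statistic": f"r_{a}_{b}", "value": c.r,
                             "ci_low": c.ci_low, "ci_high": c.ci_high, "n": c.n})
            else:
                rows.append({"measure": measure, "statistic": f"r_{a}_{b}", "value": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "n": len(sub)})

    ds_wide = _scope_matrix(ds_table, "ds", scopes)
    corr_rows("davids", ds_wide)
    if len(ds_wide) >= 2 and len(ds_wide.columns) >= 2:
        icc = icc_oneway(ds_wide.to_numpy())
        rows.append({"measure": "davids", "statistic": "icc", "value": icc.icc,
                     "ci_low": np.nan, "ci_high": np.nan, "n": icc.n_subjects})

    perch_wide = _scope_matrix(perch_table, "score", scopes)
    corr_rows("perch", perch_wide)
    if len(perch_wide) >= 2 and len(perch_wide.columns) >= 2:
        icc = icc_oneway(perch_wide.to_numpy())
        rows.append({"measure": "perch", "statistic": "icc", "value": icc.icc,
                     "ci_low": np.nan, "ci_high": np.nan, "n": icc.n_subjects})

    ds_overall = ds_table[ds_table["scope"] == "overall"].set_index("bird")["ds"]
    pair = pd.concat({"elo": elo_final, "ds": ds_overall}, axis=1).dropna()
    if len(pair) >= 4:
        c = pearson_with_ci(pair["elo"], pair["ds"])
        rows.append({"measure": "elo_vs_davids", "statistic": "r", "value": c.r,
                     "ci_low": c.ci_low, "ci_high": c.ci_high, "n": c.n})

    perch_overall = perch_table[perch_table["scope"] == "overall"].set_index("bird")["score"]
    pair = pd.concat({"ds": ds_overall, "perch": perch_overall}, axis=1).dropna()
    if len(pair) >= 4:
        c = pearson_with_ci(pair["ds"], pair["perch"])
        rows.append({"measure": "davids_vs_perch", "statistic": "r", "value": c.r,
                     "ci_low": c.ci_low, "ci_high": c.ci_high, "n": c.n})

    for _, r in elo_stab.iterrows():
        rows.append({"measure": "elo_stability", "statistic": f"S_{r['family']}", "value": r["s"],
                     "ci_low": np.nan, "ci_high": np.nan, "n": r["n_days"]})
    return pd.DataFrame(rows, columns=["measure", "statistic", "value", "ci_low", "ci_high", "n"])


def _with_display(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Add a rounded display column next to each full-precision column."""
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[f"{c}_display"] = out[c].round(3)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole chain and (optionally) write the report bundle.

    Returns a dict with keys: birds, events, scans, davids, elo_final,
    stability (per-family S), perch, stability_report, analysis_frame,
    model tables (``models_main_{response}``, ``models_mediator_*``,
    ``models_dtl_*``), coefficient tables for retained models, and a
    run ``manifest``.
    """
    # --- stage: inputs -----------------------------------------------------
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        birds = list(cohort.birds)
        events = generate_displacements(cohort, config.simulation)
        scans = generate_scans(cohort, config.simulation)
        source = {"simulation": asdict(config.simulation)}
    else:
        birds = read_birds(config.birds_csv)
        events = read_displacements(config.displacements_csv)
        scans = read_scans(config.scans_csv)
        source = {"birds_csv": config.birds_csv, "displacements_csv": config.displacements_csv,
                  "scans_csv": config.scans_csv}
    events = sort_events(events)
    logger.info("inputs: %d birds, %d events, %d scans", len(birds), len(events), len(scans))

    weeks_present = sorted({e.week for e in events} | {s.week for s in scans})
    expected_weeks = (1, 2, 3)
    missing_weeks = [w for w in expected_weeks if w not in weeks_present]
    if missing_weeks:
        logger.warning("no data for week(s) %s; weekly statistics for them are omitted", missing_weeks)
    weeks = tuple(w for w in expected_weeks if w in weeks_present) or expected_weeks

    by_family: dict[str, list[Bird]] = {}
    for b in birds:
        by_family.setdefault(b.family, []).append(b)

    # --- stage: dominance --------------------------------------------------
    ds_table = davids_weekly_and_overall(events, birds, weeks=weeks)
    elo_rows = []
    stab_rows = []
    for family, members in sorted(by_family.items()):
        ids = [b.id for b in members]
        fam_events = [e for e in events if e.family == family]
        traj = elo_sequence(fam_events, ids, start=config.elo_start, k=config.elo_k,
                            expectation=config.expectation)
        for bid, t in traj.items():
            elo_rows.append({"bird": bid, "family": family, "final_elo": t.final,
                             "n_contests": len(t.series)})
        res = elo_stability(fam_events, ids, family=family, start=config.elo_start,
                            k=config.elo_k, expectation=config.expectation)
        stab_rows.append({"family": family, "s": np.nan if res.s is None else res.s,
                          "n_days": res.n_days})
    elo_final_table = pd.DataFrame(elo_rows, columns=["bird", "family", "final_elo", "n_contests"])
    stability_table = pd.DataFrame(stab_rows, columns=["family", "s", "n_days"])
    logger.info("dominance: %d score rows, %d families", len(ds_table), len(stability_table))

    # --- stage: perch ------------------------------------------------------
    perch_table = average_perch_position(scans, birds, weeks=weeks)
    n_discarded = sum(1 for s in scans if len(s.occupants) < 2)
    logger.info("perch: %d scans (%d discarded with <2 occupants)", len(scans), n_discarded)

    # --- stage: stability report -------------------------------------------
    subs = {b.id for b in birds if b.is_substitute}
    elo_final = elo_final_table[~elo_final_table["bird"].isin(subs)].set_index("bird")["final_elo"]
    report = stability_report(birds, events, ds_table, perch_table, elo_final, stability_table,
                              weeks=weeks)

    # --- stage: model selection --------------------------------------------
    frame = analysis_frame(birds, ds_table, perch_table)
    results: dict = {
        "birds": birds,
        "events": events,
        "scans": scans,
        "davids": ds_table,
        "elo_final": elo_final_table,
        "stability": stability_table,
        "perch": perch_table,
        "stability_report": report,
        "analysis_frame": frame,
    }
    coeff_tables: dict[str, pd.DataFrame] = {}
    for response in ("davids_overall", "perch_overall"):
        data = frame.dropna(subset=[response, "sex", "amount", "effort"])
        if len(data) < 12:
            logger.warning("model selection for %s skipped: only %d usable birds", response, len(data))
            continue
        fits = fit_candidates(enumerate_main_candidates(response), data)
        main = rank_models(fits, threshold=config.retention_threshold)
        results[f"models_main_{response}"] = main
        best = main.retained_specs
        med_data = data.dropna(subset=["tarsus", "weight"])
        results[f"models_mediator_{response}"] = mediator_comparison(best, med_data,
                                                                     threshold=config.retention_threshold)
        results[f"models_dtl_{response}"] = dtl_comparison(best, data,
                                                           threshold=config.retention_threshold)
        for f in main.fits:
            if f.spec in best:
                coeff_tables[f"coefficients_{response}_{f.spec.label.replace(' ', '')}"] = (
                    f.coefficients.reset_index(names="term")
                )
        logger.info("model selection (%s): best model %r", response, main.best.spec.label)
    results.update(coeff_tables)

    manifest = {
        "package": "domhier",
        "version": __version__,
        "source": source,
        "elo": {"start": config.elo_start, "k": config.elo_k, "expectation": config.expectation},
        "retention_threshold": config.retention_threshold,
        "counts": {
            "birds": len(birds),
            "events": len(events),
            "scans": len(scans),
            "scans_discarded_lt2_occupants": n_discarded,
            "substitute_birds": len(subs),
        },
        "weeks_analysed": list(weeks),
        "conventions": {
            "unobserved_dyads": "dyadic index 0.5 both directions",
            "factor_references": {"sex": "F", "amount": "Lean", "effort": "Easy"},
            "candidate_set": "15 models; two two-way interactions without the three-way excluded",
            "icc": "one-way ANOVA, weekly + overall scores as repeats",
        },
    }
    results["manifest"] = manifest

    # --- stage: outputs ----------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _with_display(ds_table, ["w", "w2", "l", "l2", "ds"]).to_csv(out / "davids_scores.csv", index=False)
        _with_display(elo_final_table, ["final_elo"]).to_csv(out / "elo_final.csv", index=False)
        _with_display(stability_table, ["s"]).to_csv(out / "stability.csv", index=False)
        _with_display(perch_table, ["score"]).to_csv(out / "perch_scores.csv", index=False)
        _with_display(report, ["value", "ci_low", "ci_high"]).to_csv(out / "stability_report.csv", index=False)
        frame.to_csv(out / "analysis_frame.csv")
        for key, val in results.items():
            if key.startswith("models_"):
                _with_display(val.table, ["loglik", "aicc", "delta", "weight"]).to_csv(
                    out / f"model_table_{key.removeprefix('models_')}.csv", index=False
                )
            elif key.startswith("coefficients_"):
                _with_display(val, ["estimate", "ci_low", "ci_high"]).to_csv(out / f"{key}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results
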