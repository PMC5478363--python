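"""Replicated parameter-recovery checks of the generator + analysis chain.

These helpers run the full inference chain (generate a cohort, score
dominance and perch behaviour, select models) on many independently
seeded synthetic cohorts and summarise whether the analysis recovers
what the generator put in.  They back both the test suite and the
reproduction script; they are deliberately thin compositions of the
public API.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Bird
from .dominance import davids_weekly_and_overall, elo_sequence, elo_stability
from .model_selection import (
    enumerate_main_candidates,
    fit_candidates,
    rank_models,
)
from .perch import average_perch_position, highest_time_from_scans
from .repeatability import icc_oneway, pearson_with_ci
from .synthetic_data import SimulationConfig, generate_cohort, generate_displacements, generate_scans

__all__ = ["dominance_replicate", "null_replicate", "perch_replicate", "replicate_seeds"]

SEX_ONLY = frozenset({("sex",)})


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """n independent child seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _bird_frame(birds: Sequence[Bird], response: pd.Series, name: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sex": [b.sex for b in birds],
            "amount": [b.amount for b in birds],
            "effort": [b.effort for b in birds],
            name: [response.get(b.id, np.nan) for b in birds],
        },
        index=[b.id for b in birds],
    )
    return df.dropna(subset=[name])


def dominance_replicate(seed: int, config: SimulationConfig | None = None) -> dict:
    """One cohort through the dominance chain; recovery summary statistics.

    Returns: fitted male coefficient on overall David's score (sex-only
    model), whether the sex-only model was strictly AICc-best among the
    15 candidates, the minimum of the three weekly DS intercorrelations,
    the final-Elo vs overall-DS Pearson r, and the per-family stability
    statistics.
    """
    cfg = dataclasses.replace(config or SimulationConfig(), seed=seed)
    cohort = generate_cohort(cfg)
    events = generate_displacements(cohort, cfg)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*never interacted.*")
        table = davids_weekly_and_overall(events, cohort.birds)
    wide = table.pivot(index="bird", columns="scope", values="ds")
    weekly_r = [
        float(np.corrcoef(wide[a], wide[b])[0, 1])
        for a, b in [("week1", "week2"), ("week1", "week3"), ("week2", "week3")]
    ]
    finals: dict[str, float] = {}
    stabilities: list[float] = []
    for family, ids in cohort.family_ids().items():
        fam_events = [e for e in events if e.family == family]
        traj = elo_sequence(fam_events, ids)
        finals.update({bid: t.final for bid, t in traj.items()})
        s = elo_stability(fam_events, ids, family=family).s
        if s is not None:
            stabilities.append(s)
    elo = pd.Series(finals).reindex(wide.index)
    elo_ds_r = float(np.corrcoef(elo, wide["overall"])[0, 1])

    frame = _bird_frame(cohort.birds, wide["overall"], "davids_overall")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*rejected.*")
        fits = fit_candidates(enumerate_main_candidates("davids_overall"), frame)
    ranked = rank_models(fits)
    sex_fit = next(f for f in fits if f.spec.terms == SEX_ONLY)
    return {
        "male_coefficient": float(sex_fit.coefficients.loc["sexM", "estimate"]),
        "sex_only_best": ranked.best.spec.terms == SEX_ONLY,
        "best_contains_sex": ("sex",) in ranked.best.spec.terms,
        "min_weekly_ds_r": min(weekly_r),
        "elo_ds_r": elo_ds_r,
        "stabilities": stabilities,
    }


def null_replicate(seed: int, config: SimulationConfig | None = None) -> dict:
    """One all-effects-zero cohort; is the intercept-only model competitive?

    Uses a generator with every latent beta set to 0 (pure noise
    hierarchy); reports the intercept-only model's AICc delta to the
    best dominance model.
    """
    base = config or SimulationConfig()
    cfg = dataclasses.replace(
        base, seed=seed, beta_sex_dom=0.0, beta_amount_dom=0.0, beta_effort_dom=0.0,
        beta_sex_perch=0.0, beta_effort_perch=0.0, interaction_perch=0.0,
    )
    cohort = generate_cohort(cfg)
    events = generate_displacements(cohort, cfg)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*never interacted.*")
        table = davids_weekly_and_overall(events, cohort.birds)
    wide = table.pivot(index="bird", columns="scope", values="ds")
    frame = _bird_frame(cohort.birds, wide["overall"], "davids_overall")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*rejected.*")
        fits = fit_candidates(enumerate_main_candidates("davids_overall"), frame)
    ranked = rank_models(fits)
    row = ranked.table[ranked.table["model"] == "1"]
    delta = float(row["delta"].iloc[0])
    return {"intercept_delta": delta, "intercept_within_2": delta <= 2.0}


def perch_replicate(seed: int, config: SimulationConfig | None = None) -> dict:
    """One cohort through the perch chain; effect recovery and repeatability."""
    cfg = dataclasses.replace(config or SimulationConfig(), seed=seed)
    cohort = generate_cohort(cfg)
    scans = generate_scans(cohort, cfg)
    table = average_perch_position(scans, cohort.birds)
    wide = table.pivot(index="bird", columns="scope", values="score")
    wide = wide[["week1", "week2", "week3", "overall"]].dropna()
    icc = icc_oneway(wide.to_numpy()).icc

    frame = _bird_frame(cohort.birds, wide["overall"], "perch_overall")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*rejected.*")
        fits = fit_candidates(enumerate_main_candidates("perch_overall"), frame)
    ranked = rank_models(fits)
    additive = next(f for f in fits if f.spec.terms == frozenset({("sex",), ("effort",)}))
    retained_terms = [f.terms for f in ranked.retained_specs]
    secs = highest_time_from_scans(scans).groupby("bird")["seconds"].sum()
    aligned = wide.index.intersection(secs.index)
    r_time = pearson_with_ci(wide.loc[aligned, "overall"], secs[aligned]).r
    return {
        "icc": float(icc),
        "sex_coefficient": float(additive.coefficients.loc["sexM", "estimate"]),
        "effort_coefficient": float(additive.coefficients.loc["effortHard", "estimate"]),
        "retained_contains_sex_effort": any(
            ("sex",) in t and ("effort",) in t for t in retained_terms
        ),
        "highest_time_r": float(r_time),
    }
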