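"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a hand-reared starling cohort: eight natal
families of four siblings, one bird per cell of the 2x2 developmental
manipulation (food Amount: Plenty/Lean x begging Effort: Easy/Hard),
sexes drawn at random per bird (the real cohort could not be sex-
balanced because nestlings are phenotypically indistinguishable).

Behaviour is driven by two latent per-bird traits:

* a **dominance ability** ``a_i = beta_sex*[male] + beta_amount*[Plenty]
  + beta_effort*[Hard] + N(0, sd_dom)`` — in a contest between i and j,
  i wins with probability ``logistic((a_i - a_j) / contest_scale)``;
* a **perch preference**, analogous betas plus its own noise, by
  default independent of dominance ability (the two measures were
  essentially uncorrelated in the data this design mirrors); an
  optional coupling parameter mixes ability in for sensitivity tests.

Displacement events arrive at a Poisson rate per observation session
(default 18.6/h, the observed average), on alternate days within each
week; perch scans are taken on the days in between, each bird present
independently per scan and the present birds ordered by preference plus
fresh per-scan noise.

Abilities are fixed across weeks by default (a stationary hierarchy,
matching the high observed stability); ``drift_sd`` adds a weekly
random walk for probing the stability statistic.

All randomness flows from one master seed via spawned child streams,
one per generation stage, so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .data_model import Bird, DisplacementEvent, ScanSample

__all__ = ["SimulationConfig", "Cohort", "generate_cohort", "generate_displacements", "generate_scans"]

_CELLS = (("Plenty", "Easy"), ("Plenty", "Hard"), ("Lean", "Easy"), ("Lean", "Hard"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-scale defaults.

    Latent-effect sizes are on the log-odds scale of a single contest
    (divided by ``contest_scale``); the dominance sex effect default is
    sized so that the fitted male offset on overall David's score
    averages about 2.8 score units.  Perch betas are sized to yield
    perch-score effects of roughly 0.15 with moderate week-to-week
    repeatability.
    """

    n_families: int = 8
    seed: int = 0

    # dominance latent structure
    beta_sex_dom: float = 1.4
    beta_amount_dom: float = 0.0
    beta_effort_dom: float = 0.0
    sd_dom: float = 0.9
    contest_scale: float = 1.0
    drift_sd: float = 0.0

    # observation design
    events_per_hour: float = 18.6
    hours_per_session: float = 1.0
    sessions_per_week: int = 3
    weeks: int = 3

    # perch latent structure
    beta_sex_perch: float = 1.3
    beta_effort_perch: float = 1.1
    interaction_perch: float = 0.0
    sd_perch_pref: float = 0.6
    sd_perch: float = 1.2
    sd_perch_week: float = 1.1
    perch_scans_per_video: int = 120
    perch_presence_prob: float = 0.8
    perch_dominance_coupling: float = 0.0

    # biometrics / telomeres
    dtl_mean: float = 0.0
    dtl_sd: float = 1.0
    dtl_missing_n: int = 4
    tarsus_mean_lean: float = 28.64
    tarsus_sd_lean: float = 0.59
    tarsus_mean_plenty: float = 29.57
    tarsus_sd_plenty: float = 0.77
    weight_mean: float = 78.0
    weight_sd: float = 5.0
    male_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sd_dom", "sd_perch_pref", "sd_perch", "sd_perch_week", "drift_sd",
                     "tarsus_sd_lean", "tarsus_sd_plenty", "weight_sd", "dtl_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("perch_presence_prob", "male_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.events_per_hour <= 0 or self.contest_scale <= 0:
            raise ValueError("events_per_hour and contest_scale must be > 0")

    def _child_rng(self, stage: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[stage])


@dataclass
class Cohort:
    """Generated birds plus their latent traits (iterates as list of Bird)."""

    birds: list[Bird]
    dominance_ability: dict[str, float]
    perch_preference: dict[str, float]

    def __iter__(self) -> Iterator[Bird]:
        return iter(self.birds)

    def __len__(self) -> int:
        return len(self.birds)

    def family_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for b in self.birds:
            out.setdefault(b.family, []).append(b.id)
        return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw the birds: families x the four treatment cells, random sexes.

    Tarsus is drawn from the Amount-specific normal (Lean birds end up
    skeletally smaller), weight from a common normal, delta_tl standard
    normal with ``dtl_missing_n`` birds set missing at random.  Latent
    dominance ability and perch preference are drawn per bird as
    documented in the module docstring.
    """
    rng = config._child_rng(0)
    birds: list[Bird] = []
    ability: dict[str, float] = {}
    preference: dict[str, float] = {}
    for fam in range(1, config.n_families + 1):
        family = f"f{fam:02d}"
        for amount, effort in _CELLS:
            bid = f"{family}{amount[0].lower()}{effort[0].lower()}"
            male = rng.random() < config.male_prob
            tarsus = (
                rng.normal(config.tarsus_mean_plenty, config.tarsus_sd_plenty)
                if amount == "Plenty"
                else rng.normal(config.tarsus_mean_lean, config.tarsus_sd_lean)
            )
            weight = rng.normal(config.weight_mean, config.weight_sd)
            dtl = rng.normal(config.dtl_mean, config.dtl_sd)
            birds.append(
                Bird(
                    id=bid,
                    family=family,
                    sex="M" if male else "F",
                    amount=amount,
                    effort=effort,
                    tarsus=float(max(tarsus, 1e-3)),
                    weight=float(max(weight, 1e-3)),
                    delta_tl=float(dtl),
                )
            )
            a = (
                config.beta_sex_dom * male
                + config.beta_amount_dom * (amount == "Plenty")
                + config.beta_effort_dom * (effort == "Hard")
                + rng.normal(0.0, config.sd_dom)
            )
            ability[bid] = float(a)
            pref = (
                config.beta_sex_perch * male
                + config.beta_effort_perch * (effort == "Hard")
                + config.interaction_perch * (male and effort == "Hard")
                + config.perch_dominance_coupling * a
                + rng.normal(0.0, config.sd_perch_pref)
            )
            preference[bid] = float(pref)
    if config.dtl_missing_n > 0:
        missing = rng.choice(len(birds), size=min(config.dtl_missing_n, len(birds)), replace=False)
        for i in missing:
            b = birds[i]
            birds[i] = Bird(
                id=b.id, family=b.family, sex=b.sex, amount=b.amount, effort=b.effort,
                tarsus=b.tarsus, weight=b.weight, delta_tl=None, is_substitute=b.is_substitute,
            )
    return Cohort(birds=birds, dominance_ability=ability, perch_preference=preference)


def generate_displacements(cohort: Cohort, config: SimulationConfig) -> list[DisplacementEvent]:
    """Poisson event streams per family session, latent-ability contests.

    Sessions fall on alternate days (days 1, 3, 5, ... within a week);
    each session's event count is Poisson(events_per_hour x hours), the
    dyad is drawn uniformly, and the higher-ability bird wins each
    contest with logistic probability.
    """
    rng = config._child_rng(1)
    events: list[DisplacementEvent] = []
    fam_ids = cohort.family_ids()
    rate = config.events_per_hour * config.hours_per_session
    for family, ids in fam_ids.items():
        base = np.array([cohort.dominance_ability[i] for i in ids])
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        for week in range(1, config.weeks + 1):
            if config.drift_sd > 0 and week > 1:
                base = base + rng.normal(0.0, config.drift_sd, size=len(ids))
            a = base
            for session in range(1, config.sessions_per_week + 1):
                day = 2 * session - 1
                n_ev = rng.poisson(rate)
                if n_ev == 0:
                    continue
                dyads = rng.integers(0, len(pairs), size=n_ev)
                u = rng.random(n_ev)
                for order, (di, uu) in enumerate(zip(dyads, u), start=1):
                    i, j = pairs[di]
                    p_i = 1.0 / (1.0 + np.exp(-(a[i] - a[j]) / config.contest_scale))
                    win_i = uu < p_i
                    events.append(
                        DisplacementEvent(
                            family=family,
                            week=week,
                            day=day,
                            video_order=order,
                            displacer=ids[i] if win_i else ids[j],
                            displaced=ids[j] if win_i else ids[i],
                        )
                    )
    return events


def generate_scans(cohort: Cohort, config: SimulationConfig) -> list[ScanSample]:
    """Perch scans on the days between dominance sessions.

    One video per (family, week, between-day); each bird is present in
    a scan independently with ``perch_presence_prob``; present birds are
    ordered highest-first by latent preference plus fresh per-scan
    normal noise of SD ``sd_perch``.  ``sd_perch_week`` adds a per-bird
    weekly wobble to the preference, modelling the week-to-week drift
    that keeps perch scores only moderately repeatable even though each
    video averages over many scans.
    """
    rng = config._child_rng(2)
    scans: list[ScanSample] = []
    for family, ids in cohort.family_ids().items():
        base_pref = np.array([cohort.perch_preference[i] for i in ids])
        for week in range(1, config.weeks + 1):
            pref = base_pref + (
                rng.normal(0.0, config.sd_perch_week, size=len(ids)) if config.sd_perch_week > 0 else 0.0
            )
            for session in range(1, config.sessions_per_week + 1):
                day = 2 * session
                for scan_index in range(1, config.perch_scans_per_video + 1):
                    present = rng.random(len(ids)) < config.perch_presence_prob
                    if not present.any():
                        occupants: tuple[str, ...] = ()
                    else:
                        noisy = pref + rng.normal(0.0, config.sd_perch, size=len(ids))
                        idx = [k for k in np.argsort(-noisy, kind="stable") if present[k]]
                        occupants = tuple(ids[k] for k in idx)
                    scans.append(
                        ScanSample(family=family, week=week, day=day, scan_index=scan_index, occupants=occupants)
                    )
    return scans
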