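"""Synthetic cohorts of rats recovering from abdominal surgery.

The generator emulates the statistical structure the composite-score
analysis assumes: each group carries a latent per-domain deficit that is
maximal on post-operative day 1 and decays exponentially over days,

    d(t) = m * exp(-r * (t - 1))   for t >= 1,  d(0) = 0,

where ``m`` is the fraction of the distance from the healthy baseline
toward the maximum-deficit anchor reached on day 1 and ``r`` the recovery
rate per day.  Treatments act as multiplicative reductions of ``m`` and
modulations of ``r``; sham animals carry a small, fast-recovering day-1
deficit; naive animals none.  Observed values are the latent expectation
plus truncated-normal noise (log-normal for the strictly positive
intestinal transit and von Frey domains).

Default parameters are calibrated so group-level day-1 medians match the
reported laparotomy cohort (e.g. food 6.75 g vs a 17.25 g healthy median,
transit 617 min vs 72.5 min) and so the expected day-1 laparotomy
composite equals the reported median of 6/18.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import ALL_DOMAINS, SCORED_DOMAINS, DOMAIN_UNITS, DeficitAnchors
from .vonfrey import DEFAULT_FILAMENTS, VonFreySession, VonFreyTrial, run_staircase

__all__ = [
    "GROUPS",
    "CohortSpec",
    "DomainModel",
    "SimulatedCohort",
    "default_domain_models",
    "simulate_cohort",
    "simulate_vonfrey_responses",
    "load_scenario",
    "dump_scenario",
]

#: Recognised experimental groups.
GROUPS: tuple[str, ...] = (
    "naive",
    "sham",
    "laparotomy",
    "laparotomy_asa",
    "laparotomy_asa_epa",
)

# Group-level scalings of the per-domain laparotomy deficit magnitude m and
# recovery rate r.  ASA+EPA reduces the deficit more and speeds recovery
# more than ASA alone; ASA slows late recovery (its benefit fades); sham is
# a small fast-recovering perturbation of naive.
GROUP_DEFICIT_SCALE: dict[str, float] = {
    "naive": 0.0,
    "sham": 0.15,
    "laparotomy": 1.0,
    "laparotomy_asa": 0.8,
    "laparotomy_asa_epa": 0.55,
}
GROUP_RECOVERY_SCALE: dict[str, float] = {
    "naive": 1.0,
    "sham": 2.0,
    "laparotomy": 1.0,
    "laparotomy_asa": 0.7,
    "laparotomy_asa_epa": 1.3,
}

#: Days encoding the three pre-operative replicate measurements.
PREOP_DAYS: tuple[int, ...] = (-3, -2, -1)
#: Domains whose baseline is the average of the three pre-op days.
AVERAGED_BASELINE_DOMAINS: tuple[str, ...] = ("food_g", "water_ml")


class CohortConfigError(ValueError):
    """Invalid cohort specification or domain model set."""


@dataclass(frozen=True)
class CohortSpec:
    """Which groups to simulate, how many animals, on which days."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 6
    days: tuple[int, ...] = (0, 1, 2, 3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        unknown = [g for g in self.groups if g not in GROUPS]
        if unknown:
            raise CohortConfigError(f"unknown group labels {unknown}")
        if not self.groups:
            raise CohortConfigError("at least one group required")
        if self.n_per_group < 1:
            raise CohortConfigError("n_per_group must be >= 1")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise CohortConfigError("days must be strictly increasing")
        if 0 not in self.days:
            raise CohortConfigError("baseline day 0 must be present")


@dataclass(frozen=True)
class DomainModel:
    """Healthy distribution and deficit kinetics for one measurement domain.

    ``deficit_magnitude`` is the laparotomy-group day-1 deficit fraction m;
    per-group values are ``m * GROUP_DEFICIT_SCALE[group]`` unless an
    explicit per-group mapping is given.  ``noise_family`` is
    ``"truncnorm"`` (truncated at physical bounds) or ``"lognormal"``
    (multiplicative, for strictly positive domains).
    """

    domain: str
    healthy_mean: float
    healthy_sd: float
    deficit_magnitude: float = 0.0
    recovery_rate: float = 0.6
    noise_family: str = "truncnorm"
    between_animal_frac: float = 0.6   # share of healthy_sd between animals
    deficit_animal_sd: float = 0.08    # animal-level spread of m (absolute)
    upper_bound: float | None = None   # e.g. 100 for sucrose preference
    group_deficit: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.domain not in ALL_DOMAINS:
            raise CohortConfigError(f"unknown domain {self.domain!r}")
        if not 0.0 <= self.deficit_magnitude <= 1.0:
            raise CohortConfigError("deficit_magnitude must lie in [0, 1]")
        if self.recovery_rate < 0 or self.healthy_sd < 0:
            raise CohortConfigError("recovery_rate and healthy_sd must be >= 0")
        if self.noise_family not in ("truncnorm", "lognormal"):
            raise CohortConfigError(f"unknown noise family {self.noise_family!r}")
        if self.domain in ("transit_min", "vonfrey_g") and self.noise_family != "lognormal":
            raise CohortConfigError(f"{self.domain} must use log-normal noise")

    def deficit_for(self, group: str) -> float:
        if self.group_deficit is not None and group in self.group_deficit:
            return float(self.group_deficit[group])
        return self.deficit_magnitude * GROUP_DEFICIT_SCALE[group]

    def recovery_for(self, group: str) -> float:
        return self.recovery_rate * GROUP_RECOVERY_SCALE[group]


@dataclass(frozen=True)
class SimulatedCohort:
    """Tidy measurements (raw CSV dialect, pre-op days negative) plus the
    latent truth used to generate them."""

    measurements: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def default_domain_models(anchors: DeficitAnchors | None = None) -> dict[str, DomainModel]:
    """Domain models calibrated to the reported group medians.

    Healthy centers come from the naive-group medians (food 17.25 g,
    transit 72.5 min, von Frey 1.2 g, distance 240 m); laparotomy day-1
    deficit fractions are back-computed from the laparotomy day-1 medians
    (food 6.75 g, transit 617 min, von Frey 0.28 g, distance ~139 m).
    Sucrose and social deficits are set so the expected day-1 laparotomy
    composite equals the reported median of 6/18.  Spreads are loose
    matches to the reported interquartile ranges.
    """
    anchors = anchors or DeficitAnchors()
    models = {
        "food_g": DomainModel("food_g", healthy_mean=17.25, healthy_sd=2.0,
                              deficit_magnitude=0.609),
        "sucrose_pref_pct": DomainModel("sucrose_pref_pct", healthy_mean=92.0,
                                        healthy_sd=4.0, deficit_magnitude=0.15,
                                        upper_bound=100.0),
        "distance_m": DomainModel("distance_m", healthy_mean=240.0,
                                  healthy_sd=25.0, deficit_magnitude=0.722),
        # log-normal domains: deficit fraction acts on the log10 scale, so it
        # is back-computed there (von Frey day-1 median 0.28 g, transit 617 min)
        "vonfrey_g": DomainModel("vonfrey_g", healthy_mean=1.2, healthy_sd=0.25,
                                 deficit_magnitude=0.428,
                                 noise_family="lognormal"),
        "transit_min": DomainModel("transit_min", healthy_mean=72.5,
                                   healthy_sd=0.20, deficit_magnitude=0.933,
                                   noise_family="lognormal"),
        "social_s": DomainModel("social_s", healthy_mean=50.0, healthy_sd=6.0,
                                deficit_magnitude=0.30),
        "water_ml": DomainModel("water_ml", healthy_mean=30.0, healthy_sd=4.0,
                                deficit_magnitude=0.5),
        # weight: slow growth, mild surgical loss; handled via drift below
        "weight_g": DomainModel("weight_g", healthy_mean=375.0, healthy_sd=25.0,
                                deficit_magnitude=0.4, recovery_rate=0.3),
    }
    return models

#: Healthy daily weight-gain fraction and maximal surgical loss fraction.
WEIGHT_GROWTH_PER_DAY = 0.008
WEIGHT_LOSS_FRACTION = 0.05


def _latent_deficit(m: np.ndarray, r: float, day: int) -> np.ndarray:
    if day <= 0:
        return np.zeros_like(m)
    return m * np.exp(-r * (day - 1))


def simulate_cohort(
    spec: CohortSpec,
    models: Mapping[str, DomainModel] | None = None,
    anchors: DeficitAnchors | None = None,
) -> SimulatedCohort:
    """Simulate a cohort; deterministic (bit-identical) given ``spec.seed``.

    The measurement table uses the raw CSV dialect: three pre-operative
    replicate days (-3, -2, -1) for the averaged-baseline domains (food and
    water), a single day-0 pre-operative test for every other domain, and
    one row per animal-day-domain on post-operative days.  The ``truth``
    table records each animal's latent deficit fraction and noiseless
    expected value per domain-day.
    """
    models = dict(models) if models is not None else default_domain_models()
    anchors = anchors or DeficitAnchors()
    missing = [d for d in SCORED_DOMAINS if d not in models]
    if missing:
        raise CohortConfigError(f"missing domain models for {missing}")
    rng = np.random.default_rng(spec.seed)

    n = spec.n_per_group
    post_days = [d for d in spec.days if d > 0]
    rows: dict[str, list] = {k: [] for k in
                             ("animal_id", "group", "day", "domain", "value", "unit")}
    truth: dict[str, list] = {k: [] for k in
                              ("animal_id", "group", "day", "domain",
                               "latent_deficit", "expected_value")}

    def emit(animals, group, day, domain, values):
        k = len(animals)
        rows["animal_id"].extend(animals)
        rows["group"].extend([group] * k)
        rows["day"].extend([day] * k)
        rows["domain"].extend([domain] * k)
        rows["value"].extend(np.asarray(values, dtype=float))
        rows["unit"].extend([DOMAIN_UNITS[domain]] * k)

    def emit_truth(animals, group, day, domain, d_t, expected):
        k = len(animals)
        truth["animal_id"].extend(animals)
        truth["group"].extend([group] * k)
        truth["day"].extend([day] * k)
        truth["domain"].extend([domain] * k)
        truth["latent_deficit"].extend(np.asarray(d_t, dtype=float))
        truth["expected_value"].extend(np.asarray(expected, dtype=float))

    for group in spec.groups:
        animals = [f"{group}_{i + 1:02d}" for i in range(n)]
        for domain in ALL_DOMAINS:
            model = models.get(domain)
            if model is None:
                continue
            lognorm = model.noise_family == "lognormal"
            if lognorm:
                center = np.log10(model.healthy_mean)
                anchor_c = np.log10(anchors.for_domain(domain)) \
                    if domain in SCORED_DOMAINS else center
                sd = model.healthy_sd  # interpreted on the log10 scale
            else:
                center = model.healthy_mean
                anchor_c = anchors.for_domain(domain) \
                    if domain in SCORED_DOMAINS else center
                sd = model.healthy_sd
            between = sd * model.between_animal_frac
            within = sd * float(np.sqrt(max(1.0 - model.between_animal_frac**2, 0.0)))

            animal_center = center + rng.normal(0.0, between, size=n)
            m_group = model.deficit_for(group)
            r_group = model.recovery_for(group)
            if m_group > 0:
                m_animal = np.clip(
                    m_group + rng.normal(0.0, model.deficit_animal_sd, size=n),
                    0.0, 1.0)
            else:
                m_animal = np.zeros(n)

            def draw(mu: np.ndarray) -> np.ndarray:
                vals = mu + rng.normal(0.0, within, size=n)
                if lognorm:
                    return 10.0 ** vals
                lo = 0.0
                hi = model.upper_bound if model.upper_bound is not None else np.inf
                # re-draw out-of-bound values (truncated normal)
                bad = (vals < lo) | (vals > hi)
                while np.any(bad):
                    vals[bad] = mu[bad] + rng.normal(0.0, within, size=int(bad.sum()))
                    bad = (vals < lo) | (vals > hi)
                return vals

            if domain == "weight_g":
                w0 = draw(animal_center)
                emit(animals, group, 0, domain, w0)
                emit_truth(animals, group, 0, domain, np.zeros(n), animal_center)
                for day in post_days:
                    d_t = _latent_deficit(m_animal, r_group, day)
                    mu = w0 * (1.0 + WEIGHT_GROWTH_PER_DAY * day
                               - WEIGHT_LOSS_FRACTION * d_t)
                    vals = mu + rng.normal(0.0, within * 0.3, size=n)
                    emit(animals, group, day, domain, vals)
                    emit_truth(animals, group, day, domain, d_t, mu)
                continue

            # baseline rows
            if domain in AVERAGED_BASELINE_DOMAINS:
                for day in PREOP_DAYS:
                    emit(animals, group, day, domain, draw(animal_center))
            else:
                base_vals = draw(animal_center)
                emit(animals, group, 0, domain, base_vals)
            emit_truth(animals, group, 0, domain, np.zeros(n),
                       10.0 ** animal_center if lognorm else animal_center)

            for day in post_days:
                d_t = _latent_deficit(m_animal, r_group, day)
                mu = animal_center + d_t * (anchor_c - animal_center)
                emit(animals, group, day, domain, draw(mu))
                emit_truth(animals, group, day, domain, d_t,
                           10.0 ** mu if lognorm else mu)

    measurements = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth)
    return SimulatedCohort(measurements=measurements, truth=truth_df, spec=spec)


def load_scenario(path) -> tuple[CohortSpec, dict[str, DomainModel]]:
    """Load a simulation scenario (cohort spec + domain-model overrides) from YAML.

    The file may carry a ``spec`` mapping (CohortSpec fields) and a
    ``models`` mapping of per-domain field overrides applied on top of
    :func:`default_domain_models`.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    spec = CohortSpec(**data.get("spec", {}))
    models = default_domain_models()
    for domain, overrides in (data.get("models") or {}).items():
        if domain not in models:
            raise CohortConfigError(f"unknown domain {domain!r} in scenario")
        models[domain] = replace(models[domain], **overrides)
    return spec, models


def dump_scenario(spec: CohortSpec, path) -> None:
    """Write the cohort spec (including its seed) as a YAML scenario file."""
    import dataclasses

    import yaml

    payload = {"spec": {
        "groups": list(spec.groups), "n_per_group": spec.n_per_group,
        "days": list(spec.days), "seed": spec.seed,
    }}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def simulate_vonfrey_responses(
    true_threshold_g: float,
    filaments: Sequence[float] = DEFAULT_FILAMENTS,
    slope: float = 10.0,
    seed: int | np.random.Generator = 0,
    start_force_g: float | None = None,
    max_trials: int = 20,
) -> VonFreySession:
    """Run one up-down staircase against a logistic psychometric responder.

    The probability of a response to force ``f`` is
    ``expit(slope * (log10 f - log10 threshold))``; an infinite slope gives
    a deterministic step at the threshold.  Staircase sequencing and
    termination follow :func:`qorscore.vonfrey.run_staircase`.
    """
    if true_threshold_g <= 0:
        raise ValueError("true threshold must be positive")
    fils = tuple(float(f) for f in filaments)
    if not fils:
        raise ValueError("filament set must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_thr = np.log10(true_threshold_g)

    def responder(force: float) -> bool:
        x = slope * (np.log10(force) - log_thr)
        if np.isinf(slope):
            p = 1.0 if np.log10(force) > log_thr else 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-x))
        return bool(rng.random() < p)

    return run_staircase(responder, filament_set=fils,
                         start_force_g=start_force_g, max_trials=max_trials)
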