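"""Quality-of-recovery (QoR) composite scoring for rodent abdominal surgery.

Six behavioral/physiological domains (food intake, sucrose preference,
horizontal travelled distance, von Frey mechanical threshold, intestinal
transit time and juvenile social exploration) are each rescaled as a
percent of maximum possible effect (%MPE) between the animal's own
pre-operative baseline (0%) and a fixed maximum-deficit anchor (100%)
obtained from a gut ischemia-reperfusion calibration cohort.  Each %MPE is
binned into an integer domain score 0-3 and the six scores are summed into
a daily composite ranging from 0 (gross impairment) to 18 (little to no
impairment).

Weight gain (% change from baseline) and water intake are tracked
alongside the composite but are not part of it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCORED_DOMAINS",
    "ALL_DOMAINS",
    "DOMAIN_UNITS",
    "DeficitAnchors",
    "DomainMPE",
    "DailyComposite",
    "DegenerateDomainError",
    "IncompleteDayError",
    "percent_mpe",
    "domain_score",
    "daily_composite",
    "weight_gain_pct",
    "sucrose_preference_pct",
    "score_measurements",
]

#: The six domains entering the composite, in canonical order.
SCORED_DOMAINS: tuple[str, ...] = (
    "food_g",
    "sucrose_pref_pct",
    "distance_m",
    "vonfrey_g",
    "transit_min",
    "social_s",
)

#: All recognised measurement domains (scored six + ancillary).
ALL_DOMAINS: tuple[str, ...] = SCORED_DOMAINS + ("water_ml", "weight_g")

#: Required unit label per domain for tidy measurement files.
DOMAIN_UNITS: dict[str, str] = {
    "food_g": "g",
    "sucrose_pref_pct": "%",
    "distance_m": "m",
    "vonfrey_g": "g",
    "transit_min": "min",
    "social_s": "s",
    "water_ml": "mL",
    "weight_g": "g",
}


class DegenerateDomainError(ValueError):
    """Raised when baseline equals the deficit anchor, making %MPE undefined."""


class IncompleteDayError(ValueError):
    """Raised when an animal-day is missing one or more scored domains."""


@dataclass(frozen=True)
class DeficitAnchors:
    """Fixed per-domain maximum-deficit values (100% MPE).

    Defaults are the calibration values measured in animals after gut
    ischemia-reperfusion injury: zero food intake, 720 min intestinal
    transit, 5% sucrose preference, 0.04 g von Frey threshold, 100 m
    nocturnal distance and 20 s juvenile social exploration.
    """

    food_g: float = 0.0
    transit_min: float = 720.0
    sucrose_pref_pct: float = 5.0
    vonfrey_g: float = 0.04
    distance_m: float = 100.0
    social_s: float = 20.0

    def __post_init__(self) -> None:
        for domain in SCORED_DOMAINS:
            if not np.isfinite(getattr(self, domain)):
                raise ValueError(f"anchor for {domain!r} must be finite")

    def for_domain(self, domain: str) -> float:
        if domain not in SCORED_DOMAINS:
            raise KeyError(f"{domain!r} is not a scored domain")
        return float(getattr(self, domain))

    def as_dict(self) -> dict[str, float]:
        return {d: float(getattr(self, d)) for d in SCORED_DOMAINS}

    def replace(self, **overrides: float) -> "DeficitAnchors":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class DomainMPE:
    """%MPE for one domain: clamped value in [0, 100] plus the raw value."""

    domain: str
    mpe_pct: float
    raw_mpe_pct: float


@dataclass(frozen=True)
class DailyComposite:
    """Six binned domain scores and their 0-18 sum for one animal-day."""

    animal_id: str
    day: int
    domain_scores: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if set(self.domain_scores) != set(SCORED_DOMAINS):
            raise IncompleteDayError(
                f"composite for {self.animal_id!r} day {self.day} must cover "
                f"exactly the six scored domains"
            )
        if self.total != sum(self.domain_scores.values()):
            raise ValueError("total does not equal the sum of domain scores")


def percent_mpe(
    test: float, baseline: float, anchor: float, domain: str = ""
) -> DomainMPE:
    """Rescale a measurement between baseline (0%) and the deficit anchor (100%).

    %MPE = (test - baseline) / (anchor - baseline) * 100, clamped to
    [0, 100].  Raw values below 0 mean the animal did better than its own
    baseline; above 100 mean it exceeded the calibrated maximum deficit.
    The formula is direction-agnostic: it is valid whether the anchor lies
    below the baseline (food, distance, von Frey, social, sucrose) or
    above it (intestinal transit).

    Raises
    ------
    DegenerateDomainError
        If ``baseline == anchor`` (the scale collapses).
    """
    test, baseline, anchor = float(test), float(baseline), float(anchor)
    if not (np.isfinite(test) and np.isfinite(baseline) and np.isfinite(anchor)):
        raise ValueError(f"non-finite input for domain {domain or '<unnamed>'}")
    if baseline == anchor:
        raise DegenerateDomainError(
            f"baseline equals anchor ({baseline}) for domain "
            f"{domain or '<unnamed>'}; %MPE is undefined"
        )
    raw = (test - baseline) / (anchor - baseline) * 100.0
    return DomainMPE(domain=domain, mpe_pct=float(np.clip(raw, 0.0, 100.0)),
                     raw_mpe_pct=raw)


def domain_score(mpe: DomainMPE | float, orientation: str = "inverted") -> int:
    """Bin a clamped %MPE into an integer 0-3 domain score.

    ``orientation="inverted"`` (default, recovery-faithful): 3 for %MPE in
    [0, 25), 2 for [25, 50), 1 for [50, 75), 0 for [75, 100] — so no
    deficit scores 3 and maximal deficit scores 0, making 18 "little to no
    impairment" as the composite is defined.  ``orientation="literal"``
    reproduces the bins exactly as printed (3 for 75-100%), kept for
    auditability.  Bins are contiguous half-open intervals; 100% falls in
    the last bin.
    """
    value = mpe.mpe_pct if isinstance(mpe, DomainMPE) else float(mpe)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"%MPE must be clamped to [0, 100], got {value}")
    bin_index = min(int(value // 25), 3)  # 0..3, 100% -> last bin
    if orientation == "inverted":
        return 3 - bin_index
    if orientation == "literal":
        return bin_index
    raise ValueError(f"unknown bin orientation {orientation!r}")


def daily_composite(
    animal_id: str, day: int, scores: Mapping[str, int]
) -> DailyComposite:
    """Sum six domain scores into the 0-18 daily composite.

    Missing domains are flagged (never rescaled or imputed).
    """
    missing = [d for d in SCORED_DOMAINS if d not in scores]
    if missing:
        raise IncompleteDayError(
            f"animal {animal_id!r} day {day}: missing domains {missing}"
        )
    extra = [d for d in scores if d not in SCORED_DOMAINS]
    if extra:
        raise ValueError(f"unknown scored domains {extra}")
    for d, s in scores.items():
        if s not in (0, 1, 2, 3):
            raise ValueError(f"domain {d!r}: score {s!r} not in {{0,1,2,3}}")
    total = int(sum(scores[d] for d in SCORED_DOMAINS))
    return DailyComposite(animal_id=animal_id, day=int(day),
                          domain_scores=dict(scores), total=total)


def weight_gain_pct(weight_t: float, weight_baseline: float) -> float:
    """Percent change in body weight from the pre-operative baseline."""
    if weight_t <= 0 or weight_baseline <= 0:
        raise ValueError("weights must be positive")
    return 100.0 * (weight_t - weight_baseline) / weight_baseline


def sucrose_preference_pct(sucrose_ml: float, water_ml: float) -> float:
    """Sucrose preference: % of sucrose volume over total fluid intake."""
    if sucrose_ml < 0 or water_ml < 0:
        raise ValueError("intake volumes must be non-negative")
    total = sucrose_ml + water_ml
    if total == 0:
        raise ValueError("zero total fluid intake: preference undefined")
    return 100.0 * sucrose_ml / total


def score_measurements(
    measurements: pd.DataFrame,
    anchors: DeficitAnchors | None = None,
    orientation: str = "inverted",
    days: Iterable[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a tidy measurement table into %MPE audit and composite tables.

    Parameters
    ----------
    measurements
        Long-format frame with columns ``animal_id, group, day, domain,
        value``; day 0 rows are the per-animal baselines (pre-operative
        replicates must already be collapsed, see :func:`qorscore.io.read_measurements`).
    anchors
        Maximum-deficit anchors (defaults to the calibrated values).
    orientation
        Bin orientation passed to :func:`domain_score`.
    days
        Post-operative days to score; defaults to every day > 0 present.

    Returns
    -------
    (audit, composites)
        ``audit`` has one row per animal-day-domain with raw and clamped
        %MPE and the binned score; ``composites`` one row per animal-day
        with the six scores and the 0-18 total.  Animal-days missing any
        scored domain raise :class:`IncompleteDayError`.
    """
    anchors = anchors or DeficitAnchors()
    df = measurements.loc[measurements["domain"].isin(SCORED_DOMAINS),
                          ["animal_id", "group", "day", "domain", "value"]].copy()
    base = df[df["day"] == 0].set_index(["animal_id", "domain"])["value"]
    if base.index.has_duplicates:
        dup = base.index[base.index.duplicated()].tolist()
        raise ValueError(f"duplicate baseline rows for {dup}")
    post = df[df["day"] > 0]
    if days is not None:
        post = post[post["day"].isin(list(days))]
    if post.empty:
        raise ValueError("no post-operative measurements to score")

    audit_rows = []
    for (animal, group, day), sub in post.groupby(
        ["animal_id", "group", "day"], sort=True
    ):
        scores: dict[str, int] = {}
        for domain, value in zip(sub["domain"], sub["value"]):
            try:
                baseline = base.loc[(animal, domain)]
            except KeyError:
                raise IncompleteDayError(
                    f"animal {animal!r}: no baseline for domain {domain!r}"
                ) from None
            mpe = percent_mpe(value, baseline, anchors.for_domain(domain), domain)
            s = domain_score(mpe, orientation)
            scores[domain] = s
            audit_rows.append(
                {"animal_id": animal, "group": group, "day": day,
                 "domain": domain, "value": value, "baseline": float(baseline),
                 "anchor": anchors.for_domain(domain),
                 "raw_mpe_pct": mpe.raw_mpe_pct, "mpe_pct": mpe.mpe_pct,
                 "score": s}
            )
        daily_composite(animal, day, scores)  # validates completeness
    audit = pd.DataFrame(audit_rows)
    wide = audit.pivot_table(index=["animal_id", "group", "day"],
                             columns="domain", values="score",
                             aggfunc="first")
    wide = wide[list(SCORED_DOMAINS)].astype(int)
    wide.columns = [f"score_{d}" for d in SCORED_DOMAINS]
    wide["total"] = wide.sum(axis=1).astype(int)
    composites = wide.reset_index()
    return audit, composites
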