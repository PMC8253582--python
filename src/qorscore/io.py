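"""Measurement CSV dialect: validation, baseline collapsing, round-trips.

Measurements travel as long (tidy) CSV with columns
``animal_id, group, day, domain, value, unit``.  Day 0 is reserved for the
pre-operative baseline; raw files may instead encode pre-operative
replicate days as negative days (-3, -2, -1), which are collapsed on read:
food and water baselines are the mean of the three pre-operative days, all
other domains take the value of the pre-operative test closest to surgery.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ALL_DOMAINS, DOMAIN_UNITS
from .cohort import AVERAGED_BASELINE_DOMAINS, GROUPS

__all__ = [
    "MeasurementValidationError",
    "REQUIRED_COLUMNS",
    "read_measurements",
    "write_measurements",
    "collapse_baseline",
    "read_vonfrey_trials",
]

REQUIRED_COLUMNS = ("animal_id", "group", "day", "domain", "value", "unit")


class MeasurementValidationError(ValueError):
    """Schema violation in a measurement file; message carries line numbers."""


def _lines(index: pd.Index) -> str:
    """CSV line numbers (header = line 1) for a positional index."""
    return ", ".join(str(i + 2) for i in index[:8]) + (
        ", ..." if len(index) > 8 else ""
    )


def read_measurements(
    path: str | Path | _io.TextIOBase, collapse: bool = True
) -> pd.DataFrame:
    """Read and validate a tidy measurement CSV.

    Checks the header, domain and unit vocabulary, numeric values and
    duplicate (animal, day, domain) keys; every error message names the
    offending CSV line.  With ``collapse=True`` (default) negative pre-op
    days are folded into a single day-0 baseline row per animal-domain.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementValidationError(f"missing required columns: {missing}")
    df = df.reset_index(drop=True)

    bad = df.index[~df["domain"].isin(ALL_DOMAINS)]
    if len(bad):
        raise MeasurementValidationError(
            f"unknown domain(s) {sorted(df.loc[bad, 'domain'].unique())} "
            f"at line(s) {_lines(bad)}"
        )
    bad = df.index[df["unit"] != df["domain"].map(DOMAIN_UNITS)]
    if len(bad):
        first = bad[0]
        raise MeasurementValidationError(
            f"unit mismatch: domain {df.loc[first, 'domain']!r} requires unit "
            f"{DOMAIN_UNITS[df.loc[first, 'domain']]!r}, got "
            f"{df.loc[first, 'unit']!r} at line(s) {_lines(bad)}"
        )
    bad = df.index[~df["group"].isin(GROUPS)]
    if len(bad):
        raise MeasurementValidationError(
            f"unknown group label(s) {sorted(df.loc[bad, 'group'].unique())} "
            f"at line(s) {_lines(bad)}"
        )

    day = pd.to_numeric(df["day"], errors="coerce")
    bad = df.index[day.isna() | (day != day.round())]
    if len(bad):
        raise MeasurementValidationError(
            f"malformed day at line(s) {_lines(bad)}"
        )
    def _exact_float(s: str) -> float:
        try:
            return float(s)
        except ValueError:
            return float("nan")

    # builtin float() is correctly rounded; pandas' fast parser can be off
    # by one ULP, which would break byte-exact round-trips
    value = df["value"].map(_exact_float)
    bad = df.index[value.isna()]
    if len(bad):
        raise MeasurementValidationError(
            f"malformed numeric value at line(s) {_lines(bad)}"
        )
    bad = df.index[value < 0]
    if len(bad):
        raise MeasurementValidationError(
            f"negative measurement value at line(s) {_lines(bad)}"
        )
    out = df.assign(day=day.astype(int), value=value.astype(float))

    dup = out.duplicated(subset=["animal_id", "day", "domain"], keep=False)
    if dup.any():
        idx = out.index[dup]
        key = out.loc[idx[0], ["animal_id", "day", "domain"]].tolist()
        raise MeasurementValidationError(
            f"duplicate (animal, day, domain) rows, first key {tuple(key)}, "
            f"at line(s) {_lines(idx)}"
        )
    if collapse:
        out = collapse_baseline(out)
    return out


def collapse_baseline(df: pd.DataFrame) -> pd.DataFrame:
    """Fold negative pre-operative days into day-0 baseline rows.

    Food and water intake baselines are the mean of the pre-operative days;
    every other domain keeps the single pre-operative test closest to
    surgery.  A conflict (both day-0 and negative-day rows for the same
    animal-domain) is an error.
    """
    pre = df[df["day"] < 0]
    if pre.empty:
        return df.reset_index(drop=True)
    post = df[df["day"] >= 0]
    conflict = pd.merge(
        pre[["animal_id", "domain"]].drop_duplicates(),
        post.loc[post["day"] == 0, ["animal_id", "domain"]].drop_duplicates(),
    )
    if not conflict.empty:
        raise MeasurementValidationError(
            f"both day-0 and pre-operative rows present for "
            f"{[tuple(r) for r in conflict.itertuples(index=False)][:5]}"
        )
    collapsed = []
    for (animal, group, domain), sub in pre.groupby(
        ["animal_id", "group", "domain"], sort=True
    ):
        if domain in AVERAGED_BASELINE_DOMAINS:
            value = float(sub["value"].mean())
        else:
            value = float(sub.sort_values("day")["value"].iloc[-1])
        collapsed.append(
            {"animal_id": animal, "group": group, "day": 0, "domain": domain,
             "value": value, "unit": DOMAIN_UNITS[domain]}
        )
    out = pd.concat([post, pd.DataFrame(collapsed)], ignore_index=True)
    return out.sort_values(["animal_id", "day", "domain"]).reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy measurement frame to CSV (round-trips exactly)."""
    # %.17g round-trips every float64 bit-exactly; pandas' default writer
    # can be off by one ULP
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False,
                                             float_format="%.17g")


def read_vonfrey_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level von Frey CSV: animal_id, day, trial_index, force_g, response."""
    df = pd.read_csv(path)
    required = ("animal_id", "day", "trial_index", "force_g", "response")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MeasurementValidationError(f"missing required columns: {missing}")
    if df["force_g"].le(0).any():
        bad = df.index[df["force_g"] <= 0]
        raise MeasurementValidationError(
            f"non-positive filament force at line(s) {_lines(bad)}"
        )
    resp = df["response"]
    if resp.dtype != bool:
        mapped = resp.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False,
             "x": True, "o": False}
        )
        if mapped.isna().any():
            bad = df.index[mapped.isna()]
            raise MeasurementValidationError(
                f"malformed response at line(s) {_lines(bad)}"
            )
        df = df.assign(response=mapped.astype(bool))
    return df.sort_values(["animal_id", "day", "trial_index"]).reset_index(drop=True)
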