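"""Up-down (Dixon) von Frey threshold estimation.

Mechanical allodynia at the abdominal incision site is quantified as the
filament bending force eliciting a withdrawal/abdominal response in 50% of
presentations.  Filaments are presented as an adaptive staircase: a
response steps the force one filament down, no response one filament up.
The 50% threshold is read off the terminal response pattern with Dixon's
up-down formula on the log10 force scale:

    threshold = 10 ** (x_f + k * delta)

where ``x_f`` is log10 of the last filament presented, ``delta`` the mean
log10 spacing of the filament set, and ``k`` a tabulated factor depending
on the terminal response pattern.  The k table shipped with the package is
generated from the construction that defines it: the maximum-likelihood
location of a probit response curve whose spread equals one log-step,
given the staircase-implied stimulus levels of the terminal pattern.

Sessions that pin against either end of the filament set are censored and
clamped to that bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "DEFAULT_FILAMENTS",
    "VonFreyTrial",
    "VonFreySession",
    "ThresholdEstimate",
    "InsufficientDataError",
    "mean_log_spacing",
    "default_start_force",
    "run_staircase",
    "dixon_k",
    "estimate_threshold",
]

#: Default filament set (g): log-spaced bending forces spanning the 0.04 g
#: allodynia deficit anchor up to 15 g (the conventional rat cut-off).
DEFAULT_FILAMENTS: tuple[float, ...] = (
    0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 15.0,
)

#: Dixon k is defined for terminal patterns of up to this many trials.
PATTERN_WINDOW = 6


class InsufficientDataError(ValueError):
    """Session too short to estimate a threshold and not censored."""


@dataclass(frozen=True)
class VonFreyTrial:
    """One filament presentation: bending force (g) and whether the animal responded."""

    force_g: float
    response: bool

    def __post_init__(self) -> None:
        if self.force_g <= 0:
            raise ValueError("filament force must be positive")


@dataclass(frozen=True)
class VonFreySession:
    """An ordered up-down staircase of filament presentations."""

    trials: tuple[VonFreyTrial, ...]
    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS

    def __post_init__(self) -> None:
        fils = tuple(float(f) for f in self.filament_set)
        if len(fils) < 2 or any(b <= a for a, b in zip(fils, fils[1:])):
            raise ValueError("filament set must be strictly increasing, length >= 2")
        object.__setattr__(self, "filament_set", fils)
        object.__setattr__(self, "trials", tuple(self.trials))
        for t in self.trials:
            if not any(np.isclose(t.force_g, f) for f in fils):
                raise ValueError(f"force {t.force_g} g not in the filament set")
        self._check_staircase()

    def _check_staircase(self) -> None:
        fils = self.filament_set
        for a, b in zip(self.trials, self.trials[1:]):
            i = int(np.argmin(np.abs(np.asarray(fils) - a.force_g)))
            j = i - 1 if a.response else i + 1
            j = min(max(j, 0), len(fils) - 1)
            if not np.isclose(b.force_g, fils[j]):
                raise ValueError(
                    f"staircase rule violated: {a.force_g} g "
                    f"({'X' if a.response else 'O'}) followed by {b.force_g} g"
                )

    @property
    def pattern(self) -> str:
        """Responses as a string of X (response) / O (no response), in order."""
        return "".join("X" if t.response else "O" for t in self.trials)

    @property
    def censored_low(self) -> bool:
        """Pinned at the smallest filament: two consecutive responses there."""
        lo = self.filament_set[0]
        return any(
            a.response and b.response
            and np.isclose(a.force_g, lo) and np.isclose(b.force_g, lo)
            for a, b in zip(self.trials, self.trials[1:])
        )

    @property
    def censored_high(self) -> bool:
        """Pinned at the largest filament: two consecutive non-responses there."""
        hi = self.filament_set[-1]
        return any(
            (not a.response) and (not b.response)
            and np.isclose(a.force_g, hi) and np.isclose(b.force_g, hi)
            for a, b in zip(self.trials, self.trials[1:])
        )


@dataclass(frozen=True)
class ThresholdEstimate:
    """50% withdrawal threshold (g); ``censored`` when clamped at a bound."""

    threshold_g: float
    censored: bool = False


def mean_log_spacing(filament_set: Sequence[float]) -> float:
    """Mean log10 spacing delta of a filament set."""
    logs = np.log10(np.asarray(filament_set, dtype=float))
    return float(np.mean(np.diff(logs)))


def default_start_force(filament_set: Sequence[float] = DEFAULT_FILAMENTS) -> float:
    """Set member nearest (in log force) the geometric mean of the range."""
    fils = np.asarray(filament_set, dtype=float)
    target = 0.5 * (np.log10(fils[0]) + np.log10(fils[-1]))
    return float(fils[np.argmin(np.abs(np.log10(fils) - target))])


def run_staircase(
    responder: Callable[[float], bool],
    filament_set: Sequence[float] = DEFAULT_FILAMENTS,
    start_force_g: float | None = None,
    max_trials: int = 20,
) -> VonFreySession:
    """Run the up-down staircase against a trial-response oracle.

    Testing starts at ``start_force_g`` (default: the filament nearest the
    geometric mean of the range) and steps down after a response, up after
    none, clamped at the set bounds.  It stops once 4 trials have been
    collected after the first response reversal, when ``max_trials`` is
    reached, or when a bound is hit twice consecutively with the
    boundary-pushing outcome (a censored session).
    """
    fils = tuple(float(f) for f in filament_set)
    if max_trials < 4:
        raise ValueError("max_trials must be at least 4")
    if start_force_g is None:
        start_force_g = default_start_force(fils)
    if not any(np.isclose(start_force_g, f) for f in fils):
        raise ValueError(f"start force {start_force_g} g not in the filament set")

    idx = int(np.argmin(np.abs(np.asarray(fils) - start_force_g)))
    trials: list[VonFreyTrial] = []
    first_reversal: int | None = None  # 0-based index of the reversal trial
    while True:
        force = fils[idx]
        resp = bool(responder(force))
        trials.append(VonFreyTrial(force_g=force, response=resp))
        n = len(trials)
        if first_reversal is None and n >= 2 and resp != trials[-2].response:
            first_reversal = n - 1
        prev = trials[-2] if n >= 2 else None
        pinned_low = (resp and idx == 0 and prev is not None
                      and prev.response and np.isclose(prev.force_g, fils[0]))
        pinned_high = ((not resp) and idx == len(fils) - 1 and prev is not None
                       and (not prev.response) and np.isclose(prev.force_g, fils[-1]))
        if pinned_low or pinned_high:
            break
        if first_reversal is not None and n >= first_reversal + 1 + 4:
            break
        if n >= max_trials:
            break
        idx = min(max(idx + (-1 if resp else 1), 0), len(fils) - 1)
    return VonFreySession(trials=tuple(trials), filament_set=fils)


def _pattern_levels(pattern: str) -> np.ndarray:
    """Stimulus levels (units of delta, final trial = 0) implied by a pattern.

    Reconstructed backwards from the staircase rule: a response steps the
    next trial down, a non-response up.  Bound clamping is ignored; the
    table applies to interior (non-censored) sessions.
    """
    levels = np.zeros(len(pattern))
    for i in range(len(pattern) - 2, -1, -1):
        step = 1.0 if pattern[i] == "X" else -1.0
        levels[i] = levels[i + 1] + step
    return levels


@lru_cache(maxsize=None)
def dixon_k(pattern: str) -> float:
    """Dixon k factor for a terminal response pattern (X = response, O = none).

    k is the maximum-likelihood location (in units of the log-step delta,
    relative to the final stimulus) of a probit response curve with spread
    equal to one step, evaluated on the staircase-implied levels of the
    pattern.  Requires at least one X and one O (otherwise the likelihood
    has no interior maximum and the session is censored instead).
    """
    if set(pattern) - {"X", "O"}:
        raise ValueError(f"pattern must contain only X/O, got {pattern!r}")
    if "X" not in pattern or "O" not in pattern:
        raise ValueError("pattern must contain both a response and a non-response")
    x = _pattern_levels(pattern)
    resp = np.array([c == "X" for c in pattern])

    def score(mu: float) -> float:
        z = x - mu
        out = np.where(resp, norm.pdf(z) / norm.cdf(z),
                       -norm.pdf(z) / norm.sf(z))
        return float(np.sum(out))

    lo, hi = float(x.min() - 10.0), float(x.max() + 10.0)
    return float(brentq(score, lo, hi, xtol=1e-10))


def _load_k_table() -> dict[str, float]:
    try:
        text = resources.files("qorscore.data").joinpath("dixon_k.json").read_text()
        return {k: float(v) for k, v in json.loads(text)["k"].items()}
    except (FileNotFoundError, KeyError, json.JSONDecodeError):
        return {}


_K_TABLE: dict[str, float] = _load_k_table()


def estimate_threshold(
    session: VonFreySession, delta_log: float | None = None
) -> ThresholdEstimate:
    """Dixon up-down 50% threshold from a staircase session.

    Censored sessions (pinned at a bound) return the clamped bound with
    ``censored=True``.  Otherwise ``threshold = 10**(x_f + k*delta)`` with
    k looked up for the terminal response pattern (last
    :data:`PATTERN_WINDOW` trials, extended backwards if needed so the
    window contains both outcomes).  The estimate is always clamped to the
    filament range.
    """
    fils = session.filament_set
    if session.censored_low:
        return ThresholdEstimate(threshold_g=fils[0], censored=True)
    if session.censored_high:
        return ThresholdEstimate(threshold_g=fils[-1], censored=True)
    if len(session.trials) < 2:
        raise InsufficientDataError(
            "need at least 2 trials (or a censored session) to estimate"
        )
    if delta_log is None:
        delta_log = mean_log_spacing(fils)

    pattern = session.pattern
    window = pattern[-PATTERN_WINDOW:]
    while ("X" not in window or "O" not in window) and len(window) < len(pattern):
        window = pattern[-(len(window) + 1):]
    if "X" not in window or "O" not in window:
        raise InsufficientDataError(
            "session has no response reversal and is not censored"
        )
    k = _K_TABLE.get(window)
    if k is None:
        k = dixon_k(window)
    x_f = np.log10(session.trials[-1].force_g)
    threshold = 10.0 ** (x_f + k * delta_log)
    return ThresholdEstimate(
        threshold_g=float(np.clip(threshold, fils[0], fils[-1])), censored=False
    )


def generate_k_table(max_len: int = PATTERN_WINDOW) -> dict[str, float]:
    """Regenerate the full k table for patterns of length 2..max_len."""
    table: dict[str, float] = {}
    for n in range(2, max_len + 1):
        for bits in range(2 ** n):
            pattern = "".join(
                "X" if (bits >> (n - 1 - i)) & 1 else "O" for i in range(n)
            )
            if "X" in pattern and "O" in pattern:
                table[pattern] = round(dixon_k(pattern), 6)
    return table
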