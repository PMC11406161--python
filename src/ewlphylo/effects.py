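"""Posterior contrast algebra and reporting.

Marginal temperature effects per species and water condition, direction
probabilities, ln-scale rate conversions to percent and mg/min, variance
ratios, and the conceptual outcome classifier for water x temperature
response shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hmodel import (
    BASELINE_SPECIES,
    EffectSummary,
    PosteriorDraws,
    SPECIES_FULL_TO_SHORT,
    SPECIES_SHORT_TO_FULL,
)


@dataclass
class MarginalEffectResult:
    """Posterior of d E[ln mass]/d temperature for one species x water cell."""

    species: str
    water: bool
    draws: np.ndarray
    mean: float
    q2_5: float
    q97_5: float
    p_negative: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_negative <= 1.0):
            raise ValueError("p_negative must lie in [0, 1]")
        if self.q2_5 > self.q97_5:
            raise ValueError("quantiles out of order")


def _short_species(species: str) -> str:
    if species in SPECIES_SHORT_TO_FULL:
        return species
    if species in SPECIES_FULL_TO_SHORT:
        return SPECIES_FULL_TO_SHORT[species]
    raise ValueError(f"unknown species {species!r}")


def marginal_temperature_effect(
    draws: PosteriorDraws, species: str, water: bool
) -> MarginalEffectResult:
    """Per-draw contrast: Temp (+ species-Temp off baseline)
    + water * (Water-Temp (+ species-Water-Temp off baseline))."""
    short = _short_species(species)
    effect = draws.get("Temp").copy()
    if short != SPECIES_FULL_TO_SHORT[BASELINE_SPECIES]:
        effect += draws.get(f"{short}-Temp")
    if water:
        effect += draws.get("Water-Temp")
        if short != SPECIES_FULL_TO_SHORT[BASELINE_SPECIES]:
            effect += draws.get(f"{short}-Water-Temp")
    q_lo, q_hi = np.quantile(effect, [0.025, 0.975])
    return MarginalEffectResult(
        species=short,
        water=water,
        draws=effect,
        mean=float(effect.mean()),
        q2_5=float(q_lo),
        q97_5=float(q_hi),
        p_negative=prob_direction(effect),
    )


def prob_direction(effect_draws: np.ndarray) -> float:
    """Posterior probability the effect is negative (ties counted half)."""
    x = np.asarray(effect_draws, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one draw")
    return float((np.sum(x < 0) + 0.5 * np.sum(x == 0)) / x.size)


def percent_per_minute(coefficient: float) -> float:
    """An ln-scale rate as percent body-mass change: 100 (e^b - 1)."""
    return 100.0 * (math.exp(coefficient) - 1.0)


def mass_rate(coefficient: float, reference_mass_g: float) -> float:
    """An ln-scale per-minute rate as mg/min at a reference mass."""
    if reference_mass_g <= 0:
        raise ValueError("reference mass must be positive")
    return reference_mass_g * (math.exp(coefficient) - 1.0) * 1000.0


@dataclass
class VarianceRatio:
    value: float
    nearest_int: int


def variance_ratio(
    summary: Sequence[EffectSummary], numerator: str, denominator: str
) -> VarianceRatio:
    """Ratio of posterior-mean variance components, with the
    nearest-integer rendering used in reporting."""
    means = {s.term: s.mean for s in summary}
    for label in (numerator, denominator):
        if label not in means:
            raise ValueError(f"no summary row for {label!r}")
        if means[label] <= 0:
            raise ValueError(f"variance {label!r} must have a positive mean")
    value = means[numerator] / means[denominator]
    return VarianceRatio(value=value, nearest_int=int(round(value)))


# ---------------------------------------------------------------------------
# conceptual outcome classification


@dataclass
class SlopeInterval:
    """A net ln-mass slope (per min) with its 95% credible interval."""

    mean: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError("slope interval must bracket its mean")

    def overlaps(self, other: "SlopeInterval") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def covers_zero(self) -> bool:
        return self.lo <= 0.0 <= self.hi


OUTCOME_LABELS = ("O1", "O2", "O3", "O4", "O5", "other")


def classify_outcome(
    water_26: SlopeInterval,
    nowater_26: SlopeInterval,
    water_36: SlopeInterval | None = None,
    nowater_36: SlopeInterval | None = None,
    temp_contrast: SlopeInterval | None = None,
) -> str:
    """Label the water x temperature response shape.

    O2: the in-water and no-water slope intervals overlap (no marginal
    water effect).  Otherwise, if the 36-26 deg C slope contrast covers zero
    (no temperature interaction): O1 when the in-water slope is a gain, O4
    when a loss.  With a temperature interaction: O3 when water yields a
    small gain while the no-water slope is credibly negative, O5 when the
    in-water slope is itself a loss; conflicting evidence yields "other".
    The contrast interval may be supplied directly; otherwise it is formed
    conservatively from the per-temperature intervals (mean difference,
    half-widths added).
    """
    if water_26 is None or nowater_26 is None:
        raise ValueError("slopes for both water conditions at 26 deg C are required")
    if water_26.overlaps(nowater_26):
        return "O2"
    if temp_contrast is None and water_36 is not None and nowater_36 is not None:
        mean = 0.5 * ((water_36.mean - water_26.mean) + (nowater_36.mean - nowater_26.mean))
        half = 0.5 * (
            (water_36.hi - water_36.lo) / 2
            + (water_26.hi - water_26.lo) / 2
            + (nowater_36.hi - nowater_36.lo) / 2
            + (nowater_26.hi - nowater_26.lo) / 2
        )
        temp_contrast = SlopeInterval(mean, mean - half, mean + half)
    no_interaction = temp_contrast is None or temp_contrast.covers_zero()
    if no_interaction:
        return "O1" if water_26.mean > 0 else "O4"
    if water_26.mean > 0:
        return "O3" if nowater_26.hi < 0 else "other"
    return "O5"


def _slope_draws(draws: PosteriorDraws, short: str, water: int, temp: float, session_min: float):
    """Per-draw net ln-mass slope for one cell, folding the temperature
    level effect into an average per-minute slope over the session."""
    base_short = SPECIES_FULL_TO_SHORT[BASELINE_SPECIES]
    s = draws.get("Time").copy()
    if short != base_short:
        s += draws.get(f"{short}-Time")
    if water:
        s += draws.get("Water-Time")
        if short != base_short:
            s += draws.get(f"{short}-Water-Time")
    if temp != 26.0:
        t = draws.get("Temp").copy()
        if short != base_short:
            t += draws.get(f"{short}-Temp")
        if water:
            t += draws.get("Water-Temp")
            if short != base_short:
                t += draws.get(f"{short}-Water-Temp")
        s = s + (temp - 26.0) / session_min * t
    return s


def _interval(x) -> SlopeInterval:
    lo, hi = np.quantile(x, [0.025, 0.975])
    return SlopeInterval(float(np.mean(x)), float(lo), float(hi))


def outcome_report(draws: PosteriorDraws, session_min: float = 60.0) -> pd.DataFrame:
    """Classify each species' water x temperature response shape from the
    posterior slope intervals."""
    rows = []
    for full, short in SPECIES_FULL_TO_SHORT.items():
        w26 = _interval(_slope_draws(draws, short, 1, 26.0, session_min))
        n26 = _interval(_slope_draws(draws, short, 0, 26.0, session_min))
        contrast = _interval(
            0.5
            * (
                _slope_draws(draws, short, 1, 36.0, session_min)
                - _slope_draws(draws, short, 1, 26.0, session_min)
                + _slope_draws(draws, short, 0, 36.0, session_min)
                - _slope_draws(draws, short, 0, 26.0, session_min)
            )
        )
        rows.append(
            {
                "species": short,
                "outcome": classify_outcome(w26, n26, temp_contrast=contrast),
                "water_slope": w26.mean,
                "nowater_slope": n26.mean,
                "temp_contrast": contrast.mean,
            }
        )
    return pd.DataFrame(rows)


def marginal_effects_table(draws: PosteriorDraws) -> pd.DataFrame:
    """The full species x water grid of marginal temperature effects."""
    rows = []
    for full, short in SPECIES_FULL_TO_SHORT.items():
        for water in (True, False):
            r = marginal_temperature_effect(draws, full, water)
            rows.append(
                {
                    "species": short,
                    "water": int(water),
                    "mean": r.mean,
                    "Q2.5": r.q2_5,
                    "Q97.5": r.q97_5,
                    "p_negative": r.p_negative,
                }
            )
    return pd.DataFrame(rows)
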