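"""Raw characteristics of maternal energy-intake elevation patterns.

A lactation *pattern* is a time series of maternal metabolizable energy
intake (MEI, MJ/day) measured over days postpartum, together with the
covariates needed for allometric analysis (maternal body mass, diet
metabolizable-energy density, species and breed identifiers).

Six raw characteristics summarise each pattern:

* **initial rate** — MEI at the first measurement after the day of
  parturition (day 0 itself is never analysed),
* **peak rate** and **time to peak** — the maximum MEI and the day it is
  first attained,
* **average rate** — mean MEI from the initial measurement through the
  peak, endpoints included,
* **amplitude** — peak rate minus initial rate,
* **cumulative elevation to peak** — the time-summed excess of MEI over
  the initial rate from the initial measurement to the peak (MJ), a
  rectangle sum on the sampling grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntakePattern",
    "PatternCharacteristics",
    "InvalidPatternError",
    "initial_rate",
    "peak_rate_and_time",
    "average_rate",
    "cumulative_elevation_to_peak",
    "mei_from_mass_intake",
    "extract_characteristics",
    "cumulative_series",
    "characteristics_table",
    "MIN_ANALYSABLE_POINTS",
]

#: A pattern needs at least this many analysable points (t >= 1) before the
#: three-parameter growth model downstream is identifiable.
MIN_ANALYSABLE_POINTS = 3


class InvalidPatternError(ValueError):
    """Raised when a pattern cannot be analysed (e.g. no post-parturition data)."""


@dataclass
class IntakePattern:
    """One lactation time series of maternal metabolizable energy intake.

    Parameters
    ----------
    pattern_id : str
        Unique identifier of the pattern.
    species : str
        Latin binomial, matching a phylogeny tip label after normalization.
    breed : str
        Breed identifier within the species; empty string when unknown.
    times : array-like of float
        Days postpartum, strictly increasing. Day 0 is permitted in the
        input but excluded from every analysis.
    mei : array-like of float
        Metabolizable energy intake, MJ/day, same length as ``times``.
    diet_me_density : float
        Metabolizable-energy density of the diet, MJ/kg dry matter.
    mass_peak_kg : float
        Maternal body mass at the time of peak intake, kg.
    mass_onset_kg : float
        Maternal body mass at the onset of lactation, kg.
    """

    pattern_id: str
    species: str
    breed: str
    times: np.ndarray
    mei: np.ndarray
    diet_me_density: float
    mass_peak_kg: float
    mass_onset_kg: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mei = np.asarray(self.mei, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.mei.shape:
            raise InvalidPatternError(
                f"{self.pattern_id}: times and mei must be 1-D arrays of equal length"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidPatternError(f"{self.pattern_id}: times must be strictly increasing")
        if np.any(self.mei < 0):
            raise InvalidPatternError(f"{self.pattern_id}: negative MEI values")
        if self.diet_me_density <= 0:
            raise InvalidPatternError(f"{self.pattern_id}: diet ME density must be positive")
        if self.mass_peak_kg <= 0 or self.mass_onset_kg <= 0:
            raise InvalidPatternError(f"{self.pattern_id}: body masses must be positive")

    def analysable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and MEI restricted to days postpartum >= 1 (day 0 dropped)."""
        keep = self.times >= 1.0
        return self.times[keep], self.mei[keep]

    @property
    def n_analysable(self) -> int:
        return int(np.sum(self.times >= 1.0))


@dataclass
class PatternCharacteristics:
    """The six raw quantities extracted from a pattern (MJ/day, days, MJ)."""

    pattern_id: str
    initial_rate: float
    peak_rate: float
    time_to_peak: float
    average_rate: float
    amplitude: float
    cumulative_elevation_to_peak: float
    flags: list[str] = field(default_factory=list)


def _analysable_or_raise(pattern: IntakePattern) -> tuple[np.ndarray, np.ndarray]:
    t, y = pattern.analysable()
    if t.size == 0:
        raise InvalidPatternError(
            f"{pattern.pattern_id}: no measurements at day >= 1 after parturition"
        )
    return t, y


def initial_rate(pattern: IntakePattern) -> float:
    """MEI at the first measurement after the day of parturition (MJ/day).

    Any day-0 row (intake at parturition) is ignored.
    """
    _, y = _analysable_or_raise(pattern)
    return float(y[0])


def _median3_smooth(y: np.ndarray) -> np.ndarray:
    """Centered 3-point running median; endpoints are left unchanged."""
    if y.size < 3:
        return y.copy()
    out = y.copy()
    out[1:-1] = np.median(np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1)
    return out


def peak_rate_and_time(
    pattern: IntakePattern, robust: bool = False
) -> tuple[float, float, list[str]]:
    """Maximum MEI of the pattern and the day it is first attained.

    With ``robust=True`` the maximum is located on a centered 3-point
    median smooth of the series, which suppresses single-measurement
    spikes; the reported peak rate is the smoothed value there. Ties are
    broken by the earliest time (the peak is the first attainment of the
    maximum, just before intake levels off).

    Returns ``(peak_rate, time_to_peak, flags)``; ``flags`` contains
    ``"peak_at_series_end"`` when the maximum sits on the last
    measurement, i.e. the peak may not have been reached.
    """
    t, y = _analysable_or_raise(pattern)
    series = _median3_smooth(y) if robust else y
    idx = int(np.argmax(series))  # argmax returns the first maximal index
    flags = ["peak_at_series_end"] if idx == series.size - 1 else []
    return float(series[idx]), float(t[idx]), flags


def average_rate(pattern: IntakePattern, time_to_peak: float) -> float:
    """Arithmetic mean of MEI from the initial measurement through the peak.

    Both endpoints are included; measurements after the peak are excluded.
    """
    t, y = _analysable_or_raise(pattern)
    return float(np.mean(y[t <= time_to_peak]))


def _grid_spacing(t: np.ndarray) -> float:
    """Spacing of the sampling grid: 1 day for daily data, the measurement
    interval for coarser (e.g. weekly) data. The median spacing is used so
    occasional gaps in otherwise regular series do not distort it."""
    if t.size < 2:
        return 1.0
    return float(np.median(np.diff(t)))


def cumulative_elevation_to_peak(pattern: IntakePattern, time_to_peak: float) -> float:
    """Sum of (MEI - initial rate) x grid spacing from initial to peak (MJ).

    A rectangle sum on the sampling grid; negative summands (intake dips
    below the initial rate) are kept as-is.
    """
    t, y = _analysable_or_raise(pattern)
    dt = _grid_spacing(t)
    keep = t <= time_to_peak
    return float(np.sum(y[keep] - y[0]) * dt)


def mei_from_mass_intake(dm_intake_kg_per_day: float, me_density_mj_per_kg: float) -> float:
    """Metabolizable energy intake from dry-matter intake and diet ME density.

    MEI (MJ/day) = mass of food ingested (kg DM/day) x metabolizable-energy
    density of the diet (MJ/kg DM).
    """
    if dm_intake_kg_per_day <= 0 or me_density_mj_per_kg <= 0:
        raise ValueError("dry-matter intake and ME density must both be positive")
    return dm_intake_kg_per_day * me_density_mj_per_kg


def extract_characteristics(
    pattern: IntakePattern, robust_peak: bool = False
) -> PatternCharacteristics:
    """Extract all six raw characteristics from one pattern.

    Patterns with fewer than :data:`MIN_ANALYSABLE_POINTS` measurements at
    day >= 1 are still summarised but flagged ``"too_short"``: the growth
    model downstream needs at least three points.
    """
    init = initial_rate(pattern)
    peak, t_peak, flags = peak_rate_and_time(pattern, robust=robust_peak)
    flags = list(flags)
    if pattern.n_analysable < MIN_ANALYSABLE_POINTS:
        flags.append("too_short")
    return PatternCharacteristics(
        pattern_id=pattern.pattern_id,
        initial_rate=init,
        peak_rate=peak,
        time_to_peak=t_peak,
        average_rate=average_rate(pattern, t_peak),
        amplitude=peak - init,
        cumulative_elevation_to_peak=cumulative_elevation_to_peak(pattern, t_peak),
        flags=flags,
    )


def cumulative_series(pattern: IntakePattern) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-elevation series for growth-curve fitting.

    Returns ``(t, C)`` over the full analysable series, with time re-zeroed
    at the initial-rate measurement and ``C`` the running rectangle sum of
    (MEI - initial rate) x grid spacing, so that ``C[0] == 0``.
    """
    t, y = _analysable_or_raise(pattern)
    if t.size < MIN_ANALYSABLE_POINTS:
        raise InvalidPatternError(
            f"{pattern.pattern_id}: need >= {MIN_ANALYSABLE_POINTS} analysable points"
        )
    dt = _grid_spacing(t)
    cum = np.cumsum(y - y[0]) * dt
    return t - t[0], cum


def characteristics_table(
    patterns: list[IntakePattern], robust_peak: bool = False
) -> pd.DataFrame:
    """Characteristics of many patterns as one row per pattern.

    Carries the covariates (species, breed, diet ME density, masses) along
    so the table feeds the scaling regressions directly.
    """
    rows = []
    for p in patterns:
        try:
            ch = extract_characteristics(p, robust_peak=robust_peak)
        except InvalidPatternError as exc:
            warnings.warn(f"skipping pattern {p.pattern_id}: {exc}")
            continue
        rows.append(
            {
                "pattern_id": p.pattern_id,
                "species": p.species,
                "breed": p.breed,
                "diet_me_mj_per_kg_dm": p.diet_me_density,
                "mass_peak_kg": p.mass_peak_kg,
                "mass_onset_kg": p.mass_onset_kg,
                "initial_rate": ch.initial_rate,
                "peak_rate": ch.peak_rate,
                "time_to_peak": ch.time_to_peak,
                "average_rate": ch.average_rate,
                "amplitude": ch.amplitude,
                "cumulative_elevation_to_peak": ch.cumulative_elevation_to_peak,
                "flags": ";".join(ch.flags),
            }
        )
    return pd.DataFrame(rows)
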