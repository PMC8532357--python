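"""Specific extracellular flux and growth-rate estimation from time courses.

Specific rates q (mmol gDW^-1 h^-1) are obtained from concentration-vs-time
data by finite differences without any prior smoothing: at an interior time
point t_i the central (midpoint) difference

    q(t_i) = (C(t_{i+1}) - C(t_{i-1})) / (t_{i+1} - t_{i-1}) / X(t_i)

and one-sided differences at the series endpoints, where X is the measured
biomass concentration (gDW/L).  Consumption therefore yields negative fluxes
and production positive ones.  The central difference is exact for linear and
quadratic concentration profiles at equally spaced interior points; on an
exponential profile its relative error is ~(mu*dt)^2/6.

Biomass normalisation uses X at the evaluation point by default; the
alternative of the mean of X over the difference window is available via
``biomass_norm="midpoint"`` since published flux tables rarely say which was
used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enology import ConstraintSet

logger = logging.getLogger(__name__)


@dataclass
class FermentationSeries:
    """One strain's fermentation time course.

    times (h) strictly increasing; biomass (gDW/L) positive; each compound's
    concentration series (mmol/L) has the same length as ``times``.
    """

    strain: str
    times: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.times.size < 3:
            raise ValueError("a fermentation series needs at least 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.biomass.shape != self.times.shape:
            raise ValueError("biomass series length differs from times")
        if np.any(self.biomass <= 0):
            raise ValueError("biomass must be positive at every point")
        for comp, series in self.concentrations.items():
            if series.shape != self.times.shape:
                raise ValueError(f"series for {comp!r} has wrong length")

    def index_of(self, time_h: float) -> int:
        idx = np.nonzero(np.isclose(self.times, time_h))[0]
        if idx.size == 0:
            raise KeyError(f"time {time_h} h not in series for strain {self.strain!r}")
        return int(idx[0])


@dataclass
class FluxTable:
    """One ConstraintSet per (strain, time) plus the compound->exchange map."""

    rows: list[ConstraintSet]
    compound_to_exchange: dict[str, str]

    def row(self, strain: str, time_h: float) -> ConstraintSet:
        for cs in self.rows:
            if cs.strain == strain and np.isclose(cs.time_h, time_h):
                return cs
        raise KeyError(f"no constraint row for ({strain!r}, {time_h} h)")


def _finite_difference(values: np.ndarray, times: np.ndarray, i: int) -> float:
    """Central difference at interior points, one-sided at the endpoints."""
    n = times.size
    if n < 2:
        raise ValueError("need at least 2 points for a finite difference")
    if i == 0:
        return (values[1] - values[0]) / (times[1] - times[0])
    if i == n - 1:
        return (values[-1] - values[-2]) / (times[-1] - times[-2])
    return (values[i + 1] - values[i - 1]) / (times[i + 1] - times[i - 1])


def _norm_biomass(series: FermentationSeries, i: int, biomass_norm: str) -> float:
    if biomass_norm == "point":
        return float(series.biomass[i])
    if biomass_norm == "midpoint":
        lo = max(i - 1, 0)
        hi = min(i + 1, series.times.size - 1)
        return float((series.biomass[lo] + series.biomass[hi]) / 2.0)
    raise ValueError(f"unknown biomass_norm {biomass_norm!r}")


def estimate_specific_flux(
    series: FermentationSeries,
    compound: str,
    time_h: float,
    biomass_norm: str = "point",
) -> float:
    """Specific consumption/production rate of ``compound`` at ``time_h``."""
    if compound not in series.concentrations:
        raise KeyError(f"compound {compound!r} not measured for strain {series.strain!r}")
    i = series.index_of(time_h)
    dCdt = _finite_difference(series.concentrations[compound], series.times, i)
    return dCdt / _norm_biomass(series, i, biomass_norm)


def estimate_growth_rate(
    series: FermentationSeries, time_h: float, biomass_norm: str = "point"
) -> float:
    """Specific growth rate mu(t) = X'(t)/X(t) by the same difference scheme."""
    i = series.index_of(time_h)
    dXdt = _finite_difference(series.biomass, series.times, i)
    return dXdt / _norm_biomass(series, i, biomass_norm)


def build_flux_table(
    series_by_strain: list[FermentationSeries],
    time_points: list[float],
    mapping: dict[str, str],
    biomass_norm: str = "point",
) -> FluxTable:
    """Estimate all mapped compounds' fluxes and growth rates per strain x time.

    Compounds present in a series but absent from ``mapping`` are excluded
    with a logged warning; a requested time missing from any series is an
    error.
    """
    rows: list[ConstraintSet] = []
    for series in series_by_strain:
        unmapped = sorted(set(series.concentrations) - set(mapping))
        if unmapped:
            logger.warning(
                "strain %s: compounds without exchange mapping excluded: %s",
                series.strain,
                unmapped,
            )
        for t in time_points:
            series.index_of(t)  # raises KeyError if missing
            fixed = {
                mapping[comp]: estimate_specific_flux(series, comp, t, biomass_norm)
                for comp in series.concentrations
                if comp in mapping
            }
            mu = estimate_growth_rate(series, t, biomass_norm)
            rows.append(ConstraintSet(series.strain, float(t), fixed, mu))
    seen = set()
    for cs in rows:
        key = (cs.strain, cs.time_h)
        if key in seen:
            raise ValueError(f"duplicate (strain, time) pair {key}")
        seen.add(key)
    return FluxTable(rows, dict(mapping))


# ---------------------------------------------------------------------------
# CSV I/O: one file per strain with columns time_h, biomass_gDW_L, <compound>...


def series_to_frame(series: FermentationSeries) -> pd.DataFrame:
    data = {"time_h": series.times, "biomass_gDW_L": series.biomass}
    data.update(series.concentrations)
    return pd.DataFrame(data)


def write_series_csv(series: FermentationSeries, path: str) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series_csv(path: str, strain: str) -> FermentationSeries:
    df = pd.read_csv(path)
    for col in ("time_h", "biomass_gDW_L"):
        if col not in df.columns:
            raise ValueError(f"series CSV {path!r} lacks required column {col!r}")
    comps = [c for c in df.columns if c not in ("time_h", "biomass_gDW_L")]
    return FermentationSeries(
        strain=strain,
        times=df["time_h"].to_numpy(),
        biomass=df["biomass_gDW_L"].to_numpy(),
        concentrations={c: df[c].to_numpy() for c in comps},
    )
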