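"""Observed-series I/O and goodness-of-fit against model trajectories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LegacyLagError
from .outlet_response import ConcentrationSeries

__all__ = ["ObservedSeries", "read_observed", "write_observed", "rmse"]


@dataclass(frozen=True)
class ObservedSeries:
    """Observed outlet concentrations vs. years since conversion."""

    years: np.ndarray
    values: np.ndarray  # mg/L

    def __post_init__(self):
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if years.shape != values.shape or years.ndim != 1 or years.size == 0:
            raise ValueError("years and values must be matching non-empty 1-D arrays")
        if np.any(np.diff(years) < 0):
            raise ValueError("years must be sorted")
        if np.any(values < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)


def read_observed(path) -> ObservedSeries:
    """Read a two-column (year, mg/L) delimited file; header optional."""
    years, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                years.append(float(parts[0]))
                values.append(float(parts[1]))
            except (ValueError, IndexError):
                if not years:
                    continue  # header
                raise ValueError(f"malformed observed-series line: {line!r}")
    return ObservedSeries(np.asarray(years), np.asarray(values))


def write_observed(series: ObservedSeries, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("year\tconcentration_mg_per_L\n")
        for y, v in zip(series.years, series.values):
            fh.write(f"{float(y)!r}\t{float(v)!r}\n")


def rmse(observed: ObservedSeries, predicted: ConcentrationSeries) -> float:
    """Root-mean-square error of a predicted trajectory at observation times.

    Predictions are interpolated linearly to the observation times; only
    observations inside the predicted time support contribute, and an empty
    overlap is an error.
    """
    lo, hi = predicted.times[0], predicted.times[-1]
    mask = (observed.years >= lo) & (observed.years <= hi)
    if not np.any(mask):
        raise LegacyLagError(
            "observed series does not overlap the predicted time support"
        )
    pred = np.interp(observed.years[mask], predicted.times, predicted.values)
    diff = observed.values[mask] - pred
    return float(np.sqrt(np.mean(diff * diff)))
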