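"""Cross-species pressure extrapolation and the travel-advisory calculator.

A pressure excursion measured in a rabbit eye is translated to a
human-equivalent excursion through the rigidity chain: the measured
log10-pressure change is converted to the (species-independent) volume
change using the rabbit rigidity, then back to a log-pressure change using
a human rigidity coefficient, and anchored at the eye's own baseline
pressure.  Refitting the altitude regression on the transformed series
yields human-equivalent slopes in mmHg per 100 m, compared across eyes by
CI overlap exactly as in the source-species analysis.

The advisory calculator turns a slope (with its CI) and a planned altitude
gain into a predicted final IOP with an interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import RigidityCoefficient, extrapolate_pressure
from .regression import (
    Method,
    RegressionFit,
    TripSeries,
    _ols,
    classify_significance,
    fit_iop_altitude,
)

__all__ = [
    "ExtrapolatedSeries",
    "AdvisoryResult",
    "transform_series_to_human",
    "fit_human_series",
    "extrapolation_table",
    "format_extrapolation_table",
    "predict_travel_iop",
]


@dataclass(frozen=True)
class ExtrapolatedSeries:
    """Human-equivalent pressures derived from one source eye's series."""

    source_eye: str
    coefficient: RigidityCoefficient
    points: tuple[tuple[float, float], ...]  # (altitude m, human pressure mmHg)
    baseline_pressure: float

    def altitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.points], dtype=float)

    def pressures(self) -> np.ndarray:
        return np.array([p for _, p in self.points], dtype=float)

    def ascent_points(self) -> "ExtrapolatedSeries":
        peak = int(np.argmax(self.altitudes()))
        return ExtrapolatedSeries(
            self.source_eye, self.coefficient, self.points[: peak + 1], self.baseline_pressure
        )


def transform_series_to_human(
    series: TripSeries,
    e_source: RigidityCoefficient,
    e_target: RigidityCoefficient,
    method: Method = "applanation",
    baseline_pressure: Optional[float] = None,
) -> ExtrapolatedSeries:
    """Station-by-station rigidity transform of a measured trip series.

    Each station's pressure is referenced to the series baseline (the
    first station by default, or an explicit ``baseline_pressure`` in mmHg)
    and mapped through the extrapolation chain.  The baseline station maps
    to the baseline pressure itself; with ``e_source == e_target`` the
    transform is the identity.
    """
    y = series.pressures(method)
    alts = series.altitudes()
    keep = ~np.isnan(y)
    y, alts = y[keep], alts[keep]
    if len(y) == 0:
        raise ValueError(f"eye {series.eye_id!r} has no {method} measurements")
    p1_source = float(y[0])
    p1_target = p1_source if baseline_pressure is None else float(baseline_pressure)
    points = tuple(
        (float(a), extrapolate_pressure((p1_source, p), e_source, e_target, p1_target))
        for a, p in zip(alts, y)
    )
    return ExtrapolatedSeries(
        source_eye=series.eye_id,
        coefficient=e_target,
        points=points,
        baseline_pressure=p1_target,
    )


def fit_human_series(
    ex: ExtrapolatedSeries, ci_level: float = 0.95, ascent_only: bool = False
) -> RegressionFit:
    """OLS of human-equivalent pressure on altitude/100 (same contract as
    the source-species fit)."""
    if ascent_only:
        ex = ex.ascent_points()
    return _ols(ex.altitudes() / 100.0, ex.pressures(), ci_level)


def extrapolation_table(
    all_series: Sequence[TripSeries],
    e_source: RigidityCoefficient,
    coefficients: Sequence[RigidityCoefficient],
    benchmark_eye: str,
    method: Method = "applanation",
    ci_level: float = 0.95,
    ascent_only: bool = False,
) -> pd.DataFrame:
    """Human-equivalent regression report: one row per (eye, coefficient).

    Significance of each row is classified by CI overlap against the
    benchmark eye's fit under the same coefficient (the benchmark row
    itself is left blank, as it is its own reference).
    """
    ids = [s.eye_id for s in all_series]
    if benchmark_eye not in ids:
        raise ValueError(f"benchmark eye {benchmark_eye!r} not among series {ids}")
    rows = []
    for coeff in coefficients:
        fits = {}
        for series in all_series:
            ex = transform_series_to_human(series, e_source, coeff, method)
            fits[series.eye_id] = fit_human_series(ex, ci_level, ascent_only)
        bench = fits[benchmark_eye]
        for series in all_series:
            fit = fits[series.eye_id]
            sig = "" if series.eye_id == benchmark_eye else classify_significance(fit, bench)
            rows.append(
                {
                    "case": series.eye_id,
                    "coefficient": coeff.name,
                    "intercept": fit.intercept,
                    "slope_per_100m": fit.slope,
                    "ci_low": fit.ci95[0],
                    "ci_high": fit.ci95[1],
                    "significance": sig,
                }
            )
    return pd.DataFrame(rows)


def format_extrapolation_table(table: pd.DataFrame, round_like_report: bool = True) -> str:
    """Text rendering of the extrapolation report, one block per coefficient."""
    blocks = []
    for coeff, grp in table.groupby("coefficient", sort=False):
        lines = [f"Coefficient: {coeff}", "-" * 72]
        for _, r in grp.iterrows():
            if round_like_report:
                eqn = f"Y = {r.intercept:+.2f} {r.slope_per_100m:+.2f}x"
                ci = f"({r.ci_low:.1f} to {r.ci_high:.1f})"
            else:
                eqn = f"Y = {r.intercept!r} + {r.slope_per_100m!r}x"
                ci = f"({r.ci_low!r} to {r.ci_high!r})"
            lines.append(f"{r['case']:<12} {eqn:<28} {ci:<18} {r.significance}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)


@dataclass(frozen=True)
class AdvisoryResult:
    """Predicted final IOP after an altitude gain, with its interval."""

    predicted_iop: float
    ci95: tuple[float, float]
    delta_iop: float
    altitude_change: float


def predict_travel_iop(
    baseline_iop: float,
    slope: float,
    slope_ci: tuple[float, float],
    altitude_change: float,
) -> AdvisoryResult:
    """Final-IOP advisory for a planned ascent.

    ``delta = slope * altitude_change/100`` added to the baseline; the
    interval applies the slope CI's endpoints to the same altitude gain.
    Descent advisories (negative altitude change) are out of scope.
    """
    if baseline_iop <= 0:
        raise ValueError(f"baseline IOP must be > 0 mmHg, got {baseline_iop}")
    if altitude_change < 0:
        raise ValueError(f"altitude change must be >= 0 m, got {altitude_change}")
    steps = altitude_change / 100.0
    delta = steps * slope
    lo, hi = slope_ci
    return AdvisoryResult(
        predicted_iop=baseline_iop + delta,
        ci95=(baseline_iop + steps * lo, baseline_iop + steps * hi),
        delta_iop=delta,
        altitude_change=altitude_change,
    )
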