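"""Per-eye altitude-IOP regression and tonometry method agreement.

Each study eye contributes an ordered series of intraocular pressure
measurements taken at road-trip stations of known altitude, by two
tonometry methods (applanation / Tono-pen and indentation / Schiötz).  The
analysis is a plain ordinary-least-squares fit of IOP (mmHg) on altitude
expressed in hundreds of metres, so the slope reads directly as "mmHg per
100 m of altitude rise".  Slopes of different eyes are compared through the
overlap of their 95% t-confidence intervals against a benchmark eye.

Method agreement between the two tonometers is summarised by a paired
Wilcoxon signed-rank test (zero differences dropped, mid-rank ties) plus
Pearson and Spearman correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .core import DomainError

__all__ = [
    "TAMPONADES",
    "EyeConfig",
    "TripMeasurement",
    "TripSeries",
    "RegressionFit",
    "MethodAgreement",
    "fit_iop_altitude",
    "slope_confidence_interval",
    "classify_significance",
    "method_agreement",
]

#: Tamponade configurations of the experimental model: nonexpansile (18%)
#: SF6 at various vitreous-cavity fill fractions, room air, saline control,
#: and an undiluted SF6 bubble injected without vitrectomy.
TAMPONADES = ("SF6_18pct", "room_air", "BSS", "SF6_100pct_no_vitrectomy")

Method = Literal["applanation", "indentation"]


@dataclass(frozen=True)
class EyeConfig:
    """One study eye: surgical status and tamponade configuration.

    Exactly one of ``fill_fraction`` (vitrectomized eyes, proportion of the
    vitreous cavity exchanged) and ``injected_volume_cc`` (the
    non-vitrectomized, directly injected eye) may be set.
    """

    eye_id: str
    vitrectomized: bool = True
    tamponade: Optional[str] = None
    fill_fraction: Optional[float] = None
    injected_volume_cc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tamponade is not None and self.tamponade not in TAMPONADES:
            raise ValueError(f"unknown tamponade {self.tamponade!r}; expected one of {TAMPONADES}")
        if self.fill_fraction is not None and self.injected_volume_cc is not None:
            raise ValueError("set fill_fraction or injected_volume_cc, not both")
        if self.fill_fraction is not None and not (0.0 <= self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must be in [0, 1], got {self.fill_fraction}")
        if self.injected_volume_cc is not None and self.injected_volume_cc <= 0:
            raise ValueError(f"injected_volume_cc must be > 0, got {self.injected_volume_cc}")


@dataclass(frozen=True)
class TripMeasurement:
    """IOP at one altitude station, by both tonometry methods."""

    altitude_m: float
    iop_applanation: Optional[float] = None
    iop_indentation: Optional[float] = None
    phase: Literal["ascent", "descent"] = "ascent"
    temperature_c: Optional[float] = None  # recorded but unused by the analysis

    def __post_init__(self) -> None:
        if self.altitude_m <= 0:
            raise ValueError(f"altitude must be > 0 m, got {self.altitude_m}")
        for label, v in (("iop_applanation", self.iop_applanation),
                         ("iop_indentation", self.iop_indentation)):
            if v is not None and v <= 0:
                raise DomainError(f"{label}={v} must be > 0 mmHg")

    def iop(self, method: Method) -> Optional[float]:
        return self.iop_applanation if method == "applanation" else self.iop_indentation


@dataclass(frozen=True)
class TripSeries:
    """One eye's ordered measurements over the road trip.

    The first measurement is the baseline (trip start, lowest altitude).
    """

    eye: EyeConfig
    measurements: tuple[TripMeasurement, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))

    @property
    def eye_id(self) -> str:
        return self.eye.eye_id

    def altitudes(self) -> np.ndarray:
        return np.array([m.altitude_m for m in self.measurements], dtype=float)

    def pressures(self, method: Method = "applanation") -> np.ndarray:
        vals = [m.iop(method) for m in self.measurements]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    def ascent(self) -> "TripSeries":
        """Sub-series up to and including the highest station."""
        alts = self.altitudes()
        peak = int(np.argmax(alts))
        return replace(self, measurements=self.measurements[: peak + 1])


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of IOP on altitude in 100 m units.

    ``slope`` and ``se_slope`` are in mmHg per 100 m; ``intercept`` is the
    fitted IOP at altitude 0.  ``ci95`` is the t-based interval for the
    slope at the fit's confidence level (95% by default).
    """

    slope: float
    intercept: float
    ci95: tuple[float, float]
    n: int
    se_slope: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"regression needs >= 3 points, got n={self.n}")
        if not (self.ci95[0] <= self.slope <= self.ci95[1]):
            raise ValueError("slope must lie inside its confidence interval")

    @property
    def df(self) -> int:
        return self.n - 2


def _ols(x: np.ndarray, y: np.ndarray, ci_level: float = 0.95) -> RegressionFit:
    if len(x) < 3:
        raise ValueError(f"regression needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all altitudes identical")
    res = stats.linregress(x, y)
    se = float(res.stderr)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, len(x) - 2))
    rsq = float(res.rvalue**2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95=(float(res.slope) - tcrit * se, float(res.slope) + tcrit * se),
        n=len(x),
        se_slope=se,
        r_squared=rsq,
    )


def fit_iop_altitude(
    series: TripSeries,
    method: Method = "applanation",
    ci_level: float = 0.95,
    ascent_only: bool = False,
) -> RegressionFit:
    """OLS of IOP (mmHg) on altitude/100 for one eye.

    All stations — ascent and descent — enter the fit by default;
    ``ascent_only=True`` restricts to stations up to the trip's highest
    point (a sensitivity analysis).  Stations lacking the chosen method's
    reading are dropped.
    """
    if ascent_only:
        series = series.ascent()
    y = series.pressures(method)
    x = series.altitudes() / 100.0
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError(
            f"eye {series.eye_id!r}: need >= 3 {method} measurements, have {int(keep.sum())}"
        )
    return _ols(x[keep], y[keep], ci_level)


def slope_confidence_interval(fit: RegressionFit, level: float = 0.95) -> tuple[float, float]:
    """t-distribution confidence interval for the slope at an arbitrary level."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, fit.df))
    return (fit.slope - tcrit * fit.se_slope, fit.slope + tcrit * fit.se_slope)


def classify_significance(candidate: RegressionFit, benchmark: RegressionFit) -> str:
    """``"Sig"`` if the two slopes' 95% CIs are disjoint, else ``"NS"``."""
    lo_c, hi_c = candidate.ci95
    lo_b, hi_b = benchmark.ci95
    return "Sig" if (hi_c < lo_b or lo_c > hi_b) else "NS"


@dataclass(frozen=True)
class MethodAgreement:
    """Paired agreement statistics between the two tonometry channels."""

    wilcoxon_p: float
    pearson_r: float
    spearman_rho: float
    r_squared: float
    all_differences_zero: bool = False


def method_agreement(series: TripSeries) -> MethodAgreement:
    """Agreement between applanation and indentation readings of one eye.

    Wilcoxon signed-rank is two-sided with zero differences dropped and
    mid-rank ties (exact null distribution where scipy supports it).  When
    every paired difference is zero the test is undefined; p is reported as
    1 with ``all_differences_zero`` set.  ``r_squared`` is the square of the
    Pearson correlation.
    """
    app = series.pressures("applanation")
    ind = series.pressures("indentation")
    keep = ~(np.isnan(app) | np.isnan(ind))
    app, ind = app[keep], ind[keep]
    if len(app) < 5:
        raise ValueError(f"eye {series.eye_id!r}: need >= 5 paired measurements, have {len(app)}")
    pearson = float(stats.pearsonr(app, ind).statistic)
    spearman = float(stats.spearmanr(app, ind).statistic)
    if np.all(app == ind):
        return MethodAgreement(1.0, pearson, spearman, pearson**2, all_differences_zero=True)
    wp = float(stats.wilcoxon(app, ind, zero_method="wilcox").pvalue)
    return MethodAgreement(wp, pearson, spearman, pearson**2)
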