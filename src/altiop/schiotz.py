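"""Schiötz indentation-tonometry calibration and two-weight rigidity estimation.

A Schiötz tonometer rests a weighted plunger on the cornea; the scale
reading reflects how deeply the plunger indents the globe, which depends on
both the true intraocular pressure and the ocular rigidity.  Calibration
tables map a (plunger weight, scale reading) pair to the corresponding
intraocular pressure and indentation volume.

Reading the same eye with two different plunger weights gives two
(pressure, indentation volume) points on that eye's pressure-volume curve,
from which the rigidity follows directly:

    E = (log10 P_heavy - log10 P_light) / (V_heavy - V_light)

This is the classical tabular method.  The calibration table itself is
injectable data (CSV with columns ``weight_g, scale_reading, pressure_mmhg,
volume_mm3``) so that any published table can be supplied; tests use a small
synthetic table with the required monotonic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .core import DomainError, RigidityCoefficient

__all__ = [
    "CalibrationRangeError",
    "SchiotzReading",
    "CalibrationTable",
    "average_replicates",
    "rigidity_from_two_weights",
    "mean_rigidity",
]

CALIBRATION_COLUMNS = ("weight_g", "scale_reading", "pressure_mmhg", "volume_mm3")


class CalibrationRangeError(ValueError):
    """A reading falls outside the calibration table's tabulated range."""


@dataclass(frozen=True)
class SchiotzReading:
    """One Schiötz measurement: plunger weight (g) and scale reading."""

    weight_g: float
    scale_reading: float

    def __post_init__(self) -> None:
        if self.scale_reading < 0:
            raise ValueError(f"scale reading must be >= 0, got {self.scale_reading}")


class CalibrationTable:
    """Scale-reading -> (pressure, indentation volume) calibration per weight.

    Within each plunger weight, pressure must strictly decrease and
    indentation volume strictly increase with the scale reading (a deeper
    indentation means a softer, lower-pressure eye and a larger displaced
    volume), and at least two rows must be present.  Between tabulated scale
    readings, pressure is interpolated linearly in log10(pressure) — the
    rigidity framework is linear in log pressure — and volume linearly.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in CALIBRATION_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"calibration table missing columns: {missing}")
        table = table.loc[:, list(CALIBRATION_COLUMNS)].astype(float)
        table = table.sort_values(["weight_g", "scale_reading"]).reset_index(drop=True)
        if (table["pressure_mmhg"] <= 0).any():
            raise DomainError("calibration pressures must be > 0 mmHg")
        for weight, grp in table.groupby("weight_g"):
            if len(grp) < 2:
                raise ValueError(f"weight {weight} g has fewer than 2 calibration rows")
            if not grp["scale_reading"].is_unique:
                raise ValueError(f"duplicate scale readings for weight {weight} g")
            if not grp["pressure_mmhg"].is_monotonic_decreasing:
                raise ValueError(f"pressure must strictly decrease with scale reading (weight {weight} g)")
            if not grp["volume_mm3"].is_monotonic_increasing:
                raise ValueError(f"volume must strictly increase with scale reading (weight {weight} g)")
        self._table = table

    @classmethod
    def from_csv(cls, path: Union[str, PathLike]) -> "CalibrationTable":
        return cls(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(sorted(self._table["weight_g"].unique()))

    def lookup(self, reading: SchiotzReading) -> tuple[float, float]:
        """Interpolated (pressure mmHg, indentation volume mm^3) for a reading.

        Exact at tabulated grid points.  Raises :class:`CalibrationRangeError`
        for an unsupported plunger weight or a scale reading outside the
        tabulated range for its weight.
        """
        grp = self._table[self._table["weight_g"] == reading.weight_g]
        if grp.empty:
            raise CalibrationRangeError(
                f"unsupported plunger weight {reading.weight_g} g; "
                f"table covers {self.weights}"
            )
        s = grp["scale_reading"].to_numpy()
        lo, hi = s[0], s[-1]
        if not (lo <= reading.scale_reading <= hi):
            raise CalibrationRangeError(
                f"scale reading {reading.scale_reading} outside tabulated range "
                f"[{lo}, {hi}] for weight {reading.weight_g} g"
            )
        logp = float(np.interp(reading.scale_reading, s, np.log10(grp["pressure_mmhg"].to_numpy())))
        vol = float(np.interp(reading.scale_reading, s, grp["volume_mm3"].to_numpy()))
        return 10.0 ** logp, vol


def average_replicates(readings: Sequence[SchiotzReading]) -> SchiotzReading:
    """Average replicate readings on the scale-reading axis.

    Replicates taken at one station are averaged *before* the (nonlinear)
    calibration lookup, so the averaged scale reading, not the averaged
    pressure, enters the table.  All replicates must share one plunger
    weight.
    """
    if not readings:
        raise ValueError("no readings to average")
    weights = {r.weight_g for r in readings}
    if len(weights) > 1:
        raise ValueError(f"replicates mix plunger weights: {sorted(weights)}")
    return SchiotzReading(
        weight_g=readings[0].weight_g,
        scale_reading=float(np.mean([r.scale_reading for r in readings])),
    )


def rigidity_from_two_weights(
    table: CalibrationTable,
    light: SchiotzReading,
    heavy: SchiotzReading,
) -> RigidityCoefficient:
    """Estimate ocular rigidity from paired readings at two plunger weights.

    Looks both readings up in the calibration table and applies the rigidity
    relation to the two (pressure, volume) points.  Symmetric in its two
    reading arguments (swapping them flips numerator and denominator signs).

    Raises
    ------
    DomainError
        If the two looked-up indentation volumes coincide (the rigidity
        quotient is undefined) or the readings share a plunger weight.
    """
    if light.weight_g == heavy.weight_g:
        raise DomainError(
            f"two-weight estimation needs distinct plunger weights, both are {light.weight_g} g"
        )
    p_l, v_l = table.lookup(light)
    p_h, v_h = table.lookup(heavy)
    if v_h == v_l:
        raise DomainError(
            f"degenerate readings: equal indentation volumes ({v_l} mm^3) at both weights"
        )
    e = (np.log10(p_h) - np.log10(p_l)) / (v_h - v_l)
    return RigidityCoefficient(name=f"schiotz_{light.weight_g:g}g_{heavy.weight_g:g}g", value=float(e))


def mean_rigidity(values: Iterable[RigidityCoefficient], name: str = "mean") -> RigidityCoefficient:
    """Arithmetic mean of per-eye rigidity estimates."""
    vals = [v.value for v in values]
    if not vals:
        raise ValueError("cannot average an empty list of rigidity coefficients")
    return RigidityCoefficient(name=name, value=float(np.mean(vals)))
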