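"""File I/O, configuration, packaged study fixture, and the full pipeline.

Trip CSV dialect (UTF-8, comma-separated, one row per station)::

    eye_id,phase,altitude_m,iop_applanation_mmhg,iop_indentation_mmhg,temperature_c

The packaged fixture holds the six-eye rabbit road-trip dataset (nine
stations per eye, both tonometry channels) together with each eye's
surgical/tamponade configuration and the rigidity-coefficient config
(rabbit mean plus the four published human coefficients).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from os import PathLike
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import RigidityCoefficient
from .extrapolation import extrapolation_table
from .regression import (
    EyeConfig,
    TripMeasurement,
    TripSeries,
    classify_significance,
    fit_iop_altitude,
    method_agreement,
)

__all__ = [
    "TRIP_COLUMNS",
    "DataError",
    "ConfigError",
    "read_trip_csv",
    "write_trip_csv",
    "load_rigidity_coefficients",
    "load_eye_configs",
    "load_rabbit_trip",
    "AnalysisConfig",
    "PipelineReport",
    "run_pipeline",
]

logger = logging.getLogger("altiop")

TRIP_COLUMNS = (
    "eye_id",
    "phase",
    "altitude_m",
    "iop_applanation_mmhg",
    "iop_indentation_mmhg",
    "temperature_c",
)

PathArg = Union[str, PathLike]


class DataError(ValueError):
    """Malformed or physically impossible input data."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


def _data_path(name: str):
    return files("altiop.data").joinpath(name)


def _optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_trip_csv(path: PathArg, eye_configs: Optional[dict[str, EyeConfig]] = None) -> list[TripSeries]:
    """Parse a trip CSV into one :class:`TripSeries` per eye.

    Series are grouped by ``eye_id`` in order of first appearance; station
    order within an eye is preserved.  Malformed rows raise
    :class:`DataError` naming the offending line number.  An empty or
    header-only file yields an empty list (with a warning for the former).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trip file, no series read", stacklevel=2)
        return []
    missing = [c for c in TRIP_COLUMNS if c not in frame.columns and c != "temperature_c"]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    if "temperature_c" not in frame.columns:
        frame["temperature_c"] = np.nan

    series_map: dict[str, list[TripMeasurement]] = {}
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            m = TripMeasurement(
                altitude_m=float(row["altitude_m"]),
                iop_applanation=_optional(row["iop_applanation_mmhg"]),
                iop_indentation=_optional(row["iop_indentation_mmhg"]),
                phase=str(row["phase"]),
                temperature_c=_optional(row["temperature_c"]),
            )
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path}: line {line}: {exc}") from exc
        if m.phase not in ("ascent", "descent"):
            raise DataError(f"{path}: line {line}: phase must be ascent|descent, got {m.phase!r}")
        series_map.setdefault(str(row["eye_id"]), []).append(m)

    eye_configs = eye_configs or {}
    return [
        TripSeries(eye=eye_configs.get(eye_id, EyeConfig(eye_id=eye_id)), measurements=tuple(ms))
        for eye_id, ms in series_map.items()
    ]


def write_trip_csv(all_series: Sequence[TripSeries], path: PathArg) -> None:
    """Write series to the trip CSV dialect (inverse of :func:`read_trip_csv`)."""
    rows = [
        {
            "eye_id": s.eye_id,
            "phase": m.phase,
            "altitude_m": m.altitude_m,
            "iop_applanation_mmhg": m.iop_applanation,
            "iop_indentation_mmhg": m.iop_indentation,
            "temperature_c": m.temperature_c,
        }
        for s in all_series
        for m in s.measurements
    ]
    pd.DataFrame(rows, columns=list(TRIP_COLUMNS)).to_csv(path, index=False)


def load_rigidity_coefficients(path: Optional[PathArg] = None) -> dict[str, RigidityCoefficient]:
    """Named rigidity coefficients from JSON (packaged config by default).

    The packaged config holds the study's rabbit mean (0.01811667) and the
    published human coefficients: Friedenwald 0.0215, Pallikaris 0.0126,
    Dastiridou mean 0.0224, Dastiridou max 0.0343.
    """
    text = _data_path("rigidity_coefficients.json").read_text() if path is None else open(path).read()
    raw = json.loads(text)
    return {name: RigidityCoefficient(name=name, value=float(v)) for name, v in raw.items()}


def load_eye_configs() -> dict[str, EyeConfig]:
    """The six study eyes' surgical and tamponade configurations."""
    frame = pd.read_csv(_data_path("eye_config.csv"))
    configs = {}
    for _, row in frame.iterrows():
        configs[row["eye_id"]] = EyeConfig(
            eye_id=row["eye_id"],
            vitrectomized=bool(row["vitrectomized"]),
            tamponade=row["tamponade"],
            fill_fraction=_optional(row["fill_fraction"]),
            injected_volume_cc=_optional(row["injected_volume_cc"]),
        )
    return configs


def load_rabbit_trip() -> list[TripSeries]:
    """The packaged six-eye rabbit road-trip dataset (nine stations each)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return read_trip_csv(_data_path("rabbit_trip.csv"), eye_configs=load_eye_configs())


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end pipeline configuration."""

    rabbit_rigidity: RigidityCoefficient
    human_coefficients: tuple[RigidityCoefficient, ...]
    ci_level: float = 0.95
    method: str = "applanation"
    point_policy: str = "all"  # or "ascent_only"
    benchmark_eye: str = "SF6_100"

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.method not in ("applanation", "indentation"):
            raise ConfigError(f"method must be applanation|indentation, got {self.method!r}")
        if self.point_policy not in ("all", "ascent_only"):
            raise ConfigError(f"point_policy must be all|ascent_only, got {self.point_policy!r}")

    @classmethod
    def default(cls, **overrides) -> "AnalysisConfig":
        coeffs = load_rigidity_coefficients()
        humans = tuple(
            coeffs[name] for name in ("friedenwald", "pallikaris", "dastiridou_mean", "dastiridou_max")
        )
        kwargs = dict(rabbit_rigidity=coeffs["rabbit_mean"], human_coefficients=humans)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: PathArg) -> "AnalysisConfig":
        raw = json.loads(open(path).read())
        try:
            rabbit = RigidityCoefficient("rabbit_mean", float(raw["rabbit_rigidity"]))
            humans = tuple(
                RigidityCoefficient(name, float(v)) for name, v in raw["human_coefficients"].items()
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        return cls(
            rabbit_rigidity=rabbit,
            human_coefficients=humans,
            ci_level=float(raw.get("ci_level", 0.95)),
            method=raw.get("method", "applanation"),
            point_policy=raw.get("point_policy", "all"),
            benchmark_eye=raw.get("benchmark_eye", "SF6_100"),
        )


@dataclass(frozen=True)
class PipelineReport:
    """Outputs of the full pipeline: source-species fits, tonometry
    agreement, and the human extrapolation table."""

    rabbit_fits: pd.DataFrame
    agreement: pd.DataFrame
    extrapolation: pd.DataFrame


def run_pipeline(config: AnalysisConfig, trips: Sequence[TripSeries]) -> PipelineReport:
    """Deterministic composition of the regression and extrapolation stages.

    Stage 1 fits each eye's altitude regression and classifies significance
    against the benchmark eye; stage 2 computes tonometry method agreement
    per eye; stage 3 transforms every eye under every configured human
    coefficient and refits.
    """
    if not trips:
        raise DataError("no trip series provided")
    ids = [s.eye_id for s in trips]
    if config.benchmark_eye not in ids:
        raise ConfigError(f"benchmark eye {config.benchmark_eye!r} not in data ({ids})")
    ascent_only = config.point_policy == "ascent_only"
    logger.info(
        "fitting %d eyes (method=%s, point_policy=%s, ci=%.2f)",
        len(trips), config.method, config.point_policy, config.ci_level,
    )

    fits = {
        s.eye_id: fit_iop_altitude(s, config.method, config.ci_level, ascent_only) for s in trips
    }
    bench = fits[config.benchmark_eye]
    rabbit_rows = [
        {
            "case": eid,
            "intercept": f.intercept,
            "slope_per_100m": f.slope,
            "ci_low": f.ci95[0],
            "ci_high": f.ci95[1],
            "r_squared": f.r_squared,
            "significance": "" if eid == config.benchmark_eye else classify_significance(f, bench),
        }
        for eid, f in fits.items()
    ]

    logger.info("computing tonometry method agreement")
    agreement_rows = []
    for s in trips:
        a = method_agreement(s)
        agreement_rows.append(
            {
                "case": s.eye_id,
                "wilcoxon_p": a.wilcoxon_p,
                "pearson_r": a.pearson_r,
                "spearman_rho": a.spearman_rho,
                "r_squared": a.r_squared,
                "all_differences_zero": a.all_differences_zero,
            }
        )

    logger.info(
        "extrapolating with %d human coefficients against benchmark %s",
        len(config.human_coefficients), config.benchmark_eye,
    )
    extra = extrapolation_table(
        list(trips),
        config.rabbit_rigidity,
        list(config.human_coefficients),
        config.benchmark_eye,
        method=config.method,
        ci_level=config.ci_level,
        ascent_only=ascent_only,
    )
    return PipelineReport(
        rabbit_fits=pd.DataFrame(rabbit_rows),
        agreement=pd.DataFrame(agreement_rows),
        extrapolation=extra,
    )
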