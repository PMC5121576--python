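"""Friedenwald pressure-volume relations and cross-species pressure extrapolation.

Friedenwald's model of the ocular wall states that a change in intraocular
volume produces a proportional change in the *logarithm* of intraocular
pressure, the proportionality constant being the scleral (ocular) rigidity::

    E = (log10 P2 - log10 P1) / (V2 - V1)

``E`` is constant for a given eye (above ~5 mmHg) and has units of
log10(mmHg) per mm^3.  A stiffer globe (larger ``E``) shows a larger
pressure excursion for the same volume change.

Because the volume change is the species-independent quantity (an expanding
gas bubble displaces the same volume whatever the globe around it), a
pressure excursion measured in one eye can be translated to another eye of
different rigidity: divide the log-pressure change by the source rigidity to
get the volume change, multiply by the target rigidity to get the target
log-pressure change, and exponentiate back to a pressure ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Union

__all__ = [
    "DomainError",
    "RigidityCoefficient",
    "PressurePair",
    "delta_log_pressure",
    "volume_change",
    "log_change_from_volume",
    "pressure_ratio",
    "extrapolate_pressure",
]


class DomainError(ValueError):
    """A quantity lies outside the model's domain (e.g. non-positive pressure)."""


@dataclass(frozen=True)
class RigidityCoefficient:
    """A named scleral rigidity constant, in log10(mmHg) per mm^3.

    Parameters
    ----------
    name
        Identifier, e.g. ``"friedenwald"`` (human average, 0.0215) or
        ``"rabbit_mean"``.
    value
        The rigidity E.  Must be finite and strictly positive.
    """

    name: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= 0:
            raise DomainError(
                f"rigidity coefficient {self.name!r} must be finite and > 0, "
                f"got {self.value!r}"
            )


class PressurePair(NamedTuple):
    """A (baseline, elevated) pair of intraocular pressures in mmHg."""

    p1: float
    p2: float


CoefficientLike = Union[RigidityCoefficient, float]


def _rigidity_value(e: CoefficientLike) -> float:
    if isinstance(e, RigidityCoefficient):
        return e.value
    e = float(e)
    if not math.isfinite(e) or e <= 0:
        raise DomainError(f"rigidity must be finite and > 0, got {e!r}")
    return e


def _check_pressure(p: float, label: str) -> float:
    p = float(p)
    if not math.isfinite(p) or p <= 0:
        raise DomainError(f"pressure {label}={p!r} must be finite and > 0 mmHg")
    return p


def delta_log_pressure(p1: float, p2: float) -> float:
    """Log10 pressure change ``log10(p2) - log10(p1)``.

    Antisymmetric under swapping the two pressures.  Raises
    :class:`DomainError` if either pressure is non-positive (the logarithm
    would be undefined).
    """
    p1 = _check_pressure(p1, "p1")
    p2 = _check_pressure(p2, "p2")
    return math.log10(p2) - math.log10(p1)


def volume_change(dlog: float, e: CoefficientLike) -> float:
    """Intraocular volume change (mm^3) producing a log10-pressure change.

    Inverts the rigidity relation: ``delta_v = dlog / E``.
    """
    return float(dlog) / _rigidity_value(e)


def log_change_from_volume(dv: float, e: CoefficientLike) -> float:
    """Log10-pressure change produced by a volume change: ``dv * E``.

    Exact algebraic inverse of :func:`volume_change` at the same coefficient.
    """
    return float(dv) * _rigidity_value(e)


def pressure_ratio(dlog: float) -> float:
    """The pressure ratio ``P2/P1 = 10**dlog`` for a log10-pressure change."""
    dlog = float(dlog)
    if not math.isfinite(dlog):
        raise DomainError(f"log-pressure change must be finite, got {dlog!r}")
    return 10.0 ** dlog


def extrapolate_pressure(
    source: PressurePair | tuple[float, float],
    e_source: CoefficientLike,
    e_target: CoefficientLike,
    p1_target: float,
) -> float:
    """Translate a pressure excursion from one eye to another eye.

    The excursion ``source.p1 -> source.p2`` measured in an eye of rigidity
    ``e_source`` is assumed to be caused by a volume change; the same volume
    change applied to an eye of rigidity ``e_target`` starting at
    ``p1_target`` gives the returned pressure::

        p1_target * 10**(e_target * (log10(p2/p1) / e_source))

    With equal rigidities and ``p1_target = source.p1`` this is the identity
    transform.
    """
    p1, p2 = source
    dlog = delta_log_pressure(p1, p2)
    dv = volume_change(dlog, e_source)
    dlog_target = log_change_from_volume(dv, e_target)
    return _check_pressure(p1_target, "p1_target") * pressure_ratio(dlog_target)
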