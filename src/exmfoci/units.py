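"""Physical-unit bookkeeping and expansion-factor arithmetic.

Expansion microscopy enlarges a specimen by a linear factor *s*; areas grow
as *s*² and volumes as *s*³.  Every measurement made on a post-expansion
image must therefore be divided by *s* before it can be compared with a
pre-expansion (native-scale) quantity.  This module holds the two tiny value
types used throughout the package — :class:`ExpansionFactor` and
:class:`PhysicalLength` — together with the conversions between them.

Conventions
-----------
* All internal coordinates and lengths are stored in **nanometres**;
  micrometres appear only at I/O boundaries.
* A :class:`PhysicalLength` carries the reference frame it was measured in
  (``pre_expansion`` or ``post_expansion``); mixing frames raises
  :class:`FrameMismatchError` instead of silently producing a wrong number.
* The default linear factor used for reporting pre-expansion equivalents is
  4.0 (the macroscale gel expansion), configurable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "ExmError",
    "FrameMismatchError",
    "ExpansionFactor",
    "PhysicalLength",
    "linear_factor_from_area_ratio",
    "linear_factor_from_volume_ratio",
    "to_pre_expansion",
    "to_post_expansion",
    "round_half_up",
]

NM_PER_UM = 1000.0

Frame = Literal["pre_expansion", "post_expansion"]
Unit = Literal["nm", "um"]


class ExmError(Exception):
    """Base class for all errors raised by this package."""


class FrameMismatchError(ExmError):
    """A length was supplied in the wrong expansion frame."""


@dataclass(frozen=True)
class ExpansionFactor:
    """Linear expansion factor with a record of how it was obtained.

    Parameters
    ----------
    linear_factor:
        Dimensionless linear scale of expansion (> 0).
    method:
        How the factor was derived: ``"area"`` (square root of an area
        ratio), ``"volume"`` (cube root of a volume ratio), ``"macro"``
        (macroscale gel measurement) or ``"assumed"``.
    raw_ratio:
        The area or volume ratio the factor was extracted from, stored for
        audit; ``None`` for macro/assumed factors.
    provenance:
        Free-text note on the source of the value.
    """

    linear_factor: float
    method: Literal["area", "volume", "macro", "assumed"] = "assumed"
    raw_ratio: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.linear_factor > 0) or not math.isfinite(self.linear_factor):
            raise ValueError(
                f"linear_factor must be a positive finite number, got {self.linear_factor!r}"
            )
        if self.raw_ratio is not None:
            exponent = {"area": 2, "volume": 3}.get(self.method)
            if exponent is not None:
                recomputed = self.raw_ratio ** (1.0 / exponent)
                if not math.isclose(recomputed, self.linear_factor, rel_tol=1e-9):
                    raise ValueError(
                        f"linear_factor {self.linear_factor} inconsistent with "
                        f"{self.method} ratio {self.raw_ratio}"
                    )


@dataclass(frozen=True)
class PhysicalLength:
    """A non-negative length with unit and expansion frame."""

    value: float
    unit: Unit = "nm"
    frame: Frame = "post_expansion"

    def __post_init__(self) -> None:
        if self.value < 0 or not math.isfinite(self.value):
            raise ValueError(f"length must be non-negative and finite, got {self.value!r}")
        if self.unit not in ("nm", "um"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.frame not in ("pre_expansion", "post_expansion"):
            raise ValueError(f"unknown frame {self.frame!r}")

    def in_nm(self) -> "PhysicalLength":
        if self.unit == "nm":
            return self
        return PhysicalLength(self.value * NM_PER_UM, "nm", self.frame)

    def in_um(self) -> "PhysicalLength":
        if self.unit == "um":
            return self
        return PhysicalLength(self.value / NM_PER_UM, "um", self.frame)


def linear_factor_from_area_ratio(area_ratio: float, provenance: str = "") -> ExpansionFactor:
    """Linear expansion factor implied by a post/pre nuclear **area** ratio.

    A 16-fold area increase corresponds to a linear factor of 4.
    """
    if not (area_ratio > 0) or not math.isfinite(area_ratio):
        raise ValueError(f"area_ratio must be positive and finite, got {area_ratio!r}")
    return ExpansionFactor(
        linear_factor=math.sqrt(area_ratio),
        method="area",
        raw_ratio=float(area_ratio),
        provenance=provenance,
    )


def linear_factor_from_volume_ratio(volume_ratio: float, provenance: str = "") -> ExpansionFactor:
    """Linear expansion factor implied by a post/pre nuclear **volume** ratio.

    A 52-fold volume increase corresponds to a linear factor of ~3.7.
    """
    if not (volume_ratio > 0) or not math.isfinite(volume_ratio):
        raise ValueError(f"volume_ratio must be positive and finite, got {volume_ratio!r}")
    return ExpansionFactor(
        linear_factor=volume_ratio ** (1.0 / 3.0),
        method="volume",
        raw_ratio=float(volume_ratio),
        provenance=provenance,
    )


def _factor_value(factor: ExpansionFactor | float) -> float:
    value = factor.linear_factor if isinstance(factor, ExpansionFactor) else float(factor)
    if not (value > 0):
        raise ValueError(f"expansion factor must be positive, got {value!r}")
    return value


def to_pre_expansion(length: PhysicalLength, factor: ExpansionFactor | float) -> PhysicalLength:
    """Convert a post-expansion length to its pre-expansion equivalent.

    The value is divided by the linear factor; the unit is preserved and the
    frame is flipped.  Raises :class:`FrameMismatchError` if ``length`` is
    already in the pre-expansion frame.
    """
    if length.frame != "post_expansion":
        raise FrameMismatchError(
            f"expected a post_expansion length, got frame {length.frame!r}"
        )
    return PhysicalLength(length.value / _factor_value(factor), length.unit, "pre_expansion")


def to_post_expansion(length: PhysicalLength, factor: ExpansionFactor | float) -> PhysicalLength:
    """Inverse of :func:`to_pre_expansion`: multiply by the linear factor."""
    if length.frame != "pre_expansion":
        raise FrameMismatchError(
            f"expected a pre_expansion length, got frame {length.frame!r}"
        )
    return PhysicalLength(length.value * _factor_value(factor), length.unit, "post_expansion")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as printed report tables do.

    Applied only when formatting output, never inside computations.
    """
    scale = 10.0 ** decimals
    return math.floor(abs(value) * scale + 0.5) / scale * (1 if value >= 0 else -1)
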