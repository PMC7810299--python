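"""Shared domain types, section geometry and error metrics.

Heights are measured from the fixed (clamped) end of the cantilever and
increase toward the free end.  Azimuths (load direction ``D`` and gauge
position ``theta_g``) are degrees from an arbitrary baseline, stored in
``[0, 360)``.  Units at the API boundary are the field's conventional ones —
microstrain (με), GPa, metres, newtons, degrees — and are converted to
coherent SI exactly once, inside the moment/strain conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAUGE_IDS",
    "TrunkloadError",
    "InvalidGeometryError",
    "UndefinedMetricError",
    "CalibrationError",
    "NoLoadError",
    "IllConditionedError",
    "ProtocolError",
    "SpecimenGeometry",
    "GaugeCalibration",
    "StrainQuartet",
    "LoadState",
    "LoadScenario",
    "section_modulus",
    "error_pct",
    "error_deg",
    "wrap_deg",
]

#: Canonical gauge names: t/b = upper/lower height, d1/d2 = radial positions.
GAUGE_IDS = ("td1", "td2", "bd1", "bd2")


class TrunkloadError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(TrunkloadError):
    """Specimen geometry violates its invariants."""


class UndefinedMetricError(TrunkloadError):
    """An error metric was requested where it is undefined (known value 0)."""


class CalibrationError(TrunkloadError):
    """A gauge calibration fit failed or is underdetermined."""


class NoLoadError(TrunkloadError):
    """Direction of force requested with no measurable load."""


class IllConditionedError(TrunkloadError):
    """Moment inversion attempted with every gauge near its neutral axis."""


class ProtocolError(TrunkloadError):
    """A pulling-test protocol parameter is physically inconsistent."""


def wrap_deg(angle: float) -> float:
    """Wrap an angle in degrees to ``[0, 360)``."""
    return float(angle) % 360.0


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cantilever specimen with two gauge heights.

    Parameters
    ----------
    h_t, h_b : float
        Heights of the upper (t) and lower (b) gauge pairs above the fixed
        end (m); ``H > h_t > h_b >= 0``.
    H : float
        Specimen length/height (m).
    d_t, d_b : float
        Trunk diameter at ``h_t`` and ``h_b`` (m).  A non-tapered specimen
        simply uses ``d_t == d_b``.
    """

    h_t: float
    h_b: float
    H: float
    d_t: float
    d_b: float

    def __post_init__(self) -> None:
        if not (self.H > self.h_t > self.h_b >= 0.0):
            raise InvalidGeometryError(
                f"need H > h_t > h_b >= 0, got H={self.H}, h_t={self.h_t}, h_b={self.h_b}"
            )
        if self.d_t <= 0.0 or self.d_b <= 0.0:
            raise InvalidGeometryError("diameters must be positive")

    @property
    def Z_t(self) -> float:
        """Section modulus at the upper gauge height (m³)."""
        return section_modulus(self.d_t)

    @property
    def Z_b(self) -> float:
        """Section modulus at the lower gauge height (m³)."""
        return section_modulus(self.d_b)

    def gauge_height(self, gauge_id: str) -> float:
        return self.h_t if gauge_id.startswith("t") else self.h_b

    def gauge_Z(self, gauge_id: str) -> float:
        return self.Z_t if gauge_id.startswith("t") else self.Z_b


@dataclass(frozen=True)
class GaugeCalibration:
    """Per-gauge parameters recovered by the pulling-test calibration.

    ``E`` is the *apparent* modulus of elasticity (GPa): it absorbs local
    material heterogeneity and the gauge factor, which is why it is fitted
    per gauge rather than assumed for the specimen.  ``theta_g`` is the
    gauge's radial position from baseline (degrees).
    """

    gauge_id: str
    E: float
    theta_g: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.gauge_id not in GAUGE_IDS:
            raise ValueError(f"unknown gauge_id {self.gauge_id!r}")
        if not (self.E > 0.0 and math.isfinite(self.E)):
            raise CalibrationError(f"{self.gauge_id}: E must be positive/finite, got {self.E}")
        object.__setattr__(self, "theta_g", wrap_deg(self.theta_g))
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise CalibrationError(f"{self.gauge_id}: r_squared {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class StrainQuartet:
    """One synchronous reading of the four gauges (με, tension positive)."""

    eps_td1: float
    eps_td2: float
    eps_bd1: float
    eps_bd2: float
    time: float | None = None

    def __post_init__(self) -> None:
        for name in ("eps_td1", "eps_td2", "eps_bd1", "eps_bd2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    def eps(self, gauge_id: str) -> float:
        return getattr(self, f"eps_{gauge_id}")


@dataclass(frozen=True)
class LoadState:
    """Estimator output: force amount, centroid, directions and moments.

    ``F`` (N) is reported non-negative with the sign folded into the
    directions; ``C`` (m) shares the height datum of the geometry; ``D_t``
    and ``D_b`` are the directions estimated independently at the two
    heights and are deliberately *not* merged.  Fields that could not be
    computed for a sample are NaN with a reason in ``flags``.
    """

    F: float
    C: float
    D_t: float
    D_b: float
    M_t: float
    M_b: float
    flags: tuple[str, ...] = field(default=())

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class LoadScenario:
    """Ground-truth load: point loads along the trunk plus one azimuth.

    A continuous force profile f(h) is represented as a discrete set of
    point loads ``(height above the fixed end (m), magnitude (N))``; dense
    point sets approximate continuous profiles arbitrarily well.
    """

    loads: tuple[tuple[float, float], ...]
    direction: float
    label: str = ""

    def __init__(self, loads, direction: float, label: str = ""):
        object.__setattr__(self, "loads", tuple((float(h), float(m)) for h, m in loads))
        object.__setattr__(self, "direction", wrap_deg(direction))
        object.__setattr__(self, "label", label)
        for h, m in self.loads:
            if m < 0.0:
                raise ValueError(f"load magnitude {m} < 0")
            if h < 0.0:
                raise ValueError(f"load height {h} < 0")

    @property
    def total_force(self) -> float:
        """Σ magnitudes (N) — the ground-truth F."""
        return sum(m for _, m in self.loads)

    def centroid(self) -> float:
        """Force-weighted mean height (m) — the ground-truth C."""
        F = self.total_force
        if F == 0.0:
            raise NoLoadError("centroid undefined for a zero total load")
        return sum(h * m for h, m in self.loads) / F


def section_modulus(diameter: float) -> float:
    """Section modulus Z = π·d³/32 of a solid circular cross-section (m³).

    Relates the bending moment M at a cross-section to the extreme-fiber
    stress σ = M/Z.
    """
    if diameter <= 0.0:
        raise InvalidGeometryError(f"diameter must be positive, got {diameter}")
    return math.pi * diameter**3 / 32.0


def error_pct(known: float, estimated: float) -> float:
    """Relative estimation error |1 − estimated/known| × 100 (%)."""
    if known == 0.0:
        raise UndefinedMetricError("error_pct undefined for known == 0")
    return abs(1.0 - estimated / known) * 100.0


def error_deg(known: float, estimated: float) -> float:
    """Absolute angular separation in degrees, wrapped to ``[0, 180]``.

    The plain difference would report 358° for (359°, 1°); circumferential
    loading makes wrap-around unavoidable, so the metric takes the shorter
    arc.
    """
    d = abs(known - estimated) % 360.0
    return 360.0 - d if d > 180.0 else d
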