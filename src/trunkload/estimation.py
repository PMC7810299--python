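"""Invert strain readings into force amount, centroid and direction.

Given one :class:`~trunkload.core.StrainQuartet`, calibrated per-gauge
parameters and the specimen geometry:

1. the direction of force is estimated at each height from the ratio of the
   two same-height gauge responses (an arctangent whose 180° ambiguity is
   resolved from the observed strain signs);
2. the bending moment at each height is recovered by least squares over the
   same-height gauges, using that height's direction estimate;
3. the force amount F = (M_b − M_t)/(h_t − h_b) and the centroid
   C = M_t·(h_t − h_b)/(M_b − M_t) + h_t follow from the two moments.

Three degraded parameter assignments (assuming a right angle between d1 and
d2, a common averaged E, or both) are provided as baselines to quantify what
the per-gauge calibration buys.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    GAUGE_IDS,
    CalibrationError,
    GaugeCalibration,
    IllConditionedError,
    InvalidGeometryError,
    LoadState,
    NoLoadError,
    SpecimenGeometry,
    StrainQuartet,
    wrap_deg,
)

__all__ = [
    "AssignmentMode",
    "COS_FLOOR",
    "direction",
    "moment_at_height",
    "force_amount",
    "force_centroid",
    "apply_assignment",
    "estimate_state",
    "estimate_series",
]

#: Conditioning floor on |cos(D − θ_g)|: a gauge closer than this to its
#: neutral axis is dropped from the moment combination.
COS_FLOOR = 1e-6


class AssignmentMode(str, Enum):
    """Which calibration parameters the estimator is allowed to use."""

    FULL = "full"
    RIGHT_ANGLE = "right_angle"
    COMMON_E = "common_E"
    RIGHT_ANGLE_COMMON_E = "right_angle_common_E"


def _y_Nm(eps_ue: float, E_gpa: float, Z: float) -> float:
    # gauge response as an equivalent moment: ε·E·Z in coherent SI
    return eps_ue * 1e-6 * E_gpa * 1e9 * Z


def direction(
    eps_d1: float,
    eps_d2: float,
    cal_d1: GaugeCalibration,
    cal_d2: GaugeCalibration,
    Z_d1: float,
    Z_d2: float,
) -> float:
    """Direction of force (degrees in [0, 360)) from two same-height gauges.

    tan D = (y₁ cos θ₂ − y₂ cos θ₁) / (y₂ sin θ₁ − y₁ sin θ₂) with
    y_i = ε_i·E_i·Z_i.  The bare arctangent cannot tell D from D + 180°;
    of the two candidates we keep the one whose predicted strain signs
    (ε_i ∝ −cos(D − θ_g,i)) match the observed signs, trusting the gauge
    with the larger |cos(D − θ_g,i)| — the one farther from its neutral
    axis — first.
    """
    if eps_d1 == 0.0 and eps_d2 == 0.0:
        raise NoLoadError("both strains zero: direction of force undefined")
    th1, th2 = math.radians(cal_d1.theta_g), math.radians(cal_d2.theta_g)
    if abs(math.sin(th1 - th2)) < COS_FLOOR:
        raise IllConditionedError(
            "gauges d1/d2 are (anti)parallel: direction unidentifiable"
        )
    y1 = _y_Nm(eps_d1, cal_d1.E, Z_d1)
    y2 = _y_Nm(eps_d2, cal_d2.E, Z_d2)
    num = y1 * math.cos(th2) - y2 * math.cos(th1)
    den = y2 * math.sin(th1) - y1 * math.sin(th2)
    if abs(num) < 1e-300 and abs(den) < 1e-300:
        raise IllConditionedError("direction numerator and denominator both vanish")
    D = math.atan2(num, den)  # D or D + π
    # sign check against the candidate's predicted compression pattern
    eps = (eps_d1, eps_d2)
    for cand in (D, D + math.pi):
        c = (-math.cos(cand - th1), -math.cos(cand - th2))
        order = sorted((0, 1), key=lambda i: abs(c[i]), reverse=True)
        for i in order:
            if eps[i] != 0.0 and abs(c[i]) >= COS_FLOOR:
                match = (eps[i] > 0) == (c[i] > 0)
                break
        else:
            match = True
        if match:
            return wrap_deg(math.degrees(cand))
    # both candidates rejected: inconsistent signs, keep the raw branch
    return wrap_deg(math.degrees(D))


def moment_at_height(
    eps_d1: float,
    eps_d2: float,
    cal_d1: GaugeCalibration,
    cal_d2: GaugeCalibration,
    Z_d1: float,
    Z_d2: float,
    D: float,
) -> float:
    """Bending moment magnitude (N·m) at one height, given the direction.

    Both same-height gauges are combined by least squares: with
    y_i = ε_i·E_i·Z_i and c_i = −cos(D − θ_g,i), M̂ = Σ y_i c_i / Σ c_i².
    This is optimal under i.i.d. strain noise and reduces to single-gauge
    inversion when the other gauge sits on its neutral axis.
    """
    Drad = math.radians(D)
    num = 0.0
    den = 0.0
    for eps, cal, Z in ((eps_d1, cal_d1, Z_d1), (eps_d2, cal_d2, Z_d2)):
        c = -math.cos(Drad - math.radians(cal.theta_g))
        if abs(c) < COS_FLOOR:
            continue
        num += _y_Nm(eps, cal.E, Z) * c
        den += c * c
    if den == 0.0:
        raise IllConditionedError("both gauges on their neutral axes for this direction")
    return num / den


def force_amount(M_t: float, M_b: float, h_t: float, h_b: float) -> float:
    """Force amount F = (M_b − M_t)/(h_t − h_b) (N).

    The moments must be signed consistently (same direction datum) before
    differencing; assumes no load acts below h_t.
    """
    if h_t <= h_b:
        raise InvalidGeometryError(f"need h_t > h_b, got h_t={h_t}, h_b={h_b}")
    return (M_b - M_t) / (h_t - h_b)


def force_centroid(M_t: float, M_b: float, h_t: float, h_b: float) -> float:
    """Centroid height C = M_t·(h_t − h_b)/(M_b − M_t) + h_t (m)."""
    if h_t <= h_b:
        raise InvalidGeometryError(f"need h_t > h_b, got h_t={h_t}, h_b={h_b}")
    if M_b == M_t:
        raise NoLoadError("M_b == M_t: zero net force, centroid undefined")
    return M_t * (h_t - h_b) / (M_b - M_t) + h_t


def apply_assignment(
    cals: Mapping[str, GaugeCalibration], mode: AssignmentMode | str
) -> dict[str, GaugeCalibration]:
    """Transform calibrations to a degraded parameter assignment.

    ``right_angle`` keeps each d1 gauge as the reference and forces
    θ_g,d2 = θ_g,d1 + 90° at each height; ``common_E`` replaces every E by
    the four-gauge arithmetic mean; the combined mode does both; ``full``
    is the identity.
    """
    mode = AssignmentMode(mode)
    out = {g: cals[g] for g in GAUGE_IDS}
    if mode in (AssignmentMode.COMMON_E, AssignmentMode.RIGHT_ANGLE_COMMON_E):
        E_bar = sum(out[g].E for g in GAUGE_IDS) / 4.0
        out = {
            g: GaugeCalibration(g, E_bar, c.theta_g, c.r_squared)
            for g, c in out.items()
        }
    if mode in (AssignmentMode.RIGHT_ANGLE, AssignmentMode.RIGHT_ANGLE_COMMON_E):
        for d1, d2 in (("td1", "td2"), ("bd1", "bd2")):
            c2 = out[d2]
            out[d2] = GaugeCalibration(
                d2, c2.E, wrap_deg(out[d1].theta_g + 90.0), c2.r_squared
            )
    return out


def estimate_state(
    q: StrainQuartet,
    cals: Mapping[str, GaugeCalibration],
    geom: SpecimenGeometry,
    mode: AssignmentMode | str = AssignmentMode.FULL,
) -> LoadState:
    """Full inversion of one strain quartet into a :class:`LoadState`.

    D_t is estimated from (td1, td2) and used for M_t; D_b from (bd1, bd2)
    for M_b; F and C follow from the moment difference.  Failures that only
    affect part of the result (e.g. zero load ⇒ undefined direction and
    centroid) produce NaN fields plus a flag instead of an exception, so a
    time series never aborts on a quiet sample.
    """
    missing = [g for g in GAUGE_IDS if g not in cals]
    if missing:
        raise CalibrationError(f"missing calibration for gauge(s): {', '.join(missing)}")
    cals = apply_assignment(cals, mode)
    nan = float("nan")
    flags: list[str] = []

    if all(q.eps(g) == 0.0 for g in GAUGE_IDS):
        return LoadState(F=0.0, C=nan, D_t=nan, D_b=nan, M_t=0.0, M_b=0.0,
                         flags=("no_load",))

    def height_pass(d1: str, d2: str, Z: float) -> tuple[float, float]:
        if q.eps(d1) == 0.0 and q.eps(d2) == 0.0:
            # no bending at this height: the moment is known (zero) even
            # though the direction is not
            flags.append(f"{d1[0]}:no_direction")
            return nan, 0.0
        try:
            D = direction(q.eps(d1), q.eps(d2), cals[d1], cals[d2], Z, Z)
        except (NoLoadError, IllConditionedError) as exc:
            flags.append(f"{d1[0]}:{type(exc).__name__}")
            return nan, nan
        try:
            M = moment_at_height(q.eps(d1), q.eps(d2), cals[d1], cals[d2], Z, Z, D)
        except IllConditionedError as exc:
            flags.append(f"{d1[0]}:{type(exc).__name__}")
            return D, nan
        if M < 0.0:  # fold sign into the direction
            M, D = -M, wrap_deg(D + 180.0)
        return D, M

    D_t, M_t = height_pass("td1", "td2", geom.Z_t)
    D_b, M_b = height_pass("bd1", "bd2", geom.Z_b)

    if math.isnan(M_t) or math.isnan(M_b):
        return LoadState(F=nan, C=nan, D_t=D_t, D_b=D_b, M_t=M_t, M_b=M_b,
                         flags=tuple(flags))

    # Moments are magnitudes along their own direction estimates; D_t and D_b
    # agree for a single-direction load, so the scalar difference is valid.
    F = force_amount(M_t, M_b, geom.h_t, geom.h_b)
    try:
        C = force_centroid(M_t, M_b, geom.h_t, geom.h_b)
    except NoLoadError:
        C = nan
        flags.append("centroid_undefined")
    return LoadState(F=F, C=C, D_t=D_t, D_b=D_b, M_t=M_t, M_b=M_b, flags=tuple(flags))


def estimate_series(
    quartets: Iterable[StrainQuartet],
    cals: Mapping[str, GaugeCalibration],
    geom: SpecimenGeometry,
    mode: AssignmentMode | str = AssignmentMode.FULL,
) -> pd.DataFrame:
    """Per-sample estimation over a strain time series.

    No smoothing is applied — the estimator works on instantaneous values
    and leaves filtering to the caller.  Returns a DataFrame with columns
    time_s, F_N, C_m, C_minus_ht_m, D_t_deg, D_b_deg, M_t_Nm, M_b_Nm, flags.
    """
    rows = []
    for q in quartets:
        s = estimate_state(q, cals, geom, mode)
        rows.append(
            {
                "time_s": q.time,
                "F_N": s.F,
                "C_m": s.C,
                "C_minus_ht_m": s.C - geom.h_t,
                "D_t_deg": s.D_t,
                "D_b_deg": s.D_b,
                "M_t_Nm": s.M_t,
                "M_b_Nm": s.M_b,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "time_s", "F_N", "C_m", "C_minus_ht_m",
            "D_t_deg", "D_b_deg", "M_t_Nm", "M_b_Nm", "flags",
        ],
    )
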