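"""Pulling-test calibration: recover each gauge's E and radial position.

A known point load pulled from a known azimuth ``D`` applies a known bending
moment ``|M|`` at a gauge's height.  The normalised gauge response

    y(D) = ε·Z / |M| = −(1/E)·cos(D − θ_g)

traces one period of a cosine as the pull direction sweeps the trunk: the
phase gives the gauge's radial position ``θ_g`` and the amplitude gives
``1/E``.  The negative sign reflects the gauge convention (tension positive):
a gauge directly facing the pull sits on the compressed side and reads
negative.

The fit is linear after the substitution y = a·cos D + b·sin D with
a = −cos θ_g/E and b = −sin θ_g/E, so ordinary least squares solves it
exactly — no initial guess, no convergence concerns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    CalibrationError,
    GaugeCalibration,
    ProtocolError,
    wrap_deg,
)

__all__ = [
    "PullRecord",
    "CalibrationSummary",
    "moment_from_pull",
    "fit_gauge",
    "calibrate_all",
    "circular_mean_deg",
]


@dataclass(frozen=True)
class PullRecord:
    """One pulling-test observation for one gauge.

    direction : known loading azimuth D (degrees)
    moment_mag : |M| at the gauge's height from the applied pull (N·m)
    strain : gauge output ε (με, tension positive)
    Z : section modulus at the gauge's height (m³)
    """

    direction: float
    moment_mag: float
    strain: float
    Z: float

    def __post_init__(self) -> None:
        if self.moment_mag <= 0.0:
            raise ProtocolError(f"moment_mag must be positive, got {self.moment_mag}")
        if self.Z <= 0.0:
            raise ProtocolError(f"Z must be positive, got {self.Z}")


def moment_from_pull(pull_force: float, pull_height: float, gauge_height: float) -> float:
    """Bending moment (N·m) a single point pull applies at a gauge height.

    The method assumes no load acts below the gauges, so a pull at or below
    the gauge height is a protocol violation rather than a zero.
    """
    if pull_force < 0.0:
        raise ProtocolError(f"pull_force must be >= 0, got {pull_force}")
    if pull_height <= gauge_height:
        raise ProtocolError(
            f"pull height {pull_height} m must exceed gauge height {gauge_height} m"
        )
    return pull_force * (pull_height - gauge_height)


def _design_ok(directions_rad: np.ndarray) -> bool:
    # Rank-2 check on the [cos, sin] design: directions all congruent mod 180°
    # make the sine (or cosine) component unidentifiable.
    X = np.column_stack([np.cos(directions_rad), np.sin(directions_rad)])
    return int(np.linalg.matrix_rank(X)) == 2


def fit_gauge(records: Sequence[PullRecord], gauge_id: str = "td1") -> GaugeCalibration:
    """Least-squares fit of the signed cosine model to pulling records.

    Returns a :class:`GaugeCalibration` with E in GPa, θ_g in degrees
    wrapped to [0, 360), and the R² of the fit (about the mean of y).

    Raises
    ------
    CalibrationError
        Fewer than 3 records, a direction design of rank < 2 (e.g. all
        pulls along one diameter), or a vanishing amplitude (all strains
        ≈ 0, E not identifiable).
    """
    if len(records) < 3:
        raise CalibrationError(f"{gauge_id}: need >= 3 pull records, got {len(records)}")
    D = np.radians([r.direction for r in records])
    if not _design_ok(D):
        raise CalibrationError(
            f"{gauge_id}: pull directions are rank-deficient (all congruent mod 180°)"
        )
    # y in coherent SI: dimensionless strain × m³ / (N·m) = 1/Pa
    y = np.array([r.strain * 1e-6 * r.Z / r.moment_mag for r in records])
    X = np.column_stack([np.cos(D), np.sin(D)])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    amplitude = math.hypot(a, b)  # = 1/E_Pa
    if not (amplitude > 0.0 and math.isfinite(amplitude)):
        raise CalibrationError(f"{gauge_id}: zero response amplitude, E not identifiable")
    E_gpa = 1.0 / amplitude / 1e9
    theta_g = wrap_deg(math.degrees(math.atan2(-b, -a)))
    resid = y - X @ np.array([a, b])
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else float("nan")
    if math.isfinite(r_squared):
        r_squared = min(max(r_squared, 0.0), 1.0)
    return GaugeCalibration(gauge_id=gauge_id, E=E_gpa, theta_g=theta_g, r_squared=r_squared)


def circular_mean_deg(angles: Iterable[float]) -> float:
    """Mean resultant direction of angles in degrees, wrapped to [0, 360).

    Arithmetic averaging breaks near the 0°/360° seam; the resultant-vector
    mean does not.
    """
    a = np.radians(np.asarray(list(angles), dtype=float))
    if a.size == 0:
        raise ValueError("no angles to average")
    return wrap_deg(math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean())))


def _circular_sd_deg(angles: Sequence[float]) -> float:
    # SD of signed deviations about the circular mean; adequate for the
    # tightly clustered replicate angles this summarises.
    mean = circular_mean_deg(angles)
    dev = np.array([(a - mean + 180.0) % 360.0 - 180.0 for a in angles])
    return float(np.sqrt(np.mean(dev**2)))


@dataclass(frozen=True)
class CalibrationSummary:
    """Across-replicate mean ± SD of one gauge's parameters."""

    gauge_id: str
    E_mean: float
    E_sd: float
    theta_g_mean: float
    theta_g_sd: float
    n_replicates: int


def calibrate_all(
    trials: Mapping[str, Mapping[str, Sequence[PullRecord]]],
) -> tuple[dict[str, dict[str, GaugeCalibration]], dict[str, CalibrationSummary]]:
    """Fit every gauge in every replicate and summarise across replicates.

    Parameters
    ----------
    trials
        ``trials[gauge_id][replicate_id]`` → pull records for that gauge on
        that replicate (e.g. one calibration day).

    Returns
    -------
    (per_replicate, summaries)
        ``per_replicate[gauge_id][replicate_id]`` → :class:`GaugeCalibration`;
        ``summaries[gauge_id]`` → mean ± SD of E (arithmetic) and θ_g
        (circular mean, SD of wrapped deviations).

    Fit failures propagate as :class:`CalibrationError` tagged with the
    gauge and replicate that caused them.
    """
    per_replicate: dict[str, dict[str, GaugeCalibration]] = {}
    summaries: dict[str, CalibrationSummary] = {}
    for gauge_id, reps in trials.items():
        per_replicate[gauge_id] = {}
        for rep_id, records in reps.items():
            try:
                per_replicate[gauge_id][rep_id] = fit_gauge(records, gauge_id=gauge_id)
            except CalibrationError as exc:
                raise CalibrationError(f"replicate {rep_id!r}: {exc}") from exc
        cals = list(per_replicate[gauge_id].values())
        Es = [c.E for c in cals]
        thetas = [c.theta_g for c in cals]
        summaries[gauge_id] = CalibrationSummary(
            gauge_id=gauge_id,
            E_mean=float(np.mean(Es)),
            E_sd=float(np.std(Es)),
            theta_g_mean=circular_mean_deg(thetas),
            theta_g_sd=_circular_sd_deg(thetas),
            n_replicates=len(cals),
        )
    return per_replicate, summaries
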