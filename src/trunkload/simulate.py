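"""Euler–Bernoulli cantilever simulator and experiment protocol builders.

The simulator turns a ground-truth :class:`~trunkload.core.LoadScenario`
into the strain quartet an ideal (or noisy) gauge set would report, using
small-deflection beam theory: the bending moment at height ``h`` is the sum
of ``magnitude · (height − h)`` over the point loads above ``h``, and each
gauge reads

    ε = −M(h_gauge) · cos(D − θ_g) / (E · Z)     (tension positive)

so a gauge facing the load is compressed and a gauge 90° away sits on the
neutral axis.  Two protocol builders reproduce the bench experiments the
method was validated on: a horizontal pole loaded with weight patterns at
five stations (known total force and centroid), and circumferential pulls
from eight azimuths at several force levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GAUGE_IDS,
    GaugeCalibration,
    LoadScenario,
    LoadState,
    ProtocolError,
    SpecimenGeometry,
    StrainQuartet,
    error_deg,
    error_pct,
    wrap_deg,
)

__all__ = [
    "GaugeLayout",
    "NoiseModel",
    "DistributedTest",
    "WOOD_POLE",
    "TABLE2_WOOD_POLE_LAYOUT",
    "moment_at",
    "strains_for",
    "make_distributed_tests",
    "make_pulling_protocol",
    "simulate_pull_records",
    "evaluate",
    "DISTRIBUTED_STATIONS",
]


@dataclass(frozen=True)
class GaugeLayout:
    """Ground-truth gauge placement: true θ_g (deg) and true E (GPa) per gauge.

    This is what the calibration stage must *recover*; the estimator never
    sees it directly.
    """

    theta_g: Mapping[str, float]
    E: Mapping[str, float]

    def __post_init__(self) -> None:
        for g in GAUGE_IDS:
            if g not in self.theta_g or g not in self.E:
                raise ValueError(f"layout missing gauge {g!r}")
            if self.E[g] <= 0.0:
                raise ValueError(f"{g}: E must be positive")

    def as_calibrations(self) -> dict[str, GaugeCalibration]:
        """The layout expressed as (perfect) calibrations."""
        return {
            g: GaugeCalibration(g, self.E[g], wrap_deg(self.theta_g[g]))
            for g in GAUGE_IDS
        }


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian strain noise: SD ``sigma`` (με), explicit seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# physics

def moment_at(scenario: LoadScenario, h: float) -> float:
    """Bending moment (N·m) at height ``h`` from the scenario's point loads.

    Loads at or below ``h`` contribute nothing (they bend only the portion
    of the cantilever beneath them).
    """
    return sum(m * (hh - h) for hh, m in scenario.loads if hh > h)


def strains_for(
    scenario: LoadScenario,
    layout: GaugeLayout,
    geom: SpecimenGeometry,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> StrainQuartet:
    """Exact (or noisy) strain quartet for one load scenario.

    If ``rng`` is given it is drawn from (so a protocol can share one
    stream); otherwise a fresh generator is seeded from ``noise.seed``.
    """
    D = radians(scenario.direction)
    eps = {}
    for g in GAUGE_IDS:
        M = moment_at(scenario, geom.gauge_height(g))
        E_pa = layout.E[g] * 1e9
        Z = geom.gauge_Z(g)
        eps[g] = -M * cos(D - radians(layout.theta_g[g])) / (E_pa * Z) * 1e6
    if noise is not None and noise.sigma > 0.0:
        if rng is None:
            rng = noise.rng()
        draw = rng.normal(0.0, noise.sigma, size=4)
        for g, dn in zip(GAUGE_IDS, draw):
            eps[g] += dn
    return StrainQuartet(
        eps_td1=eps["td1"], eps_td2=eps["td2"],
        eps_bd1=eps["bd1"], eps_bd2=eps["bd2"],
    )


# ---------------------------------------------------------------------------
# protocol builders

#: Distances of the five weight stations above the upper gauge pair (m).
DISTRIBUTED_STATIONS = (0.095, 0.194, 0.294, 0.393, 0.493)

# The 11 weight patterns of the distributed-load bench test: per-station
# loads (N; None = empty station), with the printed total force (N) and
# centroid measured from the t-gauges (m).
_DISTRIBUTED_PATTERNS = [
    # test_no, (w1..w5), total_F, C_from_t
    (1, (0.98, None, None, None, None), 0.98, 0.095),
    (2, (None, None, 0.98, None, None), 0.98, 0.294),
    (3, (None, None, None, None, 0.98), 0.98, 0.493),
    (4, (0.98, None, 0.98, None, None), 1.96, 0.195),
    (5, (0.98, None, None, None, 0.98), 1.96, 0.294),
    (6, (0.98, None, 0.98, None, 0.49), 2.45, 0.254),
    (7, (0.49, None, 0.98, None, 0.98), 2.45, 0.334),
    (8, (0.98, None, 0.49, None, 0.98), 2.45, 0.294),
    (9, (0.98, 0.98, 0.49, 0.20, 0.20), 2.85, 0.211),
    (10, (0.98, 0.20, 0.49, 0.20, 0.98), 2.85, 0.294),
    (11, (0.98, 0.49, 0.98, 0.20, 0.20), 2.85, 0.229),
]


@dataclass(frozen=True)
class DistributedTest:
    """One distributed-load pattern with its known totals."""

    test_no: int
    scenario: LoadScenario
    total_F: float       #: known total force (N)
    C_from_t: float      #: known centroid, measured from the t-gauges (m)


#: Default bench specimen: 0.01 m diameter pole, gauges 0.2 m apart.
WOOD_POLE = SpecimenGeometry(h_t=0.3, h_b=0.1, H=0.9, d_t=0.01, d_b=0.01)

#: A realistic misaligned layout (apparent E in GPa, θ_g in degrees) with
#: ~10° departures from a right angle between d1 and d2 — the magnitudes
#: observed on a calibrated wood pole.
TABLE2_WOOD_POLE_LAYOUT = GaugeLayout(
    theta_g={"td1": 159.6, "td2": 59.5, "bd1": 158.3, "bd2": 55.3},
    E={"td1": 11.2, "td2": 10.5, "bd1": 10.6, "bd2": 11.0},
)


def make_distributed_tests(
    geom: SpecimenGeometry = WOOD_POLE, direction: float = 0.0
) -> list[DistributedTest]:
    """The 11 distributed-load weight patterns as ground-truth scenarios.

    Station distances are measured from the t-gauges; scenario load heights
    are absolute (above the fixed end).  The bench rig loaded a horizontal
    cantilever with vertical weights, so the direction is fixed (default:
    aligned with the baseline) and direction estimation is not exercised by
    these fixtures.
    """
    out = []
    for test_no, weights, total_F, C_from_t in _DISTRIBUTED_PATTERNS:
        loads = [
            (geom.h_t + d, w)
            for d, w in zip(DISTRIBUTED_STATIONS, weights)
            if w is not None
        ]
        out.append(
            DistributedTest(
                test_no=test_no,
                scenario=LoadScenario(loads, direction, label=f"test{test_no}"),
                total_F=total_F,
                C_from_t=C_from_t,
            )
        )
    return out


def make_pulling_protocol(
    directions: Sequence[float] = tuple(range(0, 360, 45)),
    forces: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    pull_height: float = 0.7,
    reps: int = 3,
    geom: SpecimenGeometry = WOOD_POLE,
    direction_jitter: Sequence[float] | None = None,
) -> list[LoadScenario]:
    """Circumferential pulling protocol: directions × forces × reps.

    Each trial is a single point pull at ``pull_height``.  The default is
    the bench protocol — 8 azimuths every 45°, four force levels, three
    repetitions (96 trials).  ``direction_jitter`` (degrees, one offset per
    trial) models the "approximately every 45°" placement; the jittered
    direction is the recorded truth.
    """
    if pull_height <= geom.h_t:
        raise ProtocolError(
            f"pull height {pull_height} m must be above the upper gauges at {geom.h_t} m"
        )
    trials = [
        (d, f, r)
        for r in range(reps)
        for d in directions
        for f in forces
    ]
    if direction_jitter is not None:
        if len(direction_jitter) != len(trials):
            raise ProtocolError("need one jitter offset per trial")
        trials = [(d + j, f, r) for (d, f, r), j in zip(trials, direction_jitter)]
    return [
        LoadScenario(
            [(pull_height, f)], d, label=f"rep{r}_D{wrap_deg(d):g}_F{f:g}"
        )
        for d, f, r in trials
    ]


def simulate_pull_records(
    scenarios: Sequence[LoadScenario],
    layout: GaugeLayout,
    geom: SpecimenGeometry,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Run a pulling protocol through the simulator into a calibration table.

    Returns the documented pulling-test dialect: columns replicate_id,
    gauge_id, direction_deg, force_N, pull_height_m, strain_ue — one row
    per gauge per trial, ready for the calibration reader.
    """
    rng = noise.rng() if noise is not None else None
    rows = []
    for sc in scenarios:
        if len(sc.loads) != 1:
            raise ProtocolError("pull trials must be single point loads")
        (h, f), = sc.loads
        q = strains_for(sc, layout, geom, noise=noise, rng=rng)
        rep = sc.label.split("_")[0] if sc.label else "rep0"
        for g in GAUGE_IDS:
            rows.append(
                {
                    "replicate_id": rep,
                    "gauge_id": g,
                    "direction_deg": sc.direction,
                    "force_N": f,
                    "pull_height_m": h,
                    "strain_ue": q.eps(g),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation

def evaluate(
    truths: Sequence[LoadScenario],
    estimates: Sequence[LoadState],
    geom: SpecimenGeometry | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial and aggregate estimation errors against ground truth.

    For each (truth, estimate) pair the relative errors of F and C (%) and
    the wrapped angular errors of D_t/D_b (degrees) are computed; aggregates
    (mean, median, max) are reported per group label — the synthetic
    analogue of the bench accuracy summaries.

    Returns ``(per_trial, aggregate)`` DataFrames.
    """
    if len(truths) != len(estimates):
        raise ValueError(f"{len(truths)} truths vs {len(estimates)} estimates")
    if groups is None:
        groups = [t.label or "all" for t in truths]
    rows = []
    for truth, est, grp in zip(truths, estimates, groups):
        row = {"group": grp, "label": truth.label}
        row["err_F_pct"] = error_pct(truth.total_force, est.F)
        row["err_C_pct"] = error_pct(truth.centroid(), est.C)
        row["err_Dt_deg"] = error_deg(truth.direction, est.D_t)
        row["err_Db_deg"] = error_deg(truth.direction, est.D_b)
        rows.append(row)
    per_trial = pd.DataFrame(rows)
    metric_cols = ["err_F_pct", "err_C_pct", "err_Dt_deg", "err_Db_deg"]
    aggregate = (
        per_trial.groupby("group")[metric_cols]
        .agg(["mean", "median", "max"])
        .reset_index()
    )
    aggregate.columns = [
        "_".join(c).rstrip("_") for c in aggregate.columns.to_flat_index()
    ]
    return per_trial, aggregate
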