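"""Readers and writers for the package's CSV/JSON dialects.

One CSV dialect throughout: comma-separated, dot decimal, one header row,
unit-suffixed column names (``…_ue`` microstrain, ``…_N`` newtons, ``…_m``
metres, ``…_deg`` degrees) so a unit mistake cannot be committed silently.
Calibrations, scenarios and geometry travel as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calibration import PullRecord, moment_from_pull
from .core import (
    GAUGE_IDS,
    GaugeCalibration,
    LoadScenario,
    SpecimenGeometry,
    StrainQuartet,
)

__all__ = [
    "STRAIN_COLUMNS",
    "PULL_COLUMNS",
    "read_strain_csv",
    "write_strain_csv",
    "read_pull_csv",
    "pull_records_from_table",
    "read_calibration_json",
    "write_calibration_json",
    "read_geometry_json",
    "write_geometry_json",
    "read_scenario_json",
    "write_scenario_json",
    "read_pull_xlsx",
]

STRAIN_COLUMNS = ["time_s", "eps_td1_ue", "eps_td2_ue", "eps_bd1_ue", "eps_bd2_ue"]
PULL_COLUMNS = [
    "replicate_id", "gauge_id", "direction_deg", "force_N", "pull_height_m", "strain_ue",
]


class SchemaError(ValueError):
    """Input table does not match the documented dialect."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_strain_csv(path) -> list[StrainQuartet]:
    """Read a strain time series; warns on non-monotone timestamps."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, STRAIN_COLUMNS, path)
    for col in STRAIN_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            raise SchemaError(f"{path}: malformed value in {col!r} at line {bad[0] + 2}")
    if df["time_s"].notna().all() and not df["time_s"].is_monotonic_increasing:
        import warnings

        warnings.warn(f"{path}: timestamps are not monotonically increasing")
    return [
        StrainQuartet(
            time=row.time_s,
            eps_td1=row.eps_td1_ue,
            eps_td2=row.eps_td2_ue,
            eps_bd1=row.eps_bd1_ue,
            eps_bd2=row.eps_bd2_ue,
        )
        for row in df.itertuples()
    ]


def write_strain_csv(path, quartets: Sequence[StrainQuartet]) -> None:
    df = pd.DataFrame(
        {
            "time_s": [q.time for q in quartets],
            "eps_td1_ue": [q.eps_td1 for q in quartets],
            "eps_td2_ue": [q.eps_td2 for q in quartets],
            "eps_bd1_ue": [q.eps_bd1 for q in quartets],
            "eps_bd2_ue": [q.eps_bd2 for q in quartets],
        }
    )
    # repr-round-trip float format keeps write→read lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_pull_csv(path) -> pd.DataFrame:
    """Read a pulling-test table in the documented dialect."""
    df = pd.read_csv(path)
    _require_columns(df, PULL_COLUMNS, path)
    unknown = set(df["gauge_id"]) - set(GAUGE_IDS)
    if unknown:
        raise SchemaError(f"{path}: unknown gauge_id(s) {sorted(unknown)}")
    return df


def pull_records_from_table(
    df: pd.DataFrame, geom: SpecimenGeometry
) -> dict[str, dict[str, list[PullRecord]]]:
    """Group a pulling-test table into per-gauge, per-replicate records.

    The moment each pull applies at a gauge height and the section modulus
    there are derived from the geometry, so the table stays at the level of
    what was actually measured (force, heights, strain).
    """
    trials: dict[str, dict[str, list[PullRecord]]] = {}
    for row in df.itertuples():
        g = row.gauge_id
        rec = PullRecord(
            direction=row.direction_deg,
            moment_mag=moment_from_pull(
                row.force_N, row.pull_height_m, geom.gauge_height(g)
            ),
            strain=row.strain_ue,
            Z=geom.gauge_Z(g),
        )
        trials.setdefault(g, {}).setdefault(str(row.replicate_id), []).append(rec)
    return trials


# ---------------------------------------------------------------------------
# JSON

def write_calibration_json(
    path,
    per_replicate: Mapping[str, Mapping[str, GaugeCalibration]],
    summaries=None,
) -> None:
    payload: dict = {
        "per_replicate": {
            g: {
                rep: {"E_GPa": c.E, "theta_g_deg": c.theta_g, "r_squared": c.r_squared}
                for rep, c in reps.items()
            }
            for g, reps in per_replicate.items()
        }
    }
    if summaries is not None:
        payload["summary"] = {
            g: {
                "E_GPa_mean": s.E_mean,
                "E_GPa_sd": s.E_sd,
                "theta_g_deg_mean": s.theta_g_mean,
                "theta_g_deg_sd": s.theta_g_sd,
                "n_replicates": s.n_replicates,
            }
            for g, s in summaries.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration_json(path, replicate: str | None = None) -> dict[str, GaugeCalibration]:
    """Load one replicate's calibrations (default: the first listed).

    Estimation needs all four gauges; a missing gauge is a schema error
    naming the gauge.
    """
    payload = json.loads(Path(path).read_text())
    per_rep = payload["per_replicate"]
    out = {}
    for g in GAUGE_IDS:
        if g not in per_rep or not per_rep[g]:
            raise SchemaError(f"{path}: no calibration for gauge {g!r}")
        reps = per_rep[g]
        rep = replicate if replicate is not None else sorted(reps)[0]
        if rep not in reps:
            raise SchemaError(f"{path}: gauge {g!r} has no replicate {rep!r}")
        c = reps[rep]
        out[g] = GaugeCalibration(
            g, E=c["E_GPa"], theta_g=c["theta_g_deg"], r_squared=c.get("r_squared", 1.0)
        )
    return out


def write_geometry_json(path, geom: SpecimenGeometry) -> None:
    Path(path).write_text(
        json.dumps(
            {"h_t_m": geom.h_t, "h_b_m": geom.h_b, "H_m": geom.H,
             "d_t_m": geom.d_t, "d_b_m": geom.d_b},
            indent=2,
        )
    )


def read_geometry_json(path) -> SpecimenGeometry:
    d = json.loads(Path(path).read_text())
    try:
        return SpecimenGeometry(
            h_t=d["h_t_m"], h_b=d["h_b_m"], H=d["H_m"], d_t=d["d_t_m"], d_b=d["d_b_m"]
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing geometry field {exc}") from exc


def write_scenario_json(path, scenarios: Sequence[LoadScenario]) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "label": s.label,
                    "direction_deg": s.direction,
                    "loads": [{"height_m": h, "force_N": m} for h, m in s.loads],
                }
                for s in scenarios
            ],
            indent=2,
        )
    )


def read_scenario_json(path) -> list[LoadScenario]:
    data = json.loads(Path(path).read_text())
    return [
        LoadScenario(
            [(ld["height_m"], ld["force_N"]) for ld in s["loads"]],
            s["direction_deg"],
            label=s.get("label", ""),
        )
        for s in data
    ]


def read_pull_xlsx(path, sheet=0) -> pd.DataFrame:
    """Best-effort adapter for spreadsheet exports of pulling tests.

    Accepts any sheet whose header row carries the documented pulling-test
    column names; anything else is rejected with the list of missing
    columns.  This is a convenience for spreadsheet-based loggers, not part
    of the core path.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    _require_columns(df, PULL_COLUMNS, path)
    unknown = set(df["gauge_id"]) - set(GAUGE_IDS)
    if unknown:
        raise SchemaError(f"{path}: unknown gauge_id(s) {sorted(unknown)}")
    return df[PULL_COLUMNS]
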