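"""File formats, packaged reference tables and the end-to-end report.

All interchange is CSV (UTF-8, header row, '.' decimal, explicit unit
columns — the field mixes M⁻¹, kJ mol⁻¹ and dimensionless quantities,
so units are never implicit).  Two reference tables ship with the
package:

* ``table1_ddg.csv`` — the measured DMC interaction free energies
  (ΔΔG°, kJ mol⁻¹, ±1σ) for 13 substituents in water and chloroform.
* ``substituent_parameters.csv`` — per-substituent descriptors (σ_m,
  σ_p, β_X, PhX water→n-hexadecane transfer free energy, polarity
  class).  The Hammett constants come from the canonical compilation;
  β and the transfer values are literature-derived approximations, and
  a :class:`~dmcycle.lfer.ProvenanceWarning` is raised whenever they
  are loaded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dmc import DMCQuad, dmc_delta, solvent_difference, table_entry
from .lfer import (
    LinearFreeEnergyFit,
    ProvenanceWarning,
    SubstituentRecord,
    hammett_fit,
    model_rmse,
    nonpolar_transfer_fit,
    predict_chloroform_ddg,
    predict_water_ddg,
    resolvation_energy,
)
from .thermo import BindingMeasurement, ThermoQuantity

__all__ = [
    "load_table1",
    "load_substituent_parameters",
    "MeasurementTable",
    "read_measurements",
    "write_measurements",
    "read_quads",
    "run_report",
    "validate_report",
    "render_report_text",
]

log = logging.getLogger("dmcycle")

MEASUREMENT_COLUMNS = [
    "complex_id",
    "host",
    "guest",
    "solvent",
    "K_value",
    "K_sigma",
    "K_unit",
    "dH_value",
    "dH_sigma",
    "dH_unit",
    "T_K",
    "method",
]


def _data_path(name: str):
    return resources.files("dmcycle").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Packaged DMC interaction free energies (ΔΔG°/kJ mol⁻¹, both solvents)."""
    with resources.as_file(_data_path("table1_ddg.csv")) as p:
        df = pd.read_csv(p)
    assert len(df) == 13
    return df


def load_substituent_parameters(warn: bool = True) -> Dict[str, SubstituentRecord]:
    """Packaged substituent descriptor table as SubstituentRecord objects.

    Emits a ProvenanceWarning: β and transfer free energies are
    literature approximations, not values from the study that measured
    the packaged ΔΔG° table.
    """
    with resources.as_file(_data_path("substituent_parameters.csv")) as p:
        df = pd.read_csv(p)
    if warn:
        warnings.warn(
            "substituent beta and transfer free energies are "
            "literature-derived approximations (see the table's provenance "
            "column); downstream aqueous predictions inherit this caveat",
            ProvenanceWarning,
            stacklevel=2,
        )
    out: Dict[str, SubstituentRecord] = {}
    for _, row in df.iterrows():
        out[row["X"]] = SubstituentRecord(
            X=row["X"],
            sigma_m=float(row["sigma_m"]),
            sigma_p=float(row["sigma_p"]),
            beta=float(row["beta"]),
            dG_transfer=(
                None if pd.isna(row["dG_transfer_kJmol"])
                else float(row["dG_transfer_kJmol"])
            ),
            polarity_class=row["polarity_class"],
        )
    return out


@dataclass
class MeasurementTable:
    """A measurement CSV held losslessly: typed rows plus the raw frame.

    Unknown columns are preserved on round trip; unknown units are
    rejected row-by-row at load time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        for idx, row in self.frame.iterrows():
            where = f"row {idx} (complex {row['complex_id']!r})"
            if row["K_unit"] != "1/M":
                raise ValueError(f"{where}: unknown K unit {row['K_unit']!r}")
            if row["dH_unit"] != "kJ/mol":
                raise ValueError(f"{where}: unknown dH unit {row['dH_unit']!r}")
            if not row["K_value"] > 0:
                raise ValueError(f"{where}: association constant must be > 0")

    def measurements(self) -> Dict[str, BindingMeasurement]:
        out = {}
        for _, row in self.frame.iterrows():
            out[row["complex_id"]] = BindingMeasurement(
                host=str(row["host"]),
                guest=str(row["guest"]),
                solvent=str(row["solvent"]),
                K=ThermoQuantity(float(row["K_value"]), float(row["K_sigma"]), "1/M"),
                dH=ThermoQuantity(
                    float(row["dH_value"]), float(row["dH_sigma"]), "kJ/mol"
                ),
                T=float(row["T_K"]),
                method=str(row["method"]),
            )
        return out

    @classmethod
    def from_measurements(
        cls, measurements: Mapping[str, BindingMeasurement]
    ) -> "MeasurementTable":
        rows = []
        for cid, m in measurements.items():
            rows.append(
                {
                    "complex_id": cid,
                    "host": m.host,
                    "guest": m.guest,
                    "solvent": m.solvent,
                    "K_value": m.K.value,
                    "K_sigma": m.K.sigma,
                    "K_unit": "1/M",
                    "dH_value": m.dH.value,
                    "dH_sigma": m.dH.sigma,
                    "dH_unit": "kJ/mol",
                    "T_K": m.T,
                    "method": m.method,
                }
            )
        return cls(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))


def read_measurements(path) -> MeasurementTable:
    try:
        # round_trip float parsing so write→read→write is byte-identical
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"cannot read measurement table {path}: {exc}") from exc
    return MeasurementTable(frame)


def write_measurements(table: MeasurementTable, path) -> None:
    table.frame.to_csv(path, index=False, lineterminator="\n")


def read_quads(path, measurements: Mapping[str, BindingMeasurement]) -> List[DMCQuad]:
    """Quad definition CSV: label, X, solvent, complex_A..complex_D ids."""
    df = pd.read_csv(path)
    required = ["label", "complex_A", "complex_B", "complex_C", "complex_D"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"quad table missing column(s): {missing}")
    quads = []
    for idx, row in df.iterrows():
        try:
            quads.append(
                DMCQuad(
                    A=measurements[row["complex_A"]],
                    B=measurements[row["complex_B"]],
                    C=measurements[row["complex_C"]],
                    D=measurements[row["complex_D"]],
                    label=str(row["label"]),
                )
            )
        except KeyError as exc:
            raise ValueError(f"quad row {idx}: unknown complex id {exc}") from exc
    return quads


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------


def _ddg_frame_from_quads(quads: List[DMCQuad]) -> pd.DataFrame:
    rows = []
    for q in quads:
        dd = dmc_delta(q, "G")
        rows.append(
            {
                "label": q.label,
                "X": q.label.split("/")[0],
                "solvent": q.solvent,
                "ddG_kJmol": dd.value,
                "sigma": dd.sigma,
                "table_entry": table_entry(dd),
            }
        )
    return pd.DataFrame(rows)


def run_report(
    ddg_table: Optional[pd.DataFrame] = None,
    quads: Optional[List[DMCQuad]] = None,
    params: Optional[Dict[str, SubstituentRecord]] = None,
    seed: Optional[int] = None,
) -> dict:
    """Full LFER/solvation analysis on a Table-1-shaped ΔΔG° dataset.

    Either pass ``ddg_table`` directly (columns X, ddG_water_kJmol,
    ddG_chloroform_kJmol) or a list of DMC quads per solvent from which
    the table is computed.  Returns a JSON-serialisable bundle with the
    DMC table, solvent differences, Hammett fit, transfer-line fit,
    resolvation energies, model predictions and RMSE.
    """
    if params is None:
        params = load_substituent_parameters()
    if ddg_table is None:
        if quads is None:
            raise ValueError("provide either ddg_table or quads")
        raw = _ddg_frame_from_quads(quads)
        ddg_table = raw.pivot(index="X", columns="solvent", values="ddG_kJmol")
        ddg_table = ddg_table.rename(
            columns={"water": "ddG_water_kJmol", "chloroform": "ddG_chloroform_kJmol"}
        ).reset_index()

    df = ddg_table
    water = dict(zip(df["X"], df["ddG_water_kJmol"]))
    chcl3 = dict(zip(df["X"], df["ddG_chloroform_kJmol"]))
    diffs = {X: water[X] - chcl3[X] for X in water}

    ham = hammett_fit(
        [(params[X].sigma_m, chcl3[X]) for X in chcl3], labels=list(chcl3)
    )
    cross = LinearFreeEnergyFit().fit(
        [chcl3[X] for X in chcl3], [water[X] for X in chcl3]
    )
    np_fit = nonpolar_transfer_fit(diffs, params)
    resolv = {
        X: resolvation_energy(X, diffs, params, np_fit)
        for X in diffs
        if params[X].polarity_class == "polar"
        and params[X].dG_transfer is not None
    }
    predictions = {}
    observations = {}
    for X in chcl3:
        predictions[f"{X}/chloroform"] = predict_chloroform_ddg(params[X].sigma_m)
        observations[f"{X}/chloroform"] = chcl3[X]
        rec = params[X]
        if rec.dG_transfer is not None and not math.isnan(rec.dG_transfer):
            predictions[f"{X}/water"] = predict_water_ddg(rec)
            observations[f"{X}/water"] = water[X]
    keys = sorted(predictions)
    rmse = model_rmse([predictions[k] for k in keys], [observations[k] for k in keys])

    bundle = {
        "package_version": __version__,
        "seed": seed,
        "n_substituents": len(df),
        "ddg_water_kJmol": water,
        "ddg_chloroform_kJmol": chcl3,
        "solvent_difference_kJmol": diffs,
        "hammett_chloroform": {
            "slope": ham.slope,
            "slope_sigma": ham.slope_sigma,
            "intercept": ham.intercept,
            "intercept_sigma": ham.intercept_sigma,
            "r_squared": ham.r_squared,
        },
        "water_vs_chloroform_r_squared": cross.r_squared_,
        "nonpolar_transfer_line": {
            "slope": np_fit.slope,
            "intercept": np_fit.intercept,
            "r_squared": np_fit.r_squared,
            "substituents": list(np_fit.labels),
        },
        "resolvation_kJmol": resolv,
        "predictions_kJmol": predictions,
        "model_rmse_kJmol": rmse,
    }
    log.info(
        "report: version=%s seed=%s config_hash=%s",
        __version__,
        seed,
        hashlib.sha256(
            json.dumps({k: sorted(v) if isinstance(v, dict) else v
                        for k, v in (("w", water), ("c", chcl3))}).encode()
        ).hexdigest()[:12],
    )
    return bundle


#: required keys and types of the JSON report bundle (machine-readable summary)
REPORT_SCHEMA = {
    "package_version": str,
    "n_substituents": int,
    "ddg_water_kJmol": dict,
    "ddg_chloroform_kJmol": dict,
    "solvent_difference_kJmol": dict,
    "hammett_chloroform": dict,
    "water_vs_chloroform_r_squared": float,
    "nonpolar_transfer_line": dict,
    "resolvation_kJmol": dict,
    "predictions_kJmol": dict,
    "model_rmse_kJmol": float,
}


def validate_report(bundle: dict) -> None:
    """Raise ValueError if a report bundle is missing keys or mistyped."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in bundle:
            raise ValueError(f"report bundle missing key {key!r}")
        if not isinstance(bundle[key], typ):
            raise ValueError(
                f"report key {key!r} should be {typ.__name__}, got "
                f"{type(bundle[key]).__name__}"
            )
    for sub in ("slope", "intercept", "r_squared"):
        if sub not in bundle["hammett_chloroform"]:
            raise ValueError(f"hammett_chloroform missing {sub!r}")
        if sub not in bundle["nonpolar_transfer_line"]:
            raise ValueError(f"nonpolar_transfer_line missing {sub!r}")


def render_report_text(bundle: dict) -> str:
    """Human-readable rendering at measurement precision (integer kJ/mol)."""
    lines = ["DMC interaction free energies (kJ/mol)"]
    lines.append(f"{'X':>6} {'water':>7} {'chloroform':>11} {'difference':>11}")
    for X in bundle["ddg_water_kJmol"]:
        w = bundle["ddg_water_kJmol"][X]
        c = bundle["ddg_chloroform_kJmol"][X]
        lines.append(f"{X:>6} {round(w):>7d} {round(c):>11d} {round(w - c):>11d}")
    h = bundle["hammett_chloroform"]
    lines.append(
        "Hammett (chloroform): slope %.1f, intercept %.1f, R^2 %.2f"
        % (h["slope"], h["intercept"], h["r_squared"])
    )
    npl = bundle["nonpolar_transfer_line"]
    lines.append(
        "Non-polar transfer line: slope %.2f, intercept %.1f, R^2 %.2f"
        % (npl["slope"], npl["intercept"], npl["r_squared"])
    )
    lines.append(
        "Water vs chloroform R^2: %.2f" % bundle["water_vs_chloroform_r_squared"]
    )
    if bundle["resolvation_kJmol"]:
        res = ", ".join(
            f"{X} {v:.1f}" for X, v in bundle["resolvation_kJmol"].items()
        )
        lines.append(f"Resolvation energies (kJ/mol): {res}")
    lines.append("Model RMSE: %.1f kJ/mol" % bundle["model_rmse_kJmol"])
    return "\n".join(lines) + "\n"
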