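"""Delimited-table readers/writers and run configuration.

All tables are plain text (comma- or tab-delimited) with self-describing
headers; concentrations carry an explicit ``_M`` suffix to keep units
unambiguous.  Heats may be supplied in ucal (``heat_ucal``) or kcal
(``heat_kcal``); ucal values are converted on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .thermo import Conditions, EquilibriumPoint, GoverningParams, celsius_to_kelvin
from .titration import InjectionSchedule, TitrationTrace

__all__ = [
    "TableError",
    "ConfigError",
    "read_k_table",
    "read_heats_table",
    "write_trace",
    "read_trace",
    "write_report",
    "load_config",
    "conditions_from_config",
    "params_from_config",
    "schedule_from_config",
]

log = logging.getLogger("solvitc")

UCAL_PER_KCAL = 1e9


class TableError(ValueError):
    """A delimited input table failed validation."""


class ConfigError(ValueError):
    """A run configuration document failed validation."""


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise TableError(f"{path}: empty input file")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps write/read of traces bit-exact
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise TableError(f"{path}: no data rows")
    return df


def read_k_table(path) -> list[EquilibriumPoint]:
    """Read (temperature_C, complex_conc_M, K[, K_sd]) rows.

    Row errors are reported with their 1-based data line number.
    """
    df = _read_delimited(path)
    required = {"temperature_C", "complex_conc_M", "K"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing required columns {sorted(missing)}")
    has_sd = "K_sd" in df.columns
    points: list[EquilibriumPoint] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            sd = float(row["K_sd"]) if has_sd and pd.notna(row["K_sd"]) else None
            points.append(
                EquilibriumPoint(
                    K=float(row["K"]),
                    complex_conc=float(row["complex_conc_M"]),
                    temperature_K=celsius_to_kelvin(float(row["temperature_C"])),
                    K_sd=sd,
                )
            )
        except (TypeError, ValueError) as exc:
            raise TableError(f"{path}: line {line}: {exc}") from exc
    return points


def read_heats_table(path) -> pd.DataFrame:
    """Read per-injection heats; returns columns injection, volume_uL, heat_kcal.

    Exactly one of ``heat_kcal`` / ``heat_ucal`` must be present; ucal
    values are converted to kcal and the conversion logged.
    """
    df = _read_delimited(path)
    heat_cols = [c for c in ("heat_kcal", "heat_ucal") if c in df.columns]
    if len(heat_cols) == 0:
        raise TableError(f"{path}: need a heat_kcal or heat_ucal column")
    if len(heat_cols) == 2:
        raise TableError(f"{path}: mixed heat units (both heat_kcal and heat_ucal present)")
    for col in ("injection", "volume_uL"):
        if col not in df.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(
        {
            "injection": df["injection"].astype(int),
            "volume_uL": df["volume_uL"].astype(float),
        }
    )
    if heat_cols[0] == "heat_ucal":
        out["heat_kcal"] = df["heat_ucal"].astype(float) / UCAL_PER_KCAL
        log.info("converted heats from ucal to kcal (factor 1e-9)")
    else:
        out["heat_kcal"] = df["heat_kcal"].astype(float)
    if not np.all(np.isfinite(out["heat_kcal"])):
        raise TableError(f"{path}: non-finite heat values")
    return out


_TRACE_COLUMNS = [
    "injection", "Xt_M", "Mt_M", "molar_ratio", "Z_M", "K",
    "q_kcal", "q_norm_kcal_per_mol",
]


def write_trace(path, trace: TitrationTrace) -> None:
    """Write a titration trace at full precision (lossless round-trip)."""
    df = pd.DataFrame(
        {
            "injection": np.arange(1, trace.n_injections + 1),
            "Xt_M": trace.Xt,
            "Mt_M": trace.Mt,
            "molar_ratio": trace.molar_ratio,
            "Z_M": trace.Z,
            "K": trace.K,
            "q_kcal": trace.q,
            "q_norm_kcal_per_mol": trace.q_norm,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path, schedule: InjectionSchedule | None = None) -> TitrationTrace:
    df = _read_delimited(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing trace columns {sorted(missing)}")
    return TitrationTrace(
        Xt=df["Xt_M"].to_numpy(float),
        Mt=df["Mt_M"].to_numpy(float),
        molar_ratio=df["molar_ratio"].to_numpy(float),
        Z=df["Z_M"].to_numpy(float),
        K=df["K"].to_numpy(float),
        q=df["q_kcal"].to_numpy(float),
        q_norm=df["q_norm_kcal_per_mol"].to_numpy(float),
        schedule=schedule if schedule is not None else InjectionSchedule(n_injections=len(df)),
    )


def write_report(path, fields: dict) -> None:
    """Write a two-column key/value report table."""
    with open(path, "w") as fh:
        fh.write("key,value\n")
        for k, v in fields.items():
            fh.write(f"{k},{v!r}\n" if isinstance(v, str) else f"{k},{v:.12g}\n")


# ---------------------------------------------------------------------------
# run configuration

_CONDITIONS_KEYS = {"temperature_C", "temperature_K", "gas_constant"}
_PARAMS_KEYS = {"dG_standard", "dG_solv"}
_SCHEDULE_KEYS = {
    "n_injections", "injection_volume_uL", "cell_volume_mL", "syringe_conc_M",
    "cell_conc_initial_M", "first_injection_volume_uL", "dilution_mode",
}
_TOP_KEYS = {"conditions", "params", "schedule", "dH_bind", "seed",
             "weighting", "vant_hoff_mode", "noise"}
_NOISE_KEYS = {"heat_noise_sd", "K_lognormal_sd", "cd_noise_sd"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where}")


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected with their location so typos fail fast.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    _check_keys(doc, _TOP_KEYS, str(path))
    for block, keys in (
        ("conditions", _CONDITIONS_KEYS),
        ("params", _PARAMS_KEYS),
        ("schedule", _SCHEDULE_KEYS),
        ("noise", _NOISE_KEYS),
    ):
        if block in doc:
            if not isinstance(doc[block], dict):
                raise ConfigError(f"{path}: {block} must be a mapping")
            _check_keys(doc[block], keys, f"{path}:{block}")
    return doc


def conditions_from_config(doc: dict) -> Conditions:
    block = doc.get("conditions", {})
    kwargs = {}
    if "gas_constant" in block:
        kwargs["gas_constant"] = float(block["gas_constant"])
    if "temperature_K" in block and "temperature_C" in block:
        raise ConfigError("give temperature_C or temperature_K, not both")
    if "temperature_K" in block:
        return Conditions(temperature_K=float(block["temperature_K"]), **kwargs)
    if "temperature_C" in block:
        return Conditions.from_celsius(float(block["temperature_C"]), **kwargs)
    return Conditions(**kwargs)


def params_from_config(doc: dict) -> GoverningParams:
    block = doc.get("params")
    if block is None:
        raise ConfigError("config is missing the params block")
    if "dG_standard" not in block:
        raise ConfigError("params block needs dG_standard")
    return GoverningParams(
        dG_standard=float(block["dG_standard"]),
        dG_solv=float(block.get("dG_solv", 0.0)),
    )


def schedule_from_config(doc: dict) -> InjectionSchedule:
    block = doc.get("schedule", {})
    kwargs = {}
    if "n_injections" in block:
        kwargs["n_injections"] = int(block["n_injections"])
    if "injection_volume_uL" in block:
        kwargs["injection_volume"] = float(block["injection_volume_uL"]) * 1e-6
    if "cell_volume_mL" in block:
        kwargs["cell_volume"] = float(block["cell_volume_mL"]) * 1e-3
    if "syringe_conc_M" in block:
        kwargs["syringe_conc"] = float(block["syringe_conc_M"])
    if "cell_conc_initial_M" in block:
        kwargs["cell_conc_initial"] = float(block["cell_conc_initial_M"])
    if "first_injection_volume_uL" in block:
        kwargs["first_injection_volume"] = float(block["first_injection_volume_uL"]) * 1e-6
    if "dilution_mode" in block:
        kwargs["dilution_mode"] = str(block["dilution_mode"])
    return InjectionSchedule(**kwargs)
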