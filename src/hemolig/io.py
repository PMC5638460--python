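"""Readers and writers for the package's plain-text exchange formats.

CSV with unit-bearing headers is the canonical format for spectra and
traces (``wavelength_nm,absorbance``; ``pO2_torr,saturation``; ``time_s,N``;
``time_s,A420``; ``time_min,met_fraction``; P50 grids as
``temperature_C,pH,atp_mM,P50_torr``); fitted results are JSON; conditions
travel in YAML sidecar files.  Column names are validated on read so unit
mistakes fail loudly instead of propagating.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay import AutoxSeries, DisplacementTrace
from .equilibrium import CELSIUS_OFFSET, Condition, EquilibriumCurve
from .exceptions import InputError
from .linkage import P50Grid
from .photolysis import PhotolysisTrace
from .spectra import SpeciesComposition, Spectrum

__all__ = [
    "read_spectrum", "write_spectrum",
    "read_equilibrium_curve", "write_equilibrium_curve",
    "read_photolysis_trace", "write_photolysis_trace",
    "read_displacement", "write_displacement",
    "read_autox_series", "write_autox_series",
    "read_p50_grid", "write_p50_grid",
    "read_condition", "write_condition",
    "write_json", "composition_to_dict",
]


def _read_csv(path, columns):
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)} "
            "(units are encoded in the header names)"
        )
    return df


# -- spectra ----------------------------------------------------------------

def read_spectrum(path, label: str | None = None) -> Spectrum:
    df = _read_csv(path, ["wavelength_nm", "absorbance"])
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(),
                    label=label if label is not None else Path(path).stem)


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "absorbance": spectrum.absorbances}).to_csv(path, index=False)


def composition_to_dict(comp: SpeciesComposition) -> dict:
    return {"references": dict(comp.coefficients), "offset": comp.offset,
            "residual_rms": comp.residual_rms}


# -- equilibrium curves -----------------------------------------------------

def read_equilibrium_curve(path, condition: Condition | None = None) -> EquilibriumCurve:
    df = _read_csv(path, ["pO2_torr", "saturation"])
    return EquilibriumCurve(df["pO2_torr"].to_numpy(), df["saturation"].to_numpy(),
                            condition=condition)


def write_equilibrium_curve(curve: EquilibriumCurve, path) -> None:
    pd.DataFrame({"pO2_torr": curve.pO2_torr,
                  "saturation": curve.saturation}).to_csv(path, index=False)


# -- photolysis traces ------------------------------------------------------

def read_photolysis_trace(path, co_atm: float = 1.0,
                          condition: Condition | None = None) -> PhotolysisTrace:
    df = _read_csv(path, ["time_s", "N"])
    return PhotolysisTrace(df["time_s"].to_numpy(), df["N"].to_numpy(),
                           co_atm=co_atm, condition=condition)


def write_photolysis_trace(trace: PhotolysisTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "N": trace.N}).to_csv(path, index=False)


# -- displacement and autoxidation -----------------------------------------

def read_displacement(path, condition: Condition | None = None) -> DisplacementTrace:
    df = _read_csv(path, ["time_s", "A420"])
    return DisplacementTrace(df["time_s"].to_numpy(), df["A420"].to_numpy(),
                             condition=condition)


def write_displacement(trace: DisplacementTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "A420": trace.A420}).to_csv(path, index=False)


def read_autox_series(path) -> AutoxSeries:
    df = _read_csv(path, ["time_min", "met_fraction"])
    return AutoxSeries(df["time_min"].to_numpy(), df["met_fraction"].to_numpy())


def write_autox_series(series: AutoxSeries, path) -> None:
    pd.DataFrame({"time_min": series.times_min,
                  "met_fraction": series.met_fraction}).to_csv(path, index=False)


# -- P50 grids --------------------------------------------------------------

def read_p50_grid(path, isoform: str = "") -> P50Grid:
    df = _read_csv(path, ["temperature_C", "pH", "atp_mM", "P50_torr"])
    entries = pd.DataFrame({
        "temperature_K": df["temperature_C"] + CELSIUS_OFFSET,
        "pH": df["pH"],
        "ATP": df["atp_mM"] > 0,
        "P50_torr": df["P50_torr"],
    })
    return P50Grid(entries, isoform=isoform)


def write_p50_grid(grid: P50Grid, path) -> None:
    df = grid.frame
    pd.DataFrame({
        "temperature_C": df["temperature_K"] - CELSIUS_OFFSET,
        "pH": df["pH"],
        "atp_mM": np.where(df["ATP"], 2.0, 0.0),
        "P50_torr": df["P50_torr"],
    }).to_csv(path, index=False)


# -- conditions and generic JSON -------------------------------------------

def read_condition(path) -> Condition:
    """Condition sidecar: YAML mapping with temperature in C or K."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError(f"{path}: condition file must be a key-value mapping")
    if "temperature_K" in raw:
        temp_k = float(raw["temperature_K"])
    elif "temperature_C" in raw:
        temp_k = float(raw["temperature_C"]) + CELSIUS_OFFSET
    else:
        raise InputError(f"{path}: needs temperature_C or temperature_K")
    if "pH" not in raw:
        raise InputError(f"{path}: needs pH")
    return Condition(
        temperature_K=temp_k, pH=float(raw["pH"]),
        KCl_mM=float(raw.get("KCl_mM", 100.0)),
        ATP_mM=float(raw.get("ATP_mM", 0.0)),
        urea_mM=float(raw.get("urea_mM", 0.0)),
        heme_mM=float(raw.get("heme_mM", 0.0)),
        label=str(raw.get("label", "")),
    )


def write_condition(condition: Condition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "temperature_C": condition.temperature_C, "pH": condition.pH,
            "KCl_mM": condition.KCl_mM, "ATP_mM": condition.ATP_mM,
            "urea_mM": condition.urea_mM, "heme_mM": condition.heme_mM,
            "label": condition.label,
        }, fh, sort_keys=True)


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed float repr) for reports."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
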