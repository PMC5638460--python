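"""Thermodynamic linkage: Bohr effect and van't Hoff oxygenation enthalpy.

The pH dependence of O2 affinity (Bohr effect) is quantified by the Bohr
coefficient

    phi = d(log10 P50) / d(pH),

negative for a normal (alkaline) Bohr effect; for a tetramer the number of
O2-linked protons released on full oxygenation is approximately 4*|phi|.

The temperature dependence gives the overall oxygenation enthalpy via the
integrated van't Hoff relation between two temperatures T1 > T2 (kelvin):

    dH = -4.574 * [T1*T2 / (T1 - T2)] * dlog10(P50) / 1000   (kcal/mol)

where 4.574 = R*ln(10) in cal mol^-1 K^-1 and dlog10 P50 = log10 P50(T1) -
log10 P50(T2).  This dH contains the heat of O2 solubilisation
(-3 kcal/mol); subtracting it ("corrected" value) gives the intrinsic heat
of oxygenation customarily tabulated.

Because both the van't Hoff plot (log10 P50 vs 1/T) and the Bohr plot
(log10 P50 vs pH) are linear over the ranges of interest, P50 can be
extrapolated to temperatures below the instrument's working range (e.g.
0 degrees C for a polar species) and shifted to a nearby pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputError, InsufficientDataError

__all__ = [
    "P50Grid",
    "LinkageResult",
    "bohr_coefficient",
    "protons_per_tetramer",
    "vant_hoff_dH",
    "extrapolate_p50",
    "VANT_HOFF_CONSTANT",
    "O2_SOLUBILISATION_DH",
]

# R * ln(10) in cal mol^-1 K^-1, kept at the conventional printed precision
VANT_HOFF_CONSTANT = 4.574
# heat of O2 solubilisation in water, kcal/mol
O2_SOLUBILISATION_DH = -3.0


class P50Grid:
    """P50 values indexed by (temperature, pH, ATP) for one Hb isoform.

    Thin wrapper around a pandas DataFrame with columns
    ``temperature_K, pH, ATP, P50_torr``; the substrate of every linkage
    computation.
    """

    COLUMNS = ("temperature_K", "pH", "ATP", "P50_torr")

    def __init__(self, entries, isoform: str = ""):
        if isinstance(entries, pd.DataFrame):
            df = entries.loc[:, list(self.COLUMNS)].copy()
        else:
            df = pd.DataFrame(list(entries), columns=list(self.COLUMNS))
        df["ATP"] = df["ATP"].astype(bool)
        if (df["P50_torr"] <= 0).any():
            raise InputError("P50 values must be positive")
        if df.duplicated(subset=["temperature_K", "pH", "ATP"]).any():
            raise InputError("duplicate (temperature, pH, ATP) keys in P50 grid")
        self.frame = df.reset_index(drop=True)
        self.isoform = isoform

    def select(self, pH=None, ATP=None, temperature_K=None) -> pd.DataFrame:
        df = self.frame
        if pH is not None:
            df = df[np.isclose(df["pH"], pH)]
        if ATP is not None:
            df = df[df["ATP"] == bool(ATP)]
        if temperature_K is not None:
            df = df[np.isclose(df["temperature_K"], temperature_K)]
        return df

    def __len__(self):
        return len(self.frame)


@dataclass(frozen=True)
class LinkageResult:
    """Bundle of linkage quantities for one isoform/condition set."""

    phi: float
    dH_raw: float
    dH_corrected: float
    protons_per_tetramer: float
    extrapolated: tuple = field(default_factory=tuple)  # (temperature_K, pH, P50)
    isoform: str = ""


def bohr_coefficient(P50_a: float, pH_a: float, P50_b: float, pH_b: float) -> float:
    """Two-point Bohr coefficient phi = dlog10(P50)/dpH."""
    if P50_a <= 0 or P50_b <= 0:
        raise DomainError("P50 values must be positive")
    if pH_a == pH_b:
        raise DomainError("Bohr coefficient undefined at equal pH")
    return float((np.log10(P50_a) - np.log10(P50_b)) / (pH_a - pH_b))


def bohr_coefficient_ols(P50s, pHs) -> float:
    """Least-squares Bohr coefficient from >= 2 (P50, pH) points."""
    P50s = np.asarray(P50s, dtype=float)
    pHs = np.asarray(pHs, dtype=float)
    if P50s.size < 2:
        raise InsufficientDataError("need at least two points for a Bohr plot")
    if np.any(P50s <= 0):
        raise DomainError("P50 values must be positive")
    slope, _ = np.polyfit(pHs, np.log10(P50s), 1)
    return float(slope)


def protons_per_tetramer(phi: float) -> float:
    """O2-linked protons released per tetramer, ~ 4*|phi|."""
    return 4.0 * abs(float(phi))


def vant_hoff_dH(P50_T1: float, T1: float, P50_T2: float, T2: float,
                 solubilisation_correction: float = O2_SOLUBILISATION_DH
                 ) -> tuple[float, float]:
    """Two-point van't Hoff oxygenation enthalpy in kcal/mol.

    Returns ``(dH_raw, dH_corrected)`` where the raw value follows the
    integrated van't Hoff formula and the corrected value removes the heat
    of O2 solubilisation: dH_corrected = dH_raw - correction (the default
    correction of -3 kcal/mol makes the corrected value 3 kcal/mol more
    positive).
    """
    if P50_T1 <= 0 or P50_T2 <= 0:
        raise DomainError("P50 values must be positive")
    if T1 <= 0 or T2 <= 0:
        raise DomainError("temperatures must be positive kelvin")
    if T1 == T2:
        raise DomainError("van't Hoff enthalpy undefined at equal temperatures")
    dlog = np.log10(P50_T1) - np.log10(P50_T2)
    dH_raw = -VANT_HOFF_CONSTANT * (T1 * T2 / (T1 - T2)) * dlog / 1000.0
    dH_corrected = dH_raw - solubilisation_correction
    return float(dH_raw), float(dH_corrected)


def vant_hoff_dH_ols(P50s, temperatures_K,
                     solubilisation_correction: float = O2_SOLUBILISATION_DH
                     ) -> tuple[float, float]:
    """van't Hoff enthalpy from >= 2 points by OLS on log10 P50 vs 1/T.

    The slope of log10 P50 against 1/T equals dH_raw * 1000 / 4.574 (with
    dH in kcal/mol), which the two-point formula reproduces exactly.
    """
    P50s = np.asarray(P50s, dtype=float)
    T = np.asarray(temperatures_K, dtype=float)
    if P50s.size < 2:
        raise InsufficientDataError("need at least two temperatures")
    if np.any(P50s <= 0) or np.any(T <= 0):
        raise DomainError("P50 and temperatures must be positive")
    # slope of log10 P50 vs 1/T equals dH_raw * 1000 / 4.574, so the OLS
    # path reduces exactly to the two-point formula when given two points
    slope, _ = np.polyfit(1.0 / T, np.log10(P50s), 1)
    dH_raw = slope * VANT_HOFF_CONSTANT / 1000.0
    dH_corrected = dH_raw - solubilisation_correction
    return float(dH_raw), float(dH_corrected)


def extrapolate_p50(grid: P50Grid, target_T: float, target_pH: float,
                    phi: float = 0.0, anchor_pH: float | None = None,
                    ATP: bool = False) -> float:
    """Extrapolate P50 to (target_T, target_pH) on linear van't Hoff/Bohr plots.

    Fits log10 P50 against 1/T through the grid entries at `anchor_pH` (by
    default the pH best represented in the grid) and the given ATP state,
    evaluates the line at `target_T`, then applies the Bohr shift
    phi * (target_pH - anchor_pH).
    """
    df = grid.select(ATP=ATP)
    if anchor_pH is None:
        counts = df.groupby("pH")["P50_torr"].count()
        if counts.empty:
            raise InsufficientDataError("grid has no entries for this ATP state")
        anchor_pH = float(counts.idxmax())
    sub = df[np.isclose(df["pH"], anchor_pH)]
    if len(sub) < 2:
        raise InsufficientDataError(
            f"need >= 2 temperatures at pH {anchor_pH} (found {len(sub)})"
        )
    slope, intercept = np.polyfit(1.0 / sub["temperature_K"].to_numpy(),
                                  np.log10(sub["P50_torr"].to_numpy()), 1)
    log_p50 = slope / target_T + intercept + phi * (target_pH - anchor_pH)
    return float(10 ** log_p50)
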