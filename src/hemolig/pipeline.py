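"""End-to-end synthetic analysis pipeline and report tables.

``run_pipeline`` chains the stages over the bundled isoform presets:
equilibrium curves are generated and Hill-fitted at 25 and 15 C (pH 7.4)
and at pH 6.7 (25 C), the fitted P50s feed the Bohr / van't Hoff linkage
computations including the 0 C extrapolation, photolysis trace pairs
(+/- ATP) are generated and globally fitted for R/T fractions and
bimolecular rate constants, and displacement/autoxidation traces yield
koff,R and kox.  Output is a pair of :class:`ReportTable` objects shaped
like the equilibrium and kinetic summary tables of a ligand-binding study.

Rounding (one decimal for P50 / dH / phi / nH, two significant figures for
rates) is applied only at serialisation; the in-memory tables keep full
precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .decay import fit_monoexp, initial_rate
from .equilibrium import HillCurve
from .exceptions import InputError
from .linkage import bohr_coefficient, extrapolate_p50, protons_per_tetramer, vant_hoff_dH
from .linkage import P50Grid
from .photolysis import global_fit, summarize
from .synthetic import (
    P50_15C,
    P50_PH67_25C,
    PRESETS,
    simulate_autoxidation,
    simulate_displacement,
    simulate_equilibrium_curve,
    simulate_photolysis_trace,
)

__all__ = ["ReportTable", "run_pipeline", "write_report"]

logger = logging.getLogger("hemolig")

EQUILIBRIUM_COLUMNS = [
    "isoform", "ATP", "P50_torr_25C", "nH_25C", "P50_torr_15C", "nH_15C",
    "dH_kcal_mol", "phi", "P50_torr_0C", "koff_R_per_s", "kox_per_min",
]
KINETIC_COLUMNS = ["isoform", "ATP", "R_pct", "T_pct", "kon_R_M_s", "kon_T_M_s"]

ONE_DECIMAL = {"P50_torr_25C", "nH_25C", "P50_torr_15C", "nH_15C",
               "dH_kcal_mol", "phi", "P50_torr_0C", "R_pct", "T_pct"}
TWO_SIGFIG = {"koff_R_per_s", "kox_per_min", "kon_R_M_s", "kon_T_M_s"}


@dataclass(frozen=True)
class ReportTable:
    """A fixed-schema result table ('equilibrium' or 'kinetics' layout)."""

    kind: str
    frame: pd.DataFrame

    def __post_init__(self):
        cols = {"equilibrium": EQUILIBRIUM_COLUMNS, "kinetics": KINETIC_COLUMNS}
        if self.kind not in cols:
            raise InputError(f"unknown report kind {self.kind!r}")
        missing = [c for c in cols[self.kind] if c not in self.frame.columns]
        if missing:
            raise InputError(f"report frame missing columns {missing}")
        object.__setattr__(self, "frame",
                           self.frame.loc[:, cols[self.kind]].reset_index(drop=True))

    def rounded(self) -> pd.DataFrame:
        """Apply the serialisation rounding rules; in-memory data untouched."""
        df = self.frame.copy()
        for c in df.columns:
            if c in ONE_DECIMAL:
                df[c] = df[c].round(1)
            elif c in TWO_SIGFIG:
                df[c] = df[c].map(_round_2sf)
        return df


def _round_2sf(x):
    if x is None or not np.isfinite(x) or x == 0:
        return x
    return float(f"{x:.2g}")


def write_report(table: ReportTable, path, format: str = "csv") -> None:
    """Serialise a report with the rounding rules applied."""
    if len(table.frame) == 0:
        raise InputError("refusing to write an empty report")
    df = table.rounded()
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise InputError(f"unknown report format {format!r}; use 'csv' or 'json'")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict[str, ReportTable]:
    """Run the full synthetic-scenario analysis.

    Config keys: ``seed`` (int, required), ``isoforms`` (list of labels,
    default all three), ``noise_Y`` / ``noise_N`` / ``noise_A`` (floats),
    ``geminate_amplitude`` (fraction of total, default 0.08).  Deterministic
    given config: every stage draws from seeds spawned from ``seed``.
    """
    if not isinstance(config, dict) or "seed" not in config:
        missing = ["seed"] if isinstance(config, dict) else ["<mapping>"]
        raise InputError(f"invalid pipeline config; missing {missing}")
    seed = int(config["seed"])
    isoforms = list(config.get("isoforms", ["Hb 1", "Hb 2", "Hb 3"]))
    noise_y = float(config.get("noise_Y", 0.01))
    noise_n = float(config.get("noise_N", 0.01))
    noise_a = float(config.get("noise_A", 0.005))
    gem_amp = float(config.get("geminate_amplitude", 0.08))

    logger.info("pipeline start: version=%s config_hash=%s seed=%d",
                __version__, _config_hash(config), seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(512))

    eq_rows, kin_rows = [], []
    presets = {k: v for k, v in PRESETS.items() if v.isoform in isoforms}
    if not presets:
        raise InputError(f"no presets match isoforms {isoforms}")

    for key, preset in presets.items():
        iso, atp = preset.isoform, preset.atp
        # --- equilibrium: 25 C / 15 C pH 7.4 and 25 C pH 6.7 -------------
        fits = {}
        for tag, (p50, nh) in {
            "25C": (preset.P50_torr, preset.nH),
            "15C": P50_15C[(iso, atp)],
            "ph67": P50_PH67_25C[(iso, atp)],
        }.items():
            curve = simulate_equilibrium_curve(p50, nh, steps=5, noise_sd=noise_y,
                                               seed=next(child_seeds))
            fits[tag] = HillCurve().fit(curve.pO2_torr, curve.saturation)
            logger.info("%s %s: Hill fit P50=%.3f nH=%.3f", key, tag,
                        fits[tag].p50_, fits[tag].nh_)

        # --- linkage ------------------------------------------------------
        _, dh_corr = vant_hoff_dH(fits["25C"].p50_, 298.15, fits["15C"].p50_, 288.15)
        phi = bohr_coefficient(fits["25C"].p50_, 7.4, fits["ph67"].p50_, 6.7)
        grid = P50Grid(
            [(298.15, 7.4, atp, fits["25C"].p50_), (288.15, 7.4, atp, fits["15C"].p50_)],
            isoform=iso,
        )
        p50_0c = extrapolate_p50(grid, 273.15, 7.4, phi=phi, anchor_pH=7.4, ATP=atp)

        # --- displacement and autoxidation (stripped-row quantities) ------
        duration = max(5.0 / preset.koff_R, 0.5)
        disp = simulate_displacement(preset.koff_R, duration_s=duration,
                                     noise_sd=noise_a, seed=next(child_seeds))
        koff, _ = fit_monoexp(disp)
        autox = simulate_autoxidation(preset.kox_per_min, noise_sd=noise_a,
                                      seed=next(child_seeds))
        kox = initial_rate(autox)

        eq_rows.append({
            "isoform": iso, "ATP": atp,
            "P50_torr_25C": fits["25C"].p50_, "nH_25C": fits["25C"].nh_,
            "P50_torr_15C": fits["15C"].p50_, "nH_15C": fits["15C"].nh_,
            "dH_kcal_mol": dh_corr, "phi": phi, "P50_torr_0C": p50_0c,
            "koff_R_per_s": koff, "kox_per_min": kox,
            "protons_per_tetramer": protons_per_tetramer(phi),
        })

    # --- flash photolysis: +/- ATP pair per isoform, global fit ----------
    for iso in isoforms:
        stripped = PRESETS[f"hb{iso[-1]}_stripped"]
        with_atp = PRESETS[f"hb{iso[-1]}_atp"]
        traces = [
            simulate_photolysis_trace(p.rebinding_model(1.0, gem_amp), co_atm=1.0,
                                      noise_sd=noise_n, seed=next(child_seeds),
                                      condition=p.condition())
            for p in (stripped, with_atp)
        ]
        gf = global_fit(traces)
        for p, model in zip((stripped, with_atp), gf.models):
            s = summarize(model, gf.co_M[0], isoform=iso, condition=p.condition())
            kin_rows.append({
                "isoform": iso, "ATP": p.atp, "R_pct": s.fR_pct, "T_pct": s.fT_pct,
                "kon_R_M_s": gf.kon_R, "kon_T_M_s": gf.kon_T,
            })
            logger.info("%s ATP=%s: R=%.1f%% T=%.1f%% konR=%.3g konT=%.3g",
                        iso, p.atp, s.fR_pct, s.fT_pct, gf.kon_R, gf.kon_T)

    eq = ReportTable("equilibrium", pd.DataFrame(eq_rows))
    kin = ReportTable("kinetics", pd.DataFrame(kin_rows))
    return {"equilibrium": eq, "kinetics": kin}
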