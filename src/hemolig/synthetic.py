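"""Synthetic instrument traces with the statistical structure of the assays.

Every input the analysis pipeline consumes can be generated here: Gaussian-
band reference spectra (Soret region), Hill-shaped O2-equilibrium curves
sampled at 4-6 saturation steps between ~20 and 80%, flash-photolysis
rebinding decays (two stretched-exponential geminate terms plus R/T
bimolecular exponentials) on a log-spaced time grid, mono-exponential
stopped-flow displacement traces, and saturating-exponential autoxidation
time courses.  Noise is additive Gaussian, homoscedastic per signal type
(default sd: 0.01 on saturation and deoxy fraction, 0.002 AU on absorbance).

Generators are pure functions of their arguments including the seed, so
regeneration is bit-reproducible.  The bundled :data:`PRESETS` carry the
measured parameter sets of the three Greenland-shark Hb isoforms at 25 C,
pH 7.4 (P50/nH with and without ATP, koff,R, kox, R/T fractions and
bimolecular rate constants), so the report layer can emit synthetic
equilibrium and kinetic tables for comparison.  Geminate parameters were
never published; the defaults (8% total amplitude, lifetimes 100 ns and
1 us, beta 0.8) are declared assumptions of the generator, not measured
facts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay import AutoxSeries, DisplacementTrace
from .equilibrium import Condition, EquilibriumCurve
from .exceptions import DegenerateBasisError, InputError
from .photolysis import (
    BimolecularComponent,
    GeminateComponent,
    PhotolysisTrace,
    RebindingModel,
    co_concentration,
    model_eval,
)
from .spectra import ReferenceBasis, Spectrum

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "DEFAULT_PEAKS",
    "default_geminate",
    "make_reference_basis",
    "simulate_equilibrium_curve",
    "simulate_photolysis_trace",
    "simulate_displacement",
    "simulate_autoxidation",
    "autox_spectra",
]

# Soret/Q-band Gaussian peaks per species: (center nm, width nm, height AU).
# Band positions anchor to the monitoring wavelengths of the assays:
# 405 nm met Soret, 430/436 nm deoxy Soret region, 540/569 nm CO/oxy Q bands.
DEFAULT_PEAKS = {
    "oxy": [(415.0, 9.0, 1.00), (541.0, 8.0, 0.13), (577.0, 8.0, 0.14)],
    "deoxy": [(430.0, 11.0, 1.10), (555.0, 10.0, 0.12)],
    "met": [(405.0, 9.0, 1.50), (500.0, 12.0, 0.09), (630.0, 10.0, 0.04)],
}

# declared generator assumptions: small-amplitude geminate phase
GEMINATE_DEFAULT = ((0.04, 1e-7, 0.8), (0.04, 1e-6, 0.8))


def default_geminate(total_amplitude: float = 0.08) -> tuple[GeminateComponent, ...]:
    """The generator's geminate assumption scaled to a total amplitude."""
    scale = total_amplitude / sum(a for a, _, _ in GEMINATE_DEFAULT)
    return tuple(GeminateComponent(a * scale, tau, b) for a, tau, b in GEMINATE_DEFAULT)


@dataclass(frozen=True)
class ScenarioPreset:
    """Generator parameter set for one isoform/condition (a table row).

    Hill parameters and rates are the measured 25 C, pH 7.4 values for the
    isoform; `fR_pct` and the kon constants come from the kinetic table.
    """

    isoform: str
    atp: bool
    P50_torr: float
    nH: float
    fR_pct: float
    kon_R: float                # M^-1 s^-1
    kon_T: float                # M^-1 s^-1
    koff_R: float               # s^-1
    kox_per_min: float
    temperature_K: float = 298.15
    pH: float = 7.4
    noise_Y: float = 0.01
    noise_N: float = 0.01
    noise_AU: float = 0.002

    def condition(self) -> Condition:
        return Condition(temperature_K=self.temperature_K, pH=self.pH,
                         ATP_mM=2.0 if self.atp else 0.0, label=self.isoform)

    def rebinding_model(self, co_atm: float = 1.0,
                        geminate_amplitude: float = 0.08) -> RebindingModel:
        """Rebinding model at a given CO pressure, total amplitude 1."""
        co = co_concentration(co_atm, self.temperature_K)
        bim_total = 1.0 - geminate_amplitude
        ar = bim_total * self.fR_pct / 100.0
        at = bim_total - ar
        # a zero amplitude is represented as exactly 0 (degenerate R or T)
        return RebindingModel(
            geminate=default_geminate(geminate_amplitude),
            R=BimolecularComponent(ar, self.kon_R * co),
            T=BimolecularComponent(at, self.kon_T * co),
        )


# Measured parameter sets, 25 C, pH 7.4, 100 mM KCl (equilibrium: stripped
# and +2 mM ATP; kinetics at 1 atm CO).  koff,R at pH 6.5; kox at pH 7.45.
PRESETS: dict[str, ScenarioPreset] = {
    "hb1_stripped": ScenarioPreset("Hb 1", False, 5.5, 1.2, 84.0, 9.4e5, 2.4e5, 13.1, 2.2e-4),
    "hb1_atp": ScenarioPreset("Hb 1", True, 14.4, 1.8, 22.0, 9.4e5, 2.4e5, 10.5, 2.2e-4),
    "hb2_stripped": ScenarioPreset("Hb 2", False, 5.7, 1.6, 100.0, 7.0e5, 1.8e5, 7.1, 3.1e-4),
    "hb2_atp": ScenarioPreset("Hb 2", True, 12.5, 1.8, 12.0, 7.0e5, 1.8e5, 6.6, 3.1e-4),
    "hb3_stripped": ScenarioPreset("Hb 3", False, 7.7, 1.4, 92.0, 7.3e5, 2.8e5, 35.1, 3.9e-4),
    "hb3_atp": ScenarioPreset("Hb 3", True, 13.3, 1.9, 13.0, 7.3e5, 2.8e5, 33.3, 3.9e-4),
}

# 15 C, pH 7.4 equilibrium parameters for the same isoforms, used by the
# linkage stage of the pipeline (van't Hoff pairs with the 25 C presets).
P50_15C = {
    ("Hb 1", False): (2.9, 1.5), ("Hb 1", True): (11.6, 2.1),
    ("Hb 2", False): (2.8, 1.6), ("Hb 2", True): (9.2, 1.9),
    ("Hb 3", False): (3.9, 1.8), ("Hb 3", True): (10.6, 2.0),
}

# 25 C, pH 6.7 equilibrium parameters (low-pH arm of the Bohr comparison)
P50_PH67_25C = {
    ("Hb 1", False): (8.9, 1.4), ("Hb 1", True): (46.1, 1.6),
    ("Hb 2", False): (8.7, 1.9), ("Hb 2", True): (40.8, 1.6),
    ("Hb 3", False): (11.6, 1.7), ("Hb 3", True): (36.2, 1.7),
}


def _gaussian_sum(grid, peaks):
    ab = np.zeros_like(grid)
    for center, width, height in peaks:
        ab += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return ab


def make_reference_basis(peak_spec: dict | None = None,
                         grid: np.ndarray | None = None) -> ReferenceBasis:
    """Smooth Gaussian-sum reference spectra on a common 1-nm grid.

    `peak_spec` maps species name -> list of (center nm, width nm, height
    AU); peaks must lie inside 350-700 nm and the species must be mutually
    distinguishable (pairwise cosine similarity < 0.999 on the grid).
    """
    peaks = peak_spec if peak_spec is not None else DEFAULT_PEAKS
    if len(peaks) < 2:
        raise DegenerateBasisError("need at least two species for a basis")
    for name, plist in peaks.items():
        for center, width, height in plist:
            if not 350.0 <= center <= 700.0:
                raise InputError(f"{name}: peak center {center} nm outside 350-700 nm")
            if width <= 0 or height <= 0:
                raise InputError(f"{name}: peak width and height must be positive")
    g = np.arange(380.0, 500.0 + 1e-9, 1.0) if grid is None else np.asarray(grid, float)
    refs = {name: Spectrum(g, _gaussian_sum(g, plist), label=name)
            for name, plist in peaks.items()}
    names = list(refs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = refs[names[i]].absorbances
            b = refs[names[j]].absorbances
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            if cos >= 0.999:
                raise DegenerateBasisError(
                    f"references {names[i]!r} and {names[j]!r} are indistinguishable "
                    f"(cosine similarity {cos:.5f})"
                )
    return ReferenceBasis(refs)


def simulate_equilibrium_curve(P50: float, n: float, steps: int = 5,
                               y_range: tuple[float, float] = (0.2, 0.8),
                               noise_sd: float = 0.0, seed: int = 0,
                               condition: Condition | None = None) -> EquilibriumCurve:
    """Sample an equilibrium curve at evenly spaced target saturations.

    pO2 values are the exact Hill inverse of the noiseless target Y
    (pO2 = P50 * (Y/(1-Y))^(1/n)); Gaussian noise of standard deviation
    `noise_sd` is then added to Y only, mimicking a measurement whose
    pressure axis is set by the gas mixer and whose error is in the optical
    saturation readout.
    """
    if P50 <= 0 or n <= 0:
        raise InputError("P50 and n must be positive")
    if not 4 <= steps <= 24:
        raise InputError("steps should be a small count (4-24)")
    if noise_sd >= 0.25:
        raise InputError("noise sd >= 0.25 on a [0,1] saturation is non-physical")
    y_target = np.linspace(y_range[0], y_range[1], steps)
    pO2 = P50 * (y_target / (1.0 - y_target)) ** (1.0 / n)
    rng = np.random.default_rng(seed)
    y = y_target + rng.normal(0.0, noise_sd, size=steps) if noise_sd > 0 else y_target
    y = np.clip(y, 1e-6, 1 - 1e-6)
    return EquilibriumCurve(pO2, y, condition=condition)


def simulate_photolysis_trace(model: RebindingModel, co_atm: float = 1.0,
                              t_span: tuple[float, float] = (1e-8, 1.0),
                              points_per_decade: int = 40,
                              noise_sd: float = 0.0, seed: int = 0,
                              condition: Condition | None = None) -> PhotolysisTrace:
    """Evaluate a rebinding model on a log-spaced grid and add noise.

    The trace is normalised to its first sample (N(first) = 1, as a
    photolysis trace is normalised to the prompt absorbance change); noise
    is added afterwards and the trace is *not* renormalised, so the
    noiseless trace round-trips exactly.
    """
    lo, hi = t_span
    if not 0 < lo < hi:
        raise InputError("time span must be positive and increasing")
    n_points = int(np.round(np.log10(hi / lo) * points_per_decade)) + 1
    if n_points < 2:
        raise InputError("empty time grid")
    t = np.geomspace(lo, hi, n_points)
    if model.total_amplitude <= 0:
        raise InputError("model has zero total amplitude")
    n = model_eval(t, model)
    n = n / n[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n = n + rng.normal(0.0, noise_sd, size=n.size)
    return PhotolysisTrace(t, n, co_atm=co_atm, condition=condition)


def simulate_displacement(koff: float, duration_s: float = 1.0,
                          n_samples: int = 500, noise_sd: float = 0.0,
                          seed: int = 0, a_inf: float = 0.40,
                          delta_a: float = 0.50,
                          condition: Condition | None = None) -> DisplacementTrace:
    """Mono-exponential A420 displacement trace A(t) = A_inf + dA e^(-koff t)."""
    if koff <= 0:
        raise InputError("koff must be positive")
    if duration_s <= 0:
        raise InputError("duration must be positive")
    t = np.linspace(0.0, duration_s, n_samples)
    a = a_inf + delta_a * np.exp(-koff * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.size)
    return DisplacementTrace(t, a, condition=condition)


def simulate_autoxidation(kox: float, duration_min: float = 1200.0,
                          dt_min: float = 30.0, noise_sd: float = 0.0,
                          seed: int = 0) -> AutoxSeries:
    """Saturating-exponential met-fraction time course f(t) = 1 - e^(-kox t).

    Default cadence matches a 20-hour run sampled every 30 minutes.  The
    first timepoint is dt (not zero): the normalising reference spectrum
    defines fraction 0 at t = 0.
    """
    if kox <= 0:
        raise InputError("kox must be positive")
    if duration_min <= 0:
        raise InputError("duration must be positive")
    t = np.arange(dt_min, duration_min + 1e-9, dt_min)
    f = 1.0 - np.exp(-kox * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=f.size), 0.0, 1.0)
    return AutoxSeries(t, f)


def autox_spectra(series: AutoxSeries, basis: ReferenceBasis,
                  noise_sd: float = 0.0, seed: int = 0) -> list[Spectrum]:
    """Raw spectra for an autoxidation series: (1-f)*oxy + f*met + noise."""
    oxy = basis.references["oxy"]
    met = basis.references["met"]
    rng = np.random.default_rng(seed)
    out = []
    for tm, f in zip(series.times_min, series.met_fraction):
        ab = (1.0 - f) * oxy.absorbances + f * met.absorbances
        if noise_sd > 0:
            ab = ab + rng.normal(0.0, noise_sd, size=ab.size)
        out.append(Spectrum(basis.grid, ab, label=f"t={tm:g}min"))
    return out
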