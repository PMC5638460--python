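"""Laser flash-photolysis CO-rebinding kinetics and R/T decomposition.

After a nanosecond photolysis pulse, the surviving deoxy fraction N(t) of a
CO-ligated tetrameric hemoglobin decays by (i) geminate recombination from
inside the protein matrix on the ns-us scale, CO-concentration independent
and well described by stretched exponentials, and (ii) bimolecular rebinding
from solvent on the us-ms scale.  Because the R->T quaternary switch proceeds
during the bimolecular phase, that phase splits into a fast exponential
(rebinding to R-state molecules) and a slow one (molecules that switched to
T), giving the model

    N(t) = sum_i A_i exp[-(t/tau_i)^beta_i]            (2 geminate terms)
         + A_R exp(-k_R t) + A_T exp(-k_T t)           (bimolecular)

with beta in (0, 1] (beta = 1 recovers a plain exponential).  The relative
bimolecular amplitudes give the R/T populations at the moment of rebinding,
f_R = 100*A_R/(A_R + A_T), and the apparent rates divided by the free CO
concentration give the bimolecular rate constants k_on,R = k_R/[CO],
k_on,T = k_T/[CO].  A global fit across traces at different CO pressures
(and +/- allosteric effector) shares the rate parameters while leaving the
amplitudes free: effectors shift the R/T populations, not the rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .equilibrium import Condition
from .exceptions import (
    DomainError,
    FitError,
    InputError,
    InsufficientDataError,
    OutOfRangeError,
)

__all__ = [
    "GeminateComponent",
    "BimolecularComponent",
    "RebindingModel",
    "PhotolysisTrace",
    "KineticSummary",
    "GlobalFitResult",
    "RebindingDecay",
    "model_eval",
    "fit_trace",
    "global_fit",
    "rt_fractions",
    "bimolecular_constants",
    "co_concentration",
    "compare_conditions",
    "summarize",
    "CO_SOLUBILITY_M_PER_ATM",
]

# approximate aqueous CO solubility (Henry's law, M atm^-1); configurable
CO_SOLUBILITY_M_PER_ATM = {
    288.15: 1.15e-3,   # 15 C
    293.15: 1.06e-3,   # 20 C
    298.15: 9.8e-4,    # 25 C
}

# parameter bounds keeping the geminate and bimolecular phases separated
BETA_BOUNDS = (0.3, 1.0)
TAU_BOUNDS = (1e-9, 1e-4)       # s, geminate lifetimes
RATE_BOUNDS = (1.0, 1e6)        # s^-1, bimolecular apparent rates


@dataclass(frozen=True)
class GeminateComponent:
    """One stretched-exponential geminate term A*exp[-(t/tau)^beta]."""

    amplitude: float
    tau_s: float
    beta: float = 1.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InputError("geminate amplitude must be nonnegative")
        if self.tau_s <= 0:
            raise InputError("geminate lifetime must be positive")
        if not 0 < self.beta <= 1:
            raise InputError("stretch exponent beta must lie in (0, 1]")


@dataclass(frozen=True)
class BimolecularComponent:
    """One exponential bimolecular term A*exp(-k t)."""

    amplitude: float
    rate_per_s: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise InputError("bimolecular amplitude must be nonnegative")
        if self.rate_per_s <= 0:
            raise InputError("bimolecular rate must be positive")


@dataclass(frozen=True)
class RebindingModel:
    """2-stretched + 2-exponential parameterisation of a rebinding decay.

    R is the fast bimolecular component, T the slow one; the constructor
    relabels (swaps) them if supplied the other way round so that
    ``R.rate_per_s > T.rate_per_s`` always holds.
    """

    geminate: tuple[GeminateComponent, ...]
    R: BimolecularComponent
    T: BimolecularComponent

    def __post_init__(self):
        gem = tuple(self.geminate)
        object.__setattr__(self, "geminate", gem)
        if self.T.rate_per_s > self.R.rate_per_s:
            R, T = self.T, self.R
            object.__setattr__(self, "R", R)
            object.__setattr__(self, "T", T)

    @property
    def total_amplitude(self) -> float:
        return sum(g.amplitude for g in self.geminate) + self.R.amplitude + self.T.amplitude

    @property
    def geminate_amplitude(self) -> float:
        return sum(g.amplitude for g in self.geminate)

    def scaled(self, factor: float) -> "RebindingModel":
        """All amplitudes multiplied by `factor` (rates untouched)."""
        return RebindingModel(
            geminate=tuple(replace(g, amplitude=g.amplitude * factor) for g in self.geminate),
            R=replace(self.R, amplitude=self.R.amplitude * factor),
            T=replace(self.T, amplitude=self.T.amplitude * factor),
        )


@dataclass(frozen=True)
class PhotolysisTrace:
    """A normalised rebinding decay with its CO pressure and condition."""

    times_s: np.ndarray
    N: np.ndarray
    co_atm: float
    condition: Condition | None = None

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        n = np.asarray(self.N, dtype=float)
        if t.ndim != 1 or n.shape != t.shape:
            raise InputError("times and N must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(n)):
            raise InputError("N must be finite")
        if n.max() > 1.2 or n.min() < -0.2:
            raise InputError("N is a normalised deoxy fraction; values far outside [0, 1]")
        if self.co_atm <= 0:
            raise InputError("CO partial pressure must be positive")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "N", n)

    @property
    def decades(self) -> float:
        return float(np.log10(self.times_s[-1] / self.times_s[0]))


@dataclass(frozen=True)
class KineticSummary:
    """Table-row analogue: R/T percentages and bimolecular rate constants."""

    fR_pct: float
    fT_pct: float
    kon_R: float                 # M^-1 s^-1
    kon_T: float                 # M^-1 s^-1
    geminate_pct: float          # % of total amplitude
    co_M: float                  # [CO] used for the kon conversion
    isoform: str = ""
    condition: Condition | None = None

    def __post_init__(self):
        if abs(self.fR_pct + self.fT_pct - 100.0) > 0.1:
            raise InputError("fR + fT must equal 100 within 0.1")
        if self.kon_R < self.kon_T:
            raise InputError("kon_R must exceed kon_T (R is the fast state)")


def model_eval(t, model: RebindingModel):
    """Evaluate the rebinding model N(t); vectorised, t >= 0 in seconds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be nonnegative")
    out = np.zeros_like(t, dtype=float)
    for g in model.geminate:
        out += g.amplitude * np.exp(-((t / g.tau_s) ** g.beta))
    out += model.R.amplitude * np.exp(-model.R.rate_per_s * t)
    out += model.T.amplitude * np.exp(-model.T.rate_per_s * t)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# single-trace fitting
# --------------------------------------------------------------------------

_GEMINATE_SPLIT_S = 1e-4  # boundary between geminate and bimolecular windows


def _tail_biexp_init(t, n):
    """Crude two-exponential init for the bimolecular tail (deterministic)."""
    n0 = max(n[0], 1e-6)
    # time at which the tail has decayed to half / to 1/10 of its start
    def crossing(frac):
        idx = np.nonzero(n <= frac * n0)[0]
        return t[idx[0]] if idx.size else t[-1]

    k_fast = 1.0 / max(crossing(0.5), t[0])
    k_slow = 1.0 / max(crossing(0.1), t[0])
    if k_slow >= k_fast:
        k_slow = k_fast / 5.0
    return 0.5 * n0, k_fast, 0.5 * n0, k_slow


def _default_init(trace: PhotolysisTrace, n_geminate: int) -> RebindingModel:
    t, n = trace.times_s, trace.N
    tail = t >= _GEMINATE_SPLIT_S
    if tail.sum() < 5:
        tail = t >= t[len(t) // 2]
    ar, kr, at, kt = _tail_biexp_init(t[tail], n[tail])
    gem_amp = max(n[0] - (ar + at), 0.01)
    taus = np.geomspace(1e-7, 1e-6, n_geminate)
    gem = tuple(
        GeminateComponent(gem_amp / n_geminate, float(tau), 0.9) for tau in taus
    )
    kr = float(np.clip(kr, *RATE_BOUNDS))
    kt = float(np.clip(kt, RATE_BOUNDS[0], kr * 0.99))
    return RebindingModel(
        geminate=gem,
        R=BimolecularComponent(ar, kr),
        T=BimolecularComponent(at, kt),
    )


def _model_to_params(model: RebindingModel) -> lmfit.Parameters:
    p = lmfit.Parameters()
    for i, g in enumerate(model.geminate):
        p.add(f"ag{i}", value=g.amplitude, min=0.0, max=2.0)
        p.add(f"ltau{i}", value=np.log10(g.tau_s),
              min=np.log10(TAU_BOUNDS[0]), max=np.log10(TAU_BOUNDS[1]))
        p.add(f"beta{i}", value=min(max(g.beta, BETA_BOUNDS[0] + 1e-6), 1.0),
              min=BETA_BOUNDS[0], max=BETA_BOUNDS[1])
    p.add("ar", value=model.R.amplitude, min=0.0, max=2.0)
    p.add("lkr", value=np.log10(model.R.rate_per_s),
          min=np.log10(RATE_BOUNDS[0]), max=np.log10(RATE_BOUNDS[1]))
    p.add("at", value=model.T.amplitude, min=0.0, max=2.0)
    p.add("lkt", value=np.log10(model.T.rate_per_s),
          min=np.log10(RATE_BOUNDS[0]), max=np.log10(RATE_BOUNDS[1]))
    return p


def _params_to_model(p, n_geminate: int) -> RebindingModel:
    gem = tuple(
        GeminateComponent(
            amplitude=float(p[f"ag{i}"]),
            tau_s=float(10 ** float(p[f"ltau{i}"])),
            beta=float(p[f"beta{i}"]),
        )
        for i in range(n_geminate)
    )
    return RebindingModel(
        geminate=gem,
        R=BimolecularComponent(float(p["ar"]), float(10 ** float(p["lkr"]))),
        T=BimolecularComponent(float(p["at"]), float(10 ** float(p["lkt"]))),
    )


class RebindingDecay(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of the 2-stretched + 2-exponential model.

    Samples are assumed log-spaced in time (standard practice over nine
    decades) and weighted uniformly, which equalises leverage per decade.

    Parameters
    ----------
    n_geminate : int, default 2
        Number of stretched-exponential geminate terms (1 available for
        low-SNR traces).
    init : RebindingModel or None
        Starting model; a deterministic heuristic (tail two-exponential
        peel + small geminate seed) is used when None.

    Attributes
    ----------
    model_ : RebindingModel
    converged_ : bool
    uncertainties_ : dict
        1-sigma standard errors per named parameter (where estimable).
    boundary_warnings_ : tuple of str
        E.g. a stretch exponent pinned at its bound.
    """

    def __init__(self, n_geminate: int = 2, init: RebindingModel | None = None):
        self.n_geminate = n_geminate
        self.init = init

    def fit(self, times_s, N, co_atm: float = 1.0) -> "RebindingDecay":
        t = np.asarray(times_s, dtype=float).ravel()
        n = np.asarray(N, dtype=float).ravel()
        trace = PhotolysisTrace(t, n, co_atm)
        if t.size < 50:
            raise InsufficientDataError("need >= 50 samples for a rebinding fit")
        if trace.decades < 5:
            raise InsufficientDataError("trace must span at least 5 time decades")

        init = self.init if self.init is not None else _default_init(trace, self.n_geminate)
        if len(init.geminate) != self.n_geminate:
            raise InputError("init model has the wrong number of geminate terms")
        params = _model_to_params(init)

        def resid(p):
            return model_eval(t, _params_to_model(p, self.n_geminate)) - n

        out = lmfit.minimize(resid, params, method="least_squares",
                             xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=30000)
        model = _params_to_model(out.params, self.n_geminate)
        warns = []
        # when the true slow amplitude is ~0 the two bimolecular rates
        # collapse and their amplitude split becomes a flat direction the
        # solver cannot resolve: merge into the fast (R) component
        collapsed = (model.R.rate_per_s - model.T.rate_per_s
                     < 0.05 * model.R.rate_per_s)
        if not out.success and not collapsed:
            raise FitError("rebinding fit did not converge",
                           diagnostics={"message": out.message, "last": model})
        if collapsed:
            a_tot = model.R.amplitude + model.T.amplitude
            k = ((model.R.amplitude * model.R.rate_per_s
                  + model.T.amplitude * model.T.rate_per_s) / a_tot
                 if a_tot > 0 else model.R.rate_per_s)
            model = RebindingModel(
                geminate=model.geminate,
                R=BimolecularComponent(a_tot, k),
                T=BimolecularComponent(0.0, k / 2.0),
            )
            warns.append("bimolecular rates indistinguishable; "
                         "amplitude assigned to the fast (R) component")
        self.model_ = model
        self.converged_ = True
        self.uncertainties_ = {
            name: (float(par.stderr) if par.stderr is not None else float("nan"))
            for name, par in out.params.items()
        }
        for i in range(self.n_geminate):
            b = out.params[f"beta{i}"].value
            if abs(b - BETA_BOUNDS[0]) < 1e-6:
                warns.append(f"beta{i} pinned at lower bound {BETA_BOUNDS[0]}")
        self.boundary_warnings_ = tuple(warns)
        self.residual_rms_ = float(np.sqrt(np.mean(resid(out.params) ** 2)))
        return self

    def predict(self, times_s):
        return model_eval(np.asarray(times_s, dtype=float), self.model_)


def fit_trace(trace: PhotolysisTrace, init: RebindingModel | None = None,
              n_geminate: int = 2) -> RebindingModel:
    """Fit one photolysis trace; returns the fitted RebindingModel."""
    est = RebindingDecay(n_geminate=n_geminate, init=init)
    est.fit(trace.times_s, trace.N, trace.co_atm)
    return est.model_


# --------------------------------------------------------------------------
# global fitting across CO pressures / effector conditions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalFitResult:
    """Shared-rate global fit output: per-trace models + shared constants."""

    models: tuple[RebindingModel, ...]
    kon_R: float                # M^-1 s^-1, shared
    kon_T: float                # M^-1 s^-1, shared
    co_M: tuple[float, ...]     # per-trace CO molarity used
    converged: bool
    residual_rms: float


def global_fit(traces: Sequence[PhotolysisTrace], n_geminate: int = 2,
               solubility_table: dict | None = None) -> GlobalFitResult:
    """Globally fit traces sharing geminate rates and kon_R/kon_T.

    Amplitudes stay free per trace (allosteric effectors shift the R/T
    populations, not the rate constants); each trace's bimolecular apparent
    rates are constrained to kon * [CO] with [CO] from its CO pressure via
    Henry's law.  All traces must share temperature and pH.
    """
    traces = list(traces)
    if not traces:
        raise InputError("no traces supplied")
    conds = [tr.condition for tr in traces]
    if any(c is not None for c in conds):
        keys = {(round(c.temperature_K, 6), round(c.pH, 6)) for c in conds if c is not None}
        if len(keys) > 1:
            raise InputError("global fit requires a shared temperature and pH")
    temperature = next((c.temperature_K for c in conds if c is not None), 298.15)
    co = [co_concentration(tr.co_atm, temperature, solubility_table) for tr in traces]

    # per-trace fits provide the initialisation
    singles = [fit_trace(tr, n_geminate=n_geminate) for tr in traces]
    if len(traces) == 1:
        m = singles[0]
        return GlobalFitResult(
            models=(m,), kon_R=m.R.rate_per_s / co[0], kon_T=m.T.rate_per_s / co[0],
            co_M=tuple(co), converged=True, residual_rms=float("nan"),
        )

    p = lmfit.Parameters()
    kon_r0 = float(np.mean([m.R.rate_per_s / c for m, c in zip(singles, co)]))
    kon_t0 = float(np.mean([m.T.rate_per_s / c for m, c in zip(singles, co)]))
    p.add("lkon_r", value=np.log10(kon_r0), min=2.0, max=10.0)
    p.add("lkon_t", value=np.log10(max(kon_t0, 1e2)), min=2.0, max=10.0)
    for j in range(n_geminate):
        tau0 = float(np.mean([m.geminate[j].tau_s for m in singles]))
        beta0 = float(np.mean([m.geminate[j].beta for m in singles]))
        p.add(f"ltau{j}", value=np.log10(tau0),
              min=np.log10(TAU_BOUNDS[0]), max=np.log10(TAU_BOUNDS[1]))
        p.add(f"beta{j}", value=min(max(beta0, BETA_BOUNDS[0] + 1e-6), 1.0),
              min=BETA_BOUNDS[0], max=BETA_BOUNDS[1])
    for i, m in enumerate(singles):
        for j in range(n_geminate):
            p.add(f"ag{j}_{i}", value=m.geminate[j].amplitude, min=0.0, max=2.0)
        p.add(f"ar_{i}", value=m.R.amplitude, min=0.0, max=2.0)
        p.add(f"at_{i}", value=m.T.amplitude, min=0.0, max=2.0)

    def build(pars, i):
        gem = tuple(
            GeminateComponent(float(pars[f"ag{j}_{i}"]), float(10 ** float(pars[f"ltau{j}"])),
                              float(pars[f"beta{j}"]))
            for j in range(n_geminate)
        )
        return RebindingModel(
            geminate=gem,
            R=BimolecularComponent(float(pars[f"ar_{i}"]), float(10 ** float(pars["lkon_r"])) * co[i]),
            T=BimolecularComponent(float(pars[f"at_{i}"]), float(10 ** float(pars["lkon_t"])) * co[i]),
        )

    def resid(pars):
        return np.concatenate([
            model_eval(tr.times_s, build(pars, i)) - tr.N
            for i, tr in enumerate(traces)
        ])

    out = lmfit.minimize(resid, p, method="least_squares",
                         xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=100000)
    if not out.success:
        raise FitError("global rebinding fit did not converge",
                       diagnostics={"message": out.message})
    kon_r = float(10 ** float(out.params["lkon_r"]))
    kon_t = float(10 ** float(out.params["lkon_t"]))
    if kon_t > kon_r:   # relabel so R stays the fast state
        kon_r, kon_t = kon_t, kon_r
        swapped_models = []
        for i in range(len(traces)):
            m = build(out.params, i)
            swapped_models.append(m)  # RebindingModel relabels internally
        models = tuple(swapped_models)
    else:
        models = tuple(build(out.params, i) for i in range(len(traces)))
    return GlobalFitResult(
        models=models, kon_R=kon_r, kon_T=kon_t, co_M=tuple(co),
        converged=True,
        residual_rms=float(np.sqrt(np.mean(resid(out.params) ** 2))),
    )


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

def rt_fractions(model: RebindingModel) -> tuple[float, float]:
    """R/T percentages of the bimolecular phase: fR = 100*A_R/(A_R+A_T)."""
    total = model.R.amplitude + model.T.amplitude
    if total <= 0:
        raise InputError("bimolecular amplitude is zero; fractions undefined")
    fr = 100.0 * model.R.amplitude / total
    return fr, 100.0 - fr


def bimolecular_constants(model: RebindingModel, co_M: float) -> tuple[float, float]:
    """kon_R, kon_T (M^-1 s^-1) from apparent rates and [CO] in molar."""
    if co_M <= 0:
        raise InputError("CO concentration must be positive")
    return model.R.rate_per_s / co_M, model.T.rate_per_s / co_M


def co_concentration(pressure_atm: float, temperature_K: float,
                     solubility_table: dict | None = None) -> float:
    """Dissolved CO molarity from partial pressure via Henry's law.

    Uses linear interpolation in a (temperature K -> M/atm) solubility
    table; the bundled default covers 15-25 degrees C.
    """
    if not 0 < pressure_atm <= 1.2:
        raise InputError("CO pressure must lie in (0, 1.2] atm")
    table = solubility_table or CO_SOLUBILITY_M_PER_ATM
    temps = np.array(sorted(table), dtype=float)
    sols = np.array([table[k] for k in sorted(table)], dtype=float)
    if not temps[0] <= temperature_K <= temps[-1]:
        raise OutOfRangeError(
            f"temperature {temperature_K} K outside solubility table "
            f"[{temps[0]}, {temps[-1]}] K"
        )
    return float(pressure_atm * np.interp(temperature_K, temps, sols))


def summarize(model: RebindingModel, co_M: float, isoform: str = "",
              condition: Condition | None = None) -> KineticSummary:
    """Collapse a fitted model into a table-row KineticSummary."""
    fr, ft = rt_fractions(model)
    kon_r, kon_t = bimolecular_constants(model, co_M)
    total = model.total_amplitude
    gem_pct = 100.0 * model.geminate_amplitude / total if total > 0 else 0.0
    return KineticSummary(fR_pct=fr, fT_pct=ft, kon_R=kon_r, kon_T=kon_t,
                          geminate_pct=gem_pct, co_M=co_M,
                          isoform=isoform, condition=condition)


def compare_conditions(summary_a: KineticSummary, summary_b: KineticSummary) -> dict:
    """Relative change report between two conditions (e.g. -/+ ATP or urea).

    Requires matching isoform and temperature.  Reports the change in the
    R-state fraction in percentage points and relative percent (b vs a),
    plus kon ratios.
    """
    if summary_a.isoform != summary_b.isoform:
        raise InputError("summaries are for different isoforms")
    ca, cb = summary_a.condition, summary_b.condition
    if ca is not None and cb is not None and not np.isclose(ca.temperature_K, cb.temperature_K):
        raise InputError("summaries are at different temperatures")
    d_points = summary_b.fR_pct - summary_a.fR_pct
    rel = 100.0 * d_points / summary_a.fR_pct if summary_a.fR_pct > 0 else float("nan")
    return {
        "delta_fR_points": d_points,
        "delta_fR_relative_pct": rel,
        "kon_R_ratio": summary_b.kon_R / summary_a.kon_R,
        "kon_T_ratio": summary_b.kon_T / summary_a.kon_T,
    }
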