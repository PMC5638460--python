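"""Stopped-flow O2->CO displacement (koff,R) and autoxidation rate (kox).

Mixing oxygenated hemoglobin with a CO-saturated solution replaces the bound
O2 at a rate limited by O2 dissociation; the absorbance time course at
420 nm is a single exponential whose reciprocal lifetime is koff,R (the
protein starts fully oxygenated, i.e. in the R state).

Spontaneous oxidation of ferrous oxy-heme to the ferric met form is followed
through spectral time series; after converting each spectrum to a met
fraction (two-component unmixing against oxy and met references), the
autoxidation rate kox (min^-1) is the ordinary-least-squares slope of the
initial, approximately linear phase of met fraction versus time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .equilibrium import Condition
from .exceptions import FitError, InputError, InsufficientDataError
from .spectra import ReferenceBasis, Spectrum, SpectralUnmixer

__all__ = [
    "DisplacementTrace",
    "AutoxSeries",
    "MonoExponentialDecay",
    "fit_monoexp",
    "met_fraction_timecourse",
    "initial_rate",
]


@dataclass(frozen=True)
class DisplacementTrace:
    """A420 stopped-flow time course of the O2 -> CO displacement."""

    times_s: np.ndarray
    A420: np.ndarray
    condition: Condition | None = None

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.A420, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise InputError("times and A420 must be 1-D and equal length")
        if t.size < 20:
            raise InputError("a displacement trace needs at least 20 samples")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "A420", a)


@dataclass(frozen=True)
class AutoxSeries:
    """Met-fraction time course of an autoxidation experiment (minutes)."""

    times_min: np.ndarray
    met_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        f = np.asarray(self.met_fraction, dtype=float)
        if t.ndim != 1 or f.shape != t.shape:
            raise InputError("times and fractions must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise InputError("timepoints must be strictly increasing")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise InputError("met fractions must lie in [0, 1]")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "met_fraction", np.clip(f, 0.0, 1.0))


class MonoExponentialDecay(RegressorMixin, BaseEstimator):
    """Least-squares fit of A(t) = A_inf + dA * exp(-t/tau).

    The offset absorbs the absorbance of the fully carbonylated product, so
    the estimate of the rate 1/tau is invariant under affine transformations
    of the absorbance axis.

    Attributes
    ----------
    rate_ : float
        1/tau in s^-1 (this is koff,R for a displacement trace).
    se_rate_ : float
        Standard error of the rate (delta method from se(tau)).
    a_inf_, delta_a_, tau_ : float
        Remaining fitted parameters.
    warnings_ : tuple of str
        Short-trace warning when the data span < 3 lifetimes.
    """

    @staticmethod
    def _model(t, a_inf, delta_a, tau):
        return a_inf + delta_a * np.exp(-t / tau)

    def fit(self, times_s, A) -> "MonoExponentialDecay":
        t = np.asarray(times_s, dtype=float).ravel()
        a = np.asarray(A, dtype=float).ravel()
        DisplacementTrace(t, a)  # validates
        # deterministic init: endpoints for offset/amplitude, 1/e crossing for tau
        a_inf0, da0 = a[-1], a[0] - a[-1]
        if abs(da0) < 1e-30:
            a_inf0, da0 = a.mean(), max(np.ptp(a), 1e-12)
        frac = (a - a_inf0) / da0
        idx = np.nonzero(frac <= np.exp(-1))[0]
        tau0 = t[idx[0]] if idx.size else t[-1] / 3.0
        tau0 = max(tau0, t[1] - t[0])
        try:
            popt, pcov = curve_fit(self._model, t, a, p0=[a_inf0, da0, tau0],
                                   maxfev=20000, xtol=1e-14, ftol=1e-14)
        except RuntimeError as e:
            raise FitError("mono-exponential fit did not converge",
                           diagnostics={"p0": [a_inf0, da0, tau0], "message": str(e)}) from e
        a_inf, delta_a, tau = (float(v) for v in popt)
        if tau <= 0:
            raise FitError("fitted lifetime is non-positive", diagnostics={"tau": tau})
        se_tau = float(np.sqrt(max(pcov[2, 2], 0.0)))
        self.a_inf_, self.delta_a_, self.tau_ = a_inf, delta_a, tau
        self.rate_ = 1.0 / tau
        self.se_rate_ = se_tau / tau**2
        warns = []
        if t[-1] - t[0] < 3 * tau:
            warns.append(f"trace spans only {(t[-1] - t[0]) / tau:.2f} lifetimes (< 3)")
        self.warnings_ = tuple(warns)
        return self

    def predict(self, times_s):
        return self._model(np.asarray(times_s, dtype=float), self.a_inf_,
                           self.delta_a_, self.tau_)


def fit_monoexp(trace: DisplacementTrace) -> tuple[float, float]:
    """Fit a displacement trace; returns (koff_R, standard error) in s^-1."""
    est = MonoExponentialDecay().fit(trace.times_s, trace.A420)
    for w in est.warnings_:
        warnings.warn(w, stacklevel=2)
    return est.rate_, est.se_rate_


def met_fraction_timecourse(spectra, times_min, oxy_ref: Spectrum,
                            met_ref: Spectrum) -> AutoxSeries:
    """Convert a spectral time series into a met-fraction time course.

    Each spectrum is unmixed against the two references (plus offset); the
    met fraction is met/(oxy + met).  The references must share a grid; the
    first spectrum of an experiment (collected immediately after exposure to
    oxygen) should match the oxy reference, the ferricyanide-oxidised one
    the met reference.
    """
    basis = ReferenceBasis({"oxy": oxy_ref, "met": met_ref})
    lo, hi = basis.grid[0], basis.grid[-1]
    unmixer = SpectralUnmixer(window=(lo, hi)).fit(basis)
    fractions = []
    for comp in unmixer.transform(list(spectra)):
        oxy = comp.coefficients["oxy"]
        met = comp.coefficients["met"]
        total = oxy + met
        if total <= 0:
            raise InputError("spectrum unmixed to zero oxy + met; cannot form fraction")
        fractions.append(met / total)
    return AutoxSeries(np.asarray(times_min, dtype=float), np.asarray(fractions))


def initial_rate(series: AutoxSeries, window: float = 0.10) -> float:
    """Autoxidation rate kox (min^-1) from the initial linear phase.

    OLS slope of met fraction vs time over the points with met fraction <=
    `window` (default 10% conversion, within which 1 - exp(-k t) deviates
    from linearity by < 6%).  Needs at least 3 points inside the window.
    """
    mask = series.met_fraction <= window
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points below {window:.0%} conversion (need 3)"
        )
    slope, _ = np.polyfit(series.times_min[mask], series.met_fraction[mask], 1)
    return float(slope)
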