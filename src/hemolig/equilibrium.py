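"""Hill-equation analysis of O2-equilibrium curves.

Fractional saturation of a cooperative hemoglobin as a function of O2 partial
pressure is summarised empirically by the Hill equation

    Y(pO2) = pO2^n / (P50^n + pO2^n)

where P50 (Torr) is the half-saturation pressure — the inverse measure of O2
affinity — and n (the Hill coefficient, nH) the cooperativity index; n = 1 is
the non-cooperative hyperbola, a tetramer cannot exceed n = 4.

Fitting is done on the untransformed saturation scale by nonlinear least
squares; the classical Hill-plot regression (logit Y vs log pO2) is used only
to initialise, since linearisation distorts the error structure of saturation
data.  Experimental curves typically sample 4-6 saturation steps between
roughly 20 and 80%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, FitError, InputError

__all__ = [
    "Condition",
    "EquilibriumCurve",
    "HillFit",
    "HillCurve",
    "hill_model",
    "fit_hill",
    "heme_concentration",
    "CELSIUS_OFFSET",
]

CELSIUS_OFFSET = 273.15

# millimolar extinction coefficients (mM^-1 cm^-1), heme basis
EPSILON_CO_FERROUS = 13.4   # mean of A540 and A569 of the ferrous CO adduct
EPSILON_SORET_405 = 150.0   # generic Soret estimate at 405 nm


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + CELSIUS_OFFSET


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata attached to a measured curve or trace.

    Temperatures are stored in kelvin; use :func:`celsius_to_kelvin` at the
    interface.  Concentrations in mM.
    """

    temperature_K: float
    pH: float
    KCl_mM: float = 100.0
    ATP_mM: float = 0.0
    urea_mM: float = 0.0
    heme_mM: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise InputError("temperature must be positive (kelvin)")
        if not 4.0 <= self.pH <= 12.0:
            raise InputError(f"pH {self.pH} outside plausible range [4, 12]")
        for name in ("KCl_mM", "ATP_mM", "urea_mM", "heme_mM"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")

    @property
    def temperature_C(self) -> float:
        return self.temperature_K - CELSIUS_OFFSET


@dataclass(frozen=True)
class EquilibriumCurve:
    """An O2-equilibrium curve: (pO2 Torr, fractional saturation) points."""

    pO2_torr: np.ndarray
    saturation: np.ndarray
    condition: Condition | None = None

    def __post_init__(self):
        p = np.asarray(self.pO2_torr, dtype=float)
        y = np.asarray(self.saturation, dtype=float)
        if p.ndim != 1 or y.shape != p.shape:
            raise InputError("pO2 and saturation must be 1-D and equal length")
        if p.size < 3:
            raise InputError("an equilibrium curve needs at least 3 points")
        if np.any(p <= 0):
            raise InputError("pO2 must be strictly positive")
        if np.any((y < 0) | (y > 1)):
            raise InputError("saturation must lie in [0, 1]")
        object.__setattr__(self, "pO2_torr", p)
        object.__setattr__(self, "saturation", y)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with curvature-based standard errors."""

    P50: float
    nH: float
    se_P50: float
    se_nH: float
    rss: float
    converged: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.P50 <= 0 or self.nH <= 0:
            raise InputError("P50 and nH must be positive")


def hill_model(pO2, P50, n):
    """Hill saturation Y = pO2^n / (P50^n + pO2^n).

    Vectorised in `pO2`.  Exactly 0.5 at pO2 = P50 for any n > 0; strictly
    increasing in pO2; tends to 0 and 1 in the low/high-pressure limits.
    """
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0) or P50 <= 0 or n <= 0:
        raise DomainError("hill_model requires pO2 >= 0, P50 > 0, n > 0")
    # (p/P50)^n form is overflow-safe for large pressures
    r = (p / P50) ** n
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


class HillCurve(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares Hill fit, sklearn-style.

    ``fit(pO2, Y)`` estimates P50 and nH; ``predict(pO2)`` evaluates the
    fitted curve.  Initial values come from the Hill plot (slope -> n,
    log-linear interpolation to Y = 0.5 -> P50).

    Parameters
    ----------
    p50_bounds : tuple, default (1e-6, 1000.0)
        Bounds on P50 in Torr.
    n_bounds : tuple, default (0.3, 6.0)
        Bounds on the Hill coefficient.

    Attributes
    ----------
    p50_, nh_ : float
        Fitted half-saturation pressure (Torr) and Hill coefficient.
    se_p50_, se_nh_ : float
        Asymptotic standard errors from the Jacobian at the optimum.
    rss_ : float
        Residual sum of squares on the saturation scale.
    converged_ : bool
    warnings_ : tuple of str
        E.g. an extrapolated-P50 flag when all Y lie on one side of 0.5.
    """

    def __init__(self, p50_bounds=(1e-6, 1000.0), n_bounds=(0.3, 6.0)):
        self.p50_bounds = p50_bounds
        self.n_bounds = n_bounds

    # -- initialisation ------------------------------------------------
    @staticmethod
    def _hill_plot_init(p, y):
        """Hill-plot regression: log10[Y/(1-Y)] = n (log10 p - log10 P50)."""
        eps = 1e-6
        yc = np.clip(y, eps, 1 - eps)
        x = np.log10(p)
        z = np.log10(yc / (1 - yc))
        n, b = np.polyfit(x, z, 1)
        p50 = 10 ** (-b / n) if n != 0 else float(np.median(p))
        return p50, n

    def fit(self, pO2, Y) -> "HillCurve":
        p = np.asarray(pO2, dtype=float).ravel()
        y = np.asarray(Y, dtype=float).ravel()
        EquilibriumCurve(p, y)  # validates ranges and lengths
        inside = (y > 0) & (y < 1)
        if inside.sum() < 3:
            raise InputError("need at least 3 points with 0 < Y < 1")
        p, y = p[inside], y[inside]

        warns: list[str] = []
        if np.all(y < 0.5) or np.all(y > 0.5):
            warns.append("extrapolated P50: all saturations on one side of 0.5")

        p50_0, n_0 = self._hill_plot_init(p, y)
        lo = [self.p50_bounds[0], self.n_bounds[0]]
        hi = [self.p50_bounds[1], self.n_bounds[1]]
        p50_0 = float(np.clip(p50_0, *self.p50_bounds))
        n_0 = float(np.clip(n_0, *self.n_bounds))
        try:
            popt, pcov = curve_fit(
                hill_model, p, y, p0=[p50_0, n_0], bounds=(lo, hi),
                maxfev=10000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as e:
            raise FitError(
                "Hill fit did not converge",
                diagnostics={"p0": [p50_0, n_0], "message": str(e)},
            ) from e
        resid = y - hill_model(p, *popt)
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.p50_, self.nh_ = float(popt[0]), float(popt[1])
        self.se_p50_, self.se_nh_ = float(se[0]), float(se[1])
        self.rss_ = float(resid @ resid)
        self.converged_ = True
        self.warnings_ = tuple(warns)
        self.n_points_ = int(p.size)
        return self

    def predict(self, pO2):
        return hill_model(pO2, self.p50_, self.nh_)

    def result(self) -> HillFit:
        return HillFit(
            P50=self.p50_, nH=self.nh_, se_P50=self.se_p50_, se_nH=self.se_nh_,
            rss=self.rss_, converged=self.converged_, warnings=self.warnings_,
        )


def fit_hill(curve: EquilibriumCurve, **kwargs) -> HillFit:
    """Fit the Hill equation to an equilibrium curve and return a HillFit."""
    est = HillCurve(**kwargs).fit(curve.pO2_torr, curve.saturation)
    for w in est.warnings_:
        warnings.warn(w, stacklevel=2)
    return est.result()


def heme_concentration(absorbances: dict, species: str = "co-ferrous",
                       pathlength_cm: float = 1.0) -> float:
    """Heme concentration (mM) from extinction coefficients.

    ``species="co-ferrous"`` averages A540 and A569 of the carbonylated
    ferrous protein (epsilon = 13.4 mM^-1 cm^-1 per heme); ``"generic"``
    uses the Soret absorbance at 405 nm (epsilon = 150 mM^-1 cm^-1).
    """
    if pathlength_cm <= 0:
        raise InputError("pathlength must be positive")
    ab = {float(k): float(v) for k, v in absorbances.items()}
    if species == "co-ferrous":
        try:
            a = 0.5 * (ab[540.0] + ab[569.0])
        except KeyError as e:
            raise InputError(f"co-ferrous estimate needs A540 and A569; missing {e}")
        return a / (EPSILON_CO_FERROUS * pathlength_cm)
    if species == "generic":
        if 405.0 not in ab:
            raise InputError("generic Soret estimate needs A405")
        return ab[405.0] / (EPSILON_SORET_405 * pathlength_cm)
    raise InputError(f"unknown species {species!r}; use 'co-ferrous' or 'generic'")
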