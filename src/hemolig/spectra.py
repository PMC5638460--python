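"""Spectral species decomposition for heme-protein absorbance spectra.

A measured Soret-region spectrum of a partially oxygenated hemoglobin sample
is, to very good approximation, a linear mixture of the spectra of its pure
ligation/oxidation states (oxy, deoxy, met) plus a wavelength-independent
baseline offset.  This module resolves such mixtures by nonnegative least
squares and converts the resulting species coefficients into fractional O2
saturation, Y = oxy / (oxy + deoxy).  The met coefficient is reported but
excluded from Y: oxidised hemes do not bind O2 and are treated as a separate
correction.

The decomposition is exposed both as the :class:`SpectralUnmixer` estimator
(fit on a reference basis, transform measured spectra) and as the
:func:`unmix` convenience function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateBasisError,
    InputError,
    OutOfRangeError,
    UndefinedSaturationError,
)

__all__ = [
    "Spectrum",
    "ReferenceBasis",
    "SpeciesComposition",
    "SpectralUnmixer",
    "resample_to_grid",
    "unmix",
    "saturation",
]


@dataclass(frozen=True)
class Spectrum:
    """A sampled absorbance spectrum.

    Parameters
    ----------
    wavelengths : array-like of float
        Wavelength grid in nm, strictly increasing.
    absorbances : array-like of float
        Absorbance in AU, same length as `wavelengths`, all finite.
    label : str
        Free-text identifier (species name, timestamp, ...).
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise InputError("wavelengths and absorbances must be 1-D and equal length")
        if wl.size < 1:
            raise InputError("a spectrum needs at least one sample")
        if not np.all(np.diff(wl) > 0):
            raise InputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise InputError("absorbances must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class ReferenceBasis:
    """Named pure-species reference spectra on one common wavelength grid."""

    references: Mapping[str, Spectrum]

    def __post_init__(self):
        refs = dict(self.references)
        if len(refs) < 2:
            raise InputError("a reference basis needs at least two species")
        grids = [s.wavelengths for s in refs.values()]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.array_equal(g, grids[0]):
                raise InputError("all references must share one wavelength grid")
        object.__setattr__(self, "references", refs)

    @property
    def grid(self) -> np.ndarray:
        return next(iter(self.references.values())).wavelengths

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.references)

    def matrix(self) -> np.ndarray:
        """Reference spectra stacked as columns, shape (n_wavelengths, n_refs)."""
        return np.column_stack([self.references[n].absorbances for n in self.names])


@dataclass(frozen=True)
class SpeciesComposition:
    """Result of unmixing one spectrum: species coefficients plus baseline."""

    coefficients: Mapping[str, float]
    offset: float
    residual_rms: float
    label: str = ""

    def __post_init__(self):
        coeffs = {k: float(v) for k, v in self.coefficients.items()}
        if any(v < -1e-12 for v in coeffs.values()):
            raise InputError("species coefficients must be nonnegative")
        if self.residual_rms < 0:
            raise InputError("residual must be nonnegative")
        object.__setattr__(self, "coefficients", coeffs)


def resample_to_grid(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The grid must lie within the spectrum's wavelength span; extrapolation is
    refused because Soret-band wings are steep and linear extension would
    silently corrupt the decomposition.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise InputError("grid must be a non-empty 1-D sequence")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if g.min() < lo or g.max() > hi:
        raise OutOfRangeError(
            f"grid [{g.min():g}, {g.max():g}] nm outside spectrum span [{lo:g}, {hi:g}] nm"
        )
    ab = np.interp(g, spectrum.wavelengths, spectrum.absorbances)
    return Spectrum(g, ab, label=spectrum.label)


class SpectralUnmixer(TransformerMixin, BaseEstimator):
    """Nonnegative linear unmixing against pure-species reference spectra.

    The model for a measured spectrum S(lambda) is

        S(lambda) = sum_k  c_k * R_k(lambda)  +  b,      c_k >= 0,

    with R_k the reference spectra and b an unconstrained constant offset
    (instrument baseline).  Coefficients are found by bounded-variable least
    squares, which enforces nonnegativity exactly rather than by clipping.

    Parameters
    ----------
    window : tuple of float, default (380.0, 500.0)
        Wavelength window (nm) over which the residual is minimised; the
        default covers the Soret region where the oxy/deoxy/met spectra
        differ most.

    Attributes
    ----------
    names_ : tuple of str
        Reference species names, in column order.
    grid_ : ndarray
        Wavelengths actually used in the fit (basis grid clipped to window).
    design_ : ndarray, shape (n_wavelengths, n_refs + 1)
        Design matrix; last column is the constant-offset regressor.
    """

    def __init__(self, window: tuple[float, float] = (380.0, 500.0)):
        self.window = window

    def fit(self, basis: ReferenceBasis, y=None) -> "SpectralUnmixer":
        if not isinstance(basis, ReferenceBasis):
            basis = ReferenceBasis(basis)
        lo, hi = self.window
        mask = (basis.grid >= lo) & (basis.grid <= hi)
        if mask.sum() <= len(basis.names) + 1:
            raise InputError(
                "fitting window must contain more wavelengths than references + 1"
            )
        refs = basis.matrix()[mask]
        # identical-up-to-scale references make the coefficients unidentifiable
        if np.linalg.matrix_rank(refs, tol=1e-8 * np.abs(refs).max()) < refs.shape[1]:
            raise DegenerateBasisError("reference spectra are collinear")
        self.names_ = basis.names
        self.grid_ = basis.grid[mask]
        self.design_ = np.column_stack([refs, np.ones(mask.sum())])
        return self

    def unmix_one(self, spectrum: Spectrum) -> SpeciesComposition:
        """Decompose a single spectrum; it is resampled onto the fit grid."""
        y = resample_to_grid(spectrum, self.grid_).absorbances
        n = len(self.names_)
        lb = np.r_[np.zeros(n), -np.inf]
        ub = np.full(n + 1, np.inf)
        res = lsq_linear(self.design_, y, bounds=(lb, ub), method="bvls", tol=1e-14)
        resid = y - self.design_ @ res.x
        return SpeciesComposition(
            coefficients=dict(zip(self.names_, res.x[:n])),
            offset=float(res.x[n]),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            label=spectrum.label,
        )

    def transform(self, spectra: Sequence[Spectrum]) -> list[SpeciesComposition]:
        if isinstance(spectra, Spectrum):
            spectra = [spectra]
        return [self.unmix_one(s) for s in spectra]


def unmix(spectrum: Spectrum, basis: ReferenceBasis,
          window: tuple[float, float] = (380.0, 500.0)) -> SpeciesComposition:
    """Decompose one spectrum against a reference basis (functional form)."""
    return SpectralUnmixer(window=window).fit(basis).unmix_one(spectrum)


def saturation(composition: SpeciesComposition) -> float:
    """Fractional O2 saturation from an unmixed composition.

    Y = oxy / (oxy + deoxy); the met coefficient is excluded because ferric
    hemes do not participate in the oxygenation equilibrium.  Invariant under
    uniform rescaling of all coefficients (concentration/pathlength cancel).
    """
    try:
        oxy = composition.coefficients["oxy"]
        deoxy = composition.coefficients["deoxy"]
    except KeyError as e:
        raise InputError(f"composition lacks required species {e}") from e
    total = oxy + deoxy
    if total <= 0:
        raise UndefinedSaturationError("oxy + deoxy coefficients are zero")
    return float(oxy / total)
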