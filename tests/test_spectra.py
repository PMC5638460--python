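"""Spectral resampling, nonnegative unmixing and saturation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemolig.exceptions import (
    DegenerateBasisError,
    OutOfRangeError,
    UndefinedSaturationError,
)
from hemolig.spectra import (
    ReferenceBasis,
    SpeciesComposition,
    Spectrum,
    SpectralUnmixer,
    resample_to_grid,
    saturation,
    unmix,
)
from hemolig.synthetic import make_reference_basis


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

class TestResample:
    def test_identity_on_same_grid(self, default_basis):
        s = default_basis.references["oxy"]
        out = resample_to_grid(s, s.wavelengths)
        np.testing.assert_array_equal(out.absorbances, s.absorbances)

    def test_linear_midpoint(self):
        s = Spectrum([400.0, 500.0], [0.0, 1.0])
        out = resample_to_grid(s, [450.0])
        assert out.absorbances[0] == pytest.approx(0.5)

    def test_gaussian_band_halved_density(self):
        # dense Gaussian band -> coarse grid; compare against the analytic band
        dense = np.arange(380.0, 500.0, 0.5)
        band = 1.2 * np.exp(-0.5 * ((dense - 430.0) / 12.0) ** 2)
        coarse = np.arange(380.5, 499.0, 1.0)
        out = resample_to_grid(Spectrum(dense, band), coarse)
        analytic = 1.2 * np.exp(-0.5 * ((coarse - 430.0) / 12.0) ** 2)
        assert np.max(np.abs(out.absorbances - analytic)) < 1e-3

    def test_grid_outside_span_rejected(self):
        s = Spectrum([400.0, 500.0], [0.0, 1.0])
        with pytest.raises(OutOfRangeError):
            resample_to_grid(s, [350.0, 450.0])


# --------------------------------------------------------------------------
# unmixing
# --------------------------------------------------------------------------

def _mix(basis, coeffs, offset=0.0):
    ab = sum(c * basis.references[n].absorbances for n, c in coeffs.items()) + offset
    return Spectrum(basis.grid, ab, label="mixture")


def brute_force_unmix(spectrum, basis, coarse=0.05, fine=1e-3, cmax=1.5):
    """Independent oracle: exhaustive grid search over coefficients.

    For fixed coefficients the optimal constant offset is the mean residual,
    so centering the spectrum and the reference columns absorbs the offset
    and the residual SSE is an exact quadratic form in the coefficients,
    evaluated over a full coarse grid and then a fine grid around the coarse
    minimum (exhaustive within the refinement window).
    """
    R = basis.matrix()
    y = spectrum.absorbances
    Rc = R - R.mean(axis=0)
    yc = y - y.mean()
    G = Rc.T @ Rc
    b = Rc.T @ yc

    def sse_grid(axes):
        grids = np.meshgrid(*axes, indexing="ij")
        C = np.stack([g.ravel() for g in grids], axis=1)
        sse = np.einsum("ij,jk,ik->i", C, G, C) - 2.0 * C @ b
        return C[np.argmin(sse)]

    c0 = sse_grid([np.arange(0.0, cmax + 1e-12, coarse)] * R.shape[1])
    axes = [np.arange(max(c - coarse, 0.0), c + coarse + 1e-12, fine) for c in c0]
    return sse_grid(axes)


class TestUnmix:
    def test_pure_species(self, default_basis):
        comp = unmix(default_basis.references["oxy"], default_basis)
        assert comp.coefficients["oxy"] == pytest.approx(1.0, abs=1e-8)
        assert comp.coefficients["deoxy"] == pytest.approx(0.0, abs=1e-8)
        assert comp.coefficients["met"] == pytest.approx(0.0, abs=1e-8)
        assert comp.offset == pytest.approx(0.0, abs=1e-8)
        assert comp.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_exact_mixture_recovered(self, default_basis):
        true = {"oxy": 0.6, "deoxy": 0.3, "met": 0.1}
        comp = unmix(_mix(default_basis, true, offset=0.02), default_basis)
        for name, c in true.items():
            assert comp.coefficients[name] == pytest.approx(c, abs=1e-8)
        assert comp.offset == pytest.approx(0.02, abs=1e-8)

    @given(
        oxy=st.floats(0.0, 1.2), deoxy=st.floats(0.0, 1.2),
        met=st.floats(0.0, 1.2), offset=st.floats(-0.1, 0.1),
    )
    def test_any_exact_combination_recovered(self, oxy, deoxy, met, offset):
        basis = make_reference_basis()
        true = {"oxy": oxy, "deoxy": deoxy, "met": met}
        comp = unmix(_mix(basis, true, offset), basis)
        for name, c in true.items():
            assert comp.coefficients[name] == pytest.approx(c, abs=1e-7)

    def test_noisy_mixture_matches_brute_force(self, default_basis, rng):
        true = {"oxy": 0.6, "deoxy": 0.3, "met": 0.1}
        spec = _mix(default_basis, true, offset=0.02)
        noisy = Spectrum(spec.wavelengths,
                         spec.absorbances + rng.normal(0, 0.002, len(spec)))
        comp = unmix(noisy, default_basis)
        for name, c in true.items():
            assert comp.coefficients[name] == pytest.approx(c, abs=0.01)
        # brute-force oracle on a small-grid version of the same problem
        small = np.arange(380.0, 500.1, 4.0)  # 31 wavelengths
        small_basis = ReferenceBasis({
            n: resample_to_grid(s, small)
            for n, s in default_basis.references.items()
        })
        small_noisy = resample_to_grid(noisy, small)
        oracle = brute_force_unmix(small_noisy, small_basis)
        comp_small = unmix(small_noisy, small_basis, window=(small[0], small[-1]))
        solver = [comp_small.coefficients[n] for n in small_basis.names]
        np.testing.assert_allclose(solver, oracle, atol=1.5e-3)

    def test_residual_nonincreasing_with_extra_reference(self, default_basis):
        # signal contains met; unmixing with met in the basis cannot be worse
        spec = _mix(default_basis, {"oxy": 0.5, "deoxy": 0.3, "met": 0.2})
        two = ReferenceBasis({n: default_basis.references[n] for n in ("oxy", "deoxy")})
        r2 = unmix(spec, two).residual_rms
        r3 = unmix(spec, default_basis).residual_rms
        assert r3 <= r2 + 1e-12

    def test_degenerate_basis_rejected(self, default_basis):
        oxy = default_basis.references["oxy"]
        doubled = Spectrum(oxy.wavelengths, 2.0 * oxy.absorbances, label="oxy2x")
        basis = ReferenceBasis({"oxy": oxy, "oxy2x": doubled})
        with pytest.raises(DegenerateBasisError):
            SpectralUnmixer().fit(basis)


# --------------------------------------------------------------------------
# saturation
# --------------------------------------------------------------------------

class TestSaturation:
    @pytest.mark.parametrize("coeffs,expected", [
        ({"oxy": 1.0, "deoxy": 0.0}, 1.0),
        ({"oxy": 0.25, "deoxy": 0.25}, 0.5),
        ({"oxy": 0.6, "deoxy": 0.3, "met": 0.1}, 0.6 / 0.9),
    ])
    def test_values(self, coeffs, expected):
        comp = SpeciesComposition(coeffs, offset=0.0, residual_rms=0.0)
        assert saturation(comp) == pytest.approx(expected, abs=1e-12)

    @given(scale=st.floats(1e-3, 1e3),
           oxy=st.floats(0.01, 2.0), deoxy=st.floats(0.01, 2.0))
    def test_invariant_under_uniform_scaling(self, scale, oxy, deoxy):
        a = SpeciesComposition({"oxy": oxy, "deoxy": deoxy}, 0.0, 0.0)
        b = SpeciesComposition({"oxy": oxy * scale, "deoxy": deoxy * scale}, 0.0, 0.0)
        assert saturation(a) == pytest.approx(saturation(b), rel=1e-9)

    def test_undefined_when_no_heme_signal(self):
        comp = SpeciesComposition({"oxy": 0.0, "deoxy": 0.0, "met": 1.0}, 0.0, 0.0)
        with pytest.raises(UndefinedSaturationError):
            saturation(comp)
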