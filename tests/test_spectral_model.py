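import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersev import (AMINO_ACIDS, AminoAcidBasis, CompositionVector, Spectrum,
                    derive_coefficients, fit_composition, mean_deviation,
                    simulate_spectrum)
from sersev.exceptions import FitError, SersevError

AA = list(AMINO_ACIDS)


@pytest.fixture(scope="module")
def shared_basis():
    """Read-only basis reused across hypothesis examples."""
    from sersev import SyntheticDatasetSpec, WavenumberGrid, generate_basis

    return generate_basis(SyntheticDatasetSpec(
        seed=7, grid=WavenumberGrid(564.0, 1681.0, 200)))


class TestDeriveCoefficients:
    def test_uniform(self, toy_basis):
        uniform_act = AminoAcidBasis(toy_basis.spectra, {a: 2.0 for a in AA})
        c = derive_coefficients(CompositionVector.uniform(), uniform_act)
        assert np.allclose(c.as_array(), 0.05)

    def test_delta_unaffected_by_activity(self, toy_basis):
        c = derive_coefficients(CompositionVector.delta("G"), toy_basis)
        assert c["G"] == pytest.approx(1.0)

    def test_hand_computation(self, toy_basis):
        act = {a: 1.0 for a in AA}
        act["A"] = 3.0
        basis = AminoAcidBasis(toy_basis.spectra, act)
        f = CompositionVector({"G": 0.5, "A": 0.5})
        c = derive_coefficients(f, basis)
        assert c["G"] == pytest.approx(0.25)
        assert c["A"] == pytest.approx(0.75)


class TestSimulate:
    def test_delta_returns_basis_spectrum(self, toy_basis):
        s = simulate_spectrum(CompositionVector.delta("W"), toy_basis)
        assert np.array_equal(s.intensities, toy_basis.spectra["W"].intensities)

    def test_two_component_mean(self, toy_basis):
        s = simulate_spectrum(CompositionVector({"A": 0.5, "C": 0.5}), toy_basis)
        expect = 0.5 * (toy_basis.spectra["A"].intensities
                        + toy_basis.spectra["C"].intensities)
        assert np.allclose(s.intensities, expect)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1), alpha=st.floats(0.0, 1.0))
    def test_linearity(self, shared_basis, seed, alpha):
        rng = np.random.default_rng(seed)
        c1 = CompositionVector.from_array(rng.dirichlet(np.ones(20)))
        c2 = CompositionVector.from_array(rng.dirichlet(np.ones(20)))
        blend = CompositionVector.from_array(
            alpha * c1.as_array() + (1 - alpha) * c2.as_array(), normalize=True)
        lhs = simulate_spectrum(blend, shared_basis).intensities
        rhs = (alpha * simulate_spectrum(c1, shared_basis).intensities
               + (1 - alpha) * simulate_spectrum(c2, shared_basis).intensities)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestFit:
    def test_two_component_exact_recovery(self, toy_basis):
        target = Spectrum(toy_basis.grid,
                          0.3 * toy_basis.spectra["A"].intensities
                          + 0.7 * toy_basis.spectra["F"].intensities)
        fit = fit_composition(target, toy_basis)
        assert fit.coefficients["A"] == pytest.approx(0.3, abs=1e-6)
        assert fit.coefficients["F"] == pytest.approx(0.7, abs=1e-6)

    def test_single_basis_spectrum(self, toy_basis):
        fit = fit_composition(toy_basis.spectra["M"], toy_basis)
        assert fit.coefficients["M"] == pytest.approx(1.0, abs=1e-6)
        assert fit.residual_norm < 1e-8

    def test_zero_target_error(self, toy_basis):
        with pytest.raises(FitError):
            fit_composition(Spectrum(toy_basis.grid,
                                     np.zeros(toy_basis.grid.n_points)),
                            toy_basis)

    def test_noisy_mixture_recovery(self, toy_basis):
        rng = np.random.default_rng(99)
        c = CompositionVector.from_array(rng.dirichlet(np.full(20, 5.0)))
        clean = simulate_spectrum(c, toy_basis).intensities
        target = Spectrum(toy_basis.grid,
                          clean + rng.normal(0, 0.01, clean.size))
        fit = fit_composition(target, toy_basis)
        err = np.abs(fit.coefficients.as_array() - c.as_array()).mean()
        assert err < 0.02

    @settings(max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_exact_recovery_property(self, shared_basis, seed):
        # simulate -> fit is the identity on the simplex at zero noise
        rng = np.random.default_rng(seed)
        c = CompositionVector.from_array(rng.dirichlet(np.ones(20)))
        fit = fit_composition(simulate_spectrum(c, shared_basis), shared_basis)
        assert np.abs(fit.coefficients.as_array() - c.as_array()).max() < 1e-6

    def test_degenerate_basis_warns(self, toy_basis):
        spectra = dict(toy_basis.spectra)
        spectra["C"] = spectra["A"].with_intensities(spectra["A"].intensities)
        degen = AminoAcidBasis(spectra, toy_basis.activity)
        target = Spectrum(degen.grid, spectra["A"].intensities)
        with pytest.warns(RuntimeWarning, match="linearly dependent"):
            fit_composition(target, degen)

    def test_boosted_deterministic_and_valid(self, toy_basis):
        target = simulate_spectrum(
            CompositionVector({"A": 0.5, "W": 0.5}), toy_basis)
        f1 = fit_composition(target, toy_basis, method="boosted", seed=3)
        f2 = fit_composition(target, toy_basis, method="boosted", seed=3)
        assert np.array_equal(f1.raw_weights, f2.raw_weights)
        assert f1.method == "boosted"
        # the boosted reading should put most importance on the true pair
        top2 = set(np.argsort(f1.coefficients.as_array())[-2:])
        assert top2 == {AA.index("A"), AA.index("W")}


def _brute_force_simplex(target, B3, step=0.01):
    """Enumerate all weight triples on the 2-simplex at the given step and
    return the residual-minimizing one (independent oracle for NNLS)."""
    n = round(1.0 / step)
    best, best_r = None, np.inf
    for i, j in itertools.product(range(n + 1), repeat=2):
        if i + j > n:
            continue
        w = np.array([i, j, n - i - j]) / n
        r = np.linalg.norm(target - w @ B3)
        if r < best_r:
            best, best_r = w, r
    return best


class TestNNLSOracle:
    @pytest.mark.parametrize("true_w", [(0.2, 0.3, 0.5), (0.07, 0.9, 0.03),
                                        (1.0, 0.0, 0.0)])
    def test_matches_grid_search(self, toy_basis, true_w):
        picks = ["A", "H", "Y"]
        B3 = np.vstack([toy_basis.spectra[a].intensities for a in picks])
        target_y = np.asarray(true_w) @ B3
        fit = fit_composition(Spectrum(toy_basis.grid, target_y), toy_basis)
        grid_w = _brute_force_simplex(target_y, B3)
        fitted3 = np.array([fit.coefficients[a] for a in picks])
        assert np.abs(fitted3 - grid_w).max() <= 0.01 + 1e-9


class TestMeanDeviation:
    def test_zero_for_identical(self):
        c = CompositionVector.uniform()
        assert mean_deviation(c, c) == 0.0
        assert mean_deviation(c, c, "absolute") == 0.0

    def test_hand_computed_relative(self):
        ref = CompositionVector.uniform()
        fit = CompositionVector.from_array(
            np.array([0.055] * 10 + [0.045] * 10))
        assert mean_deviation(fit, ref) == pytest.approx(10.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.dirichlet(np.ones(20))
        b = rng.dirichlet(np.ones(20))
        perm = rng.permutation(20)
        d1 = mean_deviation(CompositionVector.from_array(a),
                            CompositionVector.from_array(b))
        d2 = mean_deviation(CompositionVector.from_array(a[perm]),
                            CompositionVector.from_array(b[perm]))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_unknown_mode_rejected(self):
        c = CompositionVector.uniform()
        with pytest.raises(ValueError):
            mean_deviation(c, c, "squared")
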