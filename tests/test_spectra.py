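import math

import numpy as np
import pytest

import nuclens as nl
from nuclens.constants import EPS_PER_SIGMA, SIGMA_PREFACTOR_EV_CM2


def fine_params(delta):
    """Grid fine enough to integrate even a δ = 0.001 eV line accurately."""
    step = min(0.005, delta / 2.0)
    return nl.LineShapeParams(delta_eV=delta, grid_min_eV=0.5,
                              grid_max_eV=10.0, grid_step_eV=step)


class TestGaussianLineshape:
    def test_peak_value_delta_0p2(self):
        assert nl.gaussian_lineshape(3.0, 3.0, 0.2) == pytest.approx(
            1.0 / (0.2 * math.sqrt(math.pi)), rel=1e-12
        )
        assert 1.0 / (0.2 * math.sqrt(math.pi)) == pytest.approx(2.8209, abs=5e-5)

    def test_unit_area(self):
        from scipy.integrate import quad
        area, _ = quad(lambda e: nl.gaussian_lineshape(e, 3.0, 0.2), 1.0, 5.0)
        assert area == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self):
        for x in (0.01, 0.3, 1.7):
            assert nl.gaussian_lineshape(3.0 + x, 3.0, 0.2) == pytest.approx(
                nl.gaussian_lineshape(3.0 - x, 3.0, 0.2), rel=1e-12
            )

    def test_nonpositive_delta(self):
        with pytest.raises(ValueError):
            nl.gaussian_lineshape(3.0, 3.0, 0.0)


class TestCrossSection:
    def test_single_line_integrates_to_prefactor(self):
        """∫σ dE / f equals C = πe²ħ/(2mcε₀) ≈ 1.0976e-16 eV·cm², computed
        here from hand-typed CODATA values independent of the package."""
        recs = [nl.TransitionRecord(geom_id=0, state=1, E_va_eV=3.0, f=0.1)]
        table = nl.cross_section(recs, fine_params(0.2))
        integral = np.trapezoid(table.sigma, table.E_grid)
        e, hbar, m, c, eps0, ev = (1.602176634e-19, 1.054571817e-34,
                                   9.1093837015e-31, 2.99792458e8,
                                   8.8541878128e-12, 1.602176634e-19)
        c_oracle = math.pi * e**2 * hbar / (2 * m * c * eps0) / ev * 1e4
        assert integral / 0.1 == pytest.approx(c_oracle, rel=1e-6)

    def test_zero_f_gives_zero_sigma(self):
        recs = [nl.TransitionRecord(geom_id=k, state=1, E_va_eV=3.0, f=0.0)
                for k in range(3)]
        table = nl.cross_section(recs)
        assert np.all(table.sigma == 0.0)

    def test_duplicated_geometry_equals_single(self):
        one = [nl.TransitionRecord(geom_id=0, state=1, E_va_eV=3.2, f=0.05)]
        two = one + [nl.TransitionRecord(geom_id=1, state=1, E_va_eV=3.2,
                                         f=0.05)]
        ta, tb = nl.cross_section(one), nl.cross_section(two)
        np.testing.assert_allclose(tb.sigma, ta.sigma, rtol=1e-12)
        assert tb.meta["N_p"] == 2

    def test_table1_visible_band_peaks_near_d3(self, table1):
        """With the worked-example table at δ = 0.2 eV, the tallest σ(λ)
        maximum beyond 350 nm lies within 10 nm of the D3 line (428 nm)."""
        table = nl.cross_section(table1, nl.LineShapeParams())
        lam = table.lambda_grid
        vis = lam > 350.0
        lam_peak = lam[vis][np.argmax(table.sigma[vis])]
        assert abs(lam_peak - 428.0) < 10.0

    @pytest.mark.parametrize("delta", [0.001, 0.2, 0.5])
    def test_sum_rule_independent_of_broadening(self, delta):
        """∫σ dE = C × mean(Σ_l f) for any δ — reconvolution at δ = 0.001
        changes the line shape but not the integrated intensity."""
        recs = nl.make_transition_ensemble(
            10, [(3.0, 0.1, 0.05, 0.01), (4.2, 0.05, 0.02, 0.0)], seed=6
        )
        mean_f = sum(r.f for r in recs) / 10
        table = nl.cross_section(recs, fine_params(delta))
        integral = np.trapezoid(table.sigma, table.E_grid)
        assert integral == pytest.approx(SIGMA_PREFACTOR_EV_CM2 * mean_f,
                                         rel=1e-6)

    def test_sigma_nonneg_and_permutation_invariant(self):
        recs = nl.make_transition_ensemble(8, [(3.0, 0.2, 0.03, 0.01)], seed=7)
        table = nl.cross_section(recs)
        assert np.all(table.sigma >= 0)
        rng = np.random.default_rng(0)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        table2 = nl.cross_section(shuffled)
        np.testing.assert_allclose(table2.sigma, table.sigma, rtol=1e-12)

    def test_narrow_delta_peak_converges_to_line_position(self):
        recs = [nl.TransitionRecord(geom_id=0, state=1, E_va_eV=3.137, f=0.1)]
        params = nl.LineShapeParams(delta_eV=0.004, grid_min_eV=2.0,
                                    grid_max_eV=4.0, grid_step_eV=0.002)
        table = nl.cross_section(recs, params)
        peak = table.E_grid[np.argmax(table.sigma)]
        assert abs(peak - 3.137) <= params.grid_step_eV

    def test_empty_transitions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nl.cross_section([])

    def test_differing_state_counts_warn(self):
        recs = [
            nl.TransitionRecord(geom_id=0, state=1, E_va_eV=3.0, f=0.1),
            nl.TransitionRecord(geom_id=1, state=1, E_va_eV=3.0, f=0.1),
            nl.TransitionRecord(geom_id=1, state=2, E_va_eV=4.0, f=0.1),
        ]
        with pytest.warns(UserWarning, match="per geometry"):
            nl.cross_section(recs)


class TestSamplingError:
    def test_identical_signals_zero_error(self):
        sig = np.ones((5, 10))
        assert np.all(nl.sampling_error(sig) == 0.0)

    def test_two_point_formula(self):
        x = 3.7e-19
        sig = np.array([[0.0], [2 * x]])
        assert nl.sampling_error(sig, mode="population-std")[0] == \
            pytest.approx(x, rel=1e-12)
        assert nl.sampling_error(sig)[0] == pytest.approx(x, rel=1e-12)
        # sample std x√2, SEM = x√2/√2 = x

    def test_single_geometry_rejected(self):
        with pytest.raises(ValueError):
            nl.sampling_error(np.ones((1, 4)))

    def test_sem_matches_bootstrap_at_band_center(self):
        """δσ at band center agrees with a 10 000-replicate bootstrap of the
        mean within the chi-square 99% band for N_p = 100."""
        from scipy.stats import chi2
        recs = nl.make_transition_ensemble(100, [(3.0, 0.1, 0.05, 0.0)],
                                           seed=9)
        params = nl.LineShapeParams(delta_eV=0.2, grid_min_eV=2.5,
                                    grid_max_eV=3.5, grid_step_eV=0.01)
        table = nl.cross_section(recs, params)
        center = np.argmin(np.abs(table.E_grid - 3.0))
        vals = table.sigma_k[:, center]
        rng = np.random.default_rng(10)
        boots = rng.choice(vals, size=(10_000, len(vals)), replace=True)
        boot_sem = boots.mean(axis=1).std(ddof=1)
        n = len(vals)
        lo = np.sqrt(chi2.ppf(0.005, n - 1) / (n - 1))
        hi = np.sqrt(chi2.ppf(0.995, n - 1) / (n - 1))
        ratio = table.dsigma[center] / boot_sem
        assert lo < ratio < hi


class TestUnitConversions:
    def test_zero_sigma_zero_eps(self):
        t = nl.SpectrumTable(E_grid=np.array([1.0, 2.0]),
                             sigma=np.zeros(2), dsigma=np.zeros(2))
        out = nl.to_molar_extinction(t)
        assert np.all(out.eps == 0.0)

    def test_conversion_factor_from_avogadro(self):
        """σ = 1e-20 cm² maps to ε ≈ 2.6154 M⁻¹cm⁻¹; the factor is
        N_A/(1000 ln 10) recomputed here from the CODATA Avogadro number."""
        t = nl.SpectrumTable(E_grid=np.array([1.0, 2.0]),
                             sigma=np.full(2, 1e-20), dsigma=np.zeros(2))
        out = nl.to_molar_extinction(t)
        oracle = 6.02214076e23 / (1000.0 * math.log(10.0))
        assert out.eps[0] == pytest.approx(1e-20 * oracle, rel=1e-12)
        assert out.eps[0] == pytest.approx(2.6154, rel=1e-4)

    def test_ratio_constant_across_grid(self):
        recs = nl.make_transition_ensemble(5, [(3.0, 0.1, 0.05, 0.01)], seed=1)
        out = nl.to_molar_extinction(nl.cross_section(recs))
        mask = out.sigma > 0
        np.testing.assert_allclose(out.eps[mask] / out.sigma[mask],
                                   EPS_PER_SIGMA, rtol=1e-12)


class TestOscillatorStrength:
    def test_two_thirds_E_mu_squared(self):
        assert nl.oscillator_strength(0.1, math.sqrt(1.5)) == \
            pytest.approx(0.1, rel=1e-12)
        assert nl.oscillator_strength(0.5, 0.0) == 0.0
        for e in (0.1, 0.2, 0.3):
            assert nl.oscillator_strength(e, 1.0) == \
                pytest.approx((2.0 / 3.0) * e, rel=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            nl.oscillator_strength(-0.1, 1.0)


class TestEnergyWavelength:
    @pytest.mark.parametrize("ev,nm", [(3.66, 339), (3.52, 352),
                                       (2.29, 541), (2.90, 428)])
    def test_printed_pairs_round_trip(self, ev, nm):
        assert round(nl.energy_to_wavelength(ev)) == nm

    def test_involution(self):
        for e in (0.7, 3.66, 9.9):
            assert nl.wavelength_to_energy(nl.energy_to_wavelength(e)) == \
                pytest.approx(e, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nl.energy_to_wavelength(0.0)
        with pytest.raises(ValueError):
            nl.wavelength_to_energy(-1.0)


class TestDeconvolution:
    def test_single_state_component_equals_total(self):
        recs = [nl.TransitionRecord(geom_id=0, state=1, E_va_eV=3.0, f=0.1)]
        table = nl.deconvolve_by_state(recs)
        np.testing.assert_allclose(table.per_state[1], table.sigma,
                                   rtol=1e-12)

    def test_components_sum_to_total(self, table1):
        table = nl.deconvolve_by_state(table1, nl.LineShapeParams())
        total = sum(table.per_state.values())
        np.testing.assert_allclose(total, table.sigma, rtol=1e-12,
                                   atol=1e-30)

    def test_dominant_visible_component_is_largest_f_state(self, table1):
        """The state with f = 0.0238 (D3, l = 2) dominates the visible band."""
        table = nl.deconvolve_by_state(table1, nl.LineShapeParams())
        vis = table.lambda_grid > 350.0
        dominant = max(table.per_state,
                       key=lambda s: table.per_state[s][vis].max())
        f_by_state = {r.state: r.f for r in table1}
        assert f_by_state[dominant] == pytest.approx(0.0238)


class TestPhotolysisRate:
    def _flat_spectrum(self, sigma_val, lo_nm=300.0, hi_nm=420.0):
        e = np.linspace(nl.wavelength_to_energy(hi_nm),
                        nl.wavelength_to_energy(lo_nm), 400)
        return nl.SpectrumTable(E_grid=e, sigma=np.full_like(e, sigma_val),
                                dsigma=np.zeros_like(e))

    def test_rectangle_integral(self):
        """φ = 1, σ = 1e-19 cm², I = 1e14 photons cm⁻²s⁻¹nm⁻¹ over a 100 nm
        window gives J = 1e-3 s⁻¹."""
        table = self._flat_spectrum(1e-19, 290.0, 430.0)
        lam = np.linspace(300.0, 400.0, 201)
        inputs = nl.PhotolysisInputs(lambda_nm=lam, phi=np.ones_like(lam),
                                     irradiance=np.full_like(lam, 1e14))
        assert nl.photolysis_rate(table, inputs) == pytest.approx(1e-3,
                                                                  rel=1e-6)

    def test_zero_quantum_yield(self):
        table = self._flat_spectrum(1e-19)
        lam = np.linspace(310.0, 410.0, 51)
        inputs = nl.PhotolysisInputs(lambda_nm=lam, phi=np.zeros_like(lam),
                                     irradiance=np.full_like(lam, 1e14))
        assert nl.photolysis_rate(table, inputs) == 0.0

    def test_quadrature_convergence_on_smooth_band(self, table1):
        table = nl.cross_section(table1, nl.LineShapeParams())
        results = []
        for n in (801, 1601):
            lam = np.linspace(360.0, 500.0, n)
            inputs = nl.PhotolysisInputs(
                lambda_nm=lam, phi=np.ones_like(lam),
                irradiance=np.full_like(lam, 1e14),
            )
            results.append(nl.photolysis_rate(table, inputs))
        assert results[1] == pytest.approx(results[0], rel=1e-6)

    def test_disjoint_grids_rejected(self):
        table = self._flat_spectrum(1e-19, 300.0, 420.0)
        lam = np.linspace(600.0, 700.0, 11)
        inputs = nl.PhotolysisInputs(lambda_nm=lam, phi=np.ones_like(lam),
                                     irradiance=np.ones_like(lam))
        with pytest.raises(ValueError, match="disjoint"):
            nl.photolysis_rate(table, inputs)
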