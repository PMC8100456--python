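"""Forward-model oracles: Rg geometry, the empirical Rh relation, the Debye
equation against brute force, Guinier recovery and PRE distance averaging."""

import numpy as np
import pytest

from saxsbme import (
    ConformationalEnsemble,
    ScatteringProfile,
    compute_rg,
    compute_rh_from_rg,
    debye_saxs_frame,
    ensemble_rh,
    ensemble_saxs,
    frame_rg_series,
    guinier_fit,
    mean_inverse_r6,
    pre_distances,
    pre_ratio_profile,
    ratios_from_mean_r6,
)
from saxsbme.forward_models import PREParameters, gaussian_bead_form_factor


class TestRg:
    def test_point_mass_is_zero(self):
        assert compute_rg(np.zeros((1, 3))) == 0.0

    def test_two_beads_symmetry(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert compute_rg(coords) == pytest.approx(1.0)

    def test_square_closed_form(self):
        coords = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float)
        assert compute_rg(coords) == pytest.approx(np.sqrt(2.0))

    def test_zero_weight_error(self):
        with pytest.raises(ValueError, match="weight"):
            compute_rg(np.zeros((2, 3)), np.zeros(2))


class TestRh:
    def test_monotone_in_rg(self):
        assert compute_rh_from_rg(20.0, 140) < compute_rh_from_rg(30.0, 140)

    def test_published_relation_value(self):
        # independent transcription of the empirical relation, evaluated by hand
        assert compute_rh_from_rg(29.7, 140) == pytest.approx(31.050414889243186, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_rh_from_rg(-1.0, 140)
        with pytest.raises(ValueError):
            compute_rh_from_rg(20.0, 1)

    def test_compact_vs_expanded_ordering(self):
        from saxsbme import generate_chain_ensemble

        compact = generate_chain_ensemble(30, 20, compaction=7.0, seed=3, rg_spring=1.0)
        expanded = generate_chain_ensemble(30, 20, seed=3)
        assert frame_rg_series(compact).mean() < frame_rg_series(expanded).mean()
        assert ensemble_rh(compact) < ensemble_rh(expanded)


class TestDebye:
    q = np.linspace(0.01, 0.3, 12)

    def test_single_bead_unity(self):
        np.testing.assert_allclose(debye_saxs_frame(np.zeros((1, 3)), None, self.q), 1.0)

    def test_two_bead_closed_form(self):
        r = 7.5
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        expected = 2 * (1 + np.sin(self.q * r) / (self.q * r))
        np.testing.assert_allclose(debye_saxs_frame(coords, None, self.q), expected,
                                   rtol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(scale=10.0, size=(20, 3))
        f = rng.uniform(0.5, 2.0, size=20)
        got = debye_saxs_frame(coords, f, self.q)
        brute = np.zeros_like(self.q)
        for a in range(20):
            for b in range(20):
                r = np.linalg.norm(coords[a] - coords[b])
                qr = self.q * r
                term = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1), 1.0)
                brute += f[a] * f[b] * term
        np.testing.assert_allclose(got, brute, rtol=1e-10)

    def test_low_q_limit_is_total_scattering_squared(self, rng):
        coords = rng.normal(scale=8.0, size=(15, 3))
        f = rng.uniform(0.5, 2.0, size=15)
        i0 = debye_saxs_frame(coords, f, np.array([1e-6]))[0]
        assert i0 == pytest.approx(f.sum() ** 2, rel=1e-6)

    def test_gaussian_form_factor_damps(self, rng):
        coords = rng.normal(scale=8.0, size=(10, 3))
        flat = debye_saxs_frame(coords, None, self.q)
        smeared = debye_saxs_frame(
            coords, gaussian_bead_form_factor(np.ones(10), r_bead=3.0), self.q
        )
        assert np.all(smeared <= flat + 1e-12)

    def test_nan_coordinates_rejected(self):
        coords = np.array([[0.0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError, match="NaN|finite"):
            debye_saxs_frame(coords, None, self.q)


class TestEnsembleAverage:
    def _two_frame(self):
        f1 = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        f2 = np.array([[0.0, 0, 0], [8.0, 0, 0], [16.0, 0, 0]])
        return ConformationalEnsemble(coords=np.stack([f1, f2]))

    def test_delta_weights_select_frame(self):
        ens = self._two_frame()
        q = np.linspace(0.02, 0.2, 8)
        one = debye_saxs_frame(ens.coords[0], None, q)
        np.testing.assert_allclose(ensemble_saxs(ens, np.array([1.0, 0.0]), q), one,
                                   rtol=1e-12)

    def test_half_weights_are_arithmetic_mean(self):
        ens = self._two_frame()
        q = np.linspace(0.02, 0.2, 8)
        a = debye_saxs_frame(ens.coords[0], None, q)
        b = debye_saxs_frame(ens.coords[1], None, q)
        np.testing.assert_allclose(
            ensemble_saxs(ens, np.array([0.5, 0.5]), q), (a + b) / 2, rtol=1e-12
        )

    def test_linearity_in_weights(self, chain_ensemble, rng):
        q = np.linspace(0.02, 0.2, 6)
        n = chain_ensemble.n_frames
        w1 = rng.dirichlet(np.ones(n))
        w2 = rng.dirichlet(np.ones(n))
        alpha = 0.3
        mix = ensemble_saxs(chain_ensemble, alpha * w1 + (1 - alpha) * w2, q)
        parts = alpha * ensemble_saxs(chain_ensemble, w1, q) + (1 - alpha) * ensemble_saxs(
            chain_ensemble, w2, q
        )
        np.testing.assert_allclose(mix, parts, rtol=1e-10)

    def test_weight_length_mismatch(self, chain_ensemble):
        with pytest.raises(ValueError, match="length"):
            ensemble_saxs(chain_ensemble, np.ones(3), np.linspace(0.02, 0.2, 5))


class TestGuinier:
    @pytest.mark.parametrize("rg", [10.0, 20.0, 35.5, 50.0])
    def test_exact_gaussian_curve_recovery(self, rg):
        q = np.linspace(0.004, 0.05, 60)
        prof = ScatteringProfile(
            q=q, intensity=100 * np.exp(-(q**2) * rg**2 / 3), sigma=np.full_like(q, 0.01)
        )
        fit = guinier_fit(prof)
        assert fit.rg == pytest.approx(rg, rel=1e-3)
        assert fit.i0 == pytest.approx(100.0, rel=1e-3)
        assert fit.q_range_used[1] * fit.rg <= 1.1 + 1e-9

    def test_noisy_curve_within_two_percent(self, rng):
        rg = 35.5
        q = np.linspace(0.005, 0.03, 40)
        ideal = 100 * np.exp(-(q**2) * rg**2 / 3)
        noisy = ideal * (1 + 0.01 * rng.standard_normal(len(q)))
        fit = guinier_fit(ScatteringProfile(q=q, intensity=noisy, sigma=0.01 * ideal))
        assert fit.rg == pytest.approx(rg, rel=0.02)

    def test_flat_profile_reports_zero_with_warning(self):
        q = np.linspace(0.005, 0.03, 10)
        prof = ScatteringProfile(q=q, intensity=np.full_like(q, 5.0),
                                 sigma=np.full_like(q, 0.1))
        with pytest.warns(UserWarning, match="no Guinier regime"):
            fit = guinier_fit(prof)
        assert fit.rg == 0.0

    def test_rising_profile_rejected(self):
        q = np.linspace(0.005, 0.03, 10)
        prof = ScatteringProfile(q=q, intensity=np.exp(+(q**2) * 100), sigma=np.full_like(q, 0.1))
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(prof)


class TestPre:
    def test_far_label_ratio_approaches_one(self):
        # a straight, very extended chain: residues far from the label
        coords = np.zeros((1, 60, 3))
        coords[0, :, 0] = np.arange(60) * 50.0
        ens = ConformationalEnsemble(coords=coords)
        residues, ratios = pre_ratio_profile(ens, None, 1)
        assert np.all(ratios[residues > 10] > 0.999)

    def test_hand_oracle_two_frames(self):
        # distances 15 Å and 40 Å with weights [0.1, 0.9]
        r6m = np.array([0.1 * 15.0**-6 + 0.9 * 40.0**-6])
        got = ratios_from_mean_r6(r6m)[0]
        assert got == pytest.approx(0.9517291538559423, rel=1e-10)

    def test_mean_inverse_r6_weighting(self):
        d = np.array([[15.0], [40.0]])
        got = mean_inverse_r6(d, np.array([0.1, 0.9]))[0]
        assert got == pytest.approx(0.1 * 15.0**-6 + 0.9 * 40.0**-6, rel=1e-12)

    def test_halving_distances_scales_r6_by_64(self, chain_ensemble):
        _, d = pre_distances(chain_ensemble, 10)
        w = chain_ensemble.prior_weights
        np.testing.assert_allclose(
            mean_inverse_r6(d / 2, w), 64 * mean_inverse_r6(d, w), rtol=1e-12
        )

    def test_monotone_in_distance(self, rng):
        d = rng.uniform(10, 40, size=(30, 8))
        w = rng.dirichlet(np.ones(30))
        base = ratios_from_mean_r6(mean_inverse_r6(d, w))
        grown = ratios_from_mean_r6(mean_inverse_r6(d * 1.1, w))
        assert np.all(grown >= base)

    def test_label_pseudoatom_displacement(self, chain_ensemble):
        from saxsbme.forward_models import _label_positions

        pos = _label_positions(chain_ensemble.coords, 9, 6.0)
        d = np.linalg.norm(pos - chain_ensemble.coords[:, 9], axis=1)
        np.testing.assert_allclose(d, 6.0, rtol=1e-9)

    def test_site_outside_chain_rejected(self, chain_ensemble):
        with pytest.raises(ValueError, match="label_site"):
            pre_ratio_profile(chain_ensemble, None, 500)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PREParameters(tau_c=-1.0)
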