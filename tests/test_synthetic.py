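"""Generator contracts: partition of unity, coil-profile geometry,
Rician statistics, determinism."""

import numpy as np
import pytest

from coilbias.synthetic import (CohortConfig, CoilProfile, anterior_third,
                                central_third, make_cohort, make_coil_profile,
                                make_diffusion_scheme, make_tensor_truth,
                                make_tissue_phantom, posterior_third, rician,
                                simulate_bold, simulate_dwi, simulate_t1)

GRID = (32, 32, 32)
VOX = 4.0


class TestPhantom:
    def test_partition_of_unity(self, phantom):
        total = (phantom.pv_gm + phantom.pv_wm + phantom.pv_csf
                 + phantom.pv_background)
        assert np.abs(total - 1.0).max() <= 1e-6
        for pv in (phantom.pv_gm, phantom.pv_wm, phantom.pv_csf):
            assert pv.min() >= 0.0 and pv.max() <= 1.0

    def test_deterministic_under_seed(self):
        a = make_tissue_phantom(GRID, VOX, seed=11)
        b = make_tissue_phantom(GRID, VOX, seed=11)
        assert np.array_equal(a.pv_gm, b.pv_gm)
        assert np.array_equal(a.pv_wm, b.pv_wm)

    def test_gm_shell_larger_than_wm_core(self):
        ph = make_tissue_phantom((64, 64, 64), 2.0, seed=0)
        assert (ph.pv_wm > 0.5).sum() < (ph.pv_gm > 0.5).sum()

    def test_rejects_grid_too_small(self):
        with pytest.raises(ValueError, match="cannot contain|at least 32"):
            make_tissue_phantom((32, 32, 32), 1.0, seed=0)


class TestCoilProfile:
    def test_frontal_high_central_drop(self, coil8):
        ratio = (anterior_third(coil8.gain).mean()
                 / central_third(coil8.gain).mean())
        assert ratio >= 1.15

    def test_homogeneity_ordering(self, coil8, coil32):
        cv8 = coil8.gain.std() / coil8.gain.mean()
        cv32 = coil32.gain.std() / coil32.gain.mean()
        assert cv32 < cv8

    def test_posterior_dominance_32ch(self, coil32):
        assert (posterior_third(coil32.gain).mean()
                >= anterior_third(coil32.gain).mean())

    def test_zero_params_uniform(self):
        c = make_coil_profile("eight_ch", GRID, VOX, params={"a": 0, "b": 0})
        assert c.gain.std() == 0.0

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            make_coil_profile("eight_ch", GRID, VOX, params={"b": 1.5})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            make_coil_profile("four_ch", GRID, VOX)


class TestRicianNoise:
    def test_noise_free_background_statistics(self, phantom):
        """Signal-free voxels are Rayleigh: mean sigma*sqrt(pi/2), SD
        sigma*sqrt((4-pi)/2)."""
        sigma = 25.0
        coil = CoilProfile("eight_ch", np.ones(GRID), sigma, VOX)
        img = simulate_t1(phantom, coil, seed=2)
        bg = phantom.pv_background > 0.999
        assert bg.sum() >= 10_000
        assert img[bg].mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)
        ratio = img[bg].std() / sigma
        assert 0.95 * np.sqrt((4 - np.pi) / 2) <= ratio <= 1.05 * np.sqrt((4 - np.pi) / 2)

    def test_zero_sigma_exact_mixture(self, phantom, coil8):
        noiseless = CoilProfile(coil8.kind, coil8.gain, 0.0, VOX)
        img = simulate_t1(phantom, noiseless, seed=0)
        m = phantom.tissue_means
        expected = (phantom.pv_csf * m["csf"] + phantom.pv_gm * m["gm"]
                    + phantom.pv_wm * m["wm"]) * coil8.gain
        np.testing.assert_allclose(img, expected)

    def test_same_seed_identical(self, phantom, coil8):
        a = simulate_t1(phantom, coil8, seed=42)
        b = simulate_t1(phantom, coil8, seed=42)
        assert np.array_equal(a, b)


class TestDiffusionSim:
    def test_scheme_invariants(self, scheme):
        assert scheme.n_b0 >= 1
        assert scheme.n_volumes == 61
        dw = scheme.bvals > 0
        np.testing.assert_allclose(np.linalg.norm(scheme.bvecs[dw], axis=1), 1.0)
        # non-collinear: no pair of directions exactly (anti)parallel
        g = scheme.bvecs[dw]
        dots = np.abs(g @ g.T) - np.eye(len(g))
        assert dots.max() < 1.0 - 1e-6

    def test_b0_is_gain_weighted_s0(self, phantom, flat_coil, scheme,
                                    tensor_truth):
        stack = simulate_dwi(phantom, tensor_truth, scheme, flat_coil, seed=0)
        from coilbias.synthetic import DEFAULT_S0_MEANS as S0
        expected = (phantom.pv_csf * S0["csf"] + phantom.pv_gm * S0["gm"]
                    + phantom.pv_wm * S0["wm"])
        np.testing.assert_allclose(stack[..., 0], expected, atol=1e-9)

    def test_isotropic_attenuation_closed_form(self, flat_coil):
        """D = 1e-3 I at b=1000 gives S/S0 = exp(-1) in every direction."""
        ph = make_tissue_phantom(GRID, VOX, seed=1)
        from coilbias.synthetic import TensorFieldTruth
        d = np.broadcast_to(1e-3 * np.eye(3), GRID + (3, 3)).copy()
        truth = TensorFieldTruth(d_tensor=d, principal_direction=None)
        scheme = make_diffusion_scheme()
        stack = simulate_dwi(ph, truth, scheme, flat_coil, seed=0)
        inside = ph.pv_wm > 0.99
        s0 = stack[..., 0][inside]
        for vol in range(1, scheme.n_volumes):
            np.testing.assert_allclose(stack[..., vol][inside] / s0,
                                       np.exp(-1.0), rtol=1e-10)

    def test_stick_parallel_attenuates_more(self):
        from coilbias.synthetic import _tensor_from_eigs
        d = _tensor_from_eigs((1.5e-3, 0.1e-3, 0.1e-3), [1.0, 0.0, 0.0])
        g_par = np.array([1.0, 0.0, 0.0])
        g_perp = np.array([0.0, 1.0, 0.0])
        att = lambda g: np.exp(-1000.0 * g @ d @ g)  # noqa: E731
        assert att(g_par) < att(g_perp)

    def test_negative_bval_rejected(self, phantom, flat_coil, tensor_truth):
        from coilbias.synthetic import DiffusionScheme
        bad = DiffusionScheme(bvals=np.array([-1.0, 0.0]),
                              bvecs=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="negative b-value"):
            simulate_dwi(phantom, tensor_truth, bad, flat_coil)

    def test_truth_field_wm_fa_floor(self, phantom, tensor_truth):
        from coilbias.dti import fa_of_tensor
        wm = np.argwhere(phantom.pv_wm > 0.99)[:50]
        for i, j, k in wm:
            lam = np.linalg.eigvalsh(tensor_truth.d_tensor[i, j, k])
            assert fa_of_tensor(lam) >= 0.4


class TestBoldSim:
    def test_zero_amplitude_zero_noise_is_zero(self, phantom, flat_coil):
        from coilbias.rsfmri import make_network_templates
        tpl = make_network_templates(GRID, VOX, phantom=phantom)
        data = simulate_bold(phantom, tpl, [0.0] * 8, flat_coil,
                             n_volumes=24, seed=0, noise_sigma=0.0,
                             nuisance_amplitude=0.0)
        assert np.abs(data).max() == 0.0

    def test_single_template_series_proportional(self, phantom, flat_coil):
        from coilbias.rsfmri import NetworkTemplateSet, make_network_templates
        tpl8 = make_network_templates(GRID, VOX, phantom=phantom)
        tpl = NetworkTemplateSet([tpl8.network_maps[0]], tpl8.nuisance_maps,
                                 ("net",))
        data = simulate_bold(phantom, tpl, [1.0], flat_coil, n_volumes=30,
                             seed=3, noise_sigma=0.0, nuisance_amplitude=0.0)
        m = tpl.network_maps[0]
        i0 = np.unravel_index(np.argmax(m), m.shape)
        ref = data[i0]
        sel = m > 0.05
        expected = m[sel, None] / m[i0] * ref[None, :]
        np.testing.assert_allclose(data[sel, :], expected, atol=1e-10)


class TestCohort:
    def test_cohort_shapes_and_determinism(self):
        cfg = CohortConfig(modalities=("t1",))
        a = make_cohort(4, cfg, seed=9)
        b = make_cohort(4, cfg, seed=9)
        assert len(a) == 4
        for s, t in zip(a, b):
            assert s.subject_id == t.subject_id
            assert s.age == t.age and s.sex == t.sex
            assert np.array_equal(s.t1_8ch, t.t1_8ch)
            assert np.array_equal(s.t1_32ch, t.t1_32ch)

    def test_pair_shares_phantom_and_differs_only_by_coil(self):
        cfg = CohortConfig(noise_sigma_8ch=0.0, noise_sigma_32ch=0.0)
        cohort = make_cohort(2, cfg, seed=1)
        s = cohort[0]
        g8 = s.truth["gain_8ch"]
        g32 = s.truth["gain_32ch"]
        # noiseless: acquisitions differ exactly by the gain ratio
        np.testing.assert_allclose(s.t1_32ch * g8, s.t1_8ch * g32, rtol=1e-10)

    def test_min_subjects(self):
        with pytest.raises(ValueError):
            make_cohort(1, CohortConfig(), seed=0)
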