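"""Paired inference engine: t-map arithmetic, TFCE against a brute-force
oracle, sign-flip permutation exactness, symmetry and calibration."""

import numpy as np
import pytest
from scipy import ndimage

from coilbias.stats import (EffectSummary, paired_t, permutation_fwe,
                            summarize_effect, tfce)

SHAPE = (10, 10, 10)
FULL = np.ones(SHAPE, bool)


def brute_force_tfce(stat, mask, h_power=2.0, e_power=0.5, n_steps=100,
                     connectivity=26):
    """Independent oracle: label the suprathreshold set at every discrete
    threshold and sum extent^E * height^H * dh."""
    stat = np.where(mask, np.clip(stat, 0, None), 0.0)
    vmax = stat.max()
    out = np.zeros(stat.shape)
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    struct = (np.ones((3, 3, 3), int) if connectivity == 26
              else ndimage.generate_binary_structure(3, 1))
    for k in range(1, n_steps + 1):
        h = k * dh
        # same tie convention as the implementation: voxels within 1e-12
        # (relative) of a threshold are suprathreshold
        sup = stat >= h - 1e-12 * vmax
        lab, n_lab = ndimage.label(sup, structure=struct)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        out[sup] += (sizes[lab][sup] ** e_power) * (h**h_power) * dh
    return out


class TestPairedT:
    def test_identical_conditions_zero(self):
        maps = [np.random.default_rng(i).random(SHAPE) for i in range(4)]
        t, flag = paired_t(maps, [m.copy() for m in maps], FULL)
        assert np.abs(t).max() == 0.0
        assert flag.all()

    def test_hand_computed_value(self):
        a = [np.zeros(SHAPE)] * 3
        b = [np.full(SHAPE, v) for v in (1.0, 2.0, 3.0)]
        t, _ = paired_t(a, b, FULL)
        assert t[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        a = [rng.random(SHAPE) for _ in range(5)]
        b = [rng.random(SHAPE) for _ in range(5)]
        t1, _ = paired_t(a, b, FULL)
        perm = [3, 1, 4, 0, 2]
        t2, _ = paired_t([a[i] for i in perm], [b[i] for i in perm], FULL)
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            paired_t([np.zeros(SHAPE)] * 2, [np.zeros(SHAPE)] * 2, FULL)


class TestTfce:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        stat = ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0) * 4
        mine = tfce(stat, FULL)
        ref = brute_force_tfce(stat, FULL)
        assert np.abs(mine - ref).max() <= 1e-6 * ref.max()

    def test_matches_oracle_on_masked_map(self, ball_mask):
        rng = np.random.default_rng(2)
        sub = ball_mask[11:21, 11:21, 11:21]
        stat = rng.standard_normal(SHAPE) * 2
        mine = tfce(stat, sub)
        ref = brute_force_tfce(stat, sub)
        assert np.abs(mine - ref).max() <= 1e-6 * max(ref.max(), 1e-30)

    def test_single_voxel_discrete_sum(self):
        stat = np.zeros(SHAPE)
        stat[4, 4, 4] = 1.0
        val = tfce(stat, FULL)[4, 4, 4]
        expected = sum((k * 0.01) ** 2 * 0.01 for k in range(1, 101))
        assert val == pytest.approx(expected, rel=1e-12)

    def test_all_zero_map(self):
        assert np.abs(tfce(np.zeros(SHAPE), FULL)).max() == 0.0

    def test_cubic_homogeneity(self):
        """With adaptive dh, scaling the map by c scales TFCE by c^(H+1)."""
        rng = np.random.default_rng(4)
        stat = ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)
        base = tfce(stat, FULL)
        for c in (2.0, 5.0):
            np.testing.assert_allclose(tfce(c * stat, FULL), c**3 * base,
                                       rtol=1e-10)

    def test_six_connectivity(self):
        rng = np.random.default_rng(5)
        stat = rng.standard_normal(SHAPE)
        mine = tfce(stat, FULL, connectivity=6)
        ref = brute_force_tfce(stat, FULL, connectivity=6)
        assert np.abs(mine - ref).max() <= 1e-6 * ref.max()

    def test_negative_only_map_is_zero_positive_direction(self):
        stat = -np.abs(np.random.default_rng(6).standard_normal(SHAPE))
        assert tfce(stat, FULL).max() == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tfce(np.ones(SHAPE), np.zeros(SHAPE, bool))


class TestPermutationFwe:
    def _cohort(self, n, seed, effect=0.0):
        rng = np.random.default_rng(seed)
        a = [ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)
             for _ in range(n)]
        b = [ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0) + effect
             for _ in range(n)]
        return a, b

    def test_sampling_equals_enumeration_n5(self):
        """2^5 = 32 <= n_perm forces full enumeration regardless of seed."""
        a, b = self._cohort(5, 0)
        r1 = permutation_fwe(a, b, FULL, n_perm=5000, seed=1)
        r2 = permutation_fwe(a, b, FULL, n_perm=5000, seed=12345)
        assert r1.enumerated and r2.enumerated
        assert r1.n_permutations == 32
        np.testing.assert_array_equal(r1.p_fwe_pos, r2.p_fwe_pos)
        np.testing.assert_array_equal(r1.p_fwe_neg, r2.p_fwe_neg)

    def test_seed_determinism_sampled(self):
        a, b = self._cohort(10, 1)
        r1 = permutation_fwe(a, b, FULL, n_perm=200, seed=7)
        r2 = permutation_fwe(a, b, FULL, n_perm=200, seed=7)
        np.testing.assert_array_equal(r1.p_fwe_pos, r2.p_fwe_pos)
        assert not r1.enumerated

    def test_p_floor_and_monotonicity(self):
        a, b = self._cohort(6, 2, effect=0.5)
        r = permutation_fwe(a, b, FULL, n_perm=5000, seed=0)
        inside = r.p_fwe_pos[r.mask]
        assert inside.min() >= 1.0 / r.n_permutations - 1e-12
        # p is non-increasing in the observed TFCE value
        tf = r.tfce_pos[r.mask]
        order = np.argsort(tf)
        assert np.all(np.diff(inside[order]) <= 1e-12)

    def test_direction_symmetry_exact(self):
        a, b = self._cohort(9, 3, effect=0.3)
        # swapping conditions negates every difference map exactly
        r = permutation_fwe(a, b, FULL, n_perm=300, seed=5)
        rn = permutation_fwe(b, a, FULL, n_perm=300, seed=5)
        np.testing.assert_array_equal(r.p_fwe_pos, rn.p_fwe_neg)
        np.testing.assert_array_equal(r.p_fwe_neg, rn.p_fwe_pos)
        np.testing.assert_allclose(r.tfce_pos, rn.tfce_neg, atol=1e-12)

    def test_injected_effect_recovered(self, ball_mask):
        """A 5% multiplicative effect confined to a known region is found
        with Dice >= 0.5 at n=20."""
        rng = np.random.default_rng(11)
        region = np.zeros(SHAPE, bool)
        region[3:7, 3:7, 3:7] = True
        base = 100.0 + ndimage.gaussian_filter(
            rng.standard_normal((20,) + SHAPE), 1.0) * 2.0
        a = list(base)
        b = [x * np.where(region, 1.05, 1.0)
             + ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0) * 0.5
             for x in base]
        r = permutation_fwe(a, b, FULL, n_perm=500, seed=3)
        inter = (r.sig_mask_pos & region).sum()
        dice = 2 * inter / (r.sig_mask_pos.sum() + region.sum())
        assert dice >= 0.5

    def test_zero_variance_voxels_flagged(self):
        a = [np.zeros(SHAPE) for _ in range(4)]
        b = [np.zeros(SHAPE) for _ in range(4)]
        t, flag = paired_t(a, b, FULL)
        assert flag.all() and np.abs(t).max() == 0.0

    def test_low_n_perm_warns(self):
        a, b = self._cohort(8, 4)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_fwe(a, b, FULL, n_perm=50, seed=0)

    def test_seed_required_for_sampling(self):
        a, b = self._cohort(10, 5)
        with pytest.raises(ValueError, match="seed"):
            permutation_fwe(a, b, FULL, n_perm=200, seed=None)


class TestEffectSummary:
    def test_uniform_multiplicative_change(self):
        rng = np.random.default_rng(0)
        a = [rng.uniform(50, 150, SHAPE) for _ in range(6)]
        b = [1.062 * x for x in a]
        s = summarize_effect(a, b, FULL)
        assert s.pct_change == pytest.approx(6.2, rel=1e-9)
        assert not s.degenerate

    def test_constant_difference_degenerate(self):
        a = [np.zeros(SHAPE)] * 4
        b = [np.ones(SHAPE)] * 4
        s = summarize_effect(a, b, FULL)
        assert s.degenerate and np.isinf(s.effect_size)

    def test_swap_negates_effect_size(self):
        rng = np.random.default_rng(1)
        a = [rng.uniform(80, 120, SHAPE) for _ in range(5)]
        b = [x + rng.normal(2, 1, SHAPE) for x in a]
        s_ab = summarize_effect(a, b, FULL)
        s_ba = summarize_effect(b, a, FULL)
        assert s_ba.effect_size == pytest.approx(-s_ab.effect_size, rel=1e-12)
        assert np.sign(s_ba.pct_change) == -np.sign(s_ab.pct_change)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_effect([np.ones(SHAPE)] * 3, [np.ones(SHAPE)] * 3,
                             np.zeros(SHAPE, bool))
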