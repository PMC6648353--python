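"""Paired within-subject inference: t-maps, TFCE, sign-flip permutation FWE.

The paired design is realized as a one-sample test on per-subject
difference maps d_i = b_i - a_i.  Under the null of no coil effect each
subject's difference is sign-symmetric, so the permutation group is the
2^n sign flips of the subjects.  The permutation statistic is the
TFCE-transformed t-map; family-wise error control comes from the null
distribution of its maximum over the analysis mask (the observed labeling
is always a member of the null).  Both directions are tested: the negative
direction is the same machinery on the negated difference maps.

Defaults follow the method's canonical choices: TFCE H=2, E=0.5,
26-connectivity, 100 adaptive threshold steps; 5000 permutations at
alpha = 0.05 (full enumeration replaces sampling whenever 2^n <= n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tfce import neighbor_table, tfce_compact

__all__ = ["PairedStatResult", "EffectSummary", "paired_t", "tfce",
           "permutation_fwe", "summarize_effect"]


@dataclass
class EffectSummary:
    """Pooled effect over a significant-voxel set.

    ``effect_size`` is the paired Cohen's d of the pooled per-subject
    differences; ``pct_change`` is 100 * (mean_b - mean_a) / mean_a with
    the first condition (the 8-channel coil in the paired-coil design) as
    baseline.  ``degenerate`` marks zero-variance differences (d -> inf).
    """

    effect_size: float
    pct_change: float
    n_voxels: int
    degenerate: bool = False


@dataclass
class PairedStatResult:
    """Full output of a paired TFCE/FWE permutation analysis."""

    t_map: np.ndarray
    tfce_pos: np.ndarray
    tfce_neg: np.ndarray
    p_fwe_pos: np.ndarray   # 1 outside the mask
    p_fwe_neg: np.ndarray
    sig_mask_pos: np.ndarray
    sig_mask_neg: np.ndarray
    effect_pos: EffectSummary | None
    effect_neg: EffectSummary | None
    mask: np.ndarray
    n_permutations: int
    enumerated: bool
    seed: int | None
    alpha: float
    tfce_h: float
    tfce_e: float
    connectivity: int
    zero_variance: np.ndarray | None = None
    null_max: np.ndarray | None = None


def _stack(maps) -> np.ndarray:
    arrs = [np.asarray(m, dtype=float) for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError("maps have inconsistent shapes")
    return np.stack(arrs)


def paired_t(maps_a, maps_b, mask: np.ndarray):
    """Voxelwise paired t-map: t = mean(d) / (SD(d)/sqrt(n)), d = b - a.

    Subjects must be aligned across the two lists (same order).  Voxels
    with zero difference variance get t = 0 and are flagged in the second
    return value.
    """
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape != b.shape:
        raise ValueError("maps_a and maps_b must match in count and shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    mask = np.asarray(mask, dtype=bool)
    d = (b - a).reshape(n, -1)[:, mask.ravel()]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = 0.0
    t_map = np.zeros(mask.shape)
    t_map[mask] = t
    flag = np.zeros(mask.shape, dtype=bool)
    flag[mask] = zero
    return t_map, flag


def tfce(stat_map: np.ndarray, mask: np.ndarray, h: float = 2.0,
         e: float = 0.5, n_steps: int = 100, connectivity: int = 26
         ) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    Integrates component-extent^e * height^h over ``n_steps`` adaptive
    thresholds (dh = max/n_steps) under the given voxel connectivity.
    For the negative direction call with the negated map.  Raises on an
    empty mask.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    nb = neighbor_table(mask, connectivity)
    vals = np.asarray(stat_map, dtype=float)[mask]
    out = np.zeros(mask.shape)
    out[mask] = tfce_compact(np.clip(vals, 0.0, None), nb, n_steps, e, h)
    return out


def _sign_patterns(n: int, n_perm: int, seed: int | None):
    """Sign-flip patterns: identity first; complement-closed random sample,
    or the full 2^n enumeration when it is no larger than ``n_perm``."""
    if 2**n <= n_perm:
        grid = np.indices((2,) * n).reshape(n, -1).T
        signs = 1 - 2 * grid  # rows of +-1; first row all +1
        return signs.astype(np.int8), True
    if seed is None:
        raise ValueError("a seed is mandatory for sampled permutations")
    rng = np.random.default_rng(seed)
    patterns = [np.ones(n, dtype=np.int8), -np.ones(n, dtype=np.int8)]
    remaining = n_perm - 2
    for _ in range(remaining // 2):
        s = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
        patterns.append(s)
        patterns.append(-s)
    if remaining % 2:
        patterns.append(rng.choice(np.array([-1, 1], dtype=np.int8), size=n))
    return np.stack(patterns), False


def permutation_fwe(maps_a, maps_b, mask: np.ndarray, n_perm: int = 5000,
                    seed: int | None = 0, alpha: float = 0.05,
                    tfce_h: float = 2.0, tfce_e: float = 0.5,
                    tfce_steps: int = 100, connectivity: int = 26
                    ) -> PairedStatResult:
    """Sign-flip max-TFCE permutation test with FWE-corrected p-maps.

    For each direction, p_fwe(v) is the proportion of null maxima (over
    the mask, observed labeling included) at or above the observed TFCE
    value, so p_fwe >= 1/n_perm always.  Significant masks threshold the
    p-maps at ``alpha``.  Sampled runs are deterministic under ``seed``;
    with 2^n <= n_perm the full enumeration is used and the seed is moot.

    The sampled sign patterns are closed under negation (each random
    pattern is paired with its complement), which makes the two directions
    share one null distribution and renders the positive/negative symmetry
    exact.
    """
    import warnings

    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape != b.shape:
        raise ValueError("maps_a and maps_b must match in count and shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    d = (b - a).reshape(n, -1)[:, mask.ravel()]  # (n, V)
    sumsq = np.sum(d**2, axis=0)
    nb_table = neighbor_table(mask, connectivity)

    signs, enumerated = _sign_patterns(n, n_perm, seed)
    n_used = len(signs)

    # all permuted t-maps in one pass (sign flips only change the mean term)
    means = (signs.astype(float) @ d) / n  # (P, V)
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmaps = means / np.sqrt(var / n)
    tmaps[~np.isfinite(tmaps)] = 0.0

    null_max = np.empty(n_used)
    tfce_obs_pos = None
    tfce_obs_neg = None
    for p in range(n_used):
        tv = tmaps[p]
        tf_pos = tfce_compact(np.clip(tv, 0.0, None), nb_table,
                              tfce_steps, tfce_e, tfce_h)
        null_max[p] = tf_pos.max() if tf_pos.size else 0.0
        if p == 0:  # identity labeling: keep both observed directions
            tfce_obs_pos = tf_pos
            tfce_obs_neg = tfce_compact(np.clip(-tv, 0.0, None), nb_table,
                                        tfce_steps, tfce_e, tfce_h)

    # p(v) = fraction of null maxima >= observed, via sorted search
    sorted_null = np.sort(null_max)
    def pvals(obs):
        geq = n_used - np.searchsorted(sorted_null, obs, side="left")
        return geq / n_used

    p_pos_c = pvals(tfce_obs_pos)
    p_neg_c = pvals(tfce_obs_neg)

    t_map, zero_flag = paired_t(maps_a, maps_b, mask)

    def expand(vals, fill=0.0):
        out = np.full(mask.shape, fill)
        out[mask] = vals
        return out

    p_fwe_pos = expand(p_pos_c, fill=1.0)
    p_fwe_neg = expand(p_neg_c, fill=1.0)
    sig_pos = (p_fwe_pos < alpha) & mask
    sig_neg = (p_fwe_neg < alpha) & mask

    eff_pos = summarize_effect(maps_a, maps_b, sig_pos) if sig_pos.any() else None
    eff_neg = summarize_effect(maps_a, maps_b, sig_neg) if sig_neg.any() else None

    res = PairedStatResult(
        t_map=t_map, tfce_pos=expand(tfce_obs_pos), tfce_neg=expand(tfce_obs_neg),
        p_fwe_pos=p_fwe_pos, p_fwe_neg=p_fwe_neg,
        sig_mask_pos=sig_pos, sig_mask_neg=sig_neg,
        effect_pos=eff_pos, effect_neg=eff_neg, mask=mask,
        n_permutations=n_used, enumerated=enumerated, seed=seed, alpha=alpha,
        tfce_h=tfce_h, tfce_e=tfce_e, connectivity=connectivity,
        zero_variance=zero_flag,
    )
    res.null_max = null_max
    return res


def summarize_effect(maps_a, maps_b, sig_mask: np.ndarray) -> EffectSummary:
    """Pooled paired Cohen's d and percent change over a significant mask.

    Differences d_i(v) = b_i(v) - a_i(v) are pooled over subjects and mask
    voxels: effect_size = mean(d)/SD(d); pct_change uses the condition-a
    mean as denominator.  Raises on an empty mask; flags zero-variance
    (degenerate) pools with an infinite effect size.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if not sig_mask.any():
        raise ValueError("empty significant mask: effect undefined")
    a = _stack(maps_a)[:, sig_mask]
    b = _stack(maps_b)[:, sig_mask]
    d = (b - a).ravel()
    sd = d.std(ddof=1)
    mean_a = a.mean()
    pct = 100.0 * (b.mean() - mean_a) / mean_a if mean_a != 0 else float("nan")
    if sd == 0:
        es = float("inf") if d.mean() > 0 else (float("-inf") if d.mean() < 0 else 0.0)
        return EffectSummary(effect_size=es, pct_change=pct,
                             n_voxels=int(sig_mask.sum()), degenerate=True)
    return EffectSummary(effect_size=float(d.mean() / sd), pct_change=float(pct),
                         n_voxels=int(sig_mask.sum()))
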