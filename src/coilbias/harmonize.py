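"""Voxel-specific scaling-factor harmonization between two coils.

The cohort is split into a template half and a validation half matched on
age and sex.  Template images of each coil are averaged; the voxelwise
ratio mean(32CH)/mean(8CH), median-filtered with a ~5 mm cubic window,
becomes the ScalingField.  Multiplying validation 8CH images by the field
maps them into 32CH intensity space; success is verified by re-running the
paired inference on the validation pairs before and after scaling.

The ratio is only defined where the 8CH mean has appreciable signal: below
a floor (default 5% of the robust maximum) the field is set to 1 and the
voxel excluded from the valid mask, which prevents division blow-up in
background air.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ScalingField", "split_cohort", "estimate_scaling",
           "apply_scaling", "validate_harmonization", "HarmonizationReport"]


@dataclass
class ScalingField:
    """Voxelwise 32CH/8CH intensity ratio with validity mask."""

    ratio: np.ndarray
    valid_mask: np.ndarray
    filter_mm: float
    n_template: int
    modality: str
    voxel_mm: float = 1.0


def split_cohort(cohort, n_template: int, seed: int = 0):
    """Age/sex-matched template/validation split.

    Within each sex stratum subjects are sorted by age and assigned
    alternately to the two groups, then the assignment is rebalanced (by
    moving the closest-to-the-boundary subjects) to hit ``n_template``
    exactly.  The seed only breaks ties between equal ages.  A sex stratum
    of size 1 goes to the larger (validation-bound) group with a warning.

    Returns ``(template_set, validation_set, report)`` where the report
    holds per-group covariate means.
    """
    import warnings

    n = len(cohort)
    if not 0 < n_template < n:
        raise ValueError("n_template must be between 1 and cohort size - 1")
    rng = np.random.default_rng(seed)
    jitter = rng.random(n) * 1e-9  # tie-breaker only

    template_idx, validation_idx = [], []
    for sex in sorted({s.sex for s in cohort}):
        idx = [i for i, s in enumerate(cohort) if s.sex == sex]
        if len(idx) == 1:
            warnings.warn(f"sex stratum {sex!r} has a single subject; "
                          "assigned to the validation group")
            validation_idx.extend(idx)
            continue
        idx.sort(key=lambda i: (cohort[i].age, jitter[i]))
        template_idx.extend(idx[0::2])
        validation_idx.extend(idx[1::2])

    # rebalance to the requested template size, moving youngest-boundary
    # subjects so age matching degrades as little as possible
    while len(template_idx) > n_template:
        validation_idx.append(template_idx.pop())
    while len(template_idx) < n_template:
        template_idx.append(validation_idx.pop())

    template = [cohort[i] for i in sorted(template_idx)]
    validation = [cohort[i] for i in sorted(validation_idx)]

    def _summary(group):
        ages = [s.age for s in group]
        return {"n": len(group), "mean_age": float(np.mean(ages)),
                "sd_age": float(np.std(ages)),
                "n_female": sum(1 for s in group if s.sex == "F")}

    report = {"template": _summary(template), "validation": _summary(validation)}
    return template, validation, report


def _images(subject, modality: str, coil: str):
    attr = {"t1": "t1", "dwi": "dwi", "bold": "bold"}[modality]
    img = getattr(subject, f"{attr}_{coil}")
    if img is None:
        raise ValueError(f"subject {subject.subject_id} has no {modality} {coil} data")
    return np.asarray(img, dtype=float)


def estimate_scaling(template_set, modality: str = "t1",
                     filter_mm: float = 5.0, voxel_mm: float | None = None,
                     floor_frac: float = 0.05) -> ScalingField:
    """Estimate the voxelwise 32CH/8CH scaling field from the template set.

    Images of each coil are averaged across template subjects (4-D stacks
    are additionally averaged over their last axis, giving one mean volume
    per subject), divided voxelwise, and median-filtered with a cubic
    window of odd side length closest to ``filter_mm`` / voxel size.
    Voxels where the 8CH mean is below ``floor_frac`` of its 99th
    percentile are excluded (ratio set to 1).
    """
    if len(template_set) < 2:
        raise ValueError("need at least 2 template subjects")
    if voxel_mm is None:
        voxel_mm = template_set[0].phantom.voxel_mm

    def mean_image(coil):
        vols = []
        for s in template_set:
            img = _images(s, modality, coil)
            vols.append(img.mean(axis=-1) if img.ndim == 4 else img)
        return np.mean(vols, axis=0)

    mean8 = mean_image("8ch")
    mean32 = mean_image("32ch")
    floor = floor_frac * np.percentile(mean8, 99)
    valid = mean8 > floor
    if not valid.any():
        raise ValueError("8CH mean image is below the signal floor everywhere")

    ratio = np.ones_like(mean8)
    ratio[valid] = mean32[valid] / mean8[valid]
    width = int(round(filter_mm / voxel_mm))
    width = max(1, width + (1 - width % 2))  # nearest odd
    if width > 1:
        ratio = ndimage.median_filter(ratio, size=width, mode="nearest")
    ratio[~valid] = 1.0
    return ScalingField(ratio=ratio, valid_mask=valid, filter_mm=filter_mm,
                        n_template=len(template_set), modality=modality,
                        voxel_mm=voxel_mm)


def apply_scaling(image_8ch: np.ndarray, scaling: ScalingField,
                  modality: str | None = None) -> np.ndarray:
    """Multiply an 8CH image into 32CH intensity space.

    Voxelwise product with the ratio on the valid mask, identity outside.
    4-D stacks are scaled volume-wise.  If ``modality`` is given it must
    match the field's modality tag — a T1-derived field is never silently
    applied to diffusion or BOLD data.
    """
    if modality is not None and modality != scaling.modality:
        raise ValueError(
            f"scaling field is for {scaling.modality!r}, refusing to apply to "
            f"{modality!r} data")
    image_8ch = np.asarray(image_8ch, dtype=float)
    grid = image_8ch.shape[:3] if image_8ch.ndim == 4 else image_8ch.shape
    if grid != scaling.ratio.shape:
        raise ValueError("image grid does not match the scaling field")
    factor = np.where(scaling.valid_mask, scaling.ratio, 1.0)
    if image_8ch.ndim == 4:
        return image_8ch * factor[..., None]
    return image_8ch * factor


@dataclass
class HarmonizationReport:
    """Pre/post paired-inference comparison on the validation set."""

    modality: str
    pre: object   # PairedStatResult
    post: object
    n_sig_pre: dict = field(default_factory=dict)
    n_sig_post: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"modality": self.modality}
        for tag, res in (("pre", self.pre), ("post", self.post)):
            out[f"{tag}_sig_pos"] = int(res.sig_mask_pos.sum())
            out[f"{tag}_sig_neg"] = int(res.sig_mask_neg.sum())
            for d in ("pos", "neg"):
                eff = getattr(res, f"effect_{d}")
                out[f"{tag}_effect_{d}"] = (None if eff is None
                                            else eff.effect_size)
                out[f"{tag}_pct_change_{d}"] = (None if eff is None
                                                else eff.pct_change)
        return out


def validate_harmonization(validation_set, scaling: ScalingField, mask: np.ndarray,
                           extract=None, n_perm: int = 500, seed: int = 0,
                           alpha: float = 0.05, template_set=None
                           ) -> HarmonizationReport:
    """Re-run the paired inference on validation pairs before/after scaling.

    ``extract(image) -> map`` converts a raw image into the per-subject
    analysis map (default: identity for 3-D images).  The template and
    validation sets must be disjoint: pass ``template_set`` to have the
    overlap checked here (a shared subject id raises).
    """
    from .stats import permutation_fwe

    ids = [s.subject_id for s in validation_set]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subjects in the validation set")
    if template_set is not None:
        overlap = set(ids) & {s.subject_id for s in template_set}
        if overlap:
            raise ValueError(f"template/validation sets overlap: {sorted(overlap)}")
    if extract is None:
        extract = lambda img: img  # noqa: E731

    maps_8 = [extract(_images(s, scaling.modality, "8ch")) for s in validation_set]
    maps_32 = [extract(_images(s, scaling.modality, "32ch")) for s in validation_set]
    maps_8h = [extract(apply_scaling(_images(s, scaling.modality, "8ch"), scaling))
               for s in validation_set]

    pre = permutation_fwe(maps_8, maps_32, mask, n_perm=n_perm, seed=seed,
                          alpha=alpha)
    post = permutation_fwe(maps_8h, maps_32, mask, n_perm=n_perm, seed=seed,
                           alpha=alpha)
    return HarmonizationReport(modality=scaling.modality, pre=pre, post=post)
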