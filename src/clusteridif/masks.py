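"""Mask construction: tissue masks from probability maps, and the vascular
template (carotid + surrounding tissue) from averaged blood-weight images.

All literal thresholds ("> 0.9", "> 0.2", "between 0.001 and 0.1") are
strict inequalities; boundary values are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import MaskVolume, SpatialTransform, ValidationError
from .phantom import apply_psf
from .svca import WeightMaps

__all__ = [
    "VascularTemplate",
    "gray_matter_mask",
    "white_matter_mask",
    "carotid_template_mask",
    "surround_template_mask",
    "warp_mask",
    "average_blood_weights",
]


@dataclass
class VascularTemplate:
    """Cohort-average blood-weight volume in template space.

    ``exclusion`` optionally marks voxels to drop (venous sinuses, noise) —
    the automated stand-in for the manual clean-up step.
    """

    values: np.ndarray
    n_subjects: int = 1
    exclusion: MaskVolume | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("vascular template must be 3-D")
        if self.values.min() < 0:
            raise ValidationError("vascular template values must be nonnegative")
        if self.exclusion is not None:
            self.exclusion.require_match(self.values.shape, "vascular template")


def _check_probability(prob: np.ndarray, name: str) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 3:
        raise ValidationError(f"{name} probability map must be 3-D")
    if prob.min() < 0 or prob.max() > 1:
        raise ValidationError(f"{name} probabilities must lie within [0, 1]")
    return prob


def gray_matter_mask(gm_prob: np.ndarray, threshold: float = 0.9) -> MaskVolume:
    """Voxels with gray-matter probability strictly greater than 0.9."""
    gm_prob = _check_probability(gm_prob, "gray matter")
    return MaskVolume(gm_prob > threshold)


def white_matter_mask(
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    voxel_size,
    fwhm_mm: float = 7.0,
    spill_threshold: float = 0.005,
) -> MaskVolume:
    """White-matter voxels receiving negligible gray-matter spill-over.

    A spill map is built by Gaussian-blurring the binary gm_prob > 0.5 mask
    at the scanner FWHM; with unit gray activity the blurred indicator *is*
    the fraction of uniform gray activity spilling into each voxel.  The
    mask keeps voxels with wm_prob > 0.5 whose spill is below
    ``spill_threshold`` (0.5% by default).
    """
    gm_prob = _check_probability(gm_prob, "gray matter")
    wm_prob = _check_probability(wm_prob, "white matter")
    if gm_prob.shape != wm_prob.shape:
        raise ValidationError("gray and white probability maps must share one grid")
    gm_core = gm_prob > 0.5
    spill = apply_psf(gm_core.astype(float), fwhm_mm, voxel_size)
    return MaskVolume((wm_prob > 0.5) & (spill < spill_threshold))


def carotid_template_mask(vt: VascularTemplate, threshold: float = 0.2) -> MaskVolume:
    """Template carotid mask: blood weight strictly above 0.2, exclusions removed."""
    keep = vt.values > threshold
    if vt.exclusion is not None:
        keep &= ~vt.exclusion.indicator
    if not keep.any():
        warnings.warn(
            "carotid template mask is empty: no averaged blood weight exceeds "
            f"{threshold}", stacklevel=2,
        )
    return MaskVolume(keep)


def surround_template_mask(
    carotid_mask: MaskVolume,
    voxel_size,
    fwhm_mm: float = 7.0,
    band: tuple[float, float] = (0.001, 0.1),
) -> MaskVolume:
    """Surrounding-tissue mask: the Gaussian halo of the carotid mask.

    The binary carotid mask is blurred at the scanner FWHM and voxels whose
    blurred value falls strictly inside ``band`` are kept; carotid voxels
    themselves blur to values near 1 and are excluded, so the two masks are
    disjoint by construction.
    """
    carotid_mask.require_nonempty("carotid mask")
    lo, hi = band
    blurred = apply_psf(carotid_mask.indicator.astype(float), fwhm_mm, voxel_size)
    keep = (blurred > lo) & (blurred < hi)
    keep &= ~carotid_mask.indicator  # belt and braces for very thin masks
    return MaskVolume(keep)


def warp_mask(
    template_mask: MaskVolume,
    xf: SpatialTransform,
    subject_shape: tuple[int, int, int],
) -> MaskVolume:
    """Map a template-space mask onto the subject grid.

    ``xf`` maps template voxel coordinates to subject voxel coordinates;
    the indicator is pulled back through the inverse with nearest-neighbour
    resampling (the inverse-normalization step of the original workflow,
    restricted to affine transforms).
    """
    if xf.is_identity:
        if template_mask.shape != tuple(subject_shape):
            raise ValidationError("identity transform requires matching grids")
        return MaskVolume(template_mask.indicator.copy())
    inv = xf.inverse().matrix
    out = ndimage.affine_transform(
        template_mask.indicator.astype(np.float64),
        inv[:3, :3],
        offset=inv[:3, 3],
        output_shape=tuple(subject_shape),
        order=0,
        mode="constant",
        cval=0.0,
    )
    return MaskVolume(out > 0.5)


def average_blood_weights(
    cohort: list[WeightMaps | np.ndarray], exclusion: MaskVolume | None = None
) -> VascularTemplate:
    """Voxel-wise arithmetic mean of blood-weight maps in template space."""
    if not cohort:
        raise ValidationError("cohort of weight maps is empty")
    vols = [np.asarray(w.blood if isinstance(w, WeightMaps) else w, float) for w in cohort]
    shape = vols[0].shape
    for v in vols:
        if v.shape != shape:
            raise ValidationError("all blood-weight maps must share one grid")
    return VascularTemplate(np.mean(vols, axis=0), n_subjects=len(vols), exclusion=exclusion)
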