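"""Supervised clustering of voxel kinetics.

Each dynamic frame is standardized (z-scored over a field-of-view mask),
class template curves are built by averaging standardized mask TACs across
a small cohort, and every voxel's standardized TAC is decomposed as a
nonnegative combination of the three templates (gray matter, white matter,
blood) by active-set non-negative least squares.  The resulting weight maps
quantify each voxel's similarity to each kinetic class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core_io import DynamicImage, FrameSchedule, MaskVolume, ValidationError

__all__ = [
    "StandardizedImage",
    "TissueTemplates",
    "WeightMaps",
    "default_stats_mask",
    "standardize_frames",
    "build_template_tacs",
    "solve_weights",
]


@dataclass
class StandardizedImage:
    """Frame-wise z-scored activity; unitless.

    Within ``stats_mask`` every frame has mean 0 and standard deviation 1
    (sample sd, ddof=1).  Voxels outside the mask are transformed with the
    same per-frame statistics.
    """

    voxels: np.ndarray
    stats_mask: MaskVolume
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValidationError("standardized voxels must be 4-D")
        self.stats_mask.require_match(self.voxels.shape[:3], "standardized image")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]


@dataclass
class TissueTemplates:
    """Standardized class template TACs: one value per frame per tissue."""

    gray: np.ndarray
    white: np.ndarray
    blood: np.ndarray
    n_subjects: int = 1

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.blood = np.asarray(self.blood, dtype=float)
        n = self.gray.size
        if self.white.size != n or self.blood.size != n:
            raise ValidationError("all three templates must share the frame count")
        cond = np.linalg.cond(self.design())
        if not np.isfinite(cond) or cond > 1e12:
            raise ValidationError("template TACs are linearly dependent")

    def design(self) -> np.ndarray:
        """The (frames x 3) NNLS design matrix [gray, white, blood]."""
        return np.column_stack([self.gray, self.white, self.blood])

    def __len__(self) -> int:
        return int(self.gray.size)


@dataclass
class WeightMaps:
    """Per-voxel nonnegative similarity weights for the three classes."""

    gray: np.ndarray
    white: np.ndarray
    blood: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gray", "white", "blood"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3:
                raise ValidationError(f"weight map '{name}' must be 3-D")
            if arr.min() < 0:
                raise ValidationError(f"weight map '{name}' has negative entries")
            setattr(self, name, arr)
        if not (self.gray.shape == self.white.shape == self.blood.shape):
            raise ValidationError("weight maps must share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gray.shape

    def blood_fraction(self) -> np.ndarray:
        """Relative blood weight w_b / (w_g + w_w + w_b); 0 where all zero."""
        total = self.gray + self.white + self.blood
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, self.blood / np.where(total > 0, total, 1.0), 0.0)
        return frac


def default_stats_mask(img: DynamicImage, fraction: float = 0.05) -> MaskVolume:
    """Field-of-view mask: voxels whose mean activity exceeds ``fraction`` of
    the maximum of the mean image.  Keeps empty air out of the z-scoring."""
    mean = img.mean_image()
    return MaskVolume(mean > fraction * mean.max())


def standardize_frames(img: DynamicImage, stats_mask: MaskVolume | None = None) -> StandardizedImage:
    """Z-score every frame using statistics over ``stats_mask``.

    For frame f: ``out = (in - mean_f) / sd_f`` with mean/sd computed over
    the mask (sample sd, ddof=1).  A frame with zero within-mask variance is
    an error (named in the message).
    """
    if stats_mask is None:
        stats_mask = default_stats_mask(img)
    stats_mask.require_match(img.spatial_shape)
    stats_mask.require_nonempty("standardization statistics mask")
    sel = stats_mask.indicator
    if sel.sum() < 2:
        raise ValidationError("statistics mask must contain at least 2 voxels (ddof=1)")
    flat = img.voxels[sel]  # (n_mask, frames)
    means = flat.mean(axis=0)
    sds = flat.std(axis=0, ddof=1)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        raise ValidationError(f"frame {int(bad[0])} has zero within-mask variance")
    out = (img.voxels - means) / sds
    return StandardizedImage(out, stats_mask, img.schedule)


def build_template_tacs(
    cohort: list[tuple[StandardizedImage, MaskVolume, MaskVolume, MaskVolume]],
) -> TissueTemplates:
    """Average standardized mask TACs across a template cohort.

    ``cohort`` holds ``(standardized image, gray mask, white mask, blood
    mask)`` per subject; all subjects must share one frame schedule.  Per
    tissue the template is the across-subject mean of each subject's
    unweighted mean standardized TAC over the mask.
    """
    if not cohort:
        raise ValidationError("template cohort is empty")
    ref_sched = cohort[0][0].schedule
    per_tissue: list[list[np.ndarray]] = [[], [], []]
    for std, *tissue_masks in cohort:
        if std.schedule != ref_sched:
            raise ValidationError("all template subjects must share one frame schedule")
        for slot, mask in zip(per_tissue, tissue_masks):
            mask.require_match(std.spatial_shape)
            mask.require_nonempty("template tissue mask")
            slot.append(std.voxels[mask.indicator].mean(axis=0))
    gray, white, blood = (np.mean(s, axis=0) for s in per_tissue)
    return TissueTemplates(gray, white, blood, n_subjects=len(cohort))


def solve_weights(
    std: StandardizedImage,
    templates: TissueTemplates,
    analysis_mask: MaskVolume | None = None,
) -> WeightMaps:
    """Voxel-wise NNLS of standardized TACs against the template design.

    For each voxel v inside ``analysis_mask`` (default: the standardization
    mask) solves ``argmin_{w >= 0} ||y_v - T w||^2`` with the Lawson-Hanson
    active-set algorithm — the exact minimizer of each 3-column problem.
    Voxels outside the mask get zero weights.
    """
    if analysis_mask is None:
        analysis_mask = std.stats_mask
    analysis_mask.require_match(std.spatial_shape, "standardized image")
    T = templates.design()
    if len(templates) != std.n_frames:
        raise ValidationError("template frame count does not match image")
    if np.linalg.matrix_rank(T) < 3:
        raise ValidationError("template design matrix is rank deficient")
    sel = analysis_mask.indicator
    ys = std.voxels[sel]  # (n, frames)
    w = np.zeros((ys.shape[0], 3))
    for i in range(ys.shape[0]):
        w[i], _ = nnls(T, ys[i])
    maps = [np.zeros(std.spatial_shape) for _ in range(3)]
    for j in range(3):
        maps[j][sel] = w[:, j]
    return WeightMaps(gray=maps[0], white=maps[1], blood=maps[2])
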