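"""Domain types shared by all pipeline stages, and readers/writers.

Conventions
-----------
* All internal times are in **minutes** and activities in **kBq/mL**;
  conversions happen only at I/O boundaries (frame timing sidecars are in
  seconds, since that is how scanners report them).
* Decay correction is assumed to have been applied upstream, as is standard
  for reconstructed PET; it is never performed here.
* Voxel indices are 0-based.  Masks and images must share their spatial
  shape exactly; there is no implicit resampling.
* Voxel values may be negative (filtered-back-projection noise); they are
  never silently clipped.

Formats: NIfTI-1 for all volumes, TSV for TACs / frame timing / blood
samples, JSON or YAML for configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "FrameSchedule",
    "DynamicImage",
    "TAC",
    "BloodSampleSet",
    "MaskVolume",
    "SpatialTransform",
    "RegionLabels",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_blood_samples",
    "write_blood_samples",
    "read_tac",
    "write_tac",
    "read_mask",
    "write_mask",
    "read_volume",
    "write_volume",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing.

    Parameters
    ----------
    start_times : ndarray
        Frame start times in **seconds** post injection, strictly increasing.
    durations : ndarray
        Frame durations in **seconds**, strictly positive.  Frames must not
        overlap: ``start[i+1] >= start[i] + dur[i]``.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.start_times, dtype=float)
        du = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "durations", du)
        if st.ndim != 1 or du.ndim != 1 or st.size != du.size:
            raise ValidationError("start_times and durations must be 1-D of equal length")
        if st.size == 0:
            raise ValidationError("schedule must contain at least one frame")
        if np.any(du <= 0):
            raise ValidationError("frame durations must be strictly positive")
        if st.size > 1 and np.any(np.diff(st) <= 0):
            raise ValidationError("frame start times must be strictly increasing")
        if st.size > 1 and np.any(st[1:] < st[:-1] + du[:-1] - 1e-9):
            raise ValidationError("frames must not overlap")

    def __len__(self) -> int:
        return int(self.start_times.size)

    @property
    def mid_times_min(self) -> np.ndarray:
        """Mid-frame times in minutes."""
        return (self.start_times + self.durations / 2.0) / 60.0

    @property
    def end_time_min(self) -> float:
        return float((self.start_times[-1] + self.durations[-1]) / 60.0)

    def __eq__(self, other: object) -> bool:  # frozen dataclass w/ arrays
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start_times, other.start_times) and np.array_equal(
            self.durations, other.durations
        )


@dataclass
class DynamicImage:
    """A 4-D dynamic PET volume with voxel geometry and frame timing.

    ``voxels`` has axes (x, y, z, frame) and units kBq/mL.  Values may be
    negative due to reconstruction noise; this is deliberate and documented.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError("voxels must be a 4-D array (x, y, z, frame)")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValidationError(
                f"frame axis length {self.voxels.shape[3]} does not match "
                f"schedule length {len(self.schedule)}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError("voxel_size must be three positive lengths in mm")
        self.voxel_size = vs

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    def mean_image(self) -> np.ndarray:
        """Duration-weighted mean over frames (a 'summed' PET image)."""
        w = self.schedule.durations / self.schedule.durations.sum()
        return np.tensordot(self.voxels, w, axes=([3], [0]))


@dataclass
class TAC:
    """A time-activity curve: times in minutes, values in kBq/mL."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValidationError("times and values must have equal length")
        if self.times.size == 0:
            raise ValidationError("TAC must contain at least one sample")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("TAC times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation at times ``t`` (minutes), anchored at (0, 0)."""
        tt = np.concatenate(([0.0], self.times)) if self.times[0] > 0 else self.times
        vv = np.concatenate(([0.0], self.values)) if self.times[0] > 0 else self.values
        return np.interp(t, tt, vv)


@dataclass
class BloodSampleSet:
    """Sparse arterial blood samples anchoring PVC and metabolite correction.

    ``times`` in minutes, ``whole_blood`` in kBq/mL, ``parent_fraction``
    unitless in [0, 1]; ``f_p`` is the plasma free fraction in (0, 1].
    """

    times: np.ndarray
    whole_blood: np.ndarray
    parent_fraction: np.ndarray
    f_p: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        n = self.times.size
        if n < 2:
            raise ValidationError("at least 2 blood samples are required")
        if self.whole_blood.size != n or self.parent_fraction.size != n:
            raise ValidationError("blood sample columns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
            raise ValidationError("parent_fraction must lie within [0, 1]")
        if not (0 < self.f_p <= 1):
            raise ValidationError("f_p must lie in (0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class MaskVolume:
    """A 3-D boolean indicator volume tied to an image grid."""

    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.ndim != 3:
            raise ValidationError("mask indicator must be 3-D")
        self.indicator = ind.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def count(self) -> int:
        return int(self.indicator.sum())

    def require_match(self, shape: tuple[int, int, int], what: str = "image") -> None:
        if self.indicator.shape != tuple(shape):
            raise ValidationError(
                f"mask shape {self.indicator.shape} does not match {what} shape {tuple(shape)}"
            )

    def require_nonempty(self, what: str = "mask") -> None:
        if not self.indicator.any():
            raise ValidationError(f"{what} is empty")


@dataclass(frozen=True)
class SpatialTransform:
    """An invertible affine mapping template voxel coords -> subject voxel coords.

    Stored as a 4x4 homogeneous matrix; :meth:`identity` is the default used
    when template and subject share one grid.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (4, 4):
            raise ValidationError("transform matrix must be 4x4")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValidationError("transform is not invertible")

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, shift: tuple[float, float, float]) -> "SpatialTransform":
        m = np.eye(4)
        m[:3, 3] = shift
        return cls(m)

    def inverse(self) -> "SpatialTransform":
        return SpatialTransform(np.linalg.inv(self.matrix))

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4)))


@dataclass
class RegionLabels:
    """An integer label volume with a label -> name table; 0 is background."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValidationError("label volume must be 3-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValidationError("label volume must be integer valued")
            lab = np.round(lab).astype(int)
        if lab.min() < 0:
            raise ValidationError("labels must be nonnegative (0 = background)")
        self.labels = lab
        self.names = {int(k): str(v) for k, v in self.names.items()}

    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def name_of(self, label: int) -> str:
        return self.names.get(int(label), f"region_{int(label)}")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_TIMING_COLS = ["frame_start_s", "frame_dur_s"]


def _timing_path(image_path: str | os.PathLike) -> str:
    p = str(image_path)
    for suf in (".nii.gz", ".nii"):
        if p.endswith(suf):
            return p[: -len(suf)] + "_timing.tsv"
    return p + "_timing.tsv"


def read_dynamic_image(
    image_path: str | os.PathLike, timing_path: str | os.PathLike | None = None
) -> DynamicImage:
    """Read a 4-D NIfTI plus its frame-timing TSV sidecar.

    The sidecar has columns ``frame_start_s`` and ``frame_dur_s`` with one
    row per frame; its row count must equal the image's frame count.
    """
    if timing_path is None:
        timing_path = _timing_path(image_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    df = pd.read_csv(timing_path, sep="\t")
    missing = [c for c in _TIMING_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{timing_path}: missing columns {missing}")
    if len(df) != data.shape[3]:
        raise FormatError(
            f"{timing_path}: {len(df)} timing rows for {data.shape[3]} image frames"
        )
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(float), df["frame_dur_s"].to_numpy(float)
    )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data, tuple(float(z) for z in zooms), schedule)


def write_dynamic_image(
    img: DynamicImage,
    image_path: str | os.PathLike,
    timing_path: str | os.PathLike | None = None,
) -> None:
    """Write NIfTI + timing sidecar; :func:`read_dynamic_image` inverts it."""
    if timing_path is None:
        timing_path = _timing_path(image_path)
    affine = np.diag(list(img.voxel_size) + [1.0])
    nii = nib.Nifti1Image(img.voxels.astype(np.float64), affine)
    nii.header.set_zooms(img.voxel_size + (1.0,))
    nib.save(nii, str(image_path))
    pd.DataFrame(
        {
            "frame_start_s": img.schedule.start_times,
            "frame_dur_s": img.schedule.durations,
        }
    ).to_csv(timing_path, sep="\t", index=False, float_format="%.17g")


def read_blood_samples(path: str | os.PathLike) -> BloodSampleSet:
    """Read arterial blood samples from TSV.

    Expected columns: ``time_min``, ``whole_blood_kBq_mL``,
    ``parent_fraction``.  The plasma free fraction is carried as header
    metadata in a comment line ``# f_P = <value>``.
    """
    f_p = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip().lower() in ("f_p", "fp"):
                        f_p = float(val.strip())
            else:
                break
    if f_p is None:
        raise FormatError(f"{path}: missing '# f_P = <value>' metadata line")
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = ["time_min", "whole_blood_kBq_mL", "parent_fraction"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return BloodSampleSet(
        df["time_min"].to_numpy(float),
        df["whole_blood_kBq_mL"].to_numpy(float),
        df["parent_fraction"].to_numpy(float),
        f_p,
    )


def write_blood_samples(samples: BloodSampleSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# f_P = {samples.f_p!r}\n")
        fh.write("time_min\twhole_blood_kBq_mL\tparent_fraction\n")
        for t, wb, pf in zip(samples.times, samples.whole_blood, samples.parent_fraction):
            fh.write(f"{float(t)!r}\t{float(wb)!r}\t{float(pf)!r}\n")


def read_tac(path: str | os.PathLike) -> TAC:
    """Read a two-column TSV (time_min, value_kBq_mL) as a TAC."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2 or len(df) == 0:
        raise FormatError(f"{path}: expected a non-empty two-column TSV")
    return TAC(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_tac(tac: TAC, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\tvalue_kBq_mL\n")
        for t, v in zip(tac.times, tac.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_mask(path: str | os.PathLike) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask volume")
    return MaskVolume(data > 0.5)


def write_mask(mask: MaskVolume, path: str | os.PathLike, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.indicator.astype(np.uint8), affine), str(path))


def read_volume(path: str | os.PathLike) -> np.ndarray:
    """Read a 3-D scalar volume (e.g. probability or weight map)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume")
    return data


def write_volume(vol: np.ndarray, path: str | os.PathLike, voxel_size=(1.0, 1.0, 1.0)) -> None:
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValidationError("expected a 3-D volume")
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))
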