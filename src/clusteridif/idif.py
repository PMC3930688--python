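"""Image-derived input function extraction and correction.

From a subject's weight maps, the carotid curve is a blood-weight-weighted
average over carotid-mask voxels whose relative blood weight exceeds 50%,
and the surrounding-tissue curve is an unweighted average over
surround-mask voxels whose relative blood weight is below 0.1%.  The
carotid signal is then modelled as

    C_carotid(t) = RC * C_wb(t) + SP * C_surround(t)

with the recovery (RC) and spill-in (SP) coefficients fitted by ordinary
least squares at a handful of arterial sampling times, the whole-blood IDIF
recovered by inverting the model, radiometabolites removed with a
monoexponential parent-fraction fit, and the plasma-parent curve finished
with a tri-exponential tail fit (the measured rise is kept as-is, since
most of the area under the curve sits under the peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .core_io import TAC, BloodSampleSet, DynamicImage, MaskVolume, ValidationError
from .svca import WeightMaps

__all__ = [
    "PVCCoefficients",
    "ParentFractionFit",
    "InputFunction",
    "extract_carotid_tac",
    "extract_surround_tac",
    "fit_pvc",
    "correct_pvc",
    "fit_parent_fraction",
    "metabolite_correct",
    "fit_triexponential",
]


@dataclass
class PVCCoefficients:
    """Recovery (RC) and spill-in (SP) coefficients with fit diagnostics."""

    rc: float
    sp: float
    residual_norm: float = 0.0
    n_samples: int = 0
    sp_negative: bool = False

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ValidationError(f"recovery coefficient must be positive, got {self.rc}")
        # SP < 0 is physically odd but numerically possible: flag, don't fail.
        self.sp_negative = bool(self.sp < 0)


@dataclass
class ParentFractionFit:
    """Monoexponential parent-fraction model f(t) = a * exp(-lam * t)."""

    a: float
    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("parent-fraction decay rate must be nonnegative")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        f = self.a * np.exp(-self.lam * np.asarray(t, dtype=float))
        return np.clip(f, 0.0, 1.0)


@dataclass
class InputFunction:
    """Metabolite-corrected plasma input: measured rise + tri-exponential tail.

    ``times``/``values`` hold the corrected plasma-parent samples at
    mid-frame times.  From ``peak_time`` onward the curve is represented by
    the fitted ``sum_j A_j exp(-lam_j t)`` (A_j >= 0, lam_j >= 0, so the
    fitted tail is nonnegative by construction); before the peak the
    measured samples are linearly interpolated with a (0, 0) anchor.
    """

    times: np.ndarray
    values: np.ndarray
    amplitudes: np.ndarray
    rates: np.ndarray
    peak_time: float
    fit_rmse: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.amplitudes < 0) or np.any(self.rates < 0):
            raise ValidationError("tri-exponential parameters must be nonnegative")

    def tail(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-self.rates[:, None] * t[None, :]), axis=0
        ) if t.ndim else float(np.sum(self.amplitudes * np.exp(-self.rates * t)))

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """Piecewise input: interpolated measured rise, fitted decay tail."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        pre = t <= self.peak_time
        if pre.any():
            tt = np.concatenate(([0.0], self.times))
            vv = np.concatenate(([0.0], self.values))
            out[pre] = np.interp(t[pre], tt, vv)
        if (~pre).any():
            out[~pre] = self.tail(t[~pre])
        return out

    def as_tac(self, times: np.ndarray | None = None) -> TAC:
        if times is None:
            return TAC(self.times, self.evaluate(self.times))
        return TAC(times, self.evaluate(times))

    def cumulative_integral(self, t_grid: np.ndarray) -> np.ndarray:
        """Trapezoid cumulative integral of the piecewise curve on ``t_grid``."""
        return cumulative_trapezoid(self.evaluate(t_grid), t_grid, initial=0.0)

    def auc(self, t0: float = 0.0, t1: float = 90.0, dt_min: float = 1.0 / 60.0) -> float:
        grid = np.linspace(t0, t1, max(int(round((t1 - t0) / dt_min)) + 1, 2))
        return float(np.trapezoid(self.evaluate(grid), grid))


# --------------------------------------------------------------------------
# TAC extraction
# --------------------------------------------------------------------------


def extract_carotid_tac(
    img: DynamicImage,
    carotid_mask: MaskVolume,
    weights: WeightMaps,
    blood_fraction_threshold: float = 0.5,
) -> TAC:
    """Blood-weighted mean TAC over the selected carotid voxels.

    Selection keeps carotid-mask voxels whose relative blood weight
    ``w_b / (w_g + w_w + w_b)`` is strictly above the threshold (default
    50%); values are averaged weighted by the blood weight itself.
    """
    carotid_mask.require_match(img.spatial_shape)
    carotid_mask.require_nonempty("carotid mask")
    if weights.shape != img.spatial_shape:
        raise ValidationError("weight maps must share the image grid")
    frac = weights.blood_fraction()
    sel = carotid_mask.indicator & (frac > blood_fraction_threshold)
    if not sel.any():
        raise ValidationError(
            "no carotid voxel has relative blood weight above "
            f"{blood_fraction_threshold}; inspect the weight maps / threshold"
        )
    w = weights.blood[sel]
    total = w.sum()
    if total <= 0:
        raise ValidationError("selected carotid voxels carry zero blood weight")
    vals = (w[:, None] * img.voxels[sel]).sum(axis=0) / total
    return TAC(img.schedule.mid_times_min, vals)


def extract_surround_tac(
    img: DynamicImage,
    surround_mask: MaskVolume,
    weights: WeightMaps,
    blood_fraction_cutoff: float = 0.001,
) -> TAC:
    """Unweighted mean TAC over low-blood voxels of the surround mask.

    Keeps surround-mask voxels with relative blood weight strictly below
    0.1%, then averages without weighting.
    """
    surround_mask.require_match(img.spatial_shape)
    surround_mask.require_nonempty("surround mask")
    if weights.shape != img.spatial_shape:
        raise ValidationError("weight maps must share the image grid")
    frac = weights.blood_fraction()
    sel = surround_mask.indicator & (frac < blood_fraction_cutoff)
    if not sel.any():
        raise ValidationError(
            "no surround voxel has relative blood weight below "
            f"{blood_fraction_cutoff}; inspect the weight maps / cutoff"
        )
    vals = img.voxels[sel].mean(axis=0)
    return TAC(img.schedule.mid_times_min, vals)


# --------------------------------------------------------------------------
# partial volume / spill-in correction
# --------------------------------------------------------------------------


def _interp_extrap(tac: TAC, t: np.ndarray) -> np.ndarray:
    """Linear interpolation with linear extrapolation past the last sample."""
    out = tac.interp(t)
    if len(tac) > 1:
        beyond = t > tac.times[-1]
        if np.any(beyond):
            slope = (tac.values[-1] - tac.values[-2]) / (tac.times[-1] - tac.times[-2])
            out[beyond] = tac.values[-1] + slope * (t[beyond] - tac.times[-1])
    return out


def fit_pvc(carotid: TAC, surround: TAC, blood: BloodSampleSet) -> PVCCoefficients:
    """Fit C_carotid = RC * C_wb + SP * C_surround at the sampling times.

    Ordinary least squares over the arterial samples (2-4 points, two
    unknowns); image TACs are linearly interpolated from mid-frame times to
    the sample times.
    """
    if len(blood) < 2:
        raise ValidationError("PVC fit needs at least 2 blood samples")
    t = blood.times
    # mid-frame times end half a frame before the scan does; allow linear
    # extrapolation over that last half-frame (e.g. a 90-min sample against
    # an 87.5-min last mid-frame) but no further
    for tac in (carotid, surround):
        last_gap = tac.times[-1] - tac.times[-2] if len(tac) > 1 else 0.0
        if t[-1] > tac.times[-1] + last_gap / 2.0 + 1e-6:
            raise ValidationError("blood sample times extend beyond the scan duration")
    car = _interp_extrap(carotid, t)
    sur = _interp_extrap(surround, t)
    design = np.column_stack([blood.whole_blood, sur])
    if np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, np.abs(design).max())) < 2:
        raise ValidationError(
            "PVC design is rank deficient (whole blood ~ surround at the samples)"
        )
    coef, res, *_ = np.linalg.lstsq(design, car, rcond=None)
    resid = float(np.sqrt(res[0])) if res.size else float(
        np.linalg.norm(car - design @ coef)
    )
    return PVCCoefficients(
        rc=float(coef[0]), sp=float(coef[1]), residual_norm=resid, n_samples=len(blood)
    )


def correct_pvc(carotid: TAC, surround: TAC, c: PVCCoefficients) -> TAC:
    """Invert the spill model: C_wb = (C_carotid - SP * C_surround) / RC."""
    if c.rc <= 0:
        raise ValidationError("recovery coefficient must be positive")
    if not np.array_equal(carotid.times, surround.times):
        sur_vals = surround.interp(carotid.times)
    else:
        sur_vals = surround.values
    return TAC(carotid.times, (carotid.values - c.sp * sur_vals) / c.rc)


def fit_parent_fraction(blood: BloodSampleSet) -> ParentFractionFit:
    """Least-squares monoexponential fit to the parent-fraction samples."""
    pf = blood.parent_fraction
    if np.all(pf == 0):
        raise ValidationError("all parent fractions are zero; cannot fit")
    t = blood.times
    pos = pf > 0
    # log-linear start, refined by nonlinear LS with lam >= 0
    if pos.sum() >= 2:
        slope, logint = np.polyfit(t[pos], np.log(pf[pos]), 1)
        a0, l0 = float(np.exp(logint)), float(max(-slope, 0.0))
    else:
        a0, l0 = float(pf.max()), 0.01
    try:
        popt, _ = curve_fit(
            lambda tt, a, lam: a * np.exp(-lam * tt),
            t,
            pf,
            p0=[a0, l0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        a, lam = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, lam = a0, l0
    return ParentFractionFit(a=a, lam=lam)


def metabolite_correct(wb_idif: TAC, pf: ParentFractionFit) -> TAC:
    """Multiply the whole-blood IDIF by the fitted parent fraction."""
    return TAC(wb_idif.times, wb_idif.values * pf(wb_idif.times))


# --------------------------------------------------------------------------
# tri-exponential input fit
# --------------------------------------------------------------------------


def _triexp(t, a1, a2, a3, l1, l2, l3):
    return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)


def fit_triexponential(plasma: TAC, n_random_starts: int = 8, seed: int = 0) -> InputFunction:
    """Fit ``sum_j A_j exp(-lam_j t)`` to the post-peak samples.

    Multi-start nonlinear least squares (deterministic starts spanning three
    decades of rates plus seeded random restarts); nonnegativity of all six
    parameters is enforced through bounds, which also makes the fitted tail
    nonnegative everywhere.  The measured pre-peak samples are retained
    untouched in the returned piecewise input.
    """
    ipeak = int(np.argmax(plasma.values))
    if ipeak == len(plasma) - 1:
        raise ValidationError("curve peaks at the last sample; no tail to fit")
    t = plasma.times[ipeak:]
    y = plasma.values[ipeak:]
    peak_val = float(y[0])
    scale = max(abs(peak_val), 1e-12)

    starts = [
        (1.0, 0.1, 0.01),
        (0.5, 0.05, 0.005),
        (2.0, 0.2, 0.02),
        (3.0, 0.5, 0.01),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(tuple(np.sort(10 ** rng.uniform(-2.5, 0.7, 3))[::-1]))

    best = None
    for lams in starts:
        amps0 = np.full(3, scale / 3.0)
        p0 = [*amps0, *lams]
        try:
            popt, _ = curve_fit(
                _triexp,
                t,
                y,
                p0=p0,
                bounds=([0.0] * 6, [np.inf] * 3 + [20.0] * 3),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _triexp(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise ValidationError(
            "tri-exponential fit failed to converge from every start "
            f"({len(starts)} starts, {len(t)} post-peak samples)"
        )
    sse, popt = best
    amplitudes = np.asarray(popt[:3], dtype=float)
    rates = np.asarray(popt[3:], dtype=float)
    return InputFunction(
        times=plasma.times,
        values=plasma.values,
        amplitudes=amplitudes,
        rates=rates,
        peak_time=float(plasma.times[ipeak]),
        fit_rmse=float(np.sqrt(sse / t.size)),
    )
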