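"""Quantification: Logan graphical analysis and comparison statistics.

For a reversible tracer, plotting ``int_0^t C_T / C_T(t)`` against
``int_0^t C_p / C_T(t)`` becomes linear after a time t*, and the slope of
the ordinary-least-squares line through the late points is the total
distribution volume V_T; dividing by the plasma free fraction gives
V_T/f_P.  The input integral is evaluated on a 1-second grid from the
piecewise input function (measured rise + fitted tail) because most of the
area under the curve sits under the early peak; the tissue integral uses
trapezoids over mid-frame points with an initial triangle from (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import binom

from .core_io import TAC, DynamicImage, RegionLabels, ValidationError
from .idif import InputFunction

__all__ = [
    "LoganResult",
    "regional_tacs",
    "logan_vt",
    "ssd_after",
    "sign_test_probability",
    "ratio_summary",
    "group_summary",
]


@dataclass
class LoganResult:
    """Logan-plot fit: slope = V_T (mL/cm3), intercept in minutes."""

    v_t: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    v_t_over_f_p: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.v_t):
            raise ValidationError("Logan V_T is not finite")
        if self.n_points < 3:
            raise ValidationError("Logan fit needs at least 3 points")


def regional_tacs(img: DynamicImage, labels: RegionLabels) -> dict[str, TAC]:
    """Unweighted mean TAC per nonzero label; absent labels are skipped."""
    if labels.labels.shape != img.spatial_shape:
        raise ValidationError("label volume must share the image grid")
    mids = img.schedule.mid_times_min
    out: dict[str, TAC] = {}
    declared = set(labels.names) if labels.names else set()
    present = labels.present_labels()
    for lab in sorted(declared - set(present)):
        import warnings

        warnings.warn(f"label {lab} ('{labels.name_of(lab)}') absent from volume; omitted",
                      stacklevel=2)
    for lab in present:
        sel = labels.labels == lab
        out[labels.name_of(lab)] = TAC(mids, img.voxels[sel].mean(axis=0))
    return out


def _input_cumulative(input_fn: InputFunction | TAC, at_times: np.ndarray) -> np.ndarray:
    """Cumulative integral of the plasma input at ``at_times`` (minutes).

    For a full InputFunction the piecewise curve is integrated on a
    1-second grid; for a plain TAC the samples are integrated by trapezoid
    with a (0, 0) anchor.
    """
    t_end = float(at_times[-1])
    grid = np.linspace(0.0, t_end, int(round(t_end * 60.0)) + 1)
    if isinstance(input_fn, InputFunction):
        vals = input_fn.evaluate(grid)
    else:
        vals = input_fn.interp(grid)
    cum = cumulative_trapezoid(vals, grid, initial=0.0)
    return np.interp(at_times, grid, cum)


def logan_vt(
    tissue: TAC,
    input_fn: InputFunction | TAC,
    t_star: float = 30.0,
    f_p: float | None = None,
) -> LoganResult:
    """Logan graphical estimate of V_T (and V_T/f_P when f_P is given)."""
    t = tissue.times
    ct = tissue.values
    # tissue cumulative integral with an initial triangle from (0, 0)
    tt = np.concatenate(([0.0], t))
    cc = np.concatenate(([0.0], ct))
    int_ct = cumulative_trapezoid(cc, tt, initial=0.0)[1:]
    int_cp = _input_cumulative(input_fn, t)

    use = t >= t_star
    if use.sum() < 3:
        raise ValidationError(f"fewer than 3 frames at or after t* = {t_star} min")
    if np.any(ct[use] == 0):
        raise ValidationError("tissue activity is zero at a Logan point")
    x = int_cp[use] / ct[use]
    y = int_ct[use] / ct[use]
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res[0]) if res.size else float(np.sum((y - A @ [slope, intercept]) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LoganResult(
        v_t=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=int(use.sum()),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        v_t_over_f_p=(float(slope) / f_p if f_p is not None else None),
    )


def ssd_after(a: TAC, b: TAC, t0: float = 10.0) -> float:
    """Sum of squared differences at a's sample times strictly after ``t0``.

    If b is sampled at different times it is linearly interpolated onto a's
    times first.
    """
    sel = a.times > t0
    if not sel.any():
        raise ValidationError(f"no sample times after {t0} min")
    if np.array_equal(a.times, b.times):
        bv = b.values[sel]
    else:
        bv = b.interp(a.times[sel])
    return float(np.sum((a.values[sel] - bv) ** 2))


def sign_test_probability(n_success: int, n_total: int) -> float:
    """Exact one-sided binomial tail P(X >= n_success | n_total, p = 1/2)."""
    if not (0 <= n_success <= n_total):
        raise ValidationError("need 0 <= n_success <= n_total")
    return float(binom.sf(n_success - 1, n_total, 0.5))


def ratio_summary(estimated, reference) -> dict:
    """Per-subject estimated/reference ratios with error-band counts.

    Bands count subjects by |ratio - 1|: below 5%, 5-10%, above 10%.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.size != ref.size:
        raise ValidationError("estimated and reference lists differ in length")
    if np.any(ref <= 0):
        raise ValidationError("reference values must be positive")
    r = est / ref
    err = np.abs(r - 1.0)
    return {
        "ratios": r,
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)) if r.size > 1 else float("nan"),
        "n_lt_5pct": int(np.sum(err < 0.05)),
        "n_5_to_10pct": int(np.sum((err >= 0.05) & (err <= 0.10))),
        "n_gt_10pct": int(np.sum(err > 0.10)),
    }


def group_summary(values_by_group: dict[str, "np.ndarray | list"], baseline: str) -> dict:
    """Descriptive per-group mean +/- sd and percent difference vs baseline."""
    if baseline not in values_by_group:
        raise ValidationError(f"baseline group '{baseline}' missing")
    out: dict[str, dict] = {}
    base_vals = np.asarray(values_by_group[baseline], dtype=float)
    if base_vals.size == 0:
        raise ValidationError("baseline group is empty")
    base_mean = float(base_vals.mean())
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValidationError(f"group '{name}' is empty")
        out[name] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            "pct_diff_vs_baseline": float((v.mean() - base_mean) / base_mean * 100.0),
        }
    return out
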