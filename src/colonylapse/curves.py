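"""Growth-curve processing and dynamic fitness metrics.

A colony's time course of summed pixel intensity (PI) is turned into two
fitness readouts:

* **colony fitness (CF)** — the final smoothed, zero-normalized intensity,
  the classical static screen metric;
* **lagVstall (LVS)** — the signed sum over timepoints of the difference
  between the colony's endpoint-normalized curve and the plate's median
  endpoint-normalized (reference) curve.  Negative values mean the colony
  is behind the plate as a fraction of its own final intensity throughout
  ("lag"); positive values mean it tracked the plate early and fell behind
  later ("stall").

Processing order: truncate -> robust LOWESS smoothing -> zero-normalize ->
(CF) -> endpoint-normalize -> reference/deviation -> (LVS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "ShortCurveError",
    "DeadColonyError",
    "AlignmentError",
    "truncate_curve",
    "smooth_curve",
    "rlowess_batch",
    "zero_normalize",
    "endpoint_normalize",
    "reference_curve",
    "deviation_profile",
    "lag_v_stall",
    "colony_fitness",
    "growth_rate",
    "compute_metrics",
    "FRAME_INTERVAL_MIN",
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_MAX_HOURS",
    "DEFAULT_DEAD_COLONY_FRACTION",
]

FRAME_INTERVAL_MIN = 5.0
DEFAULT_SMOOTH_WINDOW = 48          # timepoints = 4 hr at 5-min framing
DEFAULT_MAX_HOURS = 40.0
DEFAULT_DEAD_COLONY_FRACTION = 0.01  # of plate median final intensity


class ShortCurveError(ValueError):
    """Raised when an operation would leave fewer than two timepoints."""


class DeadColonyError(ValueError):
    """Raised when a curve's final intensity is too low to normalize."""


class AlignmentError(ValueError):
    """Raised when curves that must share a time grid do not."""


@dataclass(frozen=True)
class GrowthCurve:
    """One colony's intensity trajectory with its identity.

    ``times`` are minutes from the first frame on a uniform 5-minute grid;
    ``values`` are summed pixel intensities (or normalized derivatives
    thereof, downstream of the normalization steps).
    """

    times: np.ndarray
    values: np.ndarray
    strain_id: str = ""
    plate_id: str = ""
    condition: str = "untreated"
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size < 2:
            raise ShortCurveError("a growth curve needs at least 2 timepoints")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return self.times.size


def truncate_curve(curve: GrowthCurve, max_hours: float = DEFAULT_MAX_HOURS) -> GrowthCurve:
    """Restrict a curve to ``time <= max_hours`` (overgrowth cutoff)."""
    if max_hours <= 0:
        raise ValueError("max_hours must be positive")
    keep = curve.times <= max_hours * 60.0
    n = int(keep.sum())
    if n < 2:
        raise ShortCurveError(f"truncation to {max_hours} hr leaves {n} timepoints")
    if n == len(curve):
        return curve
    return replace(curve, times=curve.times[:n], values=curve.values[:n])


# ---------------------------------------------------------------------------
# Robust locally weighted regression (rlowess)
# ---------------------------------------------------------------------------

def rlowess_batch(
    values: np.ndarray,
    window: int = DEFAULT_SMOOTH_WINDOW,
    robust_iters: int = 3,
    chunk: int = 256,
) -> np.ndarray:
    """Robust local linear regression over a centered timepoint window.

    Vectorized over curves: ``values`` is (n_curves, n_timepoints) on a
    uniform time grid.  Each output point is a weighted local linear fit
    (tricube distance kernel) over the ``window`` nearest timepoints,
    truncated at the edges, with ``robust_iters`` bisquare reweighting
    passes that down-weight outliers by residual magnitude.  The robust
    scale (6x the median absolute residual) is taken over each point's own
    window: colony intensities span decades, so a global scale would treat
    the entire high-intensity regime as outlying.  Exact on linear inputs.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n_curves, n = v.shape
    if window <= 1 or n < 2:
        return v.copy() if values.ndim > 1 else v[0].copy()

    window = min(window, n)
    half_l = window // 2
    pad_l, pad_r = half_l, window - 1 - half_l

    # Relative x-offsets of each window slot from the target point.
    offsets = np.arange(-pad_l, pad_r + 1, dtype=float)          # (W,)
    # Validity + tricube kernel per (target, slot); edge-dependent only.
    idx = np.arange(n)[:, None] + offsets[None, :]               # (n, W)
    valid = (idx >= 0) & (idx <= n - 1)
    dist = np.abs(offsets)[None, :] * valid
    dmax = dist.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    kern = np.clip(1.0 - (dist / dmax) ** 3, 0.0, None) ** 3
    kern = kern * valid
    # Tricube vanishes at the window's farthest point; keep it positive so
    # every in-range sample contributes and window=2 edges stay solvable.
    kern[valid] = np.maximum(kern[valid], 1e-6)

    x = offsets  # design abscissa relative to target
    out = np.empty_like(v)

    for start in range(0, n_curves, chunk):
        block = v[start : start + chunk]                          # (C, n)
        padded = np.pad(block, ((0, 0), (pad_l, pad_r)), mode="edge")
        win = np.lib.stride_tricks.sliding_window_view(padded, window, axis=1)  # (C, n, W)
        robust = np.ones_like(block)
        fit = block
        for it in range(robust_iters + 1):
            rw = np.lib.stride_tricks.sliding_window_view(
                np.pad(robust, ((0, 0), (pad_l, pad_r)), mode="edge"), window, axis=1
            )
            w = kern[None, :, :] * rw                             # (C, n, W)
            s0 = w.sum(axis=2)
            s1 = w @ x
            s2 = w @ (x * x)
            sy = (w * win).sum(axis=2)
            sxy = (w * win) @ x
            det = s0 * s2 - s1 * s1
            with np.errstate(divide="ignore", invalid="ignore"):
                fit = np.where(
                    np.abs(det) > 1e-12 * np.maximum(s2 * s0, 1e-300),
                    (s2 * sy - s1 * sxy) / det,
                    sy / np.maximum(s0, 1e-300),
                )
            if it == robust_iters:
                break
            resid = block - fit
            abs_resid = np.abs(resid)
            rwin = np.lib.stride_tricks.sliding_window_view(
                np.pad(abs_resid, ((0, 0), (pad_l, pad_r)), mode="edge"), window, axis=1)
            scale = 6.0 * np.median(rwin, axis=2)
            scale[scale == 0] = np.inf  # locally perfect fit: keep full weights
            u = np.clip(resid / scale, -1.0, 1.0)
            robust = (1.0 - u * u) ** 2
        out[start : start + chunk] = fit
    return out if values.ndim > 1 else out[0]


def smooth_curve(
    curve: GrowthCurve,
    window: int = DEFAULT_SMOOTH_WINDOW,
    robust_iters: int = 3,
) -> GrowthCurve:
    """Smooth one curve with robust LOWESS (see :func:`rlowess_batch`)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = rlowess_batch(curve.values[None, :], window, robust_iters)[0]
    return replace(curve, values=smoothed)


# ---------------------------------------------------------------------------
# Normalizations and metrics
# ---------------------------------------------------------------------------

def zero_normalize(curve: GrowthCurve) -> GrowthCurve:
    """Subtract the first value so growth starts at zero; clip negatives."""
    v = np.clip(curve.values - curve.values[0], 0.0, None)
    return replace(curve, values=v)


def endpoint_normalize(curve: GrowthCurve, min_final_intensity: float = 0.0) -> GrowthCurve:
    """Divide by the final value: progress as a fraction of final intensity.

    Raises :class:`DeadColonyError` when the final intensity does not exceed
    ``min_final_intensity`` (dead-colony rule; such colonies are excluded
    upstream and reduce replicate counts).
    """
    final = curve.values[-1]
    if final <= min_final_intensity or final <= 0:
        raise DeadColonyError(
            f"final intensity {final!r} below dead-colony threshold {min_final_intensity!r}"
        )
    return replace(curve, values=curve.values / final)


def reference_curve(curves: Sequence[GrowthCurve]) -> GrowthCurve:
    """Per-timepoint median of endpoint-normalized curves on one plate."""
    if len(curves) < 3:
        raise ValueError("a reference needs at least 3 curves")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise AlignmentError(f"curves have differing lengths: {sorted(lengths)}")
    stack = np.vstack([c.values for c in curves])
    med = np.median(stack, axis=0)
    first = curves[0]
    return GrowthCurve(first.times, med, strain_id="<reference>",
                       plate_id=first.plate_id, condition=first.condition)


def deviation_profile(curve: GrowthCurve, ref: GrowthCurve) -> GrowthCurve:
    """Pointwise (curve - reference); above the reference is positive."""
    if len(curve) != len(ref):
        raise AlignmentError("curve and reference lengths differ")
    return replace(curve, values=curve.values - ref.values)


def lag_v_stall(profile: GrowthCurve) -> float:
    """Signed sum of the deviation profile over its 5-minute samples.

    Positive = stall (ahead of the reference as fraction-of-final early,
    i.e. the colony plateaued relative to the plate); negative = lag.
    """
    return float(profile.values.sum())


def colony_fitness(curve: GrowthCurve) -> float:
    """Final intensity of a truncated, smoothed, zero-normalized curve."""
    return float(curve.values[-1])


def growth_rate(curve: GrowthCurve) -> np.ndarray:
    """dPI/dT per timepoint (central differences; one-sided at the ends)."""
    return np.gradient(curve.values, curve.times)


# ---------------------------------------------------------------------------
# Batch pipeline over a whole experiment
# ---------------------------------------------------------------------------

def compute_metrics(
    meta: pd.DataFrame,
    values: np.ndarray,
    times: np.ndarray,
    *,
    max_hours: float = DEFAULT_MAX_HOURS,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    robust_iters: int = 3,
    dead_colony_fraction: float = DEFAULT_DEAD_COLONY_FRACTION,
    spatial_correct_cf: bool = True,
) -> pd.DataFrame:
    """Run the full curve pipeline for every colony of an experiment.

    ``meta`` has one row per colony with at least ``strain_id``, ``plate_id``,
    ``condition``, ``replicate`` columns, aligned with the rows of ``values``
    (n_colonies x n_timepoints).  Curves are grouped by (plate, condition):
    the reference median and the dead-colony threshold (1% of the plate
    median final intensity by default) are plate-level quantities.

    When ``meta`` carries ``row``/``col`` positions and ``spatial_correct_cf``
    is set, each plate's final-intensity matrix is spatially corrected
    before colony fitness is read off.  lagVstall needs no such step: a
    position effect that is constant in time cancels exactly in endpoint
    normalization.

    Returns ``meta`` plus ``lag_v_stall``, ``colony_fitness`` and an
    ``excluded`` flag (dead colonies get NaN metrics).
    """
    required = {"strain_id", "plate_id", "condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"meta is missing columns: {sorted(missing)}")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != (len(meta), times.size):
        raise AlignmentError("values shape does not match meta rows / time grid")

    keep = times <= max_hours * 60.0
    if keep.sum() < 2:
        raise ShortCurveError("truncation leaves fewer than 2 timepoints")
    t = times[keep]
    v = values[:, keep]

    smoothed = rlowess_batch(v, smooth_window, robust_iters)
    zeroed = np.clip(smoothed - smoothed[:, :1], 0.0, None)
    cf = zeroed[:, -1]
    cf_out = cf.copy()

    lvs = np.full(len(meta), np.nan)
    excluded = np.zeros(len(meta), dtype=bool)
    out = meta.copy().reset_index(drop=True)
    have_positions = spatial_correct_cf and {"row", "col"} <= set(out.columns)

    for _, group in out.groupby(["plate_id", "condition"], sort=False):
        rows = group.index.to_numpy()
        finals = cf[rows]
        if have_positions:
            finals = _spatially_corrected_finals(group, finals)
            cf_out[rows] = finals
        plate_median_final = np.median(finals)
        threshold = dead_colony_fraction * plate_median_final
        dead = finals <= max(threshold, 0.0)
        live = rows[~dead]
        excluded[rows[dead]] = True
        if live.size < 3:
            excluded[live] = True
            continue
        norm = zeroed[live] / cf[live][:, None]
        ref = np.median(norm, axis=0)
        lvs[live] = (norm - ref[None, :]).sum(axis=1)

    out["colony_fitness"] = np.where(excluded, np.nan, cf_out)
    out["lag_v_stall"] = lvs
    out["excluded"] = excluded
    return out


def _spatially_corrected_finals(group: pd.DataFrame, finals: np.ndarray) -> np.ndarray:
    """Spatially correct one plate's final-intensity matrix.

    Unoccupied grid positions are filled with the plate median so they do
    not drag the moving-median surface toward zero.
    """
    from .imaging import spatial_correct  # local import to avoid a cycle

    r = group["row"].to_numpy(dtype=int)
    c = group["col"].to_numpy(dtype=int)
    n_rows, n_cols = r.max() + 1, c.max() + 1
    mat = np.full((n_rows, n_cols), float(np.median(finals)))
    mat[r, c] = finals
    if not mat.any():
        return finals
    corrected = spatial_correct(mat)
    return corrected[r, c]
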