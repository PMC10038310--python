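"""Per-frame signal extraction from fluorescence / DIC frame stacks.

Turns raw multi-frame grayscale images into the per-frame series the
detection stages consume: neuron ROI intensity with local-background
subtraction, centroid positions, tracking speed, the GCaMP/mKate2
ratiometric activity, a pan-neuronal combined head signal, and the
frame-subtraction mobility measure used for DIC movies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class RoiResult:
    """Per-frame ROI extraction output.

    ``signal = roi_mean - background_mean`` may legitimately go negative when
    the local background outshines the ROI (e.g. a neighbouring bright
    structure); such frames are kept, not clipped, so downstream code can see
    them.  Frames with no supra-threshold pixel are flagged invalid.
    """

    centroid_x: np.ndarray
    centroid_y: np.ndarray
    roi_mean: np.ndarray
    background_mean: np.ndarray
    signal: np.ndarray
    roi_pixel_count: np.ndarray
    valid: np.ndarray


def _component_stats(frame: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, int]:
    """Intensity-weighted centroid (x, y), mean intensity and size of a mask."""
    rows, cols = np.nonzero(mask)
    weights = frame[rows, cols].astype(float)
    total = weights.sum()
    if total > 0:
        cy = float((rows * weights).sum() / total)
        cx = float((cols * weights).sum() / total)
    else:  # all-zero component: geometric centroid
        cy, cx = float(rows.mean()), float(cols.mean())
    return cx, cy, float(weights.mean()), rows.size


def _pick_component(frame: np.ndarray, labels: np.ndarray, n_labels: int) -> np.ndarray:
    """Deterministic component choice: largest, then brightest, then the one
    whose centroid has the lowest (row, col)."""
    best = None
    best_key = None
    for lab in range(1, n_labels + 1):
        mask = labels == lab
        cx, cy, mean, size = _component_stats(frame, mask)
        key = (-size, -mean, cy, cx)
        if best_key is None or key < best_key:
            best_key, best = key, mask
    return best


def _background_annulus(mask: np.ndarray, margin: int) -> np.ndarray:
    """Annulus: mask dilated by ``margin`` pixels minus the mask itself."""
    if margin <= 0:
        return np.zeros_like(mask)
    dilated = ndimage.binary_dilation(mask, iterations=margin)
    return dilated & ~mask


def _extract_one(frame: np.ndarray, mask: np.ndarray, margin: int):
    cx, cy, roi_mean, size = _component_stats(frame, mask)
    annulus = _background_annulus(mask, margin)
    bg = float(frame[annulus].mean()) if annulus.any() else 0.0
    return cx, cy, roi_mean, bg, roi_mean - bg, size


def extract_roi(frame_stack: np.ndarray, intensity_threshold: float,
                dilation_margin: int = 2) -> RoiResult:
    """Track the brightest neuron across a grayscale stack.

    Per frame: pixels strictly above ``intensity_threshold`` are segmented
    into connected components (8-connectivity); the chosen component (see
    `_pick_component`) is the neuron; a background annulus is obtained by
    dilating the component by ``dilation_margin`` pixels and removing the
    component, making the extracted region slightly bigger than the neuron
    itself so the local background can be estimated and subtracted.
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (n_frames, height, width)")
    if dilation_margin < 0:
        raise ValueError("dilation_margin must be >= 0")
    n = stack.shape[0]
    out = RoiResult(*(np.full(n, np.nan) for _ in range(5)),
                    roi_pixel_count=np.zeros(n, dtype=int),
                    valid=np.zeros(n, dtype=bool))
    structure = np.ones((3, 3), dtype=bool)
    for i in range(n):
        frame = stack[i]
        above = frame > intensity_threshold
        if not above.any():
            continue
        labels, n_labels = ndimage.label(above, structure=structure)
        mask = _pick_component(frame, labels, n_labels)
        cx, cy, roi_mean, bg, signal, size = _extract_one(frame, mask, dilation_margin)
        out.centroid_x[i], out.centroid_y[i] = cx, cy
        out.roi_mean[i], out.background_mean[i] = roi_mean, bg
        out.signal[i] = signal
        out.roi_pixel_count[i] = size
        out.valid[i] = True
    return out


def pan_neuronal_signal(frame_stack: np.ndarray, head_mask_threshold: float,
                        dilation_margin: int = 2) -> RoiResult:
    """Combined head-neuron signal: all supra-threshold pixels form one ROI.

    Same background-annulus convention as :func:`extract_roi`; the signal is
    the background-subtracted *mean* over the combined mask (a mean, not a
    sum, so it does not scale with how many neurons are lit).
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (n_frames, height, width)")
    n = stack.shape[0]
    out = RoiResult(*(np.full(n, np.nan) for _ in range(5)),
                    roi_pixel_count=np.zeros(n, dtype=int),
                    valid=np.zeros(n, dtype=bool))
    for i in range(n):
        frame = stack[i]
        mask = frame > head_mask_threshold
        if not mask.any():
            continue
        cx, cy, roi_mean, bg, signal, size = _extract_one(frame, mask, dilation_margin)
        out.centroid_x[i], out.centroid_y[i] = cx, cy
        out.roi_mean[i], out.background_mean[i] = roi_mean, bg
        out.signal[i] = signal
        out.roi_pixel_count[i] = size
        out.valid[i] = True
    return out


def compute_speed(x: np.ndarray, y: np.ndarray, dt: float, pixel_size: float = 1.0,
                  valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Frame-to-frame tracking speed in micrometers per second.

    speed[i] = ||(x, y)[i] - (x, y)[i-1]|| * pixel_size / dt for i >= 1;
    speed[0] is backfilled from speed[1] so the series keeps trace length.
    A frame adjacent to an invalid position cannot have a defined step, so
    both neighbours of an invalid frame are flagged invalid in the output.

    Returns ``(speed, speed_valid)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid frames to compute speed")
    n = x.size
    speed = np.full(n, np.nan)
    step_ok = valid[1:] & valid[:-1]
    dx = np.diff(x)
    dy = np.diff(y)
    speed[1:][step_ok] = np.hypot(dx[step_ok], dy[step_ok]) * pixel_size / dt
    speed_valid = np.zeros(n, dtype=bool)
    speed_valid[1:] = step_ok
    if n >= 2:
        speed[0] = speed[1]
        speed_valid[0] = speed_valid[1]
    return speed, speed_valid


def ratiometric_activity(gcamp: np.ndarray, mkate2: np.ndarray,
                         valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Motion/expression-corrected activity: GCaMP divided by mKate2.

    The calcium-insensitive mKate2 channel shares focus drift and expression
    level with GCaMP, so the ratio cancels both.  Frames with mkate2 <= 0
    (or non-finite inputs) become invalid.  Returns ``(activity, valid)``.
    """
    gcamp = np.asarray(gcamp, dtype=float)
    mkate2 = np.asarray(mkate2, dtype=float)
    if gcamp.size != mkate2.size:
        raise ValueError("gcamp and mkate2 must have equal length")
    ok = np.isfinite(gcamp) & np.isfinite(mkate2) & (mkate2 > 0)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if not ok.any():
        raise ValueError("all frames invalid: no positive mkate2 values")
    activity = np.full(gcamp.size, np.nan)
    activity[ok] = gcamp[ok] / mkate2[ok]
    return activity, ok


def baseline_normalize(activity: np.ndarray, baseline_window: tuple[int, int],
                       valid: np.ndarray | None = None) -> np.ndarray:
    """Divide an activity series by its mean over a baseline frame window.

    This is the convention for stimulation experiments, where the pre-stimulus
    recording defines the baseline: the window is [start, stop) in frames.
    """
    activity = np.asarray(activity, dtype=float)
    start, stop = baseline_window
    if not (0 <= start < stop <= activity.size):
        raise ValueError("baseline window out of range or empty")
    seg = activity[start:stop]
    ok = np.isfinite(seg)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)[start:stop]
    if not ok.any():
        raise ValueError("no valid frames in baseline window")
    mean = seg[ok].mean()
    if mean <= 0:
        raise ValueError("baseline mean must be positive")
    return activity / mean


def frame_subtraction_mobility(frame_stack: np.ndarray) -> np.ndarray:
    """Movement measure for DIC movies: mean absolute frame difference.

    motion[i] = mean(|frame[i] - frame[i-1]|) for i >= 1; motion[0] is
    backfilled from motion[1].  The absolute value is taken because a signed
    mean of the difference matrix cancels to ~0 and carries no motion
    information; a moving worm lights up the difference image on both sides.
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, height, width) stack")
    motion = np.empty(stack.shape[0])
    motion[1:] = np.abs(np.diff(stack, axis=0)).mean(axis=(1, 2))
    motion[0] = motion[1]
    return motion
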