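"""Sleep / quiescence bout detection and bout-onset alignment.

The detection recipe for behavioral quiescence and neuronal inactivity is
the same three-stage pipeline throughout:

1. smooth the raw series over a fixed number of time points with a
   first-degree local polynomial regression (lowess convention),
2. normalize the smoothed series to [0, 1] per animal (0 = that animal's
   lowest value, 1 = its highest),
3. call maximal runs below a fractional threshold that last at least a
   preset minimum duration as bouts.

RIM inactivity uses a different rule: smooth over 5 points, find calcium
peaks of topographic prominence >= 0.2, and call peak-free gaps of at least
5 minutes inactive.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal

from .core_io import (AlignedEnsemble, Bout, BoutSet, DetectionParams,
                      PeakSet, Trace, get_preset, logger)

__all__ = [
    "smooth_local_linear", "minmax_normalize", "detect_bouts",
    "find_peaks_prominence", "detect_rim_inactivity", "align_to_onsets",
    "fraction_in_bouts", "detect_sleep",
]


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_local_linear(values: np.ndarray, window: int,
                        valid: np.ndarray | None = None,
                        method: str = "lowess") -> np.ndarray:
    """Smooth a uniformly sampled series over a fixed number of points.

    ``method='lowess'`` (default) replaces each point by the value, at its
    own position, of a degree-1 regression over the nearest ``window``
    points, weighted by the tricube kernel w = (1 - (d/dmax)^3)^3 of the
    index distance d.  At the series edges the neighborhood is the same size
    but asymmetric.  ``method='moving'`` is a plain (unweighted) mean over
    the same nearest-``window`` neighborhood.

    Invalid frames get zero weight in every local fit but still receive an
    output value interpolated from their valid neighbors.

    Parameters
    ----------
    values : array of float
    window : int
        Neighborhood size in points (not seconds); the nearest ``window``
        indices, i - (window-1)//2 ... shifted to stay in range.
    valid : bool array, optional
        Frames to include in the fits; defaults to finite values.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    if method not in ("lowess", "moving"):
        raise ValueError("method must be 'lowess' or 'moving'")
    n_valid = int(valid.sum())
    if window > n_valid:
        raise ValueError(f"window {window} exceeds number of valid points {n_valid}")
    if window == 1 or n == 1:
        return v.copy()

    k = min(window, n)
    # nearest-k neighborhoods: contiguous index blocks, clipped at the edges
    starts = np.clip(np.arange(n) - (k - 1) // 2, 0, n - k)
    idx = starts[:, None] + np.arange(k)[None, :]            # (n, k)
    ti = np.arange(n, dtype=float)[:, None]
    tj = idx.astype(float)
    vals = np.where(valid[idx], v[idx], 0.0)

    if method == "moving":
        w = valid[idx].astype(float)
    else:
        d = np.abs(tj - ti)
        dmax = d.max(axis=1, keepdims=True)
        dmax[dmax == 0] = 1.0
        w = (1.0 - (d / dmax) ** 3) ** 3
        w[~valid[idx]] = 0.0

    sw = w.sum(axis=1)
    swy = (w * vals).sum(axis=1)
    out = np.full(n, np.nan)
    have = sw > 0
    if method == "moving":
        out[have] = swy[have] / sw[have]
        return out

    swx = (w * tj).sum(axis=1)
    swxx = (w * tj * tj).sum(axis=1)
    swxy = (w * tj * vals).sum(axis=1)
    denom = sw * swxx - swx ** 2
    # a window with <2 distinct weighted points cannot pin a slope: use the
    # weighted mean there instead of dividing by ~0
    scale = np.maximum(sw * swxx, 1.0)
    fit = have & (np.abs(denom) > 1e-10 * scale)
    slope = np.zeros(n)
    slope[fit] = (sw[fit] * swxy[fit] - swx[fit] * swy[fit]) / denom[fit]
    intercept = np.full(n, np.nan)
    intercept[have] = (swy[have] - slope[have] * swx[have]) / sw[have]
    out[have] = intercept[have] + slope[have] * ti[have, 0]
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def minmax_normalize(values: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Scale a series to [0, 1] over its valid frames: (v - min)/(max - min).

    Each animal is normalized against its own extremes, so the detection
    thresholds are fractions of that animal's dynamic range and raw-unit
    scale differences between animals or setups drop out.  A constant series
    degenerates to all zeros (with a warning) so that no positive threshold
    can produce bouts in the 'above' direction while 'below' keeps its
    strictness semantics.
    """
    v = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    if valid.sum() < 2:
        raise ValueError("need >= 2 valid values to normalize")
    lo = v[valid].min()
    hi = v[valid].max()
    if hi == lo:
        warnings.warn("constant series: min-max normalization degenerates to zeros")
        out = np.where(valid, 0.0, np.nan)
        return out
    out = np.full(v.size, np.nan)
    out[valid] = (v[valid] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# Threshold + duration bout detection
# ---------------------------------------------------------------------------

def detect_bouts(normalized_values: np.ndarray, params: DetectionParams, dt: float,
                 valid: np.ndarray | None = None, animal_id: str = "",
                 label: str = "mobility_quiescence") -> BoutSet:
    """Maximal sub-threshold runs of at least ``min_duration`` become bouts.

    A frame belongs to a run when it is valid and its value is strictly
    below ``params.threshold`` (strictly above for direction='above'); ties
    at the threshold end a run.  Invalid frames break runs -- a bout cannot
    span unobserved frames.  Runs shorter than the minimum duration are
    discarded; no merging across excursions is performed.
    """
    v = np.asarray(normalized_values, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    if params.direction == "below":
        in_state = valid & (v < params.threshold)
    else:
        in_state = valid & (v > params.threshold)

    min_frames = int(np.ceil(params.min_duration / dt - 1e-9))
    bouts = []
    for start, end in _runs(in_state):
        if end - start >= min_frames:
            bouts.append(Bout(start_index=start, end_index=end, dt=dt, label=label))
    return BoutSet(animal_id=animal_id, label=label, bouts=bouts,
                   trace_duration=v.size * dt)


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs of a boolean array, half-open."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    yield from zip(starts, ends)


# ---------------------------------------------------------------------------
# Peak-prominence detection (RIM)
# ---------------------------------------------------------------------------

def find_peaks_prominence(values: np.ndarray, min_prominence: float) -> PeakSet:
    """All local maxima whose topographic prominence reaches ``min_prominence``.

    Prominence is the standard topographic definition: the peak height minus
    the higher of the two lowest points separating it from higher terrain
    (or from the series ends).  Plateau maxima are reported at their
    left-most index.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("series must be finite")
    peaks, props = sp_signal.find_peaks(v, prominence=min_prominence,
                                        plateau_size=(1, None))
    return PeakSet(indices=props["left_edges"], prominences=props["prominences"])


def detect_rim_inactivity(activity: np.ndarray, dt: float,
                          smooth_window: int = 5, min_prominence: float = 0.2,
                          min_gap: float = 300.0, valid: np.ndarray | None = None,
                          animal_id: str = "") -> BoutSet:
    """RIM inactivity: peak-free stretches of the smoothed activity.

    RIM is a wake-active neuron whose calcium signal spikes during movement;
    inactivity is therefore defined by the *absence* of peaks rather than by
    a level threshold.  The activity is smoothed over ``smooth_window``
    points, peaks of prominence >= ``min_prominence`` are located, and every
    maximal peak-free interval lasting at least ``min_gap`` seconds (5 min
    by default) becomes a ``rim_inactivity`` bout.
    """
    v = np.asarray(activity, dtype=float)
    n = v.size
    min_frames = int(np.ceil(min_gap / dt - 1e-9))
    if n < min_frames:
        warnings.warn("series shorter than the minimum inactivity gap; no bouts possible")
        return BoutSet(animal_id=animal_id, label="rim_inactivity", bouts=[],
                       trace_duration=n * dt)
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    smoothed = smooth_local_linear(v, smooth_window, valid=valid)
    finite = np.isfinite(smoothed)
    if finite.any():
        # non-finite frames cannot host peaks; fill them with the series
        # minimum so they never create spurious maxima, then search
        filled = np.where(finite, smoothed, smoothed[finite].min())
        peaks = find_peaks_prominence(filled, min_prominence)
    else:
        peaks = PeakSet(np.array([], dtype=int), np.array([]))
    # a peak frame interrupts inactivity; unobserved frames break runs too
    peak_free = valid & finite
    peak_free[peaks.indices] = False
    bouts = []
    for start, end in _runs(peak_free):
        if end - start >= min_frames:
            bouts.append(Bout(start_index=start, end_index=end, dt=dt,
                              label="rim_inactivity"))
    return BoutSet(animal_id=animal_id, label="rim_inactivity", bouts=bouts,
                   trace_duration=n * dt)


# ---------------------------------------------------------------------------
# Bout-onset alignment
# ---------------------------------------------------------------------------

def align_to_onsets(quantity: np.ndarray, boutset: BoutSet, pre: float, post: float,
                    dt: float, valid: np.ndarray | None = None,
                    quantity_label: str = "quantity") -> AlignedEnsemble:
    """Stack snippets of ``quantity`` relative to bout onsets.

    A bout is eligible only when the animal was observed and mobile
    throughout the ``pre`` seconds before onset: the pre-window must lie
    fully inside the trace, contain no frame of any other bout in
    ``boutset``, and contain only valid frames.  The snippet
    [onset - pre, onset + post) must also fit inside the trace.  Relative
    time 0 is the bout onset frame.
    """
    v = np.asarray(quantity, dtype=float)
    n = v.size
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    pre_f = int(round(pre / dt))
    post_f = int(round(post / dt))
    if pre_f < 1 or post_f < 1:
        raise ValueError("pre and post must each cover at least one frame")

    in_bout = np.zeros(n, dtype=bool)
    for b in boutset.bouts:
        in_bout[b.start_index:b.end_index] = True

    rows = []
    for b in boutset.bouts:
        lo = b.start_index - pre_f
        hi = b.start_index + post_f
        if lo < 0 or hi > n:
            continue
        pre_slice = slice(lo, b.start_index)
        if in_bout[pre_slice].any():       # another bout (or this one) intrudes
            continue
        if not valid[pre_slice].all():     # unobserved frames: not provably mobile
            continue
        rows.append(v[lo:hi])

    snippets = np.vstack(rows) if rows else np.empty((0, pre_f + post_f))
    rel_t = np.arange(-pre_f, post_f) * dt
    return AlignedEnsemble(relative_time=rel_t, snippets=snippets,
                           quantity_label=quantity_label)


# ---------------------------------------------------------------------------
# Summaries and the convenience entry point
# ---------------------------------------------------------------------------

def fraction_in_bouts(boutset: BoutSet, interval: tuple[float, float] | None = None) -> float:
    """Fraction of an interval (seconds) covered by bouts.

    Defaults to the whole trace; a windowed interval gives e.g. the fraction
    of time asleep in the 20 minutes following a heat shock.
    """
    if interval is None:
        interval = (0.0, boutset.trace_duration)
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval must have positive length")
    covered = 0.0
    for b in boutset.bouts:
        covered += max(0.0, min(b.end_time, t1) - max(b.start_time, t0))
    return covered / (t1 - t0)


def detect_sleep(trace: Trace, preset: str | DetectionParams = "calcium_20x",
                 method: str = "lowess", channel: str | None = None) -> BoutSet:
    """Full mobility-quiescence pipeline on one trace.

    Smooths the movement series (tracked speed if present, else the
    frame-subtraction motion value) over the preset's window, normalizes it
    to the animal's own [0, 1] range, and extracts sub-threshold bouts.
    """
    params = preset if isinstance(preset, DetectionParams) else get_preset(preset)
    if params.kind != "threshold":
        raise ValueError(f"preset {params.name!r} is not a threshold preset")
    if channel is None:
        channel = "speed" if trace.speed is not None else "motion"
    series = getattr(trace, channel)
    if series is None:
        raise ValueError(f"trace {trace.animal_id!r} has no {channel!r} series")
    label = "neuronal_inactivity" if channel in ("gcamp", "activity") else "mobility_quiescence"
    smoothed = smooth_local_linear(series, params.smooth_window,
                                   valid=trace.valid, method=method)
    normalized = minmax_normalize(smoothed, valid=trace.valid)
    return detect_bouts(normalized, params, trace.dt, valid=trace.valid,
                        animal_id=trace.animal_id, label=label)


def detect_neuronal_inactivity(activity: np.ndarray, dt: float,
                               preset: str | DetectionParams = "neuronal",
                               valid: np.ndarray | None = None,
                               animal_id: str = "", method: str = "lowess") -> BoutSet:
    """Pan-neuronal inactivity: same smoothing/normalization/threshold recipe
    as mobility quiescence, applied to the combined activity series with the
    20%/3-min preset."""
    params = preset if isinstance(preset, DetectionParams) else get_preset(preset)
    smoothed = smooth_local_linear(np.asarray(activity, dtype=float),
                                   params.smooth_window, valid=valid, method=method)
    normalized = minmax_normalize(smoothed, valid=valid)
    return detect_bouts(normalized, params, dt, valid=valid,
                        animal_id=animal_id, label="neuronal_inactivity")
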