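"""Single-cell trace feature extraction.

Implements the per-trace statistics used to summarise hourly time-lapse
reporter traces: maximum amplitude over the first 24 h after stimulus onset,
lag time to 1.5x baseline, width at half-maximum, a tanh fit to the initial
rise (slope a*c, pulse amplitude 2*c), per-pulse window amplitudes,
responder classification for two-pulse experiments, CVs, and feature
correlations.

Conventions (configurable where noted):

* baseline for the amplitude is the mean of the first two pre-onset frames;
  the lag baseline additionally includes the frame at onset;
* the lag threshold comparison is inclusive (a value exactly at 1.5x
  baseline counts as a crossing);
* CVs use the sample SD (n-1 denominator);
* ties in window maxima resolve to the earliest timepoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .traces import TraceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "max_amplitude",
    "lag_time",
    "half_max_width",
    "tanh_fit",
    "cv_over_time",
    "feature_cv",
    "pulse_amplitude_window",
    "classify_responders",
    "responder_stats",
    "feature_correlation",
    "extract_features",
    "TanhFit",
    "WidthResult",
    "WindowAmplitude",
    "LAG_NOT_DETECTED",
]

LAG_NOT_DETECTED = np.nan  # sentinel for traces that never reach threshold

RESPONDER_CLASSES = ("+/+", "+/-", "-/+", "-/-")


def _pre_onset(time: np.ndarray, onset: float) -> np.ndarray:
    return np.flatnonzero(time < onset)


def max_amplitude(trace: np.ndarray, time: np.ndarray, onset: float = 0.0, window: float = 24.0) -> float:
    """Maximum over the first ``window`` hours after onset minus the mean of
    the first two pre-onset frames (the basal level, assumed unaffected by
    the stimulus).  Not clamped: a flat noisy trace may come out negative.
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    pre = _pre_onset(time, onset)
    if pre.size < 2:
        raise ValueError("max_amplitude needs >= 2 pre-onset frames")
    baseline = trace[pre[:2]].mean()
    sel = (time > onset) & (time <= onset + window)
    if time.max() < onset + window:
        warnings.warn("trace ends before the 24 h amplitude window; truncating", stacklevel=2)
    if not sel.any():
        raise ValueError("no post-onset points in the amplitude window")
    return float(trace[sel].max() - baseline)


def lag_time(
    trace: np.ndarray,
    time: np.ndarray,
    onset: float = 0.0,
    ratio: float = 1.5,
    inclusive: bool = True,
) -> float:
    """First post-onset time (relative to onset) at which the trace reaches
    ``ratio`` times its baseline, the mean of the two pre-onset frames and
    the frame at onset.  Returns NaN (not detected) if never reached.
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    pre = _pre_onset(time, onset)
    at = np.flatnonzero(np.isclose(time, onset))
    if pre.size < 2 or at.size != 1:
        raise ValueError("lag_time needs two pre-onset frames and a frame at onset")
    baseline = trace[np.concatenate([pre[:2], at])].mean()
    if baseline <= 0:
        raise ValueError("baseline must be positive for a ratio threshold")
    thr = ratio * baseline
    post = np.flatnonzero(time > onset)
    hit = trace[post] >= thr if inclusive else trace[post] > thr
    if not hit.any():
        return LAG_NOT_DETECTED
    return float(time[post[np.argmax(hit)]] - onset)


@dataclass
class WidthResult:
    width: float  # h
    right_censored: bool
    left: float  # crossing times, h
    right: float


def half_max_width(
    trace: np.ndarray,
    time: np.ndarray,
    onset: float = 0.0,
    window: float = 24.0,
) -> WidthResult:
    """Width at half of the maximum amplitude (max minus baseline).

    The width is the length of the contiguous interval around the peak where
    the trace is at least baseline + half the amplitude, with linear
    interpolation at the two crossings (hourly sampling is coarse relative
    to typical widths).  If the trace never descends below the half level
    before the window end the width is right-censored and flagged.
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    pre = _pre_onset(time, onset)
    if pre.size < 2:
        raise ValueError("half_max_width needs >= 2 pre-onset frames")
    baseline = trace[pre[:2]].mean()
    sel = np.flatnonzero((time > onset) & (time <= onset + window))
    if sel.size == 0:
        raise ValueError("empty analysis window")
    t_w, y_w = time[sel], trace[sel]
    i_pk = int(np.argmax(y_w))  # earliest max on ties
    amp = y_w[i_pk] - baseline
    if amp <= 0:
        raise ValueError("no peak above baseline")
    half = baseline + 0.5 * amp

    def interp_cross(i0: int, i1: int) -> float:
        y0, y1 = y_w[i0], y_w[i1]
        if y1 == y0:
            return float(t_w[i1])
        f = (half - y0) / (y1 - y0)
        return float(t_w[i0] + f * (t_w[i1] - t_w[i0]))

    # walk left from the peak to the first point below half
    i = i_pk
    while i > 0 and y_w[i - 1] >= half:
        i -= 1
    if i == 0:
        left = float(t_w[0]) if y_w[0] >= half else float(t_w[0])
        if y_w[0] >= half:
            # rising edge before first window point: interpolate against onset value
            j0 = np.flatnonzero(np.isclose(time, onset))
            if j0.size and trace[j0[0]] < half:
                y0 = trace[j0[0]]
                f = (half - y0) / (y_w[0] - y0)
                left = float(onset + f * (t_w[0] - onset))
    else:
        left = interp_cross(i - 1, i)
    # walk right
    i = i_pk
    while i < y_w.size - 1 and y_w[i + 1] >= half:
        i += 1
    if i == y_w.size - 1:
        return WidthResult(width=float(t_w[-1] - left), right_censored=True, left=left, right=float(t_w[-1]))
    right = interp_cross(i, i + 1)
    return WidthResult(width=float(right - left), right_censored=False, left=left, right=right)


@dataclass
class TanhFit:
    a: float
    b: float
    c: float
    d: float
    slope: float  # a*c
    pulse_amplitude: float  # 2*c
    residual: float
    converged: bool


def _tanh_model(x, a, b, c, d):
    return np.tanh(a * x + b) * c + d


def tanh_fit(
    trace: np.ndarray,
    time: np.ndarray,
    onset: float = 0.0,
    window: float = 13.0,
    maxfev: int = 5000,
) -> TanhFit:
    """Fit the initial rise (first ``window`` hours after onset) to
    y = tanh(a*x + b) * c + d; the kinetic slope is a*c and the pulse
    amplitude 2*c.  x is time since onset.  On failure every field is NaN
    and ``converged`` is False.
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    sel = (time >= onset) & (time <= onset + window)
    if sel.sum() < 5:
        raise ValueError("tanh_fit needs >= 5 points in the fit window")
    x = time[sel] - onset
    y = trace[sel]
    span = float(y.max() - y.min())
    p0 = (0.5, -2.0, max(span / 2.0, 1e-6), float(y.min()) + span / 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_tanh_model, x, y, p0=p0, maxfev=maxfev)
        a, b, c, d = (float(v) for v in popt)
        resid = float(np.sqrt(np.mean((_tanh_model(x, *popt) - y) ** 2)))
        return TanhFit(a, b, c, d, slope=a * c, pulse_amplitude=2 * c, residual=resid, converged=True)
    except RuntimeError as e:
        log.debug("tanh_fit failed: %s", e)
        nan = float("nan")
        return TanhFit(nan, nan, nan, nan, nan, nan, nan, converged=False)


def cv_over_time(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Per-timepoint coefficient of variation across cells (sample SD over
    mean); NaN where the mean is zero."""
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] < 2:
        raise ValueError("cv_over_time needs >= 2 cells")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


def feature_cv(feature: np.ndarray, ddof: int = 1) -> float:
    """CV of a per-cell feature: SD of the feature across cells over its mean."""
    feature = np.asarray(feature, float)
    feature = feature[np.isfinite(feature)]
    if feature.size < 2:
        raise ValueError("feature_cv needs >= 2 finite values")
    mean = feature.mean()
    if mean == 0:
        return float("nan")
    return float(feature.std(ddof=ddof) / mean)


@dataclass
class WindowAmplitude:
    amplitude: float
    truncated: bool


def pulse_amplitude_window(
    trace: np.ndarray,
    time: np.ndarray,
    onset: float,
    end: float,
) -> WindowAmplitude:
    """Window maximum minus the value at pulse onset, over [onset, end].

    Scores each stimulation pulse independently of earlier ones (the running
    level at pulse onset is subtracted).  A window extending past the data
    is truncated and flagged.  Returns 0 for monotonically decreasing
    windows (the max is at onset).
    """
    trace = np.asarray(trace, float)
    time = np.asarray(time, float)
    truncated = time.max() < end
    sel = (time >= onset) & (time <= end)
    if not sel.any():
        raise ValueError("empty pulse window")
    i_on = np.flatnonzero(np.isclose(time, onset))
    base = trace[i_on[0]] if i_on.size else trace[sel][0]
    return WindowAmplitude(amplitude=float(trace[sel].max() - base), truncated=bool(truncated))


def classify_responders(amplitudes: np.ndarray, threshold: float) -> np.ndarray:
    """Classify cells by whether each of two pulse amplitudes exceeds the
    threshold: '+/+', '+/-', '-/+' or '-/-'."""
    amplitudes = np.asarray(amplitudes, float)
    if amplitudes.ndim != 2 or amplitudes.shape[1] != 2:
        raise ValueError("amplitudes must be (n_cells, 2)")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    r1 = amplitudes[:, 0] >= threshold
    r2 = amplitudes[:, 1] >= threshold
    out = np.empty(amplitudes.shape[0], dtype=object)
    out[r1 & r2] = "+/+"
    out[r1 & ~r2] = "+/-"
    out[~r1 & r2] = "-/+"
    out[~r1 & ~r2] = "-/-"
    return out


def responder_stats(classes: np.ndarray) -> dict:
    """Contingency counts and conditional response probabilities for a
    two-pulse responder classification."""
    classes = np.asarray(classes)
    n = classes.size
    counts = {c: int((classes == c).sum()) for c in RESPONDER_CLASSES}
    n_r1 = counts["+/+"] + counts["+/-"]
    n_not1 = counts["-/+"] + counts["-/-"]
    p2_given_1 = counts["+/+"] / n_r1 if n_r1 else float("nan")
    p2_given_not1 = counts["-/+"] / n_not1 if n_not1 else float("nan")
    return {
        "n": n,
        "counts": counts,
        "p_resp1": n_r1 / n if n else float("nan"),
        "p_resp2": (counts["+/+"] + counts["-/+"]) / n if n else float("nan"),
        "p_resp2_given_resp1": p2_given_1,
        "p_resp2_given_nonresp1": p2_given_not1,
        "independence_gap": abs(p2_given_1 - p2_given_not1),
    }


def feature_correlation(featA: np.ndarray, featB: np.ndarray) -> tuple[float, int]:
    """Pearson correlation between two per-cell features with
    pairwise-complete handling; returns (r, n).  NaN r for degenerate input.
    """
    a = np.asarray(featA, float)
    b = np.asarray(featB, float)
    if a.shape != b.shape:
        raise ValueError("features must be paired")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return float("nan"), n
    r, _ = pearsonr(a[ok], b[ok])
    return float(r), n


def extract_features(
    tm: TraceMatrix,
    onset: float | None = None,
    lag_ratio: float = 1.5,
    compute_width: bool = False,
    tanh_window: float | None = None,
) -> pd.DataFrame:
    """Per-cell feature table for a TraceMatrix: baseline, max_amplitude,
    lag_time, optionally half-max width and the tanh-rise slope/amplitude.

    Width extraction only makes sense for reporters that track endogenous
    decay; it is off by default.
    """
    onset = tm.stimulus_onsets[0] if onset is None else onset
    rows = []
    for i in range(tm.n_cells):
        y = tm.values[i]
        pre = _pre_onset(tm.time, onset)
        rec: dict = {
            "cell_id": tm.cell_ids[i],
            "baseline": float(y[pre[:2]].mean()) if pre.size >= 2 else np.nan,
            "max_amplitude": max_amplitude(y, tm.time, onset),
        }
        try:
            rec["lag_time"] = lag_time(y, tm.time, onset, ratio=lag_ratio)
        except ValueError:
            rec["lag_time"] = np.nan
        if compute_width:
            try:
                w = half_max_width(y, tm.time, onset)
                rec["width"] = w.width
                rec["width_censored"] = w.right_censored
            except ValueError:
                rec["width"] = np.nan
                rec["width_censored"] = True
        if tanh_window is not None:
            tf = tanh_fit(y, tm.time, onset, window=tanh_window)
            rec["slope"] = tf.slope
            rec["pulse_amplitude"] = tf.pulse_amplitude
        rows.append(rec)
    return pd.DataFrame(rows)
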