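"""Fluorescence recovery after photobleaching (FRAP) analysis.

The pipeline is: extract per-frame mean intensities over three regions of
interest (the bleached region, the whole cellular structure, and a camera
background region), double-normalize the bleached-region trace,

    N(t) = [(I_bleach(t) - I_bg(t)) / (I_bleach(t0) - I_bg(t0))]
         / [(I_total(t)  - I_bg(t)) / (I_total(t0)  - I_bg(t0))],

which simultaneously removes the camera offset and the gradual bleaching
caused by image acquisition, then fit the post-bleach recovery with a
single-exponential reaction-limited model

    N(t) = D + M * (1 - D) * (1 - exp(-k t)),        t >= 0,

where D is the normalized intensity immediately after the bleach, M the
mobile fraction and k the recovery rate (half-time ln 2 / k). Curves from
several cells are averaged pointwise with s.e.m.; a flow metric checks that
the bleached region recovers at the cost of the unbleached remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ImageStack


@dataclass
class FrapROISet:
    """Pixel masks for the three FRAP regions.

    The bleached region must lie inside the total-structure region; the
    background region (camera offset) must be disjoint from the structure.
    """

    roi_bleach: np.ndarray
    roi_total: np.ndarray
    roi_background: np.ndarray

    def __post_init__(self) -> None:
        b, t, g = (np.asarray(m, bool) for m in
                   (self.roi_bleach, self.roi_total, self.roi_background))
        if not (b.any() and t.any() and g.any()):
            raise ValueError("all three ROIs must be non-empty")
        if b.shape != t.shape or b.shape != g.shape:
            raise ValueError("ROI masks must share one shape")
        if np.any(b & ~t):
            raise ValueError("bleach ROI must lie within the total-structure ROI")
        if np.any(g & t):
            raise ValueError("background ROI must be disjoint from the structure")
        self.roi_bleach, self.roi_total, self.roi_background = b, t, g


@dataclass
class FrapTrace:
    """Raw ROI traces and, after normalization, the recovery curve N(t).

    ``t`` is seconds relative to the bleach (negative = pre-bleach),
    strictly increasing. ``n_prebleach`` frames precede the bleach; the
    normalization reference t0 is the mean of the pre-bleach frames (or the
    last one, see :func:`double_normalize`).
    """

    t: np.ndarray
    I_bleach: np.ndarray
    I_total: np.ndarray
    I_background: np.ndarray
    n_prebleach: int
    N: np.ndarray | None = None
    excluded_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("I_bleach", "I_total", "I_background"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length differs from t")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if not 1 <= self.n_prebleach < len(self.t):
            raise ValueError("need at least one pre-bleach and one post-bleach frame")

    @property
    def t_post(self) -> np.ndarray:
        return self.t[self.n_prebleach :]

    @property
    def N_post(self) -> np.ndarray:
        if self.N is None:
            raise ValueError("trace not yet normalized")
        return self.N[self.n_prebleach :]


@dataclass
class FrapFit:
    mobile_fraction: float
    rate: float
    t_half: float
    plateau: float
    postbleach_depth: float
    residual_norm: float


def extract_traces(series: ImageStack, rois: FrapROISet,
                   n_prebleach: int, frame_interval: float = 1.0) -> FrapTrace:
    """Per-frame arithmetic ROI means from a registered time-lapse.

    Time is assigned relative to the bleach: the first post-bleach frame is
    t = 0, pre-bleach frames carry negative times.
    """
    if "time" not in series.axes:
        raise ValueError("series must have a time axis")
    frame0 = series.frame(0).data
    for mask in (rois.roi_bleach, rois.roi_total, rois.roi_background):
        if mask.shape != frame0.shape:
            raise ValueError("ROI extends outside the frame extent")
    n_t = series.n("time")
    t = (np.arange(n_t) - n_prebleach) * frame_interval
    means = {"b": np.empty(n_t), "tot": np.empty(n_t), "bg": np.empty(n_t)}
    for i in range(n_t):
        frame = series.frame(i).data
        means["b"][i] = frame[rois.roi_bleach].mean()
        means["tot"][i] = frame[rois.roi_total].mean()
        means["bg"][i] = frame[rois.roi_background].mean()
    return FrapTrace(t, means["b"], means["tot"], means["bg"], n_prebleach)


def double_normalize(trace: FrapTrace, reference: str = "mean") -> FrapTrace:
    """Compute the double-normalized recovery curve N(t) in place and return it.

    ``reference`` picks the pre-bleach reference value: "mean" averages the
    background-corrected intensities over all pre-bleach frames (lower
    variance), "last" uses only the final pre-bleach frame. Frames whose
    corrected total intensity is not positive are flagged in
    ``excluded_frames`` and carry NaN in N.
    """
    pre = slice(0, trace.n_prebleach)
    corr_b = trace.I_bleach - trace.I_background
    corr_tot = trace.I_total - trace.I_background
    if reference == "mean":
        ref_b, ref_tot = corr_b[pre].mean(), corr_tot[pre].mean()
    elif reference == "last":
        ref_b, ref_tot = corr_b[trace.n_prebleach - 1], corr_tot[trace.n_prebleach - 1]
    else:
        raise ValueError("reference must be 'mean' or 'last'")
    if ref_b <= 0 or ref_tot <= 0:
        raise ValueError("pre-bleach reference intensities must exceed background")

    bad = corr_tot <= 0
    if bad.any():
        trace.excluded_frames = list(np.flatnonzero(bad))
        warnings.warn(f"{bad.sum()} frame(s) excluded: corrected total intensity <= 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        N = (corr_b / ref_b) / (corr_tot / ref_tot)
    N[bad] = np.nan
    trace.N = N
    return trace


def _model(t, D, M, k):
    return D + M * (1.0 - D) * (1.0 - np.exp(-k * t))


def fit_recovery(trace: FrapTrace, fix_depth: bool = True) -> FrapFit:
    """Bounded least-squares fit of the single-exponential recovery model.

    The post-bleach depth D is fixed to the first post-bleach value of N by
    default, or co-fitted with ``fix_depth=False``. The mobile fraction is
    constrained to [0, 1]; a fit hugging the lower bound (no recovery)
    reports M = 0 with an unidentifiable (NaN) rate.
    """
    t, N = trace.t_post, trace.N_post
    keep = np.isfinite(N)
    t, N = t[keep], N[keep]
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach frames to fit")
    D0 = float(N[0])
    if D0 >= 1.0:
        raise ValueError("first post-bleach value must be below 1 (no bleach detected)")

    k0 = np.log(2) / max(t[-1] / 10.0, 1e-6)
    try:
        if fix_depth:
            popt, _ = curve_fit(lambda tt, M, k: _model(tt, D0, M, k), t, N,
                                p0=[0.5, k0], bounds=([0.0, 1e-8], [1.0, np.inf]),
                                maxfev=10000)
            D, (M, k) = D0, popt
        else:
            popt, _ = curve_fit(_model, t, N,
                                p0=[D0, 0.5, k0],
                                bounds=([0.0, 0.0, 1e-8], [1.0, 1.0, np.inf]),
                                maxfev=10000)
            D, M, k = popt
    except RuntimeError as exc:
        raise RuntimeError(f"recovery fit did not converge: {exc}") from exc

    resid = float(np.sqrt(np.mean((_model(t, D, M, k) - N) ** 2)))
    # flat traces sit in a degenerate (tiny k, arbitrary M) valley: detect by
    # the fitted recovery span over the observed window, not by M alone
    span = _model(t[-1], D, M, k) - D
    if M < 1e-6 or span < 1e-4:
        M, k = 0.0, float("nan")  # flat trace: rate not identifiable
        warnings.warn("no recovery detected; rate unidentifiable", stacklevel=2)
    plateau = D + M * (1.0 - D) if np.isfinite(k) else D
    t_half = np.log(2) / k if np.isfinite(k) and k > 0 else float("nan")
    return FrapFit(float(M), float(k), float(t_half), float(plateau), float(D), resid)


def average_curves(traces: list[FrapTrace]) -> pd.DataFrame:
    """Pointwise mean and s.e.m. of normalized curves on a common time base.

    The time base is the first trace's grid clipped to the range every trace
    covers; other traces are resampled by linear interpolation. With a
    single trace the s.e.m. column is NaN.
    """
    if not traces:
        raise ValueError("no traces to average")
    for tr in traces:
        if tr.N is None:
            raise ValueError("all traces must be normalized first")
    t_lo = max(tr.t[0] for tr in traces)
    t_hi = min(tr.t[-1] for tr in traces)
    base = traces[0].t[(traces[0].t >= t_lo) & (traces[0].t <= t_hi)]
    resampled = np.vstack([np.interp(base, tr.t, tr.N) for tr in traces])
    mean = resampled.mean(axis=0)
    sem = (resampled.std(axis=0, ddof=1) / np.sqrt(len(traces))
           if len(traces) > 1 else np.full_like(mean, np.nan))
    return pd.DataFrame({"t": base, "mean": mean, "sem": sem,
                         "n_curves": len(traces)})


def flow_metric(trace: FrapTrace, n_bleach_px: int, n_total_px: int) -> pd.DataFrame:
    """Per-frame signal transfer from the unbleached into the bleached region.

    Requires that the bleached and unbleached regions partition the total
    structure (pixel counts must satisfy 0 < n_bleach < n_total). Gains and
    losses are background-corrected summed signals, normalized for
    acquisition bleaching by the log-linear trend of the total trace; the
    conservation residual gain - loss is reported per frame. The cumulative
    transfer at the last frame approaches M * (P - D) * n_bleach_px for a
    fully recovered series.
    """
    if not 0 < n_bleach_px < n_total_px:
        raise ValueError("bleached and unbleached ROIs must partition the structure")
    n_u = n_total_px - n_bleach_px
    post = slice(trace.n_prebleach, None)
    t = trace.t[post]
    sig_b = (trace.I_bleach - trace.I_background)[post] * n_bleach_px
    sig_tot = (trace.I_total - trace.I_background)[post] * n_total_px
    sig_u = sig_tot - sig_b

    # acquisition-bleaching correction from the total-signal trend
    with np.errstate(divide="ignore"):
        log_tot = np.log(np.clip(sig_tot, 1e-300, None))
    beta_hat = -np.polyfit(t, log_tot, 1)[0]
    if beta_hat * (t[-1] - t[0]) < 1e-9:  # no measurable acquisition bleaching
        fade = np.ones_like(t)
    else:
        fade = np.exp(-beta_hat * (t - t[0]))

    gain = sig_b / fade - sig_b[0]
    loss = sig_u[0] - sig_u / fade
    return pd.DataFrame({"t": t, "gain": gain, "loss": loss,
                         "transfer": 0.5 * (gain + loss),
                         "residual": gain - loss})
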