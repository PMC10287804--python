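"""Peak detection, delimitation, integration, and entropy filtering.

Each ROI trace is smoothed (local quadratic least squares), its noise level
is estimated from the smoothing residual, and candidate apexes are found by
a continuous wavelet transform with the Mexican-hat mother wavelet, cross-
checked against negative minima of the second derivative. Peak borders are
then refined in two steps: a friction walk on the smoothed trace followed
by a moving-standard-deviation walk on the raw trace, so that asymmetric
(tailing) peaks are delimited without running into baseline noise.

The information-entropy filter scores slope consistency: for an ideal peak
every point climbs monotonically to the apex and falls monotonically after
it ("normal" points); deviating points are "variant". With p and q the
variant and normal fractions, H = -p*log2(p) - q*log2(q); peaks whose H
exceeds the median over the run are discarded as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy.signal import argrelextrema, savgol_filter

from .roi import ROI


@dataclass(frozen=True)
class PeakDetectParams:
    """Detection and feature-filter parameters.

    smooth_window : odd scans — quadratic smoothing window; 7 suits sharp
        CE peaks, 15 the broader HILIC peaks.
    cwt_scales : scale widths in scans; by default 5 logarithmic scales
        spanning the [min_width, max_width] range are derived at run time.
    min_snr : apex height over noise.
    min_width / max_width : minutes — acceptable peak-width band
        (width > 2 min marks a non-peak in the reference criteria).
    min_intensity : counts — minimum apex height (5e4 in the reference
        criteria).
    min_rel_height : fraction — minimum height relative to the tallest
        peak of the same ROI; 0.25 is a suitable value.
    """

    smooth_window: int = 7
    cwt_scales: tuple[float, ...] | None = None
    min_snr: float = 3.0
    min_width: float = 0.05
    max_width: float = 2.0
    min_intensity: float = 5e4
    min_rel_height: float = 0.25
    friction: float = 0.05
    sd_window: int = 5
    sd_k: float = 2.0
    ridge_gap: int = 2

    def __post_init__(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        if not self.min_width < self.max_width:
            raise ValueError("min_width must be < max_width")
        if not 0.0 <= self.min_rel_height <= 1.0:
            raise ValueError("min_rel_height must be in [0, 1]")


@dataclass
class Peak:
    """A detected, delimited, integrated peak within one ROI."""

    roi: ROI
    apex_index: int
    left_index: int
    right_index: int
    apex_time: float = 0.0
    left_time: float = 0.0
    right_time: float = 0.0
    height: float = 0.0
    area: float = 0.0
    noise: float = 0.0
    snr: float = 0.0
    entropy_H: float = 0.0
    p_variant: float = 0.0
    q_normal: float = 1.0
    flags: set = field(default_factory=set)

    @property
    def mz(self) -> float:
        return self.roi.mz_center

    @property
    def width(self) -> float:
        return self.right_time - self.left_time


def smooth_roi(roi: ROI | np.ndarray, window: int = 7) -> np.ndarray:
    """Local quadratic least-squares smoothing of a trace.

    A constant or linear trace passes through unchanged (a degree-2 fit is
    exact for them). Traces shorter than the window are returned as copies.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    y = roi.intensities if isinstance(roi, ROI) else np.asarray(roi, dtype=float)
    if len(y) < window:
        return y.copy()
    return savgol_filter(y, window, polyorder=2, mode="interp")


def estimate_noise(roi: ROI | np.ndarray, smoothed: np.ndarray) -> float:
    """Noise level of a trace: robust SD (1.4826 x MAD) of the residual
    between the raw trace and its smoothed version. Insensitive to the
    peaks themselves dominating a few residuals."""
    y = roi.intensities if isinstance(roi, ROI) else np.asarray(roi, dtype=float)
    if len(y) != len(smoothed):
        raise ValueError("raw and smoothed traces must have equal length")
    if len(y) < 3:
        warnings.warn("trace too short for noise estimation; returning 0")
        return 0.0
    resid = np.abs(y - smoothed)
    return float(1.4826 * np.median(resid))


def default_scales(params: PeakDetectParams, scan_interval: float) -> np.ndarray:
    """Five logarithmic CWT scales spanning [min_width, max_width] in scans."""
    if params.cwt_scales is not None:
        return np.asarray(params.cwt_scales, dtype=float)
    lo = max(params.min_width / scan_interval / 2.0, 1.0)
    hi = max(params.max_width / scan_interval / 2.0, lo * 1.5)
    return np.geomspace(lo, hi, 5)


def _ridge_lines(coeffs: np.ndarray, gap: int) -> list[list[tuple[int, int]]]:
    """Link per-scale CWT maxima into ridge lines (largest scale first),
    tolerating ``gap`` missing scales."""
    n_scales, n = coeffs.shape
    maxima = [
        set(argrelextrema(coeffs[s], np.greater_equal, order=1)[0].tolist())
        for s in range(n_scales)
    ]
    ridges: list[list[tuple[int, int]]] = []
    active: list[dict] = []
    for s in range(n_scales - 1, -1, -1):
        window = max(int(np.ceil(2 * (s + 1))), 2)
        cols = sorted(maxima[s])
        used = set()
        for r in active:
            best, bestd = None, None
            for c in cols:
                if c in used:
                    continue
                d = abs(c - r["col"])
                if d <= window and (bestd is None or d < bestd):
                    best, bestd = c, d
            if best is not None:
                used.add(best)
                r["points"].append((s, best))
                r["col"] = best
                r["miss"] = 0
            else:
                r["miss"] += 1
        active = [r for r in active if r["miss"] <= gap or ridges.append(r["points"])]
        for c in cols:
            if c not in used:
                active.append({"col": c, "points": [(s, c)], "miss": 0})
    ridges.extend(r["points"] for r in active)
    return [r for r in ridges if len(r) >= 2 or n_scales < 2]


def detect_peaks(
    roi: ROI,
    params: PeakDetectParams,
    smoothed: np.ndarray | None = None,
    noise: float | None = None,
) -> list[Peak]:
    """Find provisional peaks in one ROI.

    Candidate apexes are CWT ridge maxima (Mexican-hat wavelet over the
    scale grid) that coincide, within one scale width, with a negative
    minimum of the second derivative of the smoothed trace; candidates
    below ``min_snr`` are dropped. Initial bounds sit at the nearest
    flanking zero-crossings of the second derivative.
    """
    y = roi.intensities
    n = len(y)
    if n < 3:
        return []
    if smoothed is None:
        smoothed = smooth_roi(roi, min(params.smooth_window, n - (1 - n % 2)))
    if noise is None:
        noise = estimate_noise(roi, smoothed)
    scan_interval = float(np.median(np.diff(roi.times))) if n > 1 else 1.0
    scales = default_scales(params, scan_interval)
    coeffs, _ = pywt.cwt(smoothed, scales, "mexh")

    # second derivative of the smoothed trace; negative minima mark apexes
    win = min(params.smooth_window, n - (1 - n % 2))
    if n >= win >= 5:
        d2 = savgol_filter(y, win, polyorder=2, deriv=2, mode="interp")
    else:
        d2 = np.gradient(np.gradient(smoothed))
    d2_minima = [i for i in argrelextrema(d2, np.less_equal, order=1)[0] if d2[i] < 0]

    peaks: list[Peak] = []
    taken: set[int] = set()
    for ridge in _ridge_lines(coeffs, params.ridge_gap):
        s_best, c_best = max(ridge, key=lambda sc: coeffs[sc[0], sc[1]])
        scale_w = int(np.ceil(scales[min(s_best, len(scales) - 1)]))
        # refine apex to the local maximum of the smoothed trace
        lo = max(c_best - scale_w, 0)
        hi = min(c_best + scale_w + 1, n)
        apex = lo + int(np.argmax(smoothed[lo:hi]))
        if apex in taken:
            continue
        if not any(abs(m - apex) <= scale_w for m in d2_minima):
            continue
        # height above the trace's local background, so ripples on a
        # flat noisy trace do not fake a high SNR
        background = float(np.quantile(smoothed, 0.1))
        height = float(smoothed[apex]) - background
        if noise > 0 and height / noise < params.min_snr:
            continue
        if noise == 0 and height <= 0:
            continue
        left = apex
        while left > 0 and not (d2[left - 1] > 0 >= d2[left]):
            left -= 1
        right = apex
        while right < n - 1 and not (d2[right + 1] > 0 >= d2[right]):
            right += 1
        taken.add(apex)
        peaks.append(
            Peak(
                roi=roi,
                apex_index=apex,
                left_index=left,
                right_index=right,
                noise=noise,
                snr=height / noise if noise > 0 else np.inf,
            )
        )
    peaks.sort(key=lambda p: p.apex_index)
    # provisional bounds must not cross neighbouring apexes
    for a, b in zip(peaks, peaks[1:]):
        cut = a.apex_index + int(np.argmin(smoothed[a.apex_index : b.apex_index + 1]))
        a.right_index = min(a.right_index, cut)
        b.left_index = max(b.left_index, cut)
    return peaks


def correct_borders(
    roi: ROI,
    smoothed: np.ndarray,
    peak: Peak,
    noise: float,
    friction: float = 0.05,
    sd_window: int = 5,
    sd_k: float = 2.0,
    left_limit: int | None = None,
    right_limit: int | None = None,
) -> Peak:
    """Two-step border refinement.

    Step 1 (friction, smoothed trace): from each provisional bound walk
    outward while the trace keeps falling by more than ``friction`` times
    the local height per step; stop when the decrease stalls, which
    prevents overrun into the baseline.  Step 2 (moving SD, raw trace):
    keep walking outward while the raw-trace SD in a ``sd_window``-point
    moving window exceeds ``sd_k`` x noise; the final bound is the last
    point where the local SD falls to that level.  Bounds never cross the
    apex nor the apexes of adjacent peaks.
    """
    y = roi.intensities
    n = len(y)
    apex = peak.apex_index
    lo_lim = 0 if left_limit is None else max(left_limit, 0)
    hi_lim = n - 1 if right_limit is None else min(right_limit, n - 1)

    def friction_walk(b: int, step: int, limit: int) -> int:
        while b != limit:
            nxt = b + step
            if smoothed[nxt] <= noise:  # already at the noise floor
                b = nxt
                break
            drop = smoothed[b] - smoothed[nxt]
            local = max(smoothed[b], 0.0)
            if drop > friction * local and local > 0:
                b = nxt
            else:
                break
        return b

    def local_sd(i: int) -> float:
        half = sd_window // 2
        seg = y[max(i - half, 0) : min(i + half + 1, n)]
        return float(seg.std()) if len(seg) > 1 else 0.0

    def sd_walk(b: int, step: int, limit: int) -> int:
        thresh = sd_k * noise
        while b != limit and local_sd(b) > thresh:
            b += step
        return b

    left = friction_walk(peak.left_index, -1, lo_lim)
    right = friction_walk(peak.right_index, +1, hi_lim)
    if noise > 0:
        left = sd_walk(left, -1, lo_lim)
        right = sd_walk(right, +1, hi_lim)
    left = min(left, apex - 1) if apex > lo_lim else lo_lim
    right = max(right, apex + 1) if apex < hi_lim else hi_lim
    left = max(left, lo_lim)
    right = min(right, hi_lim)
    peak.left_index, peak.right_index = int(left), int(right)
    if left == 0 or right == n - 1 or apex in (lo_lim, hi_lim):
        peak.flags.add("edge")
    return peak


def integrate_peak(
    roi: ROI, peak: Peak, subtract: float = 0.0
) -> Peak:
    """Integrate a delimited peak.

    Area is the trapezoidal integral (counts x minutes) of the raw
    intensities between the bounds, height the maximum in-bound intensity,
    apex time the time of that maximum. ``subtract`` removes a constant
    (the ROI intensity threshold, when enabled) from every point first;
    this reproduces the known slight underestimation versus manual
    integration and can be disabled.
    """
    i0, i1 = peak.left_index, peak.right_index
    t = roi.times[i0 : i1 + 1]
    y = np.clip(roi.intensities[i0 : i1 + 1] - subtract, 0.0, None)
    if len(y) == 0:
        peak.area = peak.height = 0.0
        return peak
    if len(y) < 3:
        peak.flags.add("narrow")
    peak.area = float(np.trapezoid(y, t)) if len(y) > 1 else 0.0
    j = int(np.argmax(y))
    peak.height = float(y[j])
    peak.apex_index = i0 + j
    peak.apex_time = float(t[j])
    peak.left_time = float(t[0])
    peak.right_time = float(t[-1])
    if peak.noise > 0:
        peak.snr = peak.height / peak.noise
    return peak


def peak_entropy(segment: np.ndarray, apex_offset: int | None = None) -> tuple[float, float, float]:
    """Binary slope-consistency entropy of one peak segment.

    Returns (H, p, q). Points climbing strictly before the apex and
    falling strictly after it are normal; zero or wrong-signed slopes mark
    variant points (a flat step is not a constant positive/negative
    slope). The leading point and the apex carry no incoming slope
    violation and count as normal. 0*log2(0) := 0.
    """
    y = np.asarray(segment, dtype=float)
    total = len(y)
    if total < 3:
        return 0.0, 0.0, 1.0
    apex = int(np.argmax(y)) if apex_offset is None else apex_offset
    variant = 0
    for i in range(1, total):
        slope = y[i] - y[i - 1]
        if i <= apex and slope <= 0:
            variant += 1
        elif i > apex and slope >= 0:
            variant += 1
    p = variant / total
    q = 1.0 - p
    H = 0.0
    for frac in (p, q):
        if frac > 0:
            H -= frac * np.log2(frac)
    return float(H), float(p), float(q)


def entropy_filter(peaks: Sequence[Peak]) -> tuple[list[Peak], list[Peak]]:
    """Score every peak of a run and drop those with H above the median.

    Entropy is computed on the raw trace between the peak bounds. Because
    only strictly-greater-than-median values are removed, at most half of
    the peaks can be discarded; a lone peak always survives.
    """
    peaks = list(peaks)
    if not peaks:
        return [], []
    for p in peaks:
        seg = p.roi.intensities[p.left_index : p.right_index + 1]
        H, pv, qn = peak_entropy(seg, p.apex_index - p.left_index)
        p.entropy_H, p.p_variant, p.q_normal = H, pv, qn
    med = float(np.median([p.entropy_H for p in peaks]))
    kept = [p for p in peaks if p.entropy_H <= med]
    removed = [p for p in peaks if p.entropy_H > med]
    return kept, removed


def filter_peaks(peaks: Sequence[Peak], params: PeakDetectParams) -> list[Peak]:
    """Feature filters: width band, absolute height, SNR, and height
    relative to the tallest peak of the same ROI."""
    by_roi: dict[int, float] = {}
    for p in peaks:
        key = id(p.roi)
        by_roi[key] = max(by_roi.get(key, 0.0), p.height)
    kept = []
    for p in peaks:
        if not (params.min_width <= p.width <= params.max_width):
            continue
        if p.height < params.min_intensity:
            continue
        if p.noise > 0 and p.snr < params.min_snr:
            continue
        if p.height < params.min_rel_height * by_roi[id(p.roi)]:
            continue
        kept.append(p)
    return kept


def detect_and_integrate(
    roi: ROI, params: PeakDetectParams, subtract: float = 0.0
) -> list[Peak]:
    """Full per-ROI pipeline: smooth, estimate noise, detect, correct
    borders, integrate."""
    smoothed = smooth_roi(roi, min(params.smooth_window, len(roi) - (1 - len(roi) % 2)))
    noise = estimate_noise(roi, smoothed)
    provisional = detect_peaks(roi, params, smoothed=smoothed, noise=noise)
    out = []
    for k, p in enumerate(provisional):
        # neighbouring provisional bounds sit at the shared valley, so no
        # border (nor the integration apex) can cross into the next peak
        left_lim = provisional[k - 1].right_index if k > 0 else None
        right_lim = (
            provisional[k + 1].left_index if k < len(provisional) - 1 else None
        )
        correct_borders(
            roi,
            smoothed,
            p,
            noise,
            friction=params.friction,
            sd_window=params.sd_window,
            sd_k=params.sd_k,
            left_limit=left_lim,
            right_limit=right_lim,
        )
        out.append(integrate_peak(roi, p, subtract=subtract))
    return out
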