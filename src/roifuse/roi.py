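"""Region-of-interest (ROI) extraction and low-level trace filters.

An ROI is a mass trace: centroids from consecutive scans that share an m/z
within a tolerance and exceed an intensity threshold. ROIs are grown
scan-by-scan with nearest-m/z assignment; the consensus m/z is a running
intensity-weighted mean. No synthetic noise points are ever padded into a
trace — gaps stay gaps — so peak tips are not distorted by artificial
points and replicate retention/migration times stay comparable.

Low-level filters (isotope, adduct, contaminant) remove whole traces that
would otherwise inflate the feature list with redundant or false-positive
entries. Baseline drift across the separation is removed by interpolation
through moving-window minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .raw_io import RunData

ISOTOPE_SPACING = 1.00336  # Da, 13C-12C; charges 1-2 cover the 100-700 m/z range

#: Default adduct mass offsets (Da) relative to the protonated/deprotonated ion.
DEFAULT_ADDUCTS = {
    "positive": {"Na-H": 21.9819, "K-H": 37.9559, "NH4": 17.0265},
    "negative": {"Cl": 34.9689, "formate": 46.0055},
}


@dataclass(frozen=True)
class ROIParams:
    """ROI search parameters.

    intensity_threshold : counts — centroid admission cutoff; a robust
        choice is 5-10 % of the lowest base-peak trace maximum over the
        group's runs (see :func:`recommend_threshold`).
    mz_error : Da — admission tolerance around the running consensus m/z
        (0.01 Da corresponds to 10 ppm at m/z 1000).
    min_roi_size : scans — minimum number of MS1 scans in which the m/z
        must be present; must stay below the expected peak width.
    max_gap : scans — consecutive missing scans tolerated before a trace
        is closed.
    """

    intensity_threshold: float = 5e4
    mz_error: float = 0.01
    min_roi_size: int = 5
    max_gap: int = 2

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if self.mz_error <= 0:
            raise ValueError("mz_error must be > 0")
        if self.min_roi_size < 1:
            raise ValueError("min_roi_size must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class ROI:
    """One mass trace."""

    mz_center: float
    times: np.ndarray
    intensities: np.ndarray
    scan_indices: np.ndarray
    mz_values: np.ndarray = field(default=None)  # per-member m/z
    group_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.scan_indices = np.asarray(self.scan_indices, dtype=int)
        if self.mz_values is None:
            self.mz_values = np.full_like(self.times, self.mz_center)
        else:
            self.mz_values = np.asarray(self.mz_values, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def mz_spread(self) -> float:
        return float(self.mz_values.max() - self.mz_values.min()) if len(self) else 0.0

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensities))

    @property
    def apex_time(self) -> float:
        return float(self.times[self.apex_index])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max())


class _OpenROI:
    __slots__ = ("mz_center", "weight", "times", "intensities", "scan_indices", "mzs", "last_scan")

    def __init__(self, mz: float, inten: float, time: float, scan: int) -> None:
        self.mz_center = mz
        self.weight = inten
        self.times = [time]
        self.intensities = [inten]
        self.scan_indices = [scan]
        self.mzs = [mz]
        self.last_scan = scan

    def add(self, mz: float, inten: float, time: float, scan: int) -> None:
        # running intensity-weighted mean keeps the consensus near the
        # strong (well-determined) centroids
        self.weight += inten
        self.mz_center += (mz - self.mz_center) * inten / self.weight
        self.times.append(time)
        self.intensities.append(inten)
        self.scan_indices.append(scan)
        self.mzs.append(mz)
        self.last_scan = scan


def build_rois(run: RunData, params: ROIParams) -> list[ROI]:
    """Grow ROIs scan-by-scan from centroids above the intensity threshold.

    Each admitted centroid joins at most one ROI (the nearest open trace in
    m/z within ``mz_error``; intensity-descending order breaks conflicts in
    favour of stronger centroids). Traces silent for more than ``max_gap``
    scans are closed; closed traces shorter than ``min_roi_size`` are
    discarded. Missing scans inside a kept ROI remain gaps — no values are
    fabricated.
    """
    open_rois: list[_OpenROI] = []
    finished: list[ROI] = []

    def finalize(o: _OpenROI) -> None:
        if len(o.times) >= params.min_roi_size:
            finished.append(
                ROI(
                    mz_center=o.mz_center,
                    times=np.array(o.times),
                    intensities=np.array(o.intensities),
                    scan_indices=np.array(o.scan_indices),
                    mz_values=np.array(o.mzs),
                    group_id=run.group_id,
                    replicate_id=run.replicate_id,
                )
            )

    for scan_idx, scan in enumerate(run.scans):
        still_open: list[_OpenROI] = []
        for o in open_rois:
            if scan_idx - o.last_scan > params.max_gap + 1:
                finalize(o)
            else:
                still_open.append(o)
        open_rois = still_open

        mask = scan.intensity >= params.intensity_threshold
        mzs = scan.mz[mask]
        intens = scan.intensity[mask]
        if mzs.size == 0:
            continue
        # strongest centroids claim their nearest trace first; makes the
        # result independent of within-scan centroid ordering
        order = np.lexsort((mzs, -intens))
        centers = np.array([o.mz_center for o in open_rois])
        claimed: set[int] = set()
        for ci in order:
            mz, inten = float(mzs[ci]), float(intens[ci])
            target = None
            if centers.size:
                dists = np.abs(centers - mz)
                for ri in np.argsort(dists, kind="stable"):
                    if dists[ri] > params.mz_error:
                        break
                    if ri not in claimed and open_rois[ri].last_scan != scan_idx:
                        target = int(ri)
                        break
            if target is None:
                open_rois.append(_OpenROI(mz, inten, scan.time, scan_idx))
            else:
                claimed.add(target)
                open_rois[target].add(mz, inten, scan.time, scan_idx)
    for o in open_rois:
        finalize(o)
    finished.sort(key=lambda r: (r.mz_center, r.times[0]))
    return finished


def recommend_threshold(runs: Sequence[RunData], fraction: float = 0.05) -> float:
    """Recommended ROI intensity threshold: ``fraction`` of the lowest
    base-peak chromatogram/electropherogram maximum over the given runs
    (5-10 % is a robust universal choice)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not runs:
        raise ValueError("at least one run required")
    lowest_bpc_max = min(float(r.base_peak_trace().max()) for r in runs)
    return fraction * lowest_bpc_max


def correct_baseline(roi: ROI, window: int = 50) -> ROI:
    """Subtract a drifting baseline estimated by linear interpolation
    through minima of consecutive ``window``-scan blocks; negatives are
    clipped to zero. ROIs shorter than the window lose their global
    minimum instead."""
    if window < 3:
        raise ValueError("window must be >= 3")
    y = roi.intensities
    n = len(y)
    if n == 0:
        return roi
    if n < window:
        baseline = np.full(n, y.min())
    else:
        anchors_x, anchors_y = [], []
        for start in range(0, n, window):
            block = y[start : start + window]
            j = start + int(np.argmin(block))
            anchors_x.append(j)
            anchors_y.append(y[j])
        if anchors_x[0] != 0:
            anchors_x.insert(0, 0)
            anchors_y.insert(0, anchors_y[0])
        if anchors_x[-1] != n - 1:
            anchors_x.append(n - 1)
            anchors_y.append(anchors_y[-1])
        baseline = np.interp(np.arange(n), anchors_x, anchors_y)
    corrected = np.clip(y - baseline, 0.0, None)
    return ROI(
        mz_center=roi.mz_center,
        times=roi.times,
        intensities=corrected,
        scan_indices=roi.scan_indices,
        mz_values=roi.mz_values,
        group_id=roi.group_id,
        replicate_id=roi.replicate_id,
    )


def _trace_correlation(a: ROI, b: ROI) -> float:
    """Pearson correlation of two traces on their shared scan range
    (absent scans treated as zero)."""
    lo = min(a.scan_indices.min(), b.scan_indices.min())
    hi = max(a.scan_indices.max(), b.scan_indices.max())
    xa = np.zeros(hi - lo + 1)
    xb = np.zeros(hi - lo + 1)
    xa[a.scan_indices - lo] = a.intensities
    xb[b.scan_indices - lo] = b.intensities
    if xa.std() == 0 or xb.std() == 0:
        return 0.0
    return float(np.corrcoef(xa, xb)[0, 1])


def _peak_width_scans(roi: ROI) -> float:
    """Rough full width at half maximum, in time units."""
    y = roi.intensities
    half = y.max() / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size < 2:
        return max(roi.times[-1] - roi.times[0], 1e-6)
    return max(float(roi.times[above[-1]] - roi.times[above[0]]), 1e-6)


def _coelute(a: ROI, b: ROI) -> bool:
    width = max(_peak_width_scans(a), _peak_width_scans(b))
    return abs(a.apex_time - b.apex_time) <= width


def filter_isotopes(
    rois: Sequence[ROI],
    mz_error: float = 0.01,
    corr_min: float = 0.8,
    charges: Sequence[int] = (1, 2),
) -> tuple[list[ROI], list[ROI]]:
    """Remove +1 isotopologue traces.

    A trace is flagged as an isotope when a co-eluting trace exists at
    m/z − 1.00336/z (z in ``charges``) with greater apex intensity, apex
    times within a peak width, and trace correlation >= ``corr_min``.
    """
    rois = list(rois)
    removed_idx: set[int] = set()
    by_mz = sorted(range(len(rois)), key=lambda i: rois[i].mz_center)
    mz_arr = np.array([rois[i].mz_center for i in by_mz])
    for pos, i in enumerate(by_mz):
        cand = rois[i]
        for z in charges:
            target = cand.mz_center - ISOTOPE_SPACING / z
            lo = np.searchsorted(mz_arr, target - mz_error)
            hi = np.searchsorted(mz_arr, target + mz_error, side="right")
            for q in range(lo, hi):
                j = by_mz[q]
                if j == i or j in removed_idx:
                    continue
                mono = rois[j]
                if (
                    mono.apex_intensity > cand.apex_intensity
                    and _coelute(mono, cand)
                    and _trace_correlation(mono, cand) >= corr_min
                ):
                    removed_idx.add(i)
                    break
            if i in removed_idx:
                break
    kept = [r for k, r in enumerate(rois) if k not in removed_idx]
    removed = [r for k, r in enumerate(rois) if k in removed_idx]
    return kept, removed


def filter_adducts(
    rois: Sequence[ROI],
    polarity: str,
    adduct_table: dict[str, float] | None = None,
    mz_error: float = 0.01,
) -> tuple[list[ROI], list[ROI]]:
    """Remove co-eluting adduct traces (m/z = kept m/z + configured offset).

    The default offsets cover the common ESI+ (Na-H, K-H, NH4) and ESI-
    (Cl, formate) adducts relative to [M+H]+ / [M-H]-; pass a custom table
    to override. The weaker trace of a co-eluting pair is treated as the
    adduct.
    """
    if adduct_table is None:
        adduct_table = DEFAULT_ADDUCTS.get(polarity, {})
    rois = list(rois)
    if not adduct_table:
        return rois, []
    removed_idx: set[int] = set()
    for i, cand in enumerate(rois):
        for j, base in enumerate(rois):
            if i == j or j in removed_idx:
                continue
            for offset in adduct_table.values():
                if (
                    abs(cand.mz_center - (base.mz_center + offset)) <= mz_error
                    and base.apex_intensity > cand.apex_intensity
                    and _coelute(base, cand)
                ):
                    removed_idx.add(i)
                    break
            if i in removed_idx:
                break
    kept = [r for k, r in enumerate(rois) if k not in removed_idx]
    removed = [r for k, r in enumerate(rois) if k in removed_idx]
    return kept, removed


def filter_contaminants(
    rois: Sequence[ROI],
    contaminant_mzs: Sequence[float],
    mz_error: float = 0.01,
    run_fraction: float = 0.8,
    n_scans_total: int | None = None,
) -> tuple[list[ROI], list[ROI]]:
    """Remove traces that match a contaminant m/z and persist over more
    than ``run_fraction`` of the run (background ions are present
    throughout the separation, real analytes are not)."""
    rois = list(rois)
    if not len(contaminant_mzs):
        return rois, []
    cont = np.asarray(sorted(contaminant_mzs), dtype=float)
    kept: list[ROI] = []
    removed: list[ROI] = []
    for r in rois:
        idx = np.searchsorted(cont, r.mz_center)
        near = min(
            (abs(cont[k] - r.mz_center) for k in (idx - 1, idx) if 0 <= k < cont.size),
            default=np.inf,
        )
        total = n_scans_total if n_scans_total else (int(r.scan_indices.max()) + 1)
        persistence = len(r) / max(total, 1)
        if near <= mz_error and persistence > run_fraction:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed
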