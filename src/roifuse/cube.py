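"""Replicate alignment, feature-cube construction, occurrence filtering,
scaling, transformation, and normalization for one sample group.

Integrated peaks from each replicate are matched across replicates by m/z
and time tolerance and sorted into an N x M x S array: N consensus
retention/migration times (rows), M consensus m/z values (columns), S
replicates (layers). Absent detections are stored as zero, which carries
through to the presence/absence ("knock out" / "induced") semantics of the
downstream statistics.

Migration-time shifts between CE replicates can reach a minute, so a
per-replicate global time shift (median landmark offset against a
reference replicate) is applied before matching; HILIC retention times are
stable to ~0.1 min and usually need no alignment. A mass alignment against
the cross-replicate consensus is available for instruments with drifting
mass calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

ScaleMethod = Literal["center", "auto", "pareto", "vast", "range", "level"]


@dataclass(frozen=True)
class AlignmentConfig:
    align_time: bool = False
    align_mass: bool = False
    mass_quantile: float = 0.95
    time_tolerance: float = 0.5
    mz_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.time_tolerance <= 0 or self.mz_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0.0 < self.mass_quantile < 1.0:
            raise ValueError("mass_quantile must be in (0, 1)")


@dataclass
class SimpleFeature:
    """One replicate-level detection: (m/z, time, area, height)."""

    mz: float
    time: float
    area: float
    height: float
    replicate_id: str = ""


@dataclass
class Feature:
    """A group-level feature: matched detections across the S replicates."""

    mz: float
    time: float
    areas: np.ndarray
    heights: np.ndarray
    group_id: str = ""

    @property
    def occurrence(self) -> int:
        return int(np.count_nonzero(self.areas))


@dataclass
class FeatureCube:
    """values[n, m, s]: area of the feature at time_axis[n], mz_axis[m] in
    replicate replicate_axis[s]; zero where not detected."""

    values: np.ndarray
    time_axis: np.ndarray
    mz_axis: np.ndarray
    replicate_axis: list[str]
    group_id: str = ""

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]


def align_time(
    features_by_rep: dict[str, list[SimpleFeature]],
    reference: str,
    tolerance: float = 0.5,
    mz_tolerance: float = 0.01,
) -> tuple[dict[str, list[SimpleFeature]], dict[str, float]]:
    """Global time shift per replicate from landmark features.

    Features of each non-reference replicate are matched to the reference
    by m/z and time tolerance; the median time offset over the landmarks
    is subtracted. Fewer than 3 landmarks leaves the replicate unshifted.
    Returns the shifted feature dict and the applied shifts.
    """
    if reference not in features_by_rep:
        raise ValueError(f"reference replicate {reference!r} not present")
    ref = sorted(features_by_rep[reference], key=lambda f: f.mz)
    ref_mz = np.array([f.mz for f in ref])
    shifts: dict[str, float] = {}
    out: dict[str, list[SimpleFeature]] = {}
    for rep, feats in features_by_rep.items():
        if rep == reference:
            shifts[rep] = 0.0
            out[rep] = list(feats)
            continue
        deltas = []
        for f in feats:
            lo = np.searchsorted(ref_mz, f.mz - mz_tolerance)
            hi = np.searchsorted(ref_mz, f.mz + mz_tolerance, side="right")
            best = None
            for j in range(lo, hi):
                dt = f.time - ref[j].time
                if abs(dt) <= tolerance and (best is None or abs(dt) < abs(best)):
                    best = dt
            if best is not None:
                deltas.append(best)
        if len(deltas) < 3:
            warnings.warn(f"replicate {rep}: <3 landmarks, no time shift applied")
            shifts[rep] = 0.0
            out[rep] = list(feats)
        else:
            shift = -float(np.median(deltas))
            shifts[rep] = shift
            out[rep] = [replace(f, time=f.time + shift) for f in feats]
    return out, shifts


def align_mass(
    features_by_rep: dict[str, list[SimpleFeature]],
    quantile: float = 0.95,
    mz_tolerance: float = 0.01,
    time_tolerance: float = 0.5,
) -> tuple[dict[str, list[SimpleFeature]], dict[str, float]]:
    """Shift each replicate's measured masses toward the cross-replicate
    consensus, summarizing the per-replicate mass-offset distribution at
    the given quantile (the most common masses dominate)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    pooled = _cluster_features(features_by_rep, mz_tolerance, time_tolerance)
    shifts: dict[str, float] = {}
    out: dict[str, list[SimpleFeature]] = {}
    for rep, feats in features_by_rep.items():
        deltas = []
        for cluster in pooled:
            members = {f.replicate_id: f for f in cluster}
            if rep in members and len(cluster) >= 2:
                consensus = float(np.median([f.mz for f in cluster]))
                deltas.append(members[rep].mz - consensus)
        if len(deltas) < 3:
            shifts[rep] = 0.0
            out[rep] = list(feats)
        else:
            shift = -float(np.quantile(deltas, quantile))
            shifts[rep] = shift
            out[rep] = [replace(f, mz=f.mz + shift) for f in feats]
    return out, shifts


def _cluster_features(
    features_by_rep: dict[str, list[SimpleFeature]],
    mz_tolerance: float,
    time_tolerance: float,
) -> list[list[SimpleFeature]]:
    """Greedy nearest-neighbour clustering across replicates, m/z first.

    All detections are pooled and processed in a deterministic (mz, time,
    replicate) order, so the result does not depend on file order. A
    cluster accepts at most one detection per replicate; a second
    detection from an already-present replicate opens a new cluster.
    """
    pool = []
    for rep in sorted(features_by_rep):
        for f in features_by_rep[rep]:
            if not f.replicate_id:
                f = replace(f, replicate_id=rep)
            pool.append(f)
    pool.sort(key=lambda f: (f.mz, f.time, f.replicate_id))
    clusters: list[dict] = []
    for f in pool:
        best, best_key = None, None
        for c in clusters:
            dmz = abs(f.mz - c["mz"])
            if dmz > mz_tolerance:
                continue
            dt = abs(f.time - c["time"])
            if dt > time_tolerance:
                continue
            if f.replicate_id in c["reps"]:
                continue
            key = (dmz, dt)
            if best_key is None or key < best_key:
                best, best_key = c, key
        if best is None:
            clusters.append(
                {"mz": f.mz, "time": f.time, "reps": {f.replicate_id}, "members": [f]}
            )
        else:
            best["members"].append(f)
            best["reps"].add(f.replicate_id)
            best["mz"] = float(np.mean([m.mz for m in best["members"]]))
            best["time"] = float(np.mean([m.time for m in best["members"]]))
    return [c["members"] for c in clusters]


def build_cube(
    features_by_rep: dict[str, list[SimpleFeature]],
    mz_tolerance: float = 0.01,
    time_tolerance: float = 0.5,
    group_id: str = "",
) -> tuple[FeatureCube, list[Feature]]:
    """Match features across replicates and sort areas into the
    N x M x S cube. Replicates without a detection contribute zero."""
    reps = sorted(features_by_rep)
    rep_index = {r: s for s, r in enumerate(reps)}
    S = len(reps)
    clusters = _cluster_features(features_by_rep, mz_tolerance, time_tolerance)
    feats: list[Feature] = []
    for members in clusters:
        areas = np.zeros(S)
        heights = np.zeros(S)
        for m in members:
            s = rep_index[m.replicate_id]
            areas[s] = m.area
            heights[s] = m.height
        feats.append(
            Feature(
                mz=float(np.mean([m.mz for m in members])),
                time=float(np.mean([m.time for m in members])),
                areas=areas,
                heights=heights,
                group_id=group_id,
            )
        )
    feats.sort(key=lambda f: (f.mz, f.time))
    times = np.array(sorted({round(f.time, 9) for f in feats}))
    mzs = np.array(sorted({round(f.mz, 9) for f in feats}))
    values = np.zeros((len(times), len(mzs), S))
    for f in feats:
        n = int(np.searchsorted(times, round(f.time, 9)))
        m = int(np.searchsorted(mzs, round(f.mz, 9)))
        values[n, m, :] += f.areas
    cube = FeatureCube(
        values=values,
        time_axis=times,
        mz_axis=mzs,
        replicate_axis=reps,
        group_id=group_id,
    )
    return cube, feats


def occurrence_min_count(S: int, rel_occurrence: float) -> int:
    """Minimum number of detections implied by a relative occurrence.

    50 % of 6 replicates requires 3 detections; 0 % still requires 1 (a
    feature must exist somewhere); 100 % requires all 6.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not 0.0 <= rel_occurrence <= 1.0:
        raise ValueError("rel_occurrence must be in [0, 1]")
    return max(1, int(np.ceil(rel_occurrence * S - 1e-12)))


def filter_occurrence(features: Sequence[Feature], rel_occurrence: float) -> list[Feature]:
    """Keep features detected in at least the required replicate count."""
    if not features:
        return []
    S = len(features[0].areas)
    k = occurrence_min_count(S, rel_occurrence)
    return [f for f in features if f.occurrence >= k]


def scale(cube: FeatureCube, method: ScaleMethod) -> FeatureCube:
    """Scale each feature across its S replicate layers.

    Formulations follow the standard metabolomics scaling family:
    center: x - mean; auto: (x - mean)/sd; pareto: (x - mean)/sqrt(sd);
    vast: ((x - mean)/sd) * (mean/sd); range: (x - mean)/(max - min);
    level: (x - mean)/mean. Features with a zero divisor are left
    centered only.
    """
    v = cube.values.astype(float).copy()
    mean = v.mean(axis=2, keepdims=True)
    centered = v - mean
    if method == "center":
        out = centered
    else:
        sd = v.std(axis=2, ddof=1, keepdims=True)
        if method == "auto":
            div = sd
        elif method == "pareto":
            div = np.sqrt(sd)
        elif method == "vast":
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(sd > 0, mean / sd, 0.0)
            div = np.where(factor != 0, sd / factor, 0.0)
        elif method == "range":
            div = v.max(axis=2, keepdims=True) - v.min(axis=2, keepdims=True)
        elif method == "level":
            div = mean
        else:
            raise ValueError(f"unknown scaling method {method!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(div != 0, centered / div, centered)
    return FeatureCube(
        values=out,
        time_axis=cube.time_axis,
        mz_axis=cube.mz_axis,
        replicate_axis=list(cube.replicate_axis),
        group_id=cube.group_id,
    )


def transform(
    cube: FeatureCube,
    kind: Literal["log", "power"],
    param: float = 10.0,
    offset: float | None = None,
) -> FeatureCube:
    """Elementwise log (base ``param``) or power (exponent ``param``)
    transform. For log, zeros are lifted by ``offset`` (default: the
    smallest nonzero value in the cube)."""
    v = cube.values.astype(float)
    if kind == "log":
        if offset is None:
            nz = v[v > 0]
            offset = float(nz.min()) if nz.size and (v <= 0).any() else 0.0
        out = np.log(v + offset) / np.log(param)
    elif kind == "power":
        out = np.power(v, param)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return FeatureCube(out, cube.time_axis, cube.mz_axis, list(cube.replicate_axis), cube.group_id)


def normalize(
    cube: FeatureCube,
    factors: Sequence[float] | dict[str, float] | None = None,
    internal_standard_areas: np.ndarray | None = None,
) -> FeatureCube:
    """Divide each replicate layer by its normalization factor.

    Factors may be given explicitly (per replicate, e.g. cell counts) or
    derived from internal standards: with ``internal_standard_areas``
    (standards x S), each replicate's factor is the mean standard area in
    that replicate — analyte/standard ratios then cancel instrument
    response drift.
    """
    S = cube.n_replicates
    if internal_standard_areas is not None:
        arr = np.atleast_2d(np.asarray(internal_standard_areas, dtype=float))
        factors_v = arr.mean(axis=0)
    elif isinstance(factors, dict):
        factors_v = np.array([factors[r] for r in cube.replicate_axis], dtype=float)
    elif factors is not None:
        factors_v = np.asarray(factors, dtype=float)
    else:
        raise ValueError("provide factors or internal_standard_areas")
    if factors_v.shape != (S,):
        raise ValueError(f"need {S} factors, got {factors_v.shape}")
    if np.any(factors_v <= 0):
        raise ValueError("normalization factors must be > 0")
    out = cube.values / factors_v[None, None, :]
    return FeatureCube(out, cube.time_axis, cube.mz_axis, list(cube.replicate_axis), cube.group_id)


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    """Group feature table: mz, time, occurrence, per-replicate areas and
    heights."""
    if not features:
        return pd.DataFrame(columns=["mz", "time", "occurrence"])
    S = len(features[0].areas)
    rows = []
    for f in features:
        row = {"mz": f.mz, "time": f.time, "occurrence": f.occurrence, "group": f.group_id}
        for s in range(S):
            row[f"area_rep{s + 1}"] = f.areas[s]
            row[f"height_rep{s + 1}"] = f.heights[s]
        rows.append(row)
    return pd.DataFrame(rows)
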