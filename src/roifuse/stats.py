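"""Group statistics on the augmented feature table.

Fold changes (treated mean over reference mean) are classified into
regulation classes: FC < 0.50 down, 0.50 <= FC <= 2.00 stable, FC > 2.00
up; features present only in the reference are "knock out", features
appearing only under treatment are "induced". P-values come from a
two-sample Welch t-test (optionally on log-transformed areas) and are
adjusted by the Benjamini-Hochberg step-up procedure. Volcano, PCA, and
heatmap data are exported as plain arrays/frames for external plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .cube import occurrence_min_count

Regulation = Literal["down", "stable", "up", "knock_out", "induced", "not_detected"]


@dataclass
class RegulationResult:
    feature_name: str
    fc: float
    regulation: str
    p_value: float = np.nan
    q_value: float = np.nan
    boundary_flag: bool = False  # fc exactly on the 2.00 stable/up boundary


def classify_regulation(
    ref_areas: np.ndarray,
    treat_areas: np.ndarray,
    presence_rel: float = 0.5,
    feature_name: str = "",
) -> RegulationResult:
    """Classify one feature's regulation from per-replicate areas.

    Presence on a side requires detections (nonzero areas) in at least the
    occurrence fraction ``presence_rel`` of that side's replicates.
    Present only in the reference -> knock_out; only under treatment ->
    induced; both present -> fold change mean(treat)/mean(ref) against the
    0.50 / 2.00 thresholds (2.00 exactly is stable, flagged); neither ->
    not_detected. Partial presence below the threshold on both sides
    falls back to the fold-change classification with zeros included.
    """
    ref = np.asarray(ref_areas, dtype=float)
    treat = np.asarray(treat_areas, dtype=float)
    ref_n = int(np.count_nonzero(ref))
    treat_n = int(np.count_nonzero(treat))
    ref_present = ref_n >= occurrence_min_count(len(ref), presence_rel)
    treat_present = treat_n >= occurrence_min_count(len(treat), presence_rel)
    if ref_present and treat_n == 0:
        return RegulationResult(feature_name, 0.0, "knock_out")
    if treat_present and ref_n == 0:
        return RegulationResult(feature_name, np.inf, "induced")
    if ref_n == 0 and treat_n == 0:
        return RegulationResult(feature_name, np.nan, "not_detected")
    ref_mean = ref.mean()
    if ref_mean == 0:
        return RegulationResult(feature_name, np.inf, "induced")
    fc = float(treat.mean() / ref_mean)
    if fc < 0.50:
        reg = "down"
    elif fc <= 2.00:
        reg = "stable"
    else:
        reg = "up"
    return RegulationResult(feature_name, fc, reg, boundary_flag=(fc == 2.00))


def welch_p(ref_areas: np.ndarray, treat_areas: np.ndarray, log: bool = True) -> float:
    """Two-sample Welch t-test p-value, by default on log-transformed
    areas (zeros lifted by the smallest nonzero value)."""
    a = np.asarray(ref_areas, dtype=float)
    b = np.asarray(treat_areas, dtype=float)
    if log:
        pooled = np.concatenate([a, b])
        nz = pooled[pooled > 0]
        offset = float(nz.min()) if nz.size else 1.0
        a = np.log10(a + offset)
        b = np.log10(b + offset)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def regulation_table(
    table: pd.DataFrame,
    ref_group: str,
    treat_group: str,
    presence_rel: float = 0.5,
    log_areas: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Regulation classes, Welch p and BH q for matched features of a
    reference/treated group pair in an augmented table.

    Rows of the two groups are paired via ``match_id``; unmatched rows of
    either group are classified against an all-zero partner (knock_out /
    induced candidates).
    """
    area_cols = [c for c in table.columns if c.startswith("area_rep")]
    ref_rows = table[table["group"] == ref_group]
    treat_rows = table[table["group"] == treat_group]
    if not len(ref_rows) and not len(treat_rows):
        raise ValueError("neither group present in table")
    treat_by_match = {
        int(m): i for i, m in treat_rows["match_id"].items() if pd.notna(m)
    }
    rows = []
    used_treat: set = set()
    for i, r in ref_rows.iterrows():
        ref_a = r[area_cols].to_numpy(dtype=float)
        j = treat_by_match.get(int(r["match_id"])) if pd.notna(r["match_id"]) else None
        if j is not None:
            used_treat.add(j)
            treat_a = treat_rows.loc[j, area_cols].to_numpy(dtype=float)
        else:
            treat_a = np.zeros_like(ref_a)
        rows.append((r["name"], ref_a, treat_a))
    for j, r in treat_rows.iterrows():
        if j in used_treat:
            continue
        treat_a = r[area_cols].to_numpy(dtype=float)
        rows.append((r["name"], np.zeros_like(treat_a), treat_a))
    out = []
    for nm, ref_a, treat_a in rows:
        res = classify_regulation(ref_a, treat_a, presence_rel, feature_name=nm)
        if res.regulation in ("down", "stable", "up"):
            res.p_value = welch_p(ref_a, treat_a, log=log_areas)
        out.append(res)
    df = pd.DataFrame(
        {
            "name": [r.feature_name for r in out],
            "fc": [r.fc for r in out],
            "regulation": [r.regulation for r in out],
            "p_value": [r.p_value for r in out],
        }
    )
    tested = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(df.loc[tested, "p_value"].to_numpy())
    df["q_value"] = q
    df["significant"] = (df["q_value"] < fdr).fillna(False)
    return df


def volcano_data(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Per-feature (log2 FC, -log10 p, significance) for volcano plots;
    zero p-values are clipped to the smallest positive float."""
    df = results.copy()
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore"):
        df["log2_fc"] = np.log2(df["fc"].replace(0, np.nan))
    df["neg_log10_p"] = -np.log10(np.clip(df["p_value"], tiny, None))
    df["significant"] = (df["q_value"] < fdr).fillna(False)
    return df[["name", "log2_fc", "neg_log10_p", "significant"]]


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance_fraction: np.ndarray


def pca(matrix: np.ndarray, n_components: int = 2) -> PcaResult:
    """PCA of a samples x features matrix (columns mean-centred).

    Scores have zero column means; explained fractions are
    non-increasing and sum to 1 at full rank. ``n_components`` above the
    matrix rank is truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = min(n_components, rank, min(X.shape))
    if k < n_components:
        import warnings

        warnings.warn(f"n_components truncated to rank {k}")
    model = PCA(n_components=k)
    scores = model.fit_transform(X)
    return PcaResult(
        scores=scores,
        loadings=model.components_.T,
        explained_variance_fraction=model.explained_variance_ratio_,
    )


def heatmap_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-ordered matrix for heatmaps: hierarchical clustering with
    average linkage on Euclidean distances; returns (reordered matrix,
    leaf order)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        order = np.arange(X.shape[0])
        return X, order
    Z = average(pdist(X))
    order = leaves_list(Z)
    return X[order], order
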