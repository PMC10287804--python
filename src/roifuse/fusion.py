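"""Mid-level augmentation of per-group feature cubes, feature naming,
cross-group matching, target/suspect annotation, and coverage counting.

Mid-level fusion keeps each separation method's block intact: every group
is feature-extracted, filtered, and scaled on its own, and the resulting
feature lists are concatenated into one augmented table. Because
retention and migration times are not comparable across methods, features
from different groups are linked only by m/z (within tolerance) together
with an equal number of detections within each group; time never enters
the cross-group match.

Feature names follow the "m/z @time, group" scheme, which folds the m/z
and time dimensions into a single labelled axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

log = logging.getLogger(__name__)

PROTON_EXCHANGE_MASS = 1.00783  # Da, hydrogen atom; electron mass neglected

FLAGS = ("detected", "failed", "comigrating", "absent")

#: Method identifiers of the reference detection-flag fixture.
FIXTURE_METHODS = ("hilic_neg", "ce_alkaline", "ce_acidic", "hilic_pos", "ce_cation")
NEGATIVE_METHODS = ("hilic_neg", "ce_alkaline", "ce_acidic")
POSITIVE_METHODS = ("hilic_pos", "ce_cation")
INTERNAL_STANDARD_IDS = frozenset({17, 18, 19, 20})


@dataclass(frozen=True)
class ReferenceEntry:
    """One analyte x method entry of the reference standard table."""

    analyte_id: int
    name: str
    method_id: str
    flag: str
    expected_mz: float
    expected_time: float | None = None

    def __post_init__(self) -> None:
        if self.flag not in FLAGS:
            raise ValueError(f"unknown flag {self.flag!r}")


def adduct_mz(monoisotopic_mass: float, adduct: str) -> float:
    """[M+H]+ or [M-H]- m/z from a neutral monoisotopic mass.

    Uses the hydrogen-atom mass convention (1.00783 Da, electron mass
    neglected), which reproduces the reference standard table to four
    decimals.
    """
    if monoisotopic_mass <= 0:
        raise ValueError("mass must be > 0")
    if adduct == "plusH":
        return monoisotopic_mass + PROTON_EXCHANGE_MASS
    if adduct == "minusH":
        return monoisotopic_mass - PROTON_EXCHANGE_MASS
    raise ValueError(f"unknown adduct {adduct!r}")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a molecular formula (e.g. serine C3H7NO3)."""
    return float(_pmass.calculate_mass(formula=formula))


def mz_tolerance_ppm(mz_error_da: float, at_mz: float) -> float:
    """Convert an absolute m/z tolerance to ppm at a given m/z
    (0.01 Da at m/z 1000 is 10 ppm)."""
    if at_mz <= 0:
        raise ValueError("m/z must be > 0")
    return mz_error_da / at_mz * 1e6


def name_feature(
    mz: float,
    time: float,
    group_id: str,
    mz_decimals: int = 4,
    time_decimals: int = 1,
) -> str:
    """Feature name "m/z @time, group" at the configured rounding."""
    return f"{mz:.{mz_decimals}f} @{time:.{time_decimals}f}, {group_id}"


def augment(
    feature_frames: Sequence[pd.DataFrame],
    mz_decimals: int = 4,
    time_decimals: int = 1,
) -> pd.DataFrame:
    """Concatenate per-group feature tables into one augmented table.

    Each input frame must carry mz, time, occurrence, group columns (plus
    per-replicate areas). Rows are named but never merged across groups:
    group blocks stay intact.
    """
    groups = [str(df["group"].iloc[0]) for df in feature_frames if len(df)]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group_id among cubes")
    parts = []
    for df in feature_frames:
        df = df.copy()
        if len(df):
            df["name"] = [
                name_feature(r.mz, r.time, r.group, mz_decimals, time_decimals)
                for r in df.itertuples()
            ]
        else:
            df["name"] = pd.Series(dtype=str)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if "match_id" not in out.columns:
        out["match_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["annotations"] = [[] for _ in range(len(out))]
    return out


def match_across_groups(table: pd.DataFrame, mz_tolerance: float = 0.01) -> pd.DataFrame:
    """Link features of different groups that share m/z (within tolerance)
    and have the same number of detections within their groups.

    Retention/migration time is deliberately ignored: the methods'
    separation axes are not comparable. Ambiguous multi-way candidates
    are resolved toward the smallest m/z difference; the rest stay
    unlinked and are logged.
    """
    table = table.copy()
    match_id = np.full(len(table), -1, dtype=int)
    order = np.argsort(table["mz"].to_numpy(), kind="stable")
    mz = table["mz"].to_numpy()
    occ = table["occurrence"].to_numpy()
    grp = table["group"].to_numpy()
    next_id = 0
    for pos, i in enumerate(order):
        for pos2 in range(pos + 1, len(order)):
            j = order[pos2]
            if mz[j] - mz[i] > mz_tolerance:
                break
            if grp[i] == grp[j] or occ[i] != occ[j]:
                continue
            if match_id[i] >= 0 and match_id[j] >= 0:
                if match_id[i] != match_id[j]:
                    log.info("ambiguous multi-way match at m/z %.4f left unlinked", mz[j])
                continue
            if match_id[i] >= 0:
                members = np.nonzero(match_id == match_id[i])[0]
                if any(grp[m] == grp[j] for m in members):
                    continue
                match_id[j] = match_id[i]
            elif match_id[j] >= 0:
                members = np.nonzero(match_id == match_id[j])[0]
                if any(grp[m] == grp[i] for m in members):
                    continue
                match_id[i] = match_id[j]
            else:
                match_id[i] = match_id[j] = next_id
                next_id += 1
    table["match_id"] = pd.array(
        [m if m >= 0 else pd.NA for m in match_id], dtype="Int64"
    )
    return table


def annotate_targets(
    table: pd.DataFrame,
    references: Sequence[ReferenceEntry],
    mz_tol: float = 0.01,
    time_tol: float = 0.5,
    group_method: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Label rows matching a reference analyte by m/z and RT/MT.

    ``group_method`` maps each group id to a method id so that each row is
    compared against the reference time measured with its own method.
    References without a time for that method fall back to an m/z-only
    match, labelled low-confidence.
    """
    table = table.copy()
    if "annotations" not in table.columns:
        table["annotations"] = [[] for _ in range(len(table))]
    by_method: dict[str, list[ReferenceEntry]] = {}
    for ref in references:
        by_method.setdefault(ref.method_id, []).append(ref)
    for idx, row in table.iterrows():
        method = (group_method or {}).get(row["group"], row["group"])
        for ref in by_method.get(method, []):
            if abs(row["mz"] - ref.expected_mz) > mz_tol:
                continue
            if ref.expected_time is None:
                table.at[idx, "annotations"].append(f"{ref.name} (mz-only)")
            elif abs(row["time"] - ref.expected_time) <= time_tol:
                table.at[idx, "annotations"].append(ref.name)
    return table


def annotate_suspects(
    table: pd.DataFrame,
    suspects: Sequence[tuple[str, float]],
    tol: float = 0.03,
) -> pd.DataFrame:
    """Suspect screening: label every row within +-tol of a suspect m/z;
    multiple hits are all recorded."""
    table = table.copy()
    if "annotations" not in table.columns:
        table["annotations"] = [[] for _ in range(len(table))]
    for idx, row in table.iterrows():
        for name, smz in suspects:
            if abs(row["mz"] - smz) <= tol:
                table.at[idx, "annotations"].append(f"suspect:{name}")
    return table


def load_reference_flags(path: str | Path | None = None) -> pd.DataFrame:
    """Load the shipped reference standard detection-flag table
    (40 analytes x 5 methods) or a user table in the same layout."""
    if path is None:
        src = resources.files("roifuse.data") / "table1_flags.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for m in FIXTURE_METHODS:
        bad = set(df[f"{m}_flag"]) - set(FLAGS)
        if bad:
            raise ValueError(f"unknown flags for {m}: {bad}")
    return df


def reference_entries(
    flags: pd.DataFrame, methods: Iterable[str] = FIXTURE_METHODS
) -> list[ReferenceEntry]:
    """Expand the flag table into per-analyte x method reference entries."""
    out = []
    for row in flags.itertuples():
        for m in methods:
            mz = row.mz_neg if m in NEGATIVE_METHODS else row.mz_pos
            t = getattr(row, f"{m}_time")
            out.append(
                ReferenceEntry(
                    analyte_id=int(row.analyte_id),
                    name=row.name,
                    method_id=m,
                    flag=getattr(row, f"{m}_flag"),
                    expected_mz=float(mz),
                    expected_time=None if pd.isna(t) else float(t),
                )
            )
    return out


def coverage_count(
    flags: pd.DataFrame | Sequence[ReferenceEntry],
    methods: Sequence[str],
    count_comigrating: bool = False,
    exclude_ids: frozenset[int] | set[int] = INTERNAL_STANDARD_IDS,
) -> int:
    """Number of analytes detected by at least one of the given methods.

    Co-migrating detections (seen only at the electroosmotic-flow front,
    hence unseparated) do not count unless ``count_comigrating``;
    ``exclude_ids`` removes e.g. the internal standards from the count.
    """
    if isinstance(flags, pd.DataFrame):
        entries = reference_entries(flags, FIXTURE_METHODS)
    else:
        entries = list(flags)
    known = {e.method_id for e in entries}
    for m in methods:
        if m not in known:
            raise ValueError(f"unknown method id {m!r}")
    covered = set()
    for e in entries:
        if e.method_id not in methods or e.analyte_id in exclude_ids:
            continue
        if e.flag == "detected" or (count_comigrating and e.flag == "comigrating"):
            covered.add(e.analyte_id)
    return len(covered)
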