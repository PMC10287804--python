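"""Config-driven batch orchestration of the full workflow.

Runs import -> crop -> ROI search -> peak detection/filters -> alignment
-> cube -> scaling -> augmentation -> annotation -> statistics, group by
group, each group with its own parameterization (essential when sharp CE
electropherograms and broad HILIC chromatograms are processed side by
side). Outputs are CSV tables plus a JSON manifest recording parameters
and seed; deterministic stages rerun bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cube import (
    AlignmentConfig,
    SimpleFeature,
    align_mass,
    align_time,
    build_cube,
    features_to_frame,
    filter_occurrence,
)
from .fusion import annotate_suspects, annotate_targets, augment, match_across_groups
from .peaks import PeakDetectParams, detect_and_integrate, entropy_filter, filter_peaks
from .raw_io import RawDataError, crop_run, read_run
from .roi import ROIParams, build_rois, correct_baseline, filter_contaminants, filter_isotopes
from .stats import regulation_table

log = logging.getLogger("roifuse")


class ConfigError(ValueError):
    """Invalid or inconsistent study configuration."""


@dataclass
class GroupConfig:
    group_id: str
    files: list[str]
    roi: ROIParams = field(default_factory=ROIParams)
    peaks: PeakDetectParams = field(default_factory=PeakDetectParams)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    rel_occurrence: float = 0.5
    crop_time: tuple[float, float] | None = None
    crop_mz: tuple[float, float] | None = None
    baseline_window: int = 0  # 0 disables baseline correction
    subtract_threshold: bool = True
    entropy_filter: bool = False  # optional additional noise filter
    isotope_filter: bool = False
    contaminant_mzs: list[float] = field(default_factory=list)
    method_id: str = ""


@dataclass
class StudyConfig:
    groups: list[GroupConfig]
    output_dir: str = "roifuse_out"
    phenotypes: dict[str, str] = field(default_factory=dict)  # file -> phenotype
    reference_table: str | None = None
    suspect_table: str | None = None
    match_mz_tolerance: float = 0.01
    ref_group: str | None = None
    treat_group: str | None = None
    fdr: float = 0.05
    seed: int = 0


def _coerce(value):
    # YAML 1.1 reads exponent notation without a sign ("2.0e4") as text
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


def _params_from(mapping: dict, cls):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    numeric = {
        f.name for f in dataclasses.fields(cls) if f.type in ("float", "int", "float | None")
    }
    mapping = {k: (_coerce(v) if k in numeric else v) for k, v in mapping.items()}
    return cls(**mapping)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML (or JSON) study configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError(f"unparseable config{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    groups = []
    for g in raw.get("groups", []):
        g = dict(g)
        for key, cls in (("roi", ROIParams), ("peaks", PeakDetectParams), ("alignment", AlignmentConfig)):
            if key in g:
                try:
                    g[key] = _params_from(dict(g[key]), cls)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"group {g.get('group_id')}: {exc}") from exc
        for key in ("crop_time", "crop_mz"):
            if g.get(key) is not None:
                g[key] = tuple(g[key])
        groups.append(_params_from(g, GroupConfig))
    top = {k: v for k, v in raw.items() if k != "groups"}
    cfg = _params_from({"groups": groups, **top}, StudyConfig)
    return cfg


def validate_config(config: StudyConfig | str | Path) -> list[str]:
    """Return a list of violations; empty means valid."""
    if not isinstance(config, StudyConfig):
        config = load_config(config)
    problems = []
    if not config.groups:
        problems.append("no groups defined")
    seen = set()
    for g in config.groups:
        if g.group_id in seen:
            problems.append(f"duplicate group_id {g.group_id!r}")
        seen.add(g.group_id)
        if not g.files:
            problems.append(f"group {g.group_id!r}: zero files")
        for f in g.files:
            if not Path(f).exists():
                problems.append(f"group {g.group_id!r}: missing file {f}")
        if not 0.0 <= g.rel_occurrence <= 1.0:
            problems.append(f"group {g.group_id!r}: rel_occurrence outside [0, 1]")
        if g.peaks.min_width >= g.peaks.max_width:
            problems.append(f"group {g.group_id!r}: min_width >= max_width")
    return problems


def process_group(cfg: GroupConfig) -> tuple[pd.DataFrame, dict]:
    """Run one group end to end up to its filtered feature table."""
    features_by_rep: dict[str, list[SimpleFeature]] = {}
    info: dict[str, Any] = {"group_id": cfg.group_id, "n_rois": {}, "n_peaks": {}}
    for fpath in sorted(cfg.files):
        run = read_run(fpath, group_id=cfg.group_id)
        if cfg.crop_time or cfg.crop_mz:
            run = crop_run(run, cfg.crop_time, cfg.crop_mz)
        rois = build_rois(run, cfg.roi)
        if cfg.baseline_window >= 3:
            rois = [correct_baseline(r, cfg.baseline_window) for r in rois]
        if cfg.isotope_filter:
            rois, _ = filter_isotopes(rois, cfg.roi.mz_error)
        if cfg.contaminant_mzs:
            rois, _ = filter_contaminants(
                rois, cfg.contaminant_mzs, cfg.roi.mz_error, n_scans_total=len(run)
            )
        subtract = cfg.roi.intensity_threshold if cfg.subtract_threshold else 0.0
        peaks = []
        for roi in rois:
            peaks.extend(detect_and_integrate(roi, cfg.peaks, subtract=subtract))
        if cfg.entropy_filter:
            peaks, _ = entropy_filter(peaks)
        peaks = filter_peaks(peaks, cfg.peaks)
        info["n_rois"][run.replicate_id] = len(rois)
        info["n_peaks"][run.replicate_id] = len(peaks)
        features_by_rep[run.replicate_id] = [
            SimpleFeature(
                mz=p.mz, time=p.apex_time, area=p.area, height=p.height,
                replicate_id=run.replicate_id,
            )
            for p in peaks
        ]
    al = cfg.alignment
    if al.align_time and len(features_by_rep) >= 2:
        reference = sorted(features_by_rep)[0]
        features_by_rep, shifts = align_time(
            features_by_rep, reference, al.time_tolerance, al.mz_tolerance
        )
        info["time_shifts"] = shifts
    if al.align_mass and len(features_by_rep) >= 2:
        features_by_rep, mshifts = align_mass(
            features_by_rep, al.mass_quantile, al.mz_tolerance, al.time_tolerance
        )
        info["mass_shifts"] = mshifts
    _, features = build_cube(
        features_by_rep, al.mz_tolerance, al.time_tolerance, group_id=cfg.group_id
    )
    features = filter_occurrence(features, cfg.rel_occurrence)
    frame = features_to_frame(features)
    info["n_features"] = len(frame)
    return frame, info


def run_pipeline(config: StudyConfig | str | Path) -> dict[str, Any]:
    """Execute the full study workflow and write all artifacts.

    Returns a dict with the augmented table, per-group frames, statistics
    (when a reference/treated pair is configured), and the manifest.
    """
    if not isinstance(config, StudyConfig):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "groups": [],
    }
    for g in config.groups:
        try:
            frame, info = process_group(g)
        except (RawDataError, ValueError) as exc:
            raise RuntimeError(
                f"stage failure in group {g.group_id!r}: {exc}; parameters: {g}"
            ) from exc
        frames.append(frame)
        manifest["groups"].append(info)
        frame.to_csv(out_dir / f"features_{g.group_id}.csv", index=False)
    table = augment([f for f in frames if len(f)] or frames)
    table = match_across_groups(table, config.match_mz_tolerance)
    if config.reference_table:
        refs_df = pd.read_csv(config.reference_table)
        from .fusion import ReferenceEntry

        refs = [
            ReferenceEntry(
                analyte_id=int(r.get("analyte_id", i)),
                name=str(r["name"]),
                method_id=str(r["method_id"]),
                flag=str(r.get("flag", "detected")),
                expected_mz=float(r["expected_mz"]),
                expected_time=None if pd.isna(r.get("expected_time")) else float(r["expected_time"]),
            )
            for i, r in refs_df.iterrows()
        ]
        group_method = {g.group_id: (g.method_id or g.group_id) for g in config.groups}
        table = annotate_targets(table, refs, group_method=group_method)
    if config.suspect_table:
        s_df = pd.read_csv(config.suspect_table)
        table = annotate_suspects(table, list(zip(s_df["name"], s_df["mz"])))
    export = table.copy()
    export["annotations"] = export["annotations"].map("; ".join)
    export.to_csv(out_dir / "augmented_table.csv", index=False)
    result: dict[str, Any] = {"table": table, "frames": frames, "manifest": manifest}
    if config.ref_group and config.treat_group:
        stats_df = regulation_table(
            table, config.ref_group, config.treat_group, fdr=config.fdr
        )
        stats_df.to_csv(out_dir / "regulation.csv", index=False)
        result["stats"] = stats_df
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
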