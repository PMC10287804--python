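"""Synthetic multi-platform raw-data generator with ground truth.

Emulates the two separation families fused by this package: capillary
electrophoresis, with sharp (seconds-wide) peaks but migration times that
shift replicate-to-replicate by a sizeable fraction of a minute, and
HILIC, with broader, tailing peaks and retention times stable to a few
hundredths of a minute. Each simulated feature is a Gaussian or
exponentially modified Gaussian (EMG) sampled on a regular scan grid,
with per-centroid m/z jitter, Gaussian white noise, and a constant
baseline with optional linear drift. Ground truth (realized apex time,
closed-form area, m/z, regulation class) accompanies every run so the
whole pipeline can be scored end to end.

All randomness flows from one seeded generator; writers emit mzXML (and
optionally mzML) so the import path is exercised as well.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .raw_io import RunData, Scan


@dataclass(frozen=True)
class SimFeatureSpec:
    """One planted feature."""

    mz: float
    time: float
    height: float
    width_sigma: float
    shape: Literal["gaussian", "emg"] = "gaussian"
    tau: float = 0.0
    regulation_truth: str = "stable"
    feature_id: int = -1

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width_sigma <= 0:
            raise ValueError("height and width_sigma must be > 0")


@dataclass(frozen=True)
class SimMethodProfile:
    """Separation-method characteristics of a simulated run."""

    name: str
    peak_sigma_range: tuple[float, float]
    time_jitter_sd: float
    mz_jitter_sd: float
    baseline_level: float
    noise_sd: float
    scan_interval: float
    duration: float
    polarity: str = "positive"
    baseline_drift: float = 0.0  # counts per minute, linear
    emg_tau_factor: float = 0.0  # tau = factor * sigma


#: CE-like: sharp peaks, large replicate-to-replicate migration-time shifts.
CE_PROFILE = SimMethodProfile(
    name="ce",
    peak_sigma_range=(0.02, 0.1),
    time_jitter_sd=0.3,
    mz_jitter_sd=0.001,
    baseline_level=200.0,
    noise_sd=500.0,
    scan_interval=0.005,
    duration=10.0,
    polarity="positive",
)

#: HILIC-like: broad tailing peaks, stable retention times.
HILIC_PROFILE = SimMethodProfile(
    name="hilic",
    peak_sigma_range=(0.1, 0.4),
    time_jitter_sd=0.03,
    mz_jitter_sd=0.001,
    baseline_level=200.0,
    noise_sd=500.0,
    scan_interval=0.02,
    duration=15.0,
    polarity="negative",
    baseline_drift=20.0,
    emg_tau_factor=1.0,
)


def gaussian_area(height: float, sigma: float) -> float:
    """Closed-form area of a Gaussian peak: h * sigma * sqrt(2*pi)."""
    return height * sigma * np.sqrt(2.0 * np.pi)


def _shape_trace(spec: SimFeatureSpec, t: np.ndarray, center: float) -> np.ndarray:
    if spec.shape == "gaussian" or spec.tau <= 0:
        return spec.height * np.exp(-0.5 * ((t - center) / spec.width_sigma) ** 2)
    s, tau = spec.width_sigma, spec.tau
    z = (s / tau - (t - center) / s) / np.sqrt(2.0)
    y = np.exp(s**2 / (2 * tau**2) - (t - center) / tau) * erfc(z)
    peak = y.max()
    return spec.height * y / peak if peak > 0 else y


def _shape_area(spec: SimFeatureSpec, center: float) -> float:
    if spec.shape == "gaussian" or spec.tau <= 0:
        return gaussian_area(spec.height, spec.width_sigma)
    # EMG has no closed form once renormalized to peak height; integrate a
    # dense noiseless sampling instead
    span = 6 * spec.width_sigma + 8 * spec.tau
    t = np.linspace(center - span, center + span, 4001)
    return float(np.trapezoid(_shape_trace(spec, t, center), t))


def simulate_run(
    specs: Sequence[SimFeatureSpec],
    profile: SimMethodProfile,
    replicate_seed: int,
    group_id: str = "",
    replicate_id: str = "",
) -> tuple[RunData, pd.DataFrame]:
    """Simulate one replicate run and its ground-truth table.

    One migration/retention-time shift ~N(0, time_jitter_sd) is drawn for
    the replicate and applied to every feature (the dominant CE effect);
    each emitted centroid additionally jitters in m/z. The truth table
    records realized apex time, closed-form area, and m/z per feature.
    """
    rng = np.random.default_rng(replicate_seed)
    n_scans = int(round(profile.duration / profile.scan_interval)) + 1
    times = np.arange(n_scans) * profile.scan_interval
    run_shift = rng.normal(0.0, profile.time_jitter_sd)

    traces = np.zeros((len(specs), n_scans))
    centers = np.empty(len(specs))
    for k, spec in enumerate(specs):
        centers[k] = spec.time + run_shift
        traces[k] = _shape_trace(spec, times, centers[k])

    baseline = profile.baseline_level + profile.baseline_drift * times
    noise = rng.normal(0.0, profile.noise_sd, size=traces.shape)
    signal = np.clip(traces + baseline[None, :] + noise, 0.0, None)
    mz_jitter = rng.normal(0.0, profile.mz_jitter_sd, size=traces.shape)

    scans = []
    for i in range(n_scans):
        inten = signal[:, i]
        keep = inten > 0
        scans.append(
            Scan(
                time=float(times[i]),
                mz=np.array([s.mz for s in specs])[keep] + mz_jitter[keep, i],
                intensity=inten[keep],
                ms_level=1,
                polarity=profile.polarity,
            )
        )
    run = RunData(
        scans=scans, group_id=group_id, replicate_id=replicate_id or f"rep{replicate_seed}"
    )
    truth = pd.DataFrame(
        {
            "feature_id": [s.feature_id for s in specs],
            "mz": [s.mz for s in specs],
            "apex_time": centers,
            "height": [s.height for s in specs],
            "sigma": [s.width_sigma for s in specs],
            "area": [_shape_area(s, c) for s, c in zip(specs, centers)],
            "regulation_truth": [s.regulation_truth for s in specs],
            "replicate_id": run.replicate_id,
            "seed": replicate_seed,
        }
    )
    return run, truth


def random_feature_specs(
    n_features: int,
    profile: SimMethodProfile,
    rng: np.random.Generator,
    height_range: tuple[float, float] = (2e5, 2e6),
    mz_range: tuple[float, float] = (100.0, 700.0),
    min_mz_spacing: float = 0.05,
    min_time_spacing_sigmas: float = 10.0,
) -> list[SimFeatureSpec]:
    """Draw well-separated feature positions for one method.

    m/z values are spaced by at least ``min_mz_spacing`` so traces do not
    merge, and features sharing a (rounded) m/z neighbourhood are spaced
    in time; heights are log-uniform over ``height_range``.
    """
    mzs: list[float] = []
    while len(mzs) < n_features:
        cand = rng.uniform(*mz_range)
        if all(abs(cand - m) >= min_mz_spacing for m in mzs):
            mzs.append(cand)
    margin = 0.08 * profile.duration
    specs = []
    for k, mz in enumerate(sorted(mzs)):
        sigma = rng.uniform(*profile.peak_sigma_range)
        specs.append(
            SimFeatureSpec(
                mz=mz,
                time=rng.uniform(margin, profile.duration - margin),
                height=float(np.exp(rng.uniform(*np.log(height_range)))),
                width_sigma=sigma,
                shape="emg" if profile.emg_tau_factor > 0 else "gaussian",
                tau=profile.emg_tau_factor * sigma,
                feature_id=k,
            )
        )
    return specs


REGULATION_FACTORS = {
    "stable": (0.8, 1.25),
    "up": (2.5, 8.0),
    "down": (0.125, 0.4),
}


def simulate_study(
    out_dir: str | Path,
    profiles: Sequence[SimMethodProfile] = (CE_PROFILE, HILIC_PROFILE),
    n_features: int = 40,
    n_replicates: int = 6,
    effect_fractions: dict[str, float] | None = None,
    seed: int = 0,
    write_format: str = "mzxml",
) -> pd.DataFrame:
    """Write a two-phenotype (mock vs treated) multi-method study to disk.

    Per method, ``n_features`` features are planted; a configured
    fraction of them is knocked out, induced, up-, or down-regulated in
    the treated phenotype (defaults 10/10/15/15 %, remainder stable).
    Returns the pooled truth table; files land in
    ``out_dir/<method>_<phenotype>_rep<i>.mzXML``.
    """
    if effect_fractions is None:
        effect_fractions = {"knock_out": 0.10, "induced": 0.10, "up": 0.15, "down": 0.15}
    if sum(effect_fractions.values()) > 1.0 + 1e-9:
        raise ValueError("effect fractions must sum to <= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = []
    for profile in profiles:
        specs = random_feature_specs(n_features, profile, rng)
        classes = []
        for cls, frac in effect_fractions.items():
            classes += [cls] * int(round(frac * n_features))
        classes += ["stable"] * (n_features - len(classes))
        rng.shuffle(classes)
        mock_specs, treat_specs = [], []
        for spec, cls in zip(specs, classes):
            spec = SimFeatureSpec(
                mz=spec.mz,
                time=spec.time,
                height=spec.height,
                width_sigma=spec.width_sigma,
                shape=spec.shape,
                tau=spec.tau,
                regulation_truth=cls,
                feature_id=spec.feature_id,
            )
            if cls != "induced":
                mock_specs.append(spec)
            if cls != "knock_out":
                factor = 1.0
                if cls in REGULATION_FACTORS:
                    factor = rng.uniform(*REGULATION_FACTORS[cls])
                treat_specs.append(
                    SimFeatureSpec(
                        mz=spec.mz,
                        time=spec.time,
                        height=spec.height * factor,
                        width_sigma=spec.width_sigma,
                        shape=spec.shape,
                        tau=spec.tau,
                        regulation_truth=cls,
                        feature_id=spec.feature_id,
                    )
                )
        for phenotype, phen_specs in (("mock", mock_specs), ("treated", treat_specs)):
            for r in range(n_replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                rep_id = f"{phenotype}_rep{r + 1}"
                group = f"{profile.name}_{phenotype}"
                run, truth = simulate_run(
                    phen_specs, profile, rep_seed, group_id=group, replicate_id=rep_id
                )
                fname = out_dir / f"{profile.name}_{phenotype}_rep{r + 1}.{ 'mzML' if write_format == 'mzml' else 'mzXML'}"
                if write_format == "mzml":
                    write_mzml(run, fname)
                else:
                    write_mzxml(run, fname)
                truth["method"] = profile.name
                truth["phenotype"] = phenotype
                truth["file"] = str(fname)
                truths.append(truth)
    return pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# writers


def _encode_peaks_mzxml(mz: np.ndarray, inten: np.ndarray) -> str:
    interleaved = np.empty(2 * len(mz))
    interleaved[0::2] = mz
    interleaved[1::2] = inten
    data = struct.pack(f">{len(interleaved)}d", *interleaved)
    return base64.b64encode(data).decode("ascii")


def write_mzxml(run: RunData, path: str | Path) -> None:
    """Write a run as centroided MS1 mzXML (64-bit, network byte order)."""
    path = Path(path)
    pol = "+" if run.polarity == "positive" else "-"
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans, start=1):
        payload = _encode_peaks_mzxml(scan.mz, scan.intensity)
        lines.append(
            f'  <scan num="{i}" msLevel="{scan.ms_level}" peaksCount="{len(scan.mz)}"'
            f' polarity="{pol}" retentionTime="PT{scan.time * 60.0:.6f}S" centroided="1">'
        )
        lines.append(
            '   <peaks precision="64" byteOrder="network" contentType="m/z-int"'
            f' compressionType="none" compressedLen="0">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    path.write_text("\n".join(lines))


def _encode_array_mzml(values: np.ndarray) -> str:
    data = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(data).decode("ascii")


def write_mzml(run: RunData, path: str | Path) -> None:
    """Write a run as centroided MS1 mzML (64-bit little-endian, no
    compression)."""
    path = Path(path)
    pol_cv = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if run.polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        ' <run id="run1">',
        f'  <spectrumList count="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans):
        mz64 = _encode_array_mzml(scan.mz)
        in64 = _encode_array_mzml(scan.intensity)
        lines += [
            f'   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan.mz)}">',
            f'    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>',
            '    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            f"    {pol_cv}",
            '    <scanList count="1">',
            "     <scan>",
            f'      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.time:.8f}"'
            ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>',
            "     </scan>",
            "    </scanList>",
            '    <binaryDataArrayList count="2">',
            f'     <binaryDataArray encodedLength="{len(mz64)}">',
            '      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>',
            f"      <binary>{mz64}</binary>",
            "     </binaryDataArray>",
            f'     <binaryDataArray encodedLength="{len(in64)}">',
            '      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>',
            f"      <binary>{in64}</binary>",
            "     </binaryDataArray>",
            "    </binaryDataArrayList>",
            "   </spectrum>",
        ]
    lines += ["  </spectrumList>", " </run>", "</mzML>", ""]
    path.write_text("\n".join(lines))
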