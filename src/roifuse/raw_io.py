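"""Raw MS1 data import and cropping.

Centroided MS1 spectra are read from mzXML or mzML (optionally gzipped)
into a light in-memory run representation.  Times are minutes throughout
(retention time for LC, migration time for CE).  Profile-mode data is
rejected: centroiding is out of scope and the downstream region-of-interest
search assumes one centroid per analyte per scan.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import base64
import struct
import zlib

import numpy as np
from lxml import etree
from pyteomics import mzxml


class RawDataError(ValueError):
    """Unreadable, empty, or structurally invalid raw data."""


@dataclass(frozen=True)
class Scan:
    """One centroided MS1 spectrum.

    Attributes
    ----------
    time : float
        Retention/migration time in minutes.
    mz : np.ndarray
        Centroid m/z values (Da), strictly increasing.
    intensity : np.ndarray
        Centroid intensities (counts), same length as ``mz``.
    ms_level : int
    polarity : str
        ``"positive"`` or ``"negative"``.
    """

    time: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    polarity: str = "positive"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise RawDataError("mz and intensity must be 1-D and equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            if np.any(np.diff(mz) <= 0):
                # merge exact duplicates by summing intensity
                uniq, inverse = np.unique(mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        if inten.size and inten.min() < 0:
            raise RawDataError("negative intensities")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RunData:
    """A time-ordered sequence of MS1 scans with group/replicate metadata."""

    scans: list[Scan]
    group_id: str = ""
    replicate_id: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda s: s.time)
        pols = {s.polarity for s in self.scans}
        if len(pols) > 1:
            raise RawDataError(f"mixed polarities within one run: {sorted(pols)}")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans], dtype=float)

    @property
    def polarity(self) -> str:
        return self.scans[0].polarity if self.scans else "positive"

    def base_peak_trace(self) -> np.ndarray:
        return np.array([s.base_peak_intensity for s in self.scans], dtype=float)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return gzip.open(raw)
    return raw


def _detect_format(path: str | Path) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".mzxml"):
        return "mzxml"
    if name.endswith(".mzml"):
        return "mzml"
    raise RawDataError(f"cannot infer format from file name: {path}")


def read_run(
    path: str | Path,
    format: str = "auto",
    group_id: str = "",
    replicate_id: str = "",
) -> RunData:
    """Read centroided MS1 scans from an mzXML or mzML file.

    Only MS1 spectra are retained; MS/MS scans are dropped on import.
    Raises :class:`RawDataError` for unparseable files, profile-mode data,
    mixed polarity, or files without any MS1 scan.
    """
    path = Path(path)
    if not path.exists():
        raise RawDataError(f"file not found: {path}")
    fmt = format if format != "auto" else _detect_format(path)
    scans: list[Scan] = []
    try:
        if fmt == "mzxml":
            with _open_maybe_gzip(path) as fh, mzxml.MzXML(fh) as reader:
                for entry in reader:
                    scan = _scan_from_mzxml(entry, path)
                    if scan is not None:
                        scans.append(scan)
        elif fmt == "mzml":
            with _open_maybe_gzip(path) as fh:
                scans = _read_mzml(fh, path)
        else:
            raise RawDataError(f"unknown format {fmt!r}")
    except RawDataError:
        raise
    except Exception as exc:  # parser-level failure
        raise RawDataError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not scans:
        raise RawDataError(f"{path}: no MS1 scans")
    return RunData(
        scans=scans,
        group_id=group_id,
        replicate_id=replicate_id or path.stem,
        source_path=str(path),
    )


def _scan_from_mzxml(entry: dict, path: Path) -> Scan | None:
    if int(entry.get("msLevel", 1)) != 1:
        return None
    if entry.get("centroided") is False:
        raise RawDataError(f"{path}: profile-mode data; centroided MS1 required")
    rt = entry.get("retentionTime", 0.0)  # pyteomics converts to minutes
    pol = {"+": "positive", "-": "negative"}.get(entry.get("polarity", "+"), "positive")
    mz = entry.get("m/z array")
    inten = entry.get("intensity array")
    return Scan(
        time=float(rt),
        mz=np.empty(0) if mz is None else mz,
        intensity=np.empty(0) if inten is None else inten,
        ms_level=1,
        polarity=pol,
    )


def _decode_binary(binary_el, cv: dict[str, str]) -> np.ndarray:
    data = base64.b64decode((binary_el.text or "").strip())
    if "MS:1000574" in cv:  # zlib compression
        data = zlib.decompress(data)
    fmt = "f" if "MS:1000521" in cv else "d"  # 32-bit vs 64-bit float
    n = len(data) // struct.calcsize(fmt)
    return np.asarray(struct.unpack(f"<{n}{fmt}", data), dtype=float)


def _read_mzml(fh, path: Path) -> list[Scan]:
    """Minimal mzML reader for centroided MS1 spectra (standard PSI-MS
    controlled vocabulary; 32/64-bit floats, zlib or no compression)."""
    scans: list[Scan] = []
    for _, spec in etree.iterparse(fh, tag="{*}spectrum"):
        cv = {
            el.get("accession"): el.get("value", "")
            for el in spec.iter("{*}cvParam")
        }
        unit = {
            el.get("accession"): el.get("unitName", "")
            for el in spec.iter("{*}cvParam")
        }
        level = int(cv.get("MS:1000511", 1))
        if level != 1:
            spec.clear()
            continue
        if "MS:1000128" in cv:  # profile spectrum
            raise RawDataError(f"{path}: profile-mode data; centroided MS1 required")
        rt = float(cv.get("MS:1000016", 0.0))
        if unit.get("MS:1000016", "minute") == "second":
            rt /= 60.0
        pol = "negative" if "MS:1000129" in cv else "positive"
        mz_arr = inten_arr = None
        for bda in spec.iter("{*}binaryDataArray"):
            bcv = {el.get("accession"): el.get("value", "") for el in bda.iter("{*}cvParam")}
            binary = bda.find("{*}binary")
            if binary is None:
                continue
            if "MS:1000514" in bcv:
                mz_arr = _decode_binary(binary, bcv)
            elif "MS:1000515" in bcv:
                inten_arr = _decode_binary(binary, bcv)
        if mz_arr is None or inten_arr is None:
            raise RawDataError(f"{path}: spectrum without m/z or intensity array")
        scans.append(Scan(time=rt, mz=mz_arr, intensity=inten_arr, ms_level=1, polarity=pol))
        spec.clear()
    return scans


def crop_run(
    run: RunData,
    time_window: Sequence[float] | None = None,
    mz_window: Sequence[float] | None = None,
) -> RunData:
    """Crop a run to closed time and m/z windows.

    Discarding irrelevant regions before the ROI search cuts computation
    time. Scans outside ``time_window`` are dropped; within each kept scan
    only centroids inside ``mz_window`` survive. Both intervals are closed.
    """
    if time_window is not None:
        t0, t1 = map(float, time_window)
        if not t0 < t1:
            raise ValueError("time_window must satisfy t_min < t_max")
    if mz_window is not None:
        m0, m1 = map(float, mz_window)
        if not m0 < m1:
            raise ValueError("mz_window must satisfy mz_min < mz_max")
    out: list[Scan] = []
    for scan in run.scans:
        if time_window is not None and not (t0 <= scan.time <= t1):
            continue
        if mz_window is None:
            out.append(scan)
            continue
        keep = (scan.mz >= m0) & (scan.mz <= m1)
        out.append(replace(scan, mz=scan.mz[keep], intensity=scan.intensity[keep]))
    if not out:
        warnings.warn("crop window excludes every scan; returning empty run")
    return RunData(
        scans=out,
        group_id=run.group_id,
        replicate_id=run.replicate_id,
        source_path=run.source_path,
    )
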