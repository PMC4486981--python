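"""Centroided-run data model, I/O and chromatographic peak handling.

A run is a time-ordered list of centroided MS1 scans. Three on-disk forms
are read: mzML (centroid MS1 only, via pyteomics), a native JSON schema
with scans as parallel arrays, and a long-format CSV (rt, mz, intensity)
convenient for fixtures. Extracted-ion chromatograms use a symmetric ppm
window; peaks are integrated by trapezoid with a MAD-based noise estimate
and a conventional S/N ≥ 3 detection gate.

Native JSON schema::

    {"metadata": {"sample_id": ..., "sample_type": ...,
                  "dry_mass_g": ..., "extract_volume_ml": ...},
     "scans": [{"rt": minutes, "mz": [...], "intensity": [...]}, ...]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_TYPES",
    "Scan",
    "RunMetadata",
    "CentroidRun",
    "EIC",
    "ChromPeak",
    "RunFormatError",
    "read_run",
    "write_run",
    "extract_eic",
    "integrate_peak",
]

SAMPLE_TYPES = ("standard", "blank", "matrix_spike", "cohort_sample")


class RunFormatError(ValueError):
    """Raised for malformed or unsupported run files."""


@dataclass
class Scan:
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(self.mz <= 0):
            raise RunFormatError("all m/z values must be positive")
        if self.intensity.size and np.any(self.intensity < 0):
            raise RunFormatError("intensities must be non-negative")


@dataclass
class RunMetadata:
    sample_id: str = ""
    sample_type: str = "cohort_sample"
    dry_mass_g: float | None = None
    extract_volume_ml: float | None = None

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise RunFormatError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}")


@dataclass
class CentroidRun:
    scans: list[Scan]
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self):
        if not self.scans:
            raise RunFormatError("run contains no scans")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise RunFormatError("scan retention times must be strictly increasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class EIC:
    """Extracted-ion chromatogram over a symmetric ppm window."""
    times: np.ndarray
    intensities: np.ndarray
    center_mz: float
    tol_ppm: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities differ in length")
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ChromPeak:
    apex_rt: float
    area: float  # counts * minutes
    height: float
    bounds: tuple[float, float]
    signal_to_noise: float

    def __post_init__(self):
        if not self.bounds[0] <= self.apex_rt <= self.bounds[1]:
            raise ValueError("apex must lie within the peak bounds")
        if self.height <= 0 or self.area < 0:
            raise ValueError("peak height must be positive and area non-negative")


# ---------------------------------------------------------------------------
# I/O

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".mzml": "mzml", ".json": "native_json", ".csv": "native_csv"}.get(
        suffix, "")


def read_run(path, fmt: str | None = None) -> CentroidRun:
    """Read a centroided run from mzML, native JSON or long-format CSV."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mzml":
        return _read_mzml(path)
    if fmt == "native_json":
        return _read_json(path)
    if fmt == "native_csv":
        return _read_csv(path)
    raise RunFormatError(f"unsupported run format {fmt!r} for {path}")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(node) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, zlib or none)."""
    import base64
    import zlib

    dtype, compressed = "<f8", False
    payload = b""
    for child in node:
        name = _local(child.tag)
        if name == "cvParam":
            pname = child.get("name", "")
            if pname == "32-bit float":
                dtype = "<f4"
            elif pname == "zlib compression":
                compressed = True
        elif name == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> CentroidRun:
    """Minimal mzML reader for centroided MS1 spectra.

    Iterates <spectrum> elements, requiring the centroid-spectrum cvParam
    and a scan start time (minute or second units); profile spectra and
    MS levels above 1 are respectively rejected and skipped.
    """
    from lxml import etree

    scans = []
    for i, (_, spec) in enumerate(etree.iterparse(str(path), tag="*")):
        if _local(spec.tag) != "spectrum":
            continue
        ms_level, profile, rt = 1, False, None
        arrays: dict[str, np.ndarray] = {}
        for node in spec.iter():
            name = _local(node.tag)
            if name == "cvParam":
                pname = node.get("name", "")
                if pname == "ms level":
                    ms_level = int(node.get("value", "1"))
                elif pname == "profile spectrum":
                    profile = True
                elif pname == "scan start time":
                    rt = float(node.get("value"))
                    if node.get("unitName", "minute") == "second":
                        rt /= 60.0
            elif name == "binaryDataArray":
                kinds = {c.get("name") for c in node
                         if _local(c.tag) == "cvParam"}
                data = _decode_binary_array(node)
                if "m/z array" in kinds:
                    arrays["mz"] = data
                elif "intensity array" in kinds:
                    arrays["intensity"] = data
        spec.clear()
        if ms_level != 1:
            continue
        if profile:
            raise RunFormatError(
                f"spectrum {i} is profile mode; only centroided spectra "
                "are supported")
        if rt is None:
            raise RunFormatError(f"spectrum {i} lacks a scan start time")
        if "mz" not in arrays or "intensity" not in arrays:
            raise RunFormatError(f"spectrum {i} lacks m/z or intensity arrays")
        scans.append(Scan(rt, arrays["mz"], arrays["intensity"]))
    if not scans:
        raise RunFormatError(f"{path} contains no MS1 spectra")
    scans.sort(key=lambda s: s.rt)
    return CentroidRun(scans, RunMetadata(sample_id=path.stem))


def _read_json(path: Path) -> CentroidRun:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        meta = RunMetadata(**doc.get("metadata", {}))
        scans = [Scan(float(s["rt"]), s["mz"], s["intensity"])
                 for s in doc["scans"]]
    except (KeyError, TypeError) as exc:
        raise RunFormatError(f"malformed native JSON run {path}: {exc}") from exc
    return CentroidRun(scans, meta)


def _read_csv(path: Path) -> CentroidRun:
    df = pd.read_csv(path)
    required = {"rt", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise RunFormatError(f"{path} must have columns {sorted(required)}")
    scans = [Scan(float(rt), g["mz"].to_numpy(), g["intensity"].to_numpy())
             for rt, g in df.groupby("rt", sort=True)]
    return CentroidRun(scans, RunMetadata(sample_id=path.stem))


def write_run(run: CentroidRun, path, fmt: str | None = None) -> None:
    """Write a run as native JSON or long-format CSV (mzML is read-only)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "native_json":
        doc = {
            "metadata": {
                "sample_id": run.metadata.sample_id,
                "sample_type": run.metadata.sample_type,
                "dry_mass_g": run.metadata.dry_mass_g,
                "extract_volume_ml": run.metadata.extract_volume_ml,
            },
            "scans": [{"rt": s.rt, "mz": s.mz.tolist(),
                       "intensity": s.intensity.tolist()} for s in run.scans],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif fmt == "native_csv":
        rows = [(s.rt, m, i) for s in run.scans
                for m, i in zip(s.mz, s.intensity)]
        pd.DataFrame(rows, columns=["rt", "mz", "intensity"]).to_csv(
            path, index=False)
    else:
        raise RunFormatError(f"unsupported output format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# Chromatograms

def extract_eic(run: CentroidRun, center_mz: float, tol_ppm: float = 5.0) -> EIC:
    """Per-scan summed intensity within |mz − center| / center ≤ tol_ppm."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = center_mz * tol_ppm * 1e-6
    lo, hi = center_mz - half, center_mz + half
    inten = np.empty(len(run.scans))
    for i, s in enumerate(run.scans):
        sel = (s.mz >= lo) & (s.mz <= hi)
        inten[i] = s.intensity[sel].sum() if sel.any() else 0.0
    return EIC(run.rts, inten, center_mz, tol_ppm)


def _baseline_stats(intensities: np.ndarray, exclude: np.ndarray) -> tuple[float, float]:
    """Robust baseline level and noise outside the peak window: median and
    MAD scaled to the Gaussian sigma."""
    outside = intensities[~exclude]
    if outside.size == 0:
        return 0.0, 0.0
    level = float(np.median(outside))
    mad = np.median(np.abs(outside - level))
    return level, float(1.4826 * mad)


def integrate_peak(eic: EIC, expected_rt: float, rt_tol: float = 0.10,
                   min_sn: float = 3.0) -> ChromPeak | None:
    """Locate and integrate the chromatographic peak near *expected_rt*.

    The baseline level and noise are the median and MAD-derived sigma of
    the trace outside the window. The apex is the highest baseline-corrected
    local maximum within ``expected_rt ± rt_tol`` nearest the expected RT
    (ties broken toward higher intensity); integration bounds extend
    outward until intensity falls below ``baseline + max(3 × noise, 0.5% of
    apex height)``; area is trapezoidal on the baseline-corrected trace.
    Returns None when no candidate clears S/N ≥ *min_sn*.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    t, y = eic.times, eic.intensities
    if t.size == 0:
        raise ValueError("empty EIC")
    window = np.abs(t - expected_rt) <= rt_tol
    if not window.any():
        return None
    baseline, noise = _baseline_stats(y, window)
    if y[window].max() - baseline <= 0:
        return None
    # candidate apexes: local maxima inside the window that clear the S/N gate;
    # choose the one nearest expected_rt, ties broken toward higher intensity
    idx = np.flatnonzero(window)
    left_n = np.where(idx > 0, y[np.maximum(idx - 1, 0)], -np.inf)
    right_n = np.where(idx < y.size - 1, y[np.minimum(idx + 1, y.size - 1)], -np.inf)
    is_max = (y[idx] >= left_n) & (y[idx] >= right_n) & (y[idx] > baseline)
    cand = idx[is_max]
    if noise > 0:
        cand = cand[(y[cand] - baseline) / noise >= min_sn]
    if cand.size == 0:
        return None
    order = np.lexsort((-y[cand], np.abs(t[cand] - expected_rt)))
    apex = int(cand[order[0]])
    height = y[apex] - baseline
    sn = height / noise if noise > 0 else np.inf
    floor = baseline + max(3.0 * noise, 0.005 * height)
    left = apex
    while left > 0 and y[left - 1] >= floor:
        left -= 1
    right = apex
    while right < y.size - 1 and y[right + 1] >= floor:
        right += 1
    corrected = np.clip(y[left:right + 1] - baseline, 0.0, None)
    area = float(np.trapezoid(corrected, t[left:right + 1]))
    return ChromPeak(apex_rt=float(t[apex]), area=area, height=float(height),
                     bounds=(float(t[left]), float(t[right])),
                     signal_to_noise=float(sn))
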