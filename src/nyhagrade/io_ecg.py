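"""Reading and writing ECG records and segment sets.

Two on-disk record formats are supported:

* **WFDB** (MIT signal format 16): a ``.hea`` text header plus a ``.dat``
  binary file of little-endian 16-bit integers, with per-signal gain and
  baseline for amplitude scaling.  Multi-signal records are stored
  sample-interleaved; a single lead is selected by its description.
* **CSV**: one sample per row, optional single header line; the sampling
  rate must be supplied by the caller because the file carries none.

Segment sets persist as a compressed ``.npz`` array container with a CSV
manifest sidecar recording per-segment provenance (subject, start index,
label), so a bundle is both exactly round-trippable and inspectable with
ordinary text tools.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "Segment",
    "SegmentSet",
    "read_record",
    "write_record",
    "write_segments",
    "read_segments",
]

NYHA_CLASSES = (1, 2, 3, 4)


@dataclass
class ECGRecord:
    """One labeled single-lead ECG waveform.

    Parameters
    ----------
    subject_id : str
        Opaque subject/record identifier.
    lead : str
        Lead label; the grading pipeline expects lead ``"II"``.
    fs : float
        Sampling rate in Hz (study value: 125).
    samples : ndarray
        1-D finite amplitude vector.
    label : int or None
        NYHA grade in {1, 2, 3, 4}, or ``None`` when unlabeled.
    """

    subject_id: str
    lead: str
    fs: float
    samples: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(
                f"non-finite samples at indices {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        if self.label is not None and self.label not in NYHA_CLASSES:
            raise ValueError(f"label must be a NYHA grade 1-4, got {self.label}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Segment:
    """A fixed-duration window of a record, carrying its provenance."""

    samples: np.ndarray
    fs: float
    subject_id: str
    start: int  # sample index into the source record
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class SegmentSet:
    """An ordered collection of equal-length segments with a manifest."""

    segments: list[Segment] = field(default_factory=list)
    duration_s: int = 0
    fs: float = 125.0

    def __post_init__(self) -> None:
        expected = int(round(self.duration_s * self.fs))
        for i, seg in enumerate(self.segments):
            if self.duration_s and seg.n_samples != expected:
                raise ValueError(
                    f"segment {i} has {seg.n_samples} samples, "
                    f"expected {expected} for {self.duration_s}s at {self.fs} Hz"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def manifest(self) -> pd.DataFrame:
        """Per-segment provenance table (subject_id, start, label)."""
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.segments],
                "start": [s.start for s in self.segments],
                "label": [s.label if s.label is not None else -1 for s in self.segments],
            }
        )

    def to_array(self) -> np.ndarray:
        """Stack samples into an (n_segments, segment_length) array."""
        if not self.segments:
            return np.zeros((0, 0))
        return np.stack([s.samples for s in self.segments])

    def labels(self) -> np.ndarray:
        return np.array(
            [s.label if s.label is not None else -1 for s in self.segments], dtype=int
        )


# --------------------------------------------------------------------------
# WFDB (MIT format 16)
# --------------------------------------------------------------------------

def _parse_gain_field(tok: str) -> tuple[float, int, str]:
    """Parse a WFDB gain token like ``200``, ``200/mV`` or ``200(0)/mV``."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    return gain, baseline, units


def _read_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        fmt = toks[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = _parse_gain_field(toks[2]) if len(toks) > 2 else (200.0, 0, "mV")
        desc = " ".join(toks[8:]) if len(toks) > 8 else ""
        signals.append(
            {
                "file": toks[0],
                "fmt": fmt,
                "gain": gain,
                "baseline": baseline,
                "units": units,
                "description": desc,
            }
        )
    return name, n_sig, fs, n_samp, signals


def _read_wfdb(path: Path, lead: str) -> tuple[np.ndarray, float, str]:
    hea_path = path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    name, n_sig, fs, n_samp, signals = _read_header(hea_path)
    descs = [s["description"] for s in signals]
    matches = [i for i, d in enumerate(descs) if d.upper() == lead.upper()]
    if not matches:
        raise ValueError(
            f"lead not found: no signal described as {lead!r} in {hea_path.name} "
            f"(available: {descs})"
        )
    idx = matches[0]
    sig = signals[idx]
    if sig["fmt"] != "16":
        raise ValueError(f"unsupported WFDB format {sig['fmt']!r}; only format 16 is supported")
    dat_path = hea_path.parent / sig["file"]
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_sig > 1:
        raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)[:, idx]
    if n_samp:
        raw = raw[:n_samp]
    analog = (raw.astype(float) - sig["baseline"]) / sig["gain"]
    return analog, fs, sig["description"]


def write_record(
    record: ECGRecord,
    path: str | os.PathLike,
    gain: float = 1000.0,
    baseline: int = 0,
) -> Path:
    """Write a record as a WFDB format-16 (.hea/.dat) pair.

    Amplitudes are quantized to ``round(x * gain) + baseline`` 16-bit
    integers; with the default gain of 1000 the resolution is 1 µV-scale
    (0.001 signal units).  Returns the header path.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".hea", ".dat"} else path
    digital = np.round(record.samples * gain).astype(np.int64) + baseline
    if digital.min() < -32768 or digital.max() > 32767:
        raise ValueError("samples exceed 16-bit range at this gain; lower the gain")
    digital = digital.astype("<i2")
    checksum = int(np.sum(digital.astype(np.int64)) % 65536)
    if checksum >= 32768:
        checksum -= 65536
    name = base.name
    header = (
        f"{name} 1 {record.fs:g} {len(digital)}\n"
        f"{name}.dat 16 {gain:g}({baseline})/mV 16 0 "
        f"{int(digital[0])} {checksum} 0 {record.lead}\n"
    )
    if record.label is not None:
        header += f"# label {record.label}\n"
    header += f"# subject {record.subject_id}\n"
    base.with_suffix(".hea").write_text(header)
    digital.tofile(base.with_suffix(".dat"))
    return base.with_suffix(".hea")


def _read_header_comments(hea_path: Path) -> dict:
    meta = {}
    for ln in hea_path.read_text().splitlines():
        if ln.startswith("#"):
            toks = ln[1:].split()
            if len(toks) == 2 and toks[0] in {"label", "subject"}:
                meta[toks[0]] = toks[1]
    return meta


def _read_csv(path: Path) -> np.ndarray:
    text = path.read_text()
    df = pd.read_csv(io.StringIO(text), header=None)
    # tolerate a single header row
    try:
        values = df.iloc[:, 0].astype(float).to_numpy()
        offset = 0
    except (ValueError, TypeError):
        values = df.iloc[1:, 0].astype(float).to_numpy()
        offset = 1
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        rows = (bad[:10] + offset + 1).tolist()  # 1-based file rows
        raise ValueError(f"non-finite sample values at CSV row(s) {rows}")
    return values


def read_record(
    path: str | os.PathLike,
    format: str = "wfdb",
    fs: Optional[float] = None,
    lead: str = "II",
    subject_id: Optional[str] = None,
    label: Optional[int] = None,
) -> ECGRecord:
    """Read one ECG record from disk.

    Parameters
    ----------
    path : path
        For ``wfdb``, the record base name or ``.hea`` path; for ``csv``,
        the file path.
    format : {"wfdb", "csv"}
    fs : float, optional
        Required for CSV input (the file stores no rate); ignored for WFDB,
        where the rate comes from the header.
    lead : str
        Signal description to select from a multi-signal WFDB record.
    """
    path = Path(path)
    if format == "wfdb":
        samples, fs_hdr, lead_found = _read_wfdb(path, lead)
        meta = _read_header_comments(path.with_suffix(".hea"))
        return ECGRecord(
            subject_id=subject_id or meta.get("subject", path.stem),
            lead=lead_found,
            fs=fs_hdr,
            samples=samples,
            label=label if label is not None
            else (int(meta["label"]) if "label" in meta else None),
        )
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required when reading CSV (the file stores no rate)")
        if not path.exists():
            raise FileNotFoundError(path)
        samples = _read_csv(path)
        return ECGRecord(
            subject_id=subject_id or path.stem,
            lead=lead,
            fs=fs,
            samples=samples,
            label=label,
        )
    raise ValueError(f"unknown format {format!r}; expected 'wfdb' or 'csv'")


# --------------------------------------------------------------------------
# Segment bundles (npz + manifest CSV sidecar)
# --------------------------------------------------------------------------

def write_segments(segment_set: SegmentSet, path: str | os.PathLike) -> Path:
    """Persist a segment set as ``<base>.npz`` + ``<base>.manifest.csv``."""
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    arr = segment_set.to_array()
    np.savez_compressed(
        base.with_suffix(".npz"),
        samples=arr,
        fs=np.array(segment_set.fs),
        duration_s=np.array(segment_set.duration_s),
    )
    segment_set.manifest().to_csv(base.with_suffix(".manifest.csv"), index=False)
    return base.with_suffix(".npz")


def read_segments(path: str | os.PathLike) -> SegmentSet:
    """Load a segment bundle written by :func:`write_segments`."""
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    npz_path = base.with_suffix(".npz")
    man_path = base.with_suffix(".manifest.csv")
    if not npz_path.exists():
        raise FileNotFoundError(npz_path)
    if not man_path.exists():
        raise FileNotFoundError(f"manifest sidecar missing: {man_path}")
    with np.load(npz_path) as data:
        arr = data["samples"]
        fs = float(data["fs"])
        duration_s = int(data["duration_s"])
    manifest = pd.read_csv(man_path)
    required = {"subject_id", "start", "label"}
    if not required.issubset(manifest.columns):
        raise ValueError(
            f"corrupted manifest {man_path.name}: missing columns "
            f"{sorted(required - set(manifest.columns))}"
        )
    if len(manifest) != arr.shape[0]:
        raise ValueError(
            f"manifest/sample count mismatch: {len(manifest)} manifest rows "
            f"vs {arr.shape[0]} segments"
        )
    segments = [
        Segment(
            samples=arr[i],
            fs=fs,
            subject_id=str(row.subject_id),
            start=int(row.start),
            label=None if int(row.label) < 0 else int(row.label),
        )
        for i, row in enumerate(manifest.itertuples())
    ]
    return SegmentSet(segments=segments, duration_s=duration_s, fs=fs)
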