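"""Readers and writers for the pipeline's on-disk formats.

Covered formats:

* WFDB records (header + 16-bit signal file) holding one PCG and one ECG
  channel.  Only the subset of the WFDB spec this pipeline touches is
  implemented: format 16, per-channel gain/baseline, channel names in the
  description field.
* Reference label CSV in the PhysioNet-2016 dialect (``record,-1|1``).
* S1 heart-sound annotation CSV/TSV, sample- or second-indexed.
* A compressed segment archive (numpy ``.npz`` with a schema version).

All readers are total over the corresponding writers' output; see the
round-trip tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import (
    EmptyAnnotationError,
    FormatError,
    ModalityMissingError,
    SchemaVersionError,
)

TARGET_FS = 2000.0
ARCHIVE_VERSION = 1
_WFDB_FMT = 16
_INT16_MAX = 32767


@dataclass
class SyncRecord:
    """One synchronized two-modality recording.

    ``label`` is 0 (normal), 1 (abnormal) or ``None`` when unknown;
    ``s1_onsets`` are strictly increasing sample indices of the first
    heart sound, which mark cardiac-cycle boundaries.
    """

    record_id: str
    ecg: np.ndarray
    pcg: np.ndarray
    fs: float
    label: int | None = None
    s1_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    source: str = "real"

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.pcg = np.asarray(self.pcg, dtype=np.float64)
        self.s1_onsets = np.asarray(self.s1_onsets, dtype=np.int64)
        if self.ecg.shape != self.pcg.shape or self.ecg.ndim != 1:
            raise ValueError("ECG and PCG must be 1-D arrays of equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.s1_onsets.size:
            if np.any(np.diff(self.s1_onsets) <= 0):
                raise ValueError("S1 onsets must be strictly increasing")
            if self.s1_onsets[0] < 0 or self.s1_onsets[-1] >= len(self.ecg):
                raise ValueError("S1 onsets out of record bounds")

    def __len__(self):
        return len(self.ecg)


# ---------------------------------------------------------------------
# WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------

def write_wfdb(record: SyncRecord, directory: str | Path) -> Path:
    """Write ``record`` as ``<id>.hea`` + ``<id>.dat`` (format 16).

    Channel order mirrors the stethoscope dataset layout: PCG first,
    ECG second.  Each channel gets its own gain so the 16-bit
    quantization step is at most ``max|x| / 32000``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    channels = [("PCG", record.pcg), ("ECG", record.ecg)]
    n = len(record)
    adc = np.empty((n, len(channels)), dtype="<i2")
    lines = [f"{name} {len(channels)} {record.fs:g} {n}"]
    for j, (desc, x) in enumerate(channels):
        peak = float(np.max(np.abs(x))) if n else 0.0
        gain = 32000.0 / peak if peak > 0 else 200.0
        q = np.clip(np.rint(x * gain), -_INT16_MAX, _INT16_MAX).astype("<i2")
        adc[:, j] = q
        checksum = int(np.sum(q.astype(np.int64)) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        first = int(q[0]) if n else 0
        lines.append(
            f"{name}.dat {_WFDB_FMT} {gain:.12g}(0)/mV 16 0 {first} {checksum} 0 {desc}"
        )
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    return directory / f"{name}.hea"


def _parse_header(path: Path):
    try:
        raw = [
            ln.strip() for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        head = raw[0].split()
        name = head[0].split("/")[0]
        nsig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        nsamp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"unreadable WFDB header {path}: {exc}") from exc
    if len(raw) < 1 + nsig:
        raise FormatError(f"WFDB header {path}: expected {nsig} signal lines")
    signals = []
    for ln in raw[1:1 + nsig]:
        tok = ln.split()
        try:
            fname = tok[0]
            fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
            gain_spec = tok[2] if len(tok) > 2 else "200"
            gpart = gain_spec.split("/")[0]
            if "(" in gpart:
                gain = float(gpart[:gpart.index("(")])
                baseline = int(gpart[gpart.index("(") + 1:gpart.index(")")])
            else:
                gain = float(gpart)
                baseline = int(tok[4]) if len(tok) > 4 else 0
            desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        except (IndexError, ValueError) as exc:
            raise FormatError(f"bad signal line in {path}: {ln!r}") from exc
        if gain == 0:
            gain = 200.0
        signals.append({"file": fname, "fmt": fmt, "gain": gain,
                        "baseline": baseline, "desc": desc})
    return name, nsig, fs, nsamp, signals


def _pick_channels(signals, channel_map):
    """Channel selection: case-insensitive substring match on the signal
    description, falling back to explicit indices in ``channel_map``."""
    found = {}
    for want in ("pcg", "ecg"):
        for j, sig in enumerate(signals):
            if want in sig["desc"].lower():
                found[want] = j
                break
    if channel_map:
        for want in ("pcg", "ecg"):
            if want not in found and want in channel_map:
                idx = channel_map[want]
                if 0 <= idx < len(signals):
                    found[want] = idx
    return found


def read_wfdb_record(path: str | Path,
                     channel_map: dict[str, int] | None = None) -> SyncRecord:
    """Read a two-channel WFDB record and return it at 2,000 Hz.

    ``path`` may point at the ``.hea`` file or the record stem.  Raises
    :class:`ModalityMissingError` when no ECG (or PCG) channel can be
    identified — the real dataset contains a few PCG-only records.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    name, nsig, fs, nsamp, signals = _parse_header(path)
    if nsig < 2:
        missing = "ECG" if any("pcg" in s["desc"].lower() for s in signals) else "ECG/PCG"
        raise ModalityMissingError(f"record {name}: {missing} channel absent")
    found = _pick_channels(signals, channel_map)
    for want in ("ecg", "pcg"):
        if want not in found:
            raise ModalityMissingError(f"record {name}: no {want.upper()} channel")
    dat = path.with_name(signals[0]["file"])
    if {s["fmt"] for s in signals} != {_WFDB_FMT}:
        raise FormatError(f"record {name}: only format 16 is supported")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if nsamp and raw.size != nsamp * nsig:
        raise FormatError(f"record {name}: signal file size mismatch")
    adc = raw.reshape(-1, nsig)

    def physical(j):
        s = signals[j]
        return (adc[:, j].astype(np.float64) - s["baseline"]) / s["gain"]

    ecg, pcg = physical(found["ecg"]), physical(found["pcg"])
    if fs != TARGET_FS:
        frac = Fraction(TARGET_FS / fs).limit_denominator(10000)
        ecg = resample_poly(ecg, frac.numerator, frac.denominator)
        pcg = resample_poly(pcg, frac.numerator, frac.denominator)
    return SyncRecord(record_id=name, ecg=ecg, pcg=pcg, fs=TARGET_FS)


# ---------------------------------------------------------------------
# reference labels
# ---------------------------------------------------------------------

def read_reference(csv_path: str | Path) -> dict[str, int]:
    """Read a ``record,-1|1`` reference CSV; -1 -> 0 (normal), 1 -> 1."""
    mapping: dict[str, int] = {}
    with open(csv_path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(f"{csv_path}:{i}: expected two columns")
            token = row[1].strip()
            if i == 1 and not token.lstrip("-").isdigit():
                continue  # tolerate a header line
            if token == "1":
                mapping[row[0].strip()] = 1
            elif token == "-1":
                mapping[row[0].strip()] = 0
            else:
                raise FormatError(
                    f"{csv_path}:{i}: unknown label token {token!r}"
                )
    return mapping


def write_reference(labels: dict[str, int], csv_path: str | Path) -> None:
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        for rid in sorted(labels):
            w.writerow([rid, 1 if labels[rid] == 1 else -1])


# ---------------------------------------------------------------------
# S1 annotations
# ---------------------------------------------------------------------

def read_s1_annotations(path: str | Path, fs: float = TARGET_FS) -> np.ndarray:
    """Read heart-sound annotations and return sorted unique S1 sample indices.

    The position column is auto-detected from the header: a name
    containing ``sample`` is read as sample indices, one containing
    ``time`` or ``second`` as seconds (converted with ``fs``).  The
    state column is the one containing ``label`` or ``state`` (falling
    back to the second column).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a position and a state column")
    cols = {str(c).strip().lower(): c for c in df.columns}
    pos_col = state_col = None
    in_seconds = False
    for key, c in cols.items():
        if "sample" in key:
            pos_col, in_seconds = c, False
        elif "time" in key or "second" in key:
            pos_col, in_seconds = c, True
    for key, c in cols.items():
        if "label" in key or "state" in key or "type" in key:
            state_col = c
    if pos_col is None:
        pos_col = df.columns[0]
        in_seconds = not np.issubdtype(df[pos_col].dtype, np.integer)
    if state_col is None:
        state_col = df.columns[1]
    states = df[state_col].astype(str).str.strip().str.upper()
    rows = df.loc[states == "S1", pos_col].to_numpy(dtype=np.float64)
    if rows.size == 0:
        raise EmptyAnnotationError(f"{path}: no S1 annotations")
    samples = np.rint(rows * fs).astype(np.int64) if in_seconds \
        else np.rint(rows).astype(np.int64)
    return np.unique(samples)


def write_s1_annotations(onsets: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "label"])
        for s in np.asarray(onsets, dtype=np.int64):
            w.writerow([int(s), "S1"])


# ---------------------------------------------------------------------
# segment archive
# ---------------------------------------------------------------------

def write_segment_archive(dataset, path: str | Path) -> None:
    """Write a :class:`~cardiofuse.preprocessing.SegmentDataset` losslessly."""
    segs = dataset.segments
    n = len(segs)
    length = segs[0].ecg.shape[0] if n else 0
    ecg = np.stack([s.ecg for s in segs]) if n else np.zeros((0, length))
    pcg = np.stack([s.pcg for s in segs]) if n else np.zeros((0, length))
    np.savez_compressed(
        path,
        schema_version=np.int64(ARCHIVE_VERSION),
        ecg=ecg,
        pcg=pcg,
        label=np.array([s.label for s in segs], dtype=np.int64),
        record_id=np.array([s.record_id for s in segs], dtype="U64"),
        beat_index=np.array([s.beat_index for s in segs], dtype=np.int64),
        fold=np.asarray(dataset.fold_of, dtype=np.int64)
        if dataset.fold_of is not None else np.full(n, -1, dtype=np.int64),
    )


def read_segment_archive(path: str | Path):
    from .preprocessing import BeatSegment, SegmentDataset

    with np.load(path, allow_pickle=False) as z:
        version = int(z["schema_version"])
        if version > ARCHIVE_VERSION:
            raise SchemaVersionError(
                f"{path}: archive schema {version} is newer than supported "
                f"({ARCHIVE_VERSION})"
            )
        segs = [
            BeatSegment(
                ecg=z["ecg"][i], pcg=z["pcg"][i], label=int(z["label"][i]),
                record_id=str(z["record_id"][i]),
                beat_index=int(z["beat_index"][i]),
            )
            for i in range(z["ecg"].shape[0])
        ]
        fold = z["fold"]
        fold_of = None if (fold.size and np.all(fold < 0)) or fold.size == 0 \
            else fold.copy()
    return SegmentDataset(segments=segs, fold_of=fold_of)


# ---------------------------------------------------------------------
# directory-level helpers
# ---------------------------------------------------------------------

def dataset_census(directory: str | Path,
                   reference: dict[str, int] | None = None) -> dict:
    """Count records and synchronized ECG+PCG pairs in a WFDB directory."""
    directory = Path(directory)
    n_records = n_pairs = 0
    per_label = {0: 0, 1: 0}
    for hea in sorted(directory.glob("*.hea")):
        n_records += 1
        try:
            _, nsig, _, _, signals = _parse_header(hea)
        except FormatError:
            continue
        found = _pick_channels(signals, None)
        if "ecg" in found and "pcg" in found:
            n_pairs += 1
            if reference and hea.stem in reference:
                per_label[reference[hea.stem]] += 1
    out = {"records": n_records, "synchronized_pairs": n_pairs}
    if reference:
        out["normal_pairs"] = per_label[0]
        out["abnormal_pairs"] = per_label[1]
    return out
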