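"""Data containers and plain-text I/O for synchronized ECG + accelerometer records.

A :class:`Recording` holds one ECG channel (250 Hz by default) together with a
triaxial accelerometer (25 Hz by default) sharing the same start time.
Annotations (QRS complexes, motion segments, artifact labels) are half-open,
0-based sample-index intervals collected in an :class:`IntervalSet`.

On disk a recording is a directory with ``ecg.csv`` (columns ``time, ecg``),
``acc.csv`` (``time, acc_x, acc_y, acc_z``) and a ``meta.json`` with sampling
rates, or a single CSV with all five columns where accelerometer rows are
sparse (empty at non-accelerometer sample times).  A minimal reader for WFDB
records (header plus format-16 signal file) is also provided.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "IntervalSet",
    "load_recording",
    "save_recording",
    "load_intervals",
    "save_intervals",
]


class FormatError(ValueError):
    """A file does not follow the expected schema."""


class ConsistencyError(ValueError):
    """Channel metadata and data lengths disagree."""


@dataclass
class Recording:
    """Synchronized single-lead ECG and triaxial accelerometer series.

    Parameters
    ----------
    ecg : ndarray
        ECG samples in millivolts at ``fs_ecg``.
    acc_x, acc_y, acc_z : ndarray
        Accelerometer components (g or m/s^2) at ``fs_acc``; equal lengths.
    fs_ecg, fs_acc : float
        Sampling rates in Hz. The implied durations of the two channel groups
        must agree within one accelerometer sample period.
    start_time : float
        Offset of the first sample, in seconds.
    identifier : str
        Free-text record label.
    """

    ecg: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    fs_ecg: float = 250.0
    fs_acc: float = 25.0
    start_time: float = 0.0
    identifier: str = ""

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.acc_x = np.asarray(self.acc_x, dtype=float)
        self.acc_y = np.asarray(self.acc_y, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)
        if self.fs_ecg <= 0 or self.fs_acc <= 0:
            raise ValueError("sampling rates must be positive")
        if not (len(self.acc_x) == len(self.acc_y) == len(self.acc_z)):
            raise ConsistencyError("accelerometer components differ in length")
        d_ecg = len(self.ecg) / self.fs_ecg
        d_acc = len(self.acc_x) / self.fs_acc
        if abs(d_ecg - d_acc) > 1.0 / self.fs_acc + 1e-9:
            raise ConsistencyError(
                f"ECG duration {d_ecg:.3f}s and accelerometer duration "
                f"{d_acc:.3f}s disagree beyond one accelerometer sample"
            )

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs_ecg

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) view of the accelerometer components."""
        return np.column_stack([self.acc_x, self.acc_y, self.acc_z])


def _normalize_pairs(pairs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Sort intervals and merge any that overlap. Returns (array, changed)."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        return pairs, False
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    merged: list[list[int]] = [list(pairs[0])]
    overlapped = False
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            overlapped = overlapped or s < merged[-1][1]
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    out = np.array(merged, dtype=np.int64)
    changed = overlapped or not np.array_equal(out, pairs)
    return out, changed


@dataclass
class IntervalSet:
    """Ordered, disjoint half-open ``[start, end)`` sample-index intervals.

    Indices are 0-based on a series sampled at ``fs`` Hz. Construction
    normalizes the input: intervals are sorted and overlapping ones merged.
    """

    intervals: np.ndarray
    fs: float
    label: str = ""
    n_samples: int | None = None

    def __post_init__(self) -> None:
        pairs = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(pairs) and np.any(pairs[:, 0] >= pairs[:, 1]):
            raise ValueError("intervals must satisfy start < end")
        if len(pairs) and np.any(pairs[:, 0] < 0):
            raise ValueError("interval starts must be >= 0")
        if self.n_samples is not None and len(pairs) and pairs[:, 1].max() > self.n_samples:
            raise ValueError("interval end exceeds series length")
        self.intervals, _ = _normalize_pairs(pairs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @classmethod
    def from_mask(cls, mask: np.ndarray, fs: float, label: str = "") -> "IntervalSet":
        """Build the maximal runs of True in a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        diff = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if mask.size and mask[0]:
            starts = np.r_[0, starts]
        if mask.size and mask[-1]:
            ends = np.r_[ends, mask.size]
        pairs = np.column_stack([starts, ends]) if len(starts) else np.empty((0, 2), int)
        return cls(pairs, fs=fs, label=label, n_samples=mask.size)

    def to_mask(self, n: int | None = None) -> np.ndarray:
        if n is None:
            n = self.n_samples
        if n is None:
            raise ValueError("series length unknown; pass n")
        mask = np.zeros(n, dtype=bool)
        for s, e in self.intervals:
            mask[s:min(e, n)] = True
        return mask

    def dilate(self, pad_s: float, n_samples: int | None = None) -> "IntervalSet":
        """Grow every interval by ``pad_s`` seconds on both sides and re-merge."""
        n = n_samples if n_samples is not None else self.n_samples
        pad = int(round(pad_s * self.fs))
        pairs = self.intervals.copy()
        if len(pairs):
            pairs[:, 0] = np.maximum(pairs[:, 0] - pad, 0)
            pairs[:, 1] = pairs[:, 1] + pad
            if n is not None:
                pairs[:, 1] = np.minimum(pairs[:, 1], n)
        return IntervalSet(pairs, fs=self.fs, label=self.label, n_samples=n)

    def rescale(self, fs_new: float) -> "IntervalSet":
        """Map the intervals onto a series sampled at ``fs_new`` Hz."""
        r = fs_new / self.fs
        pairs = self.intervals.astype(float)
        pairs = np.column_stack([np.floor(pairs[:, 0] * r), np.ceil(pairs[:, 1] * r)])
        n = None if self.n_samples is None else int(round(self.n_samples * r))
        return IntervalSet(pairs.astype(np.int64), fs=fs_new, label=self.label, n_samples=n)

    def complement(self, n: int | None = None) -> "IntervalSet":
        return IntervalSet.from_mask(~self.to_mask(n), fs=self.fs,
                                     label=f"not-{self.label}" if self.label else "")

    def total_samples(self) -> int:
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if len(self) else 0


# ---------------------------------------------------------------------------
# recordings

_REQ_COLS = ("time", "ecg", "acc_x", "acc_y", "acc_z")


def _infer_fs(t: np.ndarray) -> float:
    if len(t) < 2:
        raise FormatError("need at least two samples to infer a sampling rate")
    fs = 1.0 / float(np.median(np.diff(t)))
    return round(fs, 6)


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a directory of ``ecg.csv``, ``acc.csv``, ``meta.json``.

    Sample values are written with full repr precision so that a save/load
    round trip is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t_ecg = rec.start_time + np.arange(len(rec.ecg)) / rec.fs_ecg
    t_acc = rec.start_time + np.arange(len(rec.acc_x)) / rec.fs_acc
    # %.17g guarantees binary64 round-trips exactly through the text file
    pd.DataFrame({"time": t_ecg, "ecg": rec.ecg}).to_csv(
        path / "ecg.csv", index=False, float_format="%.17g")
    pd.DataFrame({
        "time": t_acc, "acc_x": rec.acc_x, "acc_y": rec.acc_y, "acc_z": rec.acc_z,
    }).to_csv(path / "acc.csv", index=False, float_format="%.17g")
    meta = {"fs_ecg": rec.fs_ecg, "fs_acc": rec.fs_acc,
            "start_time": rec.start_time, "identifier": rec.identifier}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _load_csv_dir(path: Path) -> Recording:
    ecg_df = pd.read_csv(path / "ecg.csv", float_precision="round_trip")
    acc_df = pd.read_csv(path / "acc.csv", float_precision="round_trip")
    for col in ("time", "ecg"):
        if col not in ecg_df.columns:
            raise FormatError(f"ecg.csv missing column {col!r}")
    for col in ("time", "acc_x", "acc_y", "acc_z"):
        if col not in acc_df.columns:
            raise FormatError(f"acc.csv missing column {col!r}")
    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"fs_ecg": _infer_fs(ecg_df["time"].to_numpy()),
                "fs_acc": _infer_fs(acc_df["time"].to_numpy()),
                "start_time": float(ecg_df["time"].iloc[0]), "identifier": path.name}
    return Recording(
        ecg=ecg_df["ecg"].to_numpy(),
        acc_x=acc_df["acc_x"].to_numpy(), acc_y=acc_df["acc_y"].to_numpy(),
        acc_z=acc_df["acc_z"].to_numpy(),
        fs_ecg=float(meta["fs_ecg"]), fs_acc=float(meta["fs_acc"]),
        start_time=float(meta.get("start_time", 0.0)),
        identifier=str(meta.get("identifier", "")),
    )


def _load_csv_single(path: Path) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQ_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name} missing column(s) {missing}")
    acc_rows = df.dropna(subset=["acc_x", "acc_y", "acc_z"])
    fs_ecg = _infer_fs(df["time"].to_numpy())
    fs_acc = _infer_fs(acc_rows["time"].to_numpy())
    return Recording(
        ecg=df["ecg"].to_numpy(),
        acc_x=acc_rows["acc_x"].to_numpy(), acc_y=acc_rows["acc_y"].to_numpy(),
        acc_z=acc_rows["acc_z"].to_numpy(),
        fs_ecg=fs_ecg, fs_acc=fs_acc,
        start_time=float(df["time"].iloc[0]), identifier=path.stem,
    )


def _load_wfdb(path: Path) -> Recording:
    """Minimal WFDB reader: header file plus a single format-16 signal file.

    Signals named (case-insensitively) ``ecg``/``acc_x``/``acc_y``/``acc_z``
    are picked up; accelerometer channels, when present, are stored at the
    record's sampling rate. Absent accelerometer channels become zeros.
    """
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nsig, fs, nsamp = int(head[1]), float(head[2]), int(head[3])
    sig_specs = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part.split("(")[0])
            baseline = float(gain_part.split("(")[1].rstrip(")"))
        else:
            gain, baseline = float(gain_part), 0.0
        desc = tok[8] if len(tok) > 8 else f"sig{len(sig_specs)}"
        sig_specs.append((fname, gain or 200.0, baseline, desc.lower()))
    dat = path.parent / sig_specs[0][0]
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw[: nsamp * nsig].reshape(-1, nsig)
    channels = {}
    for i, (_, gain, baseline, desc) in enumerate(sig_specs):
        channels[desc] = (raw[:, i].astype(float) - baseline) / gain
    if "ecg" not in channels:
        raise FormatError("WFDB record has no channel described as 'ecg'")
    ecg = channels["ecg"]
    if all(k in channels for k in ("acc_x", "acc_y", "acc_z")):
        ax, ay, az = channels["acc_x"], channels["acc_y"], channels["acc_z"]
        fs_acc = fs
    else:
        fs_acc = fs / 10.0
        n_acc = int(round(len(ecg) * fs_acc / fs))
        ax = ay = az = np.zeros(n_acc)
    return Recording(ecg=ecg, acc_x=ax, acc_y=ay, acc_z=az,
                     fs_ecg=fs, fs_acc=fs_acc, identifier=path.stem)


def load_recording(path: str | Path, format: str = "csv") -> Recording:
    """Load a recording from ``path``.

    ``format='csv'`` accepts either a directory (``ecg.csv`` + ``acc.csv``)
    or a single CSV with sparse accelerometer rows; ``format='wfdb'`` reads a
    WFDB header/signal pair (16-bit format only).
    """
    path = Path(path)
    if format == "csv":
        if path.is_dir():
            return _load_csv_dir(path)
        if path.exists():
            return _load_csv_single(path)
        raise FileNotFoundError(path)
    if format == "wfdb":
        return _load_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# interval annotations

def save_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write an interval annotation CSV (indices plus their times in seconds)."""
    raw = np.asarray(intervals.intervals)
    norm, changed = _normalize_pairs(raw)
    if changed:
        warnings.warn("overlapping/unsorted intervals normalized on write")
    df = pd.DataFrame({
        "label": intervals.label,
        "start_index": norm[:, 0] if len(norm) else np.array([], int),
        "end_index": norm[:, 1] if len(norm) else np.array([], int),
    })
    df["start_seconds"] = df["start_index"] / intervals.fs
    df["end_seconds"] = df["end_index"] / intervals.fs
    df.insert(0, "fs", intervals.fs)
    df.to_csv(path, index=False)


def load_intervals(path: str | Path, fs: float | None = None) -> IntervalSet:
    df = pd.read_csv(path)
    for col in ("start_index", "end_index"):
        if col not in df.columns:
            raise FormatError(f"interval file missing column {col!r}")
    if fs is None:
        fs = float(df["fs"].iloc[0]) if ("fs" in df.columns and len(df)) else 250.0
    label = str(df["label"].iloc[0]) if ("label" in df.columns and len(df)) else ""
    pairs = df[["start_index", "end_index"]].to_numpy(dtype=np.int64)
    return IntervalSet(pairs, fs=fs, label=label)
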