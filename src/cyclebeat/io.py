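"""Reading and writing single-lead ECG records.

Two on-disk representations are supported:

* WFDB (``.hea`` header, ``.dat`` signal in format 16, optional ``.atr``
  MIT-style annotations), the format used by PhysioNet databases.  Only a
  single lead is ever loaded; multi-lead files are reduced to the requested
  channel at read time.
* An internal HDF5 container that round-trips :class:`ECGRecord` losslessly.

Sample indices are 0-based throughout; sample ``k`` occurs at ``k / fs``
seconds.  Signals are stored and exchanged in millivolts.  No filtering or
normalisation is applied anywhere in this module.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "ECGRecord",
    "BeatAnnotation",
    "RHYTHM_LABELS",
    "read_wfdb_record",
    "write_wfdb_record",
    "write_internal",
    "read_internal",
    "export_csv",
]

RHYTHM_LABELS = ("NSR", "AF", "OTHER", "NOISY")

# MIT annotation type codes (subset sufficient for beat + rhythm streams)
_ANN_NORMAL = 1
_ANN_RHYTHM = 28
_ANN_SKIP = 59
_ANN_NUM = 60
_ANN_SUB = 61
_ANN_CHN = 62
_ANN_AUX = 63
_BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38, 41}


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated heartbeat: its sample index and AF membership."""

    sample_index: int
    af_flag: bool


@dataclass
class ECGRecord:
    """One lead of an ECG recording with its time base and labels.

    Parameters
    ----------
    record_id : str
        Identifier of the source recording.
    samples : ndarray
        Signal values in millivolts.
    fs : float
        Sampling frequency in Hz, strictly positive.
    rhythm_label : str, optional
        Record-level rhythm class, one of ``NSR``, ``AF``, ``OTHER``,
        ``NOISY``.
    beat_annotations : list of BeatAnnotation, optional
        Per-beat annotations with strictly increasing sample indices.
    source_lead : int
        Channel of the original file this lead came from.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    rhythm_label: Optional[str] = None
    beat_annotations: Optional[list[BeatAnnotation]] = None
    source_lead: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array (one lead)")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.rhythm_label is not None and self.rhythm_label not in RHYTHM_LABELS:
            raise ValueError(
                f"rhythm_label must be one of {RHYTHM_LABELS}, got {self.rhythm_label!r}"
            )
        if self.source_lead < 0:
            raise ValueError("source_lead must be non-negative")
        if self.beat_annotations is not None:
            idx = [a.sample_index for a in self.beat_annotations]
            if any(i < 0 or i >= self.samples.size for i in idx):
                raise ValueError("beat annotation index out of signal range")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("beat annotation indices must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds (0-based convention)."""
        return np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# WFDB


def _parse_gain_field(tok: str) -> tuple[float, float]:
    """Parse a WFDB ``gain(baseline)/units`` token -> (gain, baseline).

    A missing or zero gain means the stored integers are already mV.
    """
    tok = tok.split("/")[0]
    baseline = 0.0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(tok) if tok else 0.0
    if gain == 0.0:
        gain = 1.0  # degrade gracefully: raw integers treated as mV
    return gain, baseline


def read_wfdb_record(path: str, lead: int = 0) -> ECGRecord:
    """Read one lead of a WFDB record as an :class:`ECGRecord`.

    ``path`` is the record path without extension (``.hea``/``.dat`` and,
    if present, ``.atr`` are derived from it).  The stored integers are
    converted to millivolts with the header gain and baseline.  When an
    annotation file exists, beat annotations are returned with an
    ``af_flag`` derived by tracking ``(AFIB`` rhythm-change annotations.
    """
    hea_path = path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    with open(hea_path) as fh:
        lines = [
            ln.strip()
            for ln in fh
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
    head = lines[0].split()
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if not 0 <= lead < n_sig:
        raise ValueError(f"lead {lead} out of range for {n_sig}-lead record")
    sig_lines = [ln.split() for ln in lines[1 : 1 + n_sig]]
    dat_name = sig_lines[lead][0]
    fmt = sig_lines[lead][1].split("x")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain, baseline = (
        _parse_gain_field(sig_lines[lead][2]) if len(sig_lines[lead]) > 2 else (1.0, 0.0)
    )
    dat_path = os.path.join(os.path.dirname(hea_path), dat_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    frames = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    samples = (frames[:, lead].astype(np.float64) - baseline) / gain

    beats = None
    atr_path = path + ".atr"
    if os.path.exists(atr_path):
        anns = _read_annotations(atr_path)
        beats = annotations_to_beats(anns)
    return ECGRecord(
        record_id=record_id,
        samples=samples,
        fs=fs,
        beat_annotations=beats,
        source_lead=lead,
    )


def annotations_to_beats(
    annotations: Sequence[tuple[int, int, str]],
) -> Optional[list[BeatAnnotation]]:
    """Map a raw annotation stream to per-beat AF flags.

    ``annotations`` are ``(sample_index, type_code, aux)`` triples in file
    order.  Rhythm-change annotations whose aux text starts with ``(AFIB``
    switch the running rhythm state to AF; any other rhythm aux switches it
    off; beat annotations inherit the current state.  This is one policy for
    turning rhythm-change streams into beat labels — callers with different
    conventions can consume the raw stream instead.
    """
    beats: list[BeatAnnotation] = []
    in_af = False
    for sample, code, aux in annotations:
        if code == _ANN_RHYTHM:
            in_af = aux.startswith("(AFIB")
        elif code in _BEAT_CODES:
            beats.append(BeatAnnotation(sample_index=sample, af_flag=in_af))
    return beats or None


def _read_annotations(path: str) -> list[tuple[int, int, str]]:
    data = np.fromfile(path, dtype="<u2")
    out: list[tuple[int, int, str]] = []
    t = 0
    i = 0
    pending_aux = ""
    while i < data.size:
        word = int(data[i])
        code, interval = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and interval == 0:
            break
        if code == _ANN_SKIP and interval == 0:
            t += (int(data[i]) << 16) | int(data[i + 1])
            i += 2
        elif code == _ANN_AUX:
            n = interval
            raw = data[i : i + (n + 1) // 2].tobytes()[:n]
            i += (n + 1) // 2
            aux = raw.decode("utf-8", errors="replace")
            if out:
                out[-1] = (out[-1][0], out[-1][1], aux)
            else:
                pending_aux = aux
        elif code in (_ANN_NUM, _ANN_SUB, _ANN_CHN):
            pass
        else:
            t += interval
            out.append((t, code, pending_aux))
            pending_aux = ""
    return out


def write_wfdb_record(
    record: ECGRecord,
    path: str,
    gain: float = 200.0,
    extra_leads: Optional[np.ndarray] = None,
) -> None:
    """Write an :class:`ECGRecord` as a WFDB record (format 16).

    ``extra_leads`` (shape ``(n_extra, n_samples)``, mV) may be supplied to
    produce a multi-lead file for testing lead selection.  Annotations are
    written to ``.atr`` when present: one NORMAL beat annotation per beat,
    with ``(AFIB`` / ``(N`` rhythm-change annotations at AF state switches.
    """
    leads = [np.asarray(record.samples, dtype=np.float64)]
    if extra_leads is not None:
        extra = np.atleast_2d(np.asarray(extra_leads, dtype=np.float64))
        leads.extend(list(extra))
    n_sig = len(leads)
    name = os.path.basename(path)
    dat_name = name + ".dat"
    digital = np.stack(
        [np.clip(np.round(x * gain), -32768, 32767).astype("<i2") for x in leads], axis=1
    )
    with open(path + ".hea", "w") as fh:
        fh.write(f"{name} {n_sig} {record.fs:g} {record.samples.size}\n")
        for _ in range(n_sig):
            fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 ECG\n")
    digital.tofile(path + ".dat")
    if record.beat_annotations:
        _write_annotations(path + ".atr", record.beat_annotations)


def _write_annotations(path: str, beats: Sequence[BeatAnnotation]) -> None:
    words = bytearray()

    def emit(code: int, interval: int) -> None:
        words.extend(struct.pack("<H", (code << 10) | interval))

    def emit_time(code: int, delta: int) -> None:
        if delta > 0x3FF:
            emit(_ANN_SKIP, 0)
            words.extend(struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF))
            emit(code, 0)
        else:
            emit(code, delta)

    def emit_aux(text: str) -> None:
        raw = text.encode("utf-8")
        emit(_ANN_AUX, len(raw))
        if len(raw) % 2:
            raw += b"\x00"
        words.extend(raw)

    t = 0
    state: Optional[bool] = None
    for beat in beats:
        delta = beat.sample_index - t
        if beat.af_flag != state:
            emit_time(_ANN_RHYTHM, delta)
            emit_aux("(AFIB" if beat.af_flag else "(N")
            delta = 0
            state = beat.af_flag
        emit_time(_ANN_NORMAL, delta)
        t = beat.sample_index
    emit(0, 0)
    with open(path, "wb") as fh:
        fh.write(bytes(words))


# ---------------------------------------------------------------------------
# Internal HDF5 container


def write_internal(record: ECGRecord, path: str) -> None:
    """Write an :class:`ECGRecord` to the internal HDF5 container.

    The round trip through :func:`read_internal` is lossless: samples are
    stored as 64-bit floats, annotations in order.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=record.samples, dtype=np.float64)
        f.attrs["fs"] = float(record.fs)
        f.attrs["record_id"] = record.record_id
        f.attrs["source_lead"] = int(record.source_lead)
        if record.rhythm_label is not None:
            f.attrs["rhythm_label"] = record.rhythm_label
        if record.beat_annotations is not None:
            f.create_dataset(
                "beat_idx",
                data=np.array([a.sample_index for a in record.beat_annotations], dtype=np.int64),
            )
            f.create_dataset(
                "beat_af",
                data=np.array([a.af_flag for a in record.beat_annotations], dtype=bool),
            )


def read_internal(path: str) -> ECGRecord:
    """Read an :class:`ECGRecord` from the internal HDF5 container.

    Malformed files raise :class:`ValueError` naming the offending field.
    """
    with h5py.File(path, "r") as f:
        for key in ("samples",):
            if key not in f:
                raise ValueError(f"malformed internal file: missing dataset '{key}'")
        for key in ("fs", "record_id"):
            if key not in f.attrs:
                raise ValueError(f"malformed internal file: missing attribute '{key}'")
        samples = np.asarray(f["samples"], dtype=np.float64)
        beats = None
        if "beat_idx" in f:
            idx = np.asarray(f["beat_idx"], dtype=np.int64)
            if "beat_af" not in f or len(f["beat_af"]) != idx.size:
                raise ValueError("malformed internal file: field 'beat_af' missing or mismatched")
            af = np.asarray(f["beat_af"], dtype=bool)
            if np.any(np.diff(idx) <= 0):
                raise ValueError("malformed internal file: field 'beat_idx' not strictly increasing")
            beats = [BeatAnnotation(int(i), bool(a)) for i, a in zip(idx, af)]
        try:
            return ECGRecord(
                record_id=str(f.attrs["record_id"]),
                samples=samples,
                fs=float(f.attrs["fs"]),
                rhythm_label=str(f.attrs["rhythm_label"]) if "rhythm_label" in f.attrs else None,
                beat_annotations=beats,
                source_lead=int(f.attrs.get("source_lead", 0)),
            )
        except ValueError as exc:
            raise ValueError(f"malformed internal file: {exc}") from exc


def export_csv(record: ECGRecord, path: str) -> None:
    """Export the signal as a two-column CSV (t_seconds, mv) for inspection."""
    out = np.column_stack([record.times, record.samples])
    np.savetxt(path, out, fmt="%.9g", delimiter=",", header="t_seconds,mv", comments="")
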