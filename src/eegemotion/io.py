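"""File formats: EDF (European Data Format) and delimited text, plus manifests.

EDF files are written with one file per subject, one signal per channel
(label = bipolar channel name, physical dimension uV) and one 10-s data
record per window, 16-bit samples.  The writer/reader here implement the
standard fixed-layout EDF header (256 bytes + 256 per signal, ASCII,
space-padded) directly; malformed headers are reported with the byte
offset of the offending field, and a truncated file yields an error
rather than partial data.

Delimited text is one file per segment with header ``sample_index,value_uV``
(UTF-8, comma separator, dot decimal — no locale variants).  Either format
is accompanied by a ``manifest.csv`` mapping every
(subject, emotion, video, segment, channel) record to its file location.

The recording start date written into EDF headers is a fixed placeholder
(01.01.2000): synthetic data has no acquisition time, and a constant keeps
outputs byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .subband import Segment

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = (
    "subject", "emotion", "video", "segment", "channel", "sampling_rate", "file", "record",
)
_EDF_DATE = "01.01.00"
_EDF_TIME = "00.00.00"
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    signals: Mapping[str, np.ndarray],
    sampling_rate: float,
    record_seconds: float,
    physical_dimension: str = "uV",
) -> None:
    """Write one EDF file.

    ``signals`` maps channel labels to (n_records, samples_per_record)
    arrays in physical units; all channels must share the same shape.
    """
    labels = list(signals)
    if not labels:
        raise InputError("no signals to write")
    arrays = [np.atleast_2d(np.asarray(signals[lab], float)) for lab in labels]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise InputError("all signals must share (n_records, samples_per_record)")
    n_records, spr = arrays[0].shape

    ns = len(labels)
    header_bytes = 256 + 256 * ns
    pmins, pmaxs, digital = [], [], []
    for a in arrays:
        pmin, pmax = float(a.min()), float(a.max())
        if pmin == pmax:  # constant signal: EDF needs a nonzero physical range
            pmin, pmax = pmin - 1.0, pmax + 1.0
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((a - pmin) * scale + _DIG_MIN).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        digital.append(dig)

    def _num(x: float) -> str:
        s = f"{x:.8g}"
        return s[:8]

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))                     # patient id
        fh.write(_pad("Startdate 01-JAN-2000 X X X", 80))  # recording id
        fh.write(_pad(_EDF_DATE, 8))
        fh.write(_pad(_EDF_TIME, 8))
        fh.write(_pad(header_bytes, 8))
        fh.write(_pad("", 44))
        fh.write(_pad(n_records, 8))
        fh.write(_pad(_num(record_seconds), 8))
        fh.write(_pad(ns, 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("", 80))                         # transducer
        for _ in labels:
            fh.write(_pad(physical_dimension, 8))
        for p in pmins:
            fh.write(_pad(_num(p), 8))
        for p in pmaxs:
            fh.write(_pad(_num(p), 8))
        for _ in labels:
            fh.write(_pad(_DIG_MIN, 8))
        for _ in labels:
            fh.write(_pad(_DIG_MAX, 8))
        for _ in labels:
            fh.write(_pad("", 80))                         # prefiltering
        for _ in labels:
            fh.write(_pad(spr, 8))
        for _ in labels:
            fh.write(_pad("", 32))
        for r in range(n_records):
            for dig in digital:
                fh.write(dig[r].tobytes())


def _ascii_field(raw: bytes, offset: int, width: int, kind: str, numeric: bool = False):
    chunk = raw[offset : offset + width]
    if len(chunk) < width:
        raise FormatError(
            f"EDF header truncated: field '{kind}' at byte offset {offset} incomplete"
        )
    try:
        text = chunk.decode("ascii").strip()
    except UnicodeDecodeError:
        raise FormatError(
            f"EDF header field '{kind}' at byte offset {offset} is not ASCII"
        ) from None
    if numeric:
        try:
            return float(text)
        except ValueError:
            raise FormatError(
                f"EDF header field '{kind}' at byte offset {offset} is not numeric: {text!r}"
            ) from None
    return text


def read_edf(path) -> tuple[dict[str, np.ndarray], float, float]:
    """Read one EDF file written by :func:`write_edf` (or compatible).

    Returns (signals, sampling_rate, record_seconds) with signals mapping
    each channel label to a (n_records, samples_per_record) float array in
    physical units.  Any malformed header field or truncated payload
    raises :class:`FormatError`; no partial data is returned.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: EDF fixed header truncated at byte offset {len(raw)}")
    header_bytes = int(_ascii_field(raw, 184, 8, "header bytes", numeric=True))
    n_records = int(_ascii_field(raw, 236, 8, "number of data records", numeric=True))
    duration = _ascii_field(raw, 244, 8, "record duration", numeric=True)
    ns = int(_ascii_field(raw, 252, 4, "signal count", numeric=True))
    if ns < 1:
        raise FormatError("EDF header at byte offset 252: signal count must be >= 1")
    if header_bytes != 256 + 256 * ns:
        raise FormatError(
            f"EDF header bytes field at offset 184 ({header_bytes}) inconsistent "
            f"with signal count {ns}"
        )
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: EDF signal headers truncated at byte offset {len(raw)}")

    def _per_signal(block_offset: int, width: int, numeric: bool, kind: str):
        base = 256 + block_offset * ns
        return [
            _ascii_field(raw, base + i * width, width, f"{kind}[{i}]", numeric)
            for i in range(ns)
        ]

    # per-signal header blocks, in on-disk order
    labels = [
        _ascii_field(raw, 256 + 16 * i, 16, f"label[{i}]") for i in range(ns)
    ]
    off = 256 + ns * (16 + 80 + 8)  # skip transducer + dimension blocks
    pmins = [_ascii_field(raw, off + 8 * i, 8, f"physical min[{i}]", True) for i in range(ns)]
    off += 8 * ns
    pmaxs = [_ascii_field(raw, off + 8 * i, 8, f"physical max[{i}]", True) for i in range(ns)]
    off += 8 * ns
    dmins = [_ascii_field(raw, off + 8 * i, 8, f"digital min[{i}]", True) for i in range(ns)]
    off += 8 * ns
    dmaxs = [_ascii_field(raw, off + 8 * i, 8, f"digital max[{i}]", True) for i in range(ns)]
    off += 8 * ns + 80 * ns  # skip prefiltering
    sprs = [
        int(_ascii_field(raw, off + 8 * i, 8, f"samples per record[{i}]", True))
        for i in range(ns)
    ]

    record_words = sum(sprs)
    expected = header_bytes + 2 * record_words * n_records
    if len(raw) < expected:
        raise FormatError(
            f"{path}: EDF payload truncated at byte offset {len(raw)} (expected {expected})"
        )
    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes, count=record_words * n_records)
    payload = payload.reshape(n_records, record_words)

    signals: dict[str, np.ndarray] = {}
    col = 0
    for i, lab in enumerate(labels):
        dig = payload[:, col : col + sprs[i]].astype(float)
        col += sprs[i]
        drange = dmaxs[i] - dmins[i]
        if drange == 0:
            raise FormatError(f"EDF digital range for signal {i} is zero")
        phys = (dig - dmins[i]) * (pmaxs[i] - pmins[i]) / drange + pmins[i]
        signals[lab] = phys
    if duration <= 0:
        raise FormatError("EDF record duration at byte offset 244 must be positive")
    sampling_rate = sprs[0] / duration
    return signals, sampling_rate, duration


def read_edf_segments(path) -> dict[str, list[Segment]]:
    """Read an EDF file into one Segment per (channel, data record)."""
    signals, fs, _ = read_edf(path)
    return {
        lab: [Segment(samples=row, sampling_rate=fs, channel=lab) for row in arr]
        for lab, arr in signals.items()
    }


# -- delimited text ---------------------------------------------------------

DELIMITED_HEADER = "sample_index,value_uV"


def write_delimited_segment(segment: Segment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(DELIMITED_HEADER + "\n")
        for i, v in enumerate(segment.samples):
            fh.write(f"{i},{float(v)!r}\n")


def read_delimited(path, sampling_rate: float = 256.0) -> Segment:
    """Read one segment from delimited text (dot-decimal dialect only)."""
    values = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n\r")
        if header != DELIMITED_HEADER:
            raise FormatError(
                f"{path}: line 1: expected header {DELIMITED_HEADER!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 comma-separated fields")
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value {parts[1]!r}"
                ) from None
    if not values:
        raise FormatError(f"{path}: no samples found")
    return Segment(samples=np.array(values), sampling_rate=sampling_rate)


# -- dataset-level writers with manifests -----------------------------------

def _require_nonempty(collection: list[Segment]) -> None:
    if not collection:
        raise InputError("cannot write an empty collection")


def write_delimited_dataset(collection: Iterable[Segment], outdir) -> pd.DataFrame:
    """One text file per segment + manifest.csv; returns the manifest."""
    collection = list(collection)
    _require_nonempty(collection)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in collection:
        name = f"s{seg.subject:03d}_{seg.label}_v{seg.video}_p{seg.index}_{seg.channel}.csv"
        write_delimited_segment(seg, outdir / name)
        rows.append(
            (seg.subject, seg.label, seg.video, seg.index, seg.channel,
             seg.sampling_rate, name, 0)
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / MANIFEST_NAME, index=False)
    return manifest


def write_edf_dataset(collection: Iterable[Segment], outdir) -> pd.DataFrame:
    """One EDF file per subject, one data record per window + manifest.csv."""
    collection = list(collection)
    _require_nonempty(collection)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "subject": [s.subject for s in collection],
            "emotion": [s.label for s in collection],
            "video": [s.video for s in collection],
            "segment": [s.index for s in collection],
            "channel": [s.channel for s in collection],
        }
    )
    fs = collection[0].sampling_rate
    seconds = len(collection[0]) / fs
    rows = []
    for subj in sorted(frame["subject"].unique()):
        sel = frame.index[frame["subject"] == subj]
        windows = sorted(
            {(frame.at[i, "emotion"], frame.at[i, "video"], frame.at[i, "segment"])
             for i in sel},
            key=lambda t: (str(t[0]), t[1], t[2]),
        )
        channels = sorted({frame.at[i, "channel"] for i in sel})
        record_of = {w: r for r, w in enumerate(windows)}
        by_key = {
            (frame.at[i, "emotion"], frame.at[i, "video"], frame.at[i, "segment"],
             frame.at[i, "channel"]): collection[i]
            for i in sel
        }
        signals = {}
        for ch in channels:
            arr = []
            for w in windows:
                key = (*w, ch)
                if key not in by_key:
                    raise InputError(
                        f"subject {subj}: window {w} missing channel {ch}; EDF records "
                        "need every channel present"
                    )
                arr.append(by_key[key].samples)
            signals[ch] = np.stack(arr)
        name = f"s{subj:03d}.edf"
        write_edf(outdir / name, signals, fs, seconds)
        for w in windows:
            for ch in channels:
                rows.append((subj, w[0], w[1], w[2], ch, fs, name, record_of[w]))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / MANIFEST_NAME, index=False)
    return manifest


def load_dataset(manifest_path) -> list[Segment]:
    """Read a written dataset (either format) back via its manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing column(s) {sorted(missing)}")
    segments: list[Segment] = []
    edf_cache: dict[str, tuple[dict[str, np.ndarray], float, float]] = {}
    for row in manifest.itertuples(index=False):
        path = root / row.file
        if str(row.file).endswith(".edf"):
            if row.file not in edf_cache:
                edf_cache[row.file] = read_edf(path)
            signals, fs, _ = edf_cache[row.file]
            if row.channel not in signals:
                raise FormatError(f"{path}: channel {row.channel!r} not found")
            samples = signals[row.channel][int(row.record)]
            seg = Segment(samples=samples, sampling_rate=fs)
        else:
            seg = read_delimited(path, sampling_rate=row.sampling_rate)
        seg.label = row.emotion
        seg.subject = int(row.subject)
        seg.video = int(row.video)
        seg.index = int(row.segment)
        seg.channel = row.channel
        segments.append(seg)
    return segments
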