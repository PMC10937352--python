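"""Readers and writers: EDF recordings, TSV tables, feature and model containers.

EDF (European Data Format) is the signal container; recordings are read with
mne.  Writing uses a minimal EDF encoder implemented here (16-bit samples,
symmetric physical range per channel), sufficient for the simulator's output
and readable by any standard EDF tool.  Tables are TSV (tab-separated) to
avoid locale decimal issues; parsing is strict — malformed rows are errors
that name the offending row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SyllableEvent, validate_events
from .decoder import DecoderConfig, TrainedDecoder
from .preprocess import FeatureTensor, RawRecording
from .regions import ElectrodeMap, region_class

logger = logging.getLogger(__name__)

_EDF_DIGITAL_MAX = 32767


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a RawRecording as EDF with 0.25 s data records.

    Requires the recording length to be a whole number of records; channel
    physical range is the symmetric integer ceiling of each channel's
    amplitude, so round-trip error is bounded by half a 16-bit quantization
    step of that range.
    """
    path = Path(path)
    n_per_record = int(round(rec.rate * 0.25))
    if rec.n_times % n_per_record:
        raise ValueError(
            f"recording length {rec.n_times} is not a whole number of "
            f"0.25 s records ({n_per_record} samples)"
        )
    n_records = rec.n_times // n_per_record
    n_sig = rec.n_channels

    pmax = np.maximum(np.ceil(np.abs(rec.samples).max(axis=1)), 1.0)
    scale = _EDF_DIGITAL_MAX / pmax
    # symmetric digital range so physical = digital * pmax / 32767 exactly
    digital = np.clip(np.round(rec.samples * scale[:, None]),
                      -_EDF_DIGITAL_MAX, _EDF_DIGITAL_MAX).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field(f"Startdate 01-JAN-2020 {rec.session_id[:40]}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (n_sig + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("0.25", 8),
        _edf_field(str(n_sig), 4),
    ])
    fields = [
        [ _edf_field(ch, 16) for ch in rec.channel_ids ],
        [ _edf_field("sEEG depth", 80) ] * n_sig,
        [ _edf_field("uV", 8) ] * n_sig,
        [ _edf_field(str(int(-p)), 8) for p in pmax ],
        [ _edf_field(str(int(p)), 8) for p in pmax ],
        [ _edf_field(str(-_EDF_DIGITAL_MAX), 8) ] * n_sig,
        [ _edf_field(str(_EDF_DIGITAL_MAX), 8) ] * n_sig,
        [ _edf_field("", 80) ] * n_sig,
        [ _edf_field(str(n_per_record), 8) ] * n_sig,
        [ _edf_field("", 32) ] * n_sig,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    # records: (n_records, n_sig, n_per_record)
    data = digital.reshape(n_sig, n_records, n_per_record).transpose(1, 0, 2)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(np.ascontiguousarray(data).tobytes())
    tmp.replace(path)
    return path


def _edf_header_sample_counts(path: Path) -> list[int]:
    """Per-signal samples-per-record from the raw EDF header (for validation)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated or empty EDF header")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except ValueError:
            raise ValueError(f"{path}: unreadable EDF header (signal count)") from None
        sig = fh.read(256 * n_sig)
    if len(sig) < 256 * n_sig:
        raise ValueError(f"{path}: truncated EDF signal header")
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_sig
    counts = []
    for i in range(n_sig):
        raw = sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip()
        counts.append(int(raw))
    return counts


def read_edf(path: str | Path, session_id: str | None = None) -> RawRecording:
    """Read an EDF file into a RawRecording (µV), rejecting mixed sampling rates."""
    import mne

    path = Path(path)
    counts = _edf_header_sample_counts(path)
    if len(set(counts)) > 1:
        raise ValueError(
            f"{path}: channels have different sampling rates "
            f"({sorted(set(counts))} samples/record); uniform rate required"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data(units="uV")
    return RawRecording(samples, float(raw.info["sfreq"]),
                        list(raw.ch_names), session_id or path.stem)


# ---------------------------------------------------------------------------
# TSV tables

EVENT_COLUMNS = ["session_id", "onset_s", "offset_s", "pinyin", "tone"]
ELECTRODE_COLUMNS = ["channel_id", "region", "class"]


def write_events_tsv(events: list[SyllableEvent], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {"session_id": e.session_id, "onset_s": e.onset, "offset_s": e.offset,
         "pinyin": e.pinyin, "tone": e.tone} for e in events
    ], columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> list[SyllableEvent]:
    """Parse and validate the syllable-event table; strict on every row."""
    df = pd.read_csv(path, sep="\t", dtype={"session_id": str, "pinyin": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, after header
        try:
            tone = int(row["tone"])
            ev = SyllableEvent(float(row["onset_s"]), float(row["offset_s"]),
                               str(row["pinyin"]), tone, str(row["session_id"]))
            if tone not in (1, 2, 3, 4):
                raise ValueError(f"tone {tone} outside 1..4")
            ev.label  # validates pinyin and tone
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {rowno}: {exc}") from None
        events.append(ev)
    validate_events(events)
    return events


def write_electrodes_tsv(emap: ElectrodeMap, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {"channel_id": ch, "region": region, "class": region_class(region)}
        for ch, region in emap.entries.items()
    ], columns=ELECTRODE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_electrodes_tsv(path: str | Path) -> ElectrodeMap:
    """Parse the electrode table; the class column must match the region's
    cortical/subcortical designation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ELECTRODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    entries: dict[str, str] = {}
    for i, row in df.iterrows():
        rowno = i + 2
        region = row["region"]
        try:
            expected = region_class(region)
        except ValueError as exc:
            raise ValueError(f"{path} row {rowno}: {exc}") from None
        if row["class"] != expected:
            raise ValueError(
                f"{path} row {rowno}: region {region!r} is {expected}, "
                f"but class column says {row['class']!r}"
            )
        if row["channel_id"] in entries:
            raise ValueError(f"{path} row {rowno}: duplicate channel "
                             f"{row['channel_id']!r}")
        entries[row["channel_id"]] = region
    return ElectrodeMap(entries)


# ---------------------------------------------------------------------------
# feature tensors and trained decoders (npz containers)


def save_features(ft: FeatureTensor, path: str | Path,
                  provenance: dict | None = None) -> Path:
    path = Path(path)
    meta = {
        "rate": ft.rate,
        "band_names": list(ft.band_names),
        "channel_ids": list(ft.channel_ids),
        "session_id": ft.session_id,
        "meta": ft.meta,
        "provenance": provenance or {},
    }
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        np.savez_compressed(fh, values=ft.values, meta=json.dumps(meta))
    tmp.replace(path)
    return path


def load_features(path: str | Path) -> FeatureTensor:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        values = npz["values"]
    return FeatureTensor(values, meta["rate"], tuple(meta["band_names"]),
                         meta["channel_ids"], meta["session_id"], meta["meta"])


def save_decoder(model: TrainedDecoder, path: str | Path,
                 provenance: dict | None = None) -> Path:
    from .decoder import _walk  # parameter-tree traversal

    path = Path(path)
    arrays = {"__".join(map(str, p)): a for p, a in _walk(model.params)}
    meta = {
        "config": model.config.__dict__,
        "n_features": model.n_features,
        "task": model.task,
        "n_outputs": model.n_outputs,
        "training_log": model.training_log,
        "best_epoch": model.best_epoch,
        "provenance": provenance or {},
    }
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "wb") as fh:
        np.savez_compressed(fh, meta=json.dumps(meta), **arrays)
    tmp.replace(path)
    return path


def load_decoder(path: str | Path) -> TrainedDecoder:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        flat = {k: npz[k] for k in npz.files if k != "meta"}
    config = DecoderConfig(**meta["config"])
    layers: list[dict] = []
    out: dict = {}
    for key, arr in flat.items():
        parts = key.split("__")
        if parts[0] == "out":
            out[parts[1]] = arr
        else:
            idx = int(parts[1])
            while len(layers) <= idx:
                layers.append({})
            layers[idx].setdefault(parts[2], {})[parts[3]] = arr
    params = {"layers": layers, "out": out}
    return TrainedDecoder(params, config, meta["n_features"], meta["task"],
                          meta["n_outputs"], meta["training_log"],
                          meta["best_epoch"])
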