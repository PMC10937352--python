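"""Band-power feature extraction from raw 2 kHz sEEG.

Pipeline per session: linear detrend -> 500 Hz anti-alias low-pass ->
three parallel band features (1-30 Hz and 30-70 Hz Butterworth band-pass
series; 70-150 Hz Hilbert amplitude envelope) -> downsample to 200 Hz ->
running z-score with a 30 s window.

All filters are applied zero-phase (forward-backward, `sosfiltfilt`) so the
three band paths stay sample-aligned with no relative group delay; the
effective filter order is therefore double the design order.  Downsampling
uses polyphase resampling (`resample_poly`), whose linear-phase FIR acts as
a ~100 Hz safety low-pass on the decimated series — in particular it
prevents aliasing of any fast fluctuation left in the high-gamma envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

RAW_RATE = 2000.0
FEATURE_RATE = 200.0
ANTIALIAS_HZ = 500.0
ANTIALIAS_ORDER = 8  # design order; zero-phase application doubles it
BAND_ORDER = 6

#: band name -> (low, high) edge in Hz, in fixed feature order
BANDS: dict[str, tuple[float, float]] = {
    "1-30 Hz": (1.0, 30.0),
    "30-70 Hz": (30.0, 70.0),
    "70-150 Hz": (70.0, 150.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)
HIGH_GAMMA = "70-150 Hz"


@dataclass
class RawRecording:
    """Multichannel voltage time-series (µV), one recording session."""

    samples: np.ndarray  # (n_channels, n_times)
    rate: float
    channel_ids: list[str]
    session_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel axis")
        if self.rate <= 2 * BANDS[HIGH_GAMMA][1]:
            raise ValueError(
                f"rate {self.rate} too low for 150 Hz analysis (need > 300)"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.rate


@dataclass
class FeatureTensor:
    """(channels, 3 bands, time) z-scored band features at 200 Hz."""

    values: np.ndarray
    rate: float
    band_names: tuple[str, ...]
    channel_ids: list[str]
    session_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (channels, bands, time)")
        if self.values.shape[1] != len(self.band_names):
            raise ValueError("band axis must match band_names")
        if self.values.shape[0] != len(self.channel_ids):
            raise ValueError("channel axis must match channel_ids")

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def band_index(self, band: str) -> int:
        try:
            return self.band_names.index(band)
        except ValueError:
            raise ValueError(f"unknown band {band!r}; have {self.band_names}") from None

    def subset(self, channel_ids: list[str] | None = None,
               bands: list[str] | None = None) -> "FeatureTensor":
        """View restricted to the given channels and/or bands (order preserved)."""
        chans = list(self.channel_ids) if channel_ids is None else list(channel_ids)
        rows = [self.channel_ids.index(c) for c in chans]
        bnames = tuple(self.band_names if bands is None else bands)
        cols = [self.band_index(b) for b in bnames]
        vals = self.values[np.ix_(rows, cols)]
        return FeatureTensor(vals, self.rate, bnames, chans, self.session_id, dict(self.meta))


def _bandpass_sos(low: float, high: float, fs: float, order: int = BAND_ORDER) -> np.ndarray:
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _assert_stable(sos)
    return sos


def _lowpass_sos(cut: float, fs: float, order: int) -> np.ndarray:
    sos = signal.butter(order, cut, btype="lowpass", fs=fs, output="sos")
    _assert_stable(sos)
    return sos


def _assert_stable(sos: np.ndarray) -> None:
    # all poles strictly inside the unit circle
    _, poles, _ = signal.sos2zpk(sos)
    if not np.all(np.abs(poles) < 1.0):
        raise RuntimeError("designed filter is unstable")


def detrend_and_antialias(rec: RawRecording) -> RawRecording:
    """Remove each channel's least-squares linear trend, then low-pass at 500 Hz."""
    if rec.rate <= 2 * ANTIALIAS_HZ:
        raise ValueError(
            f"rate {rec.rate} Hz puts the {ANTIALIAS_HZ:g} Hz anti-alias cutoff at "
            "or above Nyquist"
        )
    x = signal.detrend(rec.samples, axis=-1, type="linear")
    sos = _lowpass_sos(ANTIALIAS_HZ, rec.rate, ANTIALIAS_ORDER)
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return RawRecording(x, rec.rate, list(rec.channel_ids), rec.session_id)


def _downsample(x: np.ndarray, rate: float) -> np.ndarray:
    """Polyphase decimation from ``rate`` to the 200 Hz feature rate."""
    factor = rate / FEATURE_RATE
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"rate {rate} is not an integer multiple of {FEATURE_RATE}")
    return signal.resample_poly(x, up=1, down=int(round(factor)), axis=-1)


def extract_high_gamma(rec: RawRecording) -> np.ndarray:
    """70-150 Hz Hilbert amplitude envelope per channel, at 200 Hz.

    Expects an already detrended/anti-aliased recording.
    """
    sos = _bandpass_sos(*BANDS[HIGH_GAMMA], fs=rec.rate)
    band = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    env = np.abs(signal.hilbert(band, axis=-1))
    return _downsample(env, rec.rate)


def extract_band(rec: RawRecording, band: str) -> np.ndarray:
    """6th-order Butterworth band-pass series at 200 Hz for the 1-30 or 30-70 Hz band."""
    if band == HIGH_GAMMA:
        raise ValueError("use extract_high_gamma for the 70-150 Hz envelope")
    if band not in BANDS:
        raise ValueError(f"unsupported band {band!r}; expected one of {BAND_NAMES}")
    sos = _bandpass_sos(*BANDS[band], fs=rec.rate)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return _downsample(filtered, rec.rate)


def _running_moments(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered running mean/sd along the last axis.

    The window shrinks symmetrically at the edges, so the first and last
    samples are normalized by progressively shorter (but still centered)
    windows rather than by zero-padded ones.
    """
    T = x.shape[-1]
    half = window // 2
    idx = np.arange(T)
    h = np.minimum(half, np.minimum(idx, T - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    n = (hi - lo).astype(np.float64)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    cs2 = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x * x, axis=-1)], axis=-1
    )
    mean = (cs[..., hi] - cs[..., lo]) / n
    var = (cs2[..., hi] - cs2[..., lo]) / n - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd


def running_zscore(values: np.ndarray, rate: float = FEATURE_RATE,
                   window_s: float = 30.0) -> np.ndarray:
    """Per-sample standardization by a centered running window of mean and sd.

    The sd is floored at ``max(1e-8 * global_sd, 1e-12)`` per series so flat
    segments produce zeros instead of non-finite values.
    """
    x = np.asarray(values, dtype=np.float64)
    window = int(round(window_s * rate))
    if x.shape[-1] < window:
        raise ValueError(
            f"time axis ({x.shape[-1]} samples) shorter than the "
            f"{window_s:g} s z-score window ({window} samples)"
        )
    mean, sd = _running_moments(x, window)
    gsd = x.std(axis=-1, keepdims=True)
    floor = np.maximum(1e-8 * gsd, 1e-12)
    return (x - mean) / np.maximum(sd, floor)


def preprocess_session(rec: RawRecording, zscore_window_s: float = 30.0) -> FeatureTensor:
    """Full per-session feature extraction: detrend/anti-alias, 3 band paths, z-score."""
    clean = detrend_and_antialias(rec)
    low = extract_band(clean, "1-30 Hz")
    mid = extract_band(clean, "30-70 Hz")
    hg = extract_high_gamma(clean)
    stacked = np.stack([low, mid, hg], axis=1)  # (C, 3, T')
    z = running_zscore(stacked, FEATURE_RATE, zscore_window_s)
    meta = {
        "zscore_window_s": zscore_window_s,
        "antialias_hz": ANTIALIAS_HZ,
        "antialias_order": ANTIALIAS_ORDER,
        "band_order": BAND_ORDER,
        "zero_phase": True,
        "source_rate": rec.rate,
    }
    return FeatureTensor(z, FEATURE_RATE, BAND_NAMES, list(rec.channel_ids),
                         rec.session_id, meta)
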