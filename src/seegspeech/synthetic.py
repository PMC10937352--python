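"""Synthetic sEEG generator with region- and band-specific class information.

Each session is 1/f ("pink") background noise per channel at 2 kHz.  Each
syllable event adds, to every channel of a targeted region, a narrowband
tone burst in the targeted band whose amplitude is tied to the event's class
under the targeted task: class k (zero-based) receives a burst of envelope
amplitude (k + 1) * effect_size * sigma, where sigma is that channel's
baseline envelope standard deviation in the band.  Adjacent classes are thus
separated by ``effect_size`` baseline-sd units of event-locked band
amplitude — information carried by envelope amplitude, matching the
pipeline's power/envelope features (phase coding would be invisible to them
by design).

With effect_size 0 the recordings carry no class information and every
downstream decoder should sit at chance; that null, and monotone accuracy
in effect_size, are the generator's core testable contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .dataset import SyllableEvent
from .phonetics import build_inventory, label_syllable
from .preprocess import BANDS, BAND_NAMES, RawRecording
from .regions import REGIONS, REGION_ABBREV, ElectrodeMap

#: carrier frequency used for bursts in each band (midpoint of the band)
BURST_CARRIER_HZ = {name: (lo + hi) / 2.0 for name, (lo, hi) in BANDS.items()}


@dataclass(frozen=True)
class EffectSpec:
    """Class-dependent band-power modulation injected into one region.

    ``channels`` optionally restricts the effect to specific within-region
    contact indices (distinct neural populations on distinct contacts);
    None targets every contact of the region.  Two effects sharing a
    contact and a band superpose with random relative carrier phase, which
    partially masks both — assigning them to disjoint contacts keeps each
    code recoverable.
    """

    task: str  # place | manner | tone
    region: str
    band: str  # one of BAND_NAMES
    effect_size: float  # adjacent-class separation in baseline-sd units
    latency_s: float = 0.0
    channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.task not in ("place", "manner", "tone"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _default_channels() -> dict[str, int]:
    return {r: 2 for r in REGIONS}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset; ``seed`` fixes everything."""

    n_sessions: int = 6
    session_length_s: float = 40.0
    n_channels_per_region: dict[str, int] = field(default_factory=_default_channels)
    syllable_rate_per_min: float = 22.0
    syllable_duration_s: tuple[float, float] = (0.25, 0.45)
    noise_exponent: float = 1.0  # PSD ~ 1/f^exponent
    noise_amp_uv: float = 20.0
    effects: list[EffectSpec] = field(default_factory=list)
    rate: float = 2000.0
    seed: int = 0
    corpus: list[tuple[str, int]] | None = None  # (pinyin, tone); default 21x4

    def __post_init__(self) -> None:
        for r in self.n_channels_per_region:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r} in n_channels_per_region")
        lo, hi = self.syllable_duration_s
        if not 0 < lo <= hi:
            raise ValueError("syllable durations must be positive and ordered")


def default_scenario(effect_size: float = 3.0, seed: int = 0, **overrides) -> SimConfig:
    """The default study scenario: high-gamma coding of place and manner in
    STG, manner and tone in thalamus — the qualitative region/band structure
    the evaluation is meant to recover."""
    effects = [
        EffectSpec("place", "STG", "70-150 Hz", effect_size, channels=(0,)),
        EffectSpec("manner", "STG", "70-150 Hz", effect_size, channels=(1,)),
        EffectSpec("manner", "thalamus", "70-150 Hz", effect_size, channels=(0,)),
        EffectSpec("tone", "thalamus", "70-150 Hz", effect_size, channels=(1,)),
    ]
    return replace(SimConfig(effects=effects, seed=seed), **overrides)


def _default_corpus() -> list[tuple[str, int]]:
    """Uniform coverage of the 21-initial inventory x 4 tones ("Ca" syllables)."""
    return [(c.pinyin + "a", tone) for c in build_inventory() for tone in (1, 2, 3, 4)]


def make_electrode_map(n_channels_per_region: dict[str, int]) -> ElectrodeMap:
    entries = {}
    for region in REGIONS:  # fixed region order -> stable channel order
        for i in range(n_channels_per_region.get(region, 0)):
            entries[f"{REGION_ABBREV[region]}-{i + 1}"] = region
    return ElectrodeMap(entries)


def _pink_noise(n_channels: int, n_times: int, exponent: float, amp: float,
                rate: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent, scaled to std ``amp`` per channel."""
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n_times, axis=-1)
    x *= (amp / x.std(axis=-1, keepdims=True))
    return x


def _draw_events(config: SimConfig, session_id: str,
                 rng: np.random.Generator) -> list[SyllableEvent]:
    """Jittered regular grid of non-overlapping syllables, 1 s margins."""
    corpus = config.corpus if config.corpus is not None else _default_corpus()
    interval = 60.0 / config.syllable_rate_per_min
    lo, hi = config.syllable_duration_s
    events = []
    t = 1.0
    while True:
        onset = t + rng.uniform(0, 0.2 * interval)
        dur = rng.uniform(lo, hi)
        if onset + dur > config.session_length_s - 1.0:
            break
        pinyin, tone = corpus[rng.integers(len(corpus))]
        events.append(SyllableEvent(onset, onset + dur, pinyin, tone, session_id))
        t = onset + dur + max(interval - dur, 0.05)
    return events


def _band_envelope_sd(noise: np.ndarray, band: str, rate: float) -> np.ndarray:
    """Baseline Hilbert-envelope sd of each channel's background in ``band``."""
    lo, hi = BANDS[band]
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, noise, axis=-1)
    return np.abs(signal.hilbert(filtered, axis=-1)).std(axis=-1)


def _class_index(event: SyllableEvent, task: str) -> int | None:
    label = label_syllable(event.pinyin, event.tone)
    if task in ("place", "manner") and label.zero_initial:
        return None
    return label.target_index(task)


def simulate(config: SimConfig
             ) -> tuple[list[RawRecording], list[SyllableEvent], ElectrodeMap]:
    """Generate sessions, events and the electrode map; byte-deterministic in seed."""
    emap = make_electrode_map(config.n_channels_per_region)
    channel_ids = list(emap.entries)
    n_ch = len(channel_ids)
    if n_ch == 0:
        raise ValueError("no channels configured")
    n_times = int(round(config.session_length_s * config.rate))
    t_axis = np.arange(n_times) / config.rate

    recordings: list[RawRecording] = []
    all_events: list[SyllableEvent] = []
    for s in range(config.n_sessions):
        session_id = f"session-{s + 1:02d}"
        # independent substreams so adding/removing effects never perturbs
        # the background noise or the event sequence of any session
        rng = np.random.default_rng([config.seed, s])
        burst_rng = np.random.default_rng([config.seed, s, 1])
        noise = _pink_noise(n_ch, n_times, config.noise_exponent,
                            config.noise_amp_uv, config.rate, rng)
        events = _draw_events(config, session_id, rng)
        samples = noise.copy()
        for eff in config.effects:
            region_chans = emap.channels_for_region(eff.region)
            if eff.channels is not None:
                region_chans = [region_chans[i] for i in eff.channels
                                if i < len(region_chans)]
            rows = [channel_ids.index(c) for c in region_chans]
            if not rows:
                continue
            sigma = _band_envelope_sd(noise[rows], eff.band, config.rate)
            f0 = BURST_CARRIER_HZ[eff.band]
            for ev in events:
                k = _class_index(ev, eff.task)
                if k is None:
                    continue
                start = ev.onset + eff.latency_s
                stop = min(start + (ev.offset - ev.onset), config.session_length_s)
                i0, i1 = int(round(start * config.rate)), int(round(stop * config.rate))
                if i1 <= i0:
                    continue
                taper = signal.windows.tukey(i1 - i0, alpha=0.25)
                taper /= taper.mean()  # keep the event-mean envelope on target
                phase = burst_rng.uniform(0, 2 * np.pi, size=len(rows))
                carrier = np.sin(2 * np.pi * f0 * t_axis[i0:i1][None, :]
                                 + phase[:, None])
                amp = (k + 1) * eff.effect_size * sigma
                samples[rows, i0:i1] += amp[:, None] * taper[None, :] * carrier
        recordings.append(RawRecording(samples, config.rate, channel_ids, session_id))
        all_events.extend(events)
    return recordings, all_events, emap


def verify_spectrum(rec: RawRecording, config: SimConfig,
                    events: list[SyllableEvent] | None = None,
                    emap: ElectrodeMap | None = None) -> dict:
    """Diagnostics: fitted 1/f slope, and per-effect standardized class contrast.

    The contrast for an effect is the least-squares slope of mean event-locked
    band envelope vs class index, divided by the baseline envelope sd — it
    should recover ``effect_size``.
    """
    freqs, psd = signal.welch(rec.samples, fs=rec.rate, nperseg=int(4 * rec.rate))
    # fit the log-log slope on a band dominated by the background
    sel = (freqs >= 2.0) & (freqs <= 60.0)
    slopes = [np.polyfit(np.log10(freqs[sel]), np.log10(p[sel]), 1)[0] for p in psd]
    report: dict = {"psd_slope_median": float(np.median(slopes)),
                    "psd_slopes": [float(s) for s in slopes],
                    "effects": []}
    if events is None or emap is None:
        return report
    session_events = [ev for ev in events if ev.session_id == rec.session_id]
    for eff in config.effects:
        chans = emap.channels_for_region(eff.region)
        if eff.channels is not None:
            chans = [chans[i] for i in eff.channels if i < len(chans)]
        rows = [rec.channel_ids.index(c) for c in chans if c in rec.channel_ids]
        if not rows or not session_events:
            continue
        lo, hi = BANDS[eff.band]
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
        env = np.abs(signal.hilbert(
            signal.sosfiltfilt(sos, rec.samples[rows], axis=-1), axis=-1))
        # baseline: outside all events
        mask = np.ones(rec.n_times, bool)
        for ev in session_events:
            i0 = int(ev.onset * rec.rate)
            i1 = int(ev.offset * rec.rate)
            mask[max(i0 - int(0.1 * rec.rate), 0):i1 + int(0.1 * rec.rate)] = False
        base_mean = env[:, mask].mean(axis=-1)
        base_sd = env[:, mask].std(axis=-1)
        per_class: dict[int, list[np.ndarray]] = {}
        for ev in session_events:
            k = _class_index(ev, eff.task)
            if k is None:
                continue
            i0 = int(round((ev.onset + eff.latency_s) * rec.rate))
            i1 = int(round(ev.offset * rec.rate))
            if i1 <= i0:
                continue
            per_class.setdefault(k, []).append(env[:, i0:i1].mean(axis=-1))
        if len(per_class) < 2:
            continue
        ks = sorted(per_class)
        means = np.array([np.mean(per_class[k], axis=0) for k in ks])  # (K, rows)
        std_contrast = np.polyfit(ks, (means - base_mean) / base_sd, 1)[0]
        report["effects"].append({
            "task": eff.task, "region": eff.region, "band": eff.band,
            "configured_effect_size": eff.effect_size,
            "measured_contrast": float(np.mean(std_contrast)),
        })
    return report
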