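"""Supervised dataset construction: syllable segments and sliding windows.

The decoder consumes 200 ms windows (40 samples at 200 Hz) slid sample by
sample over a syllable's feature segment.  Each segment carries 100 ms of
context on each side so that the decoder emits exactly one output per core
sample ("equal length" contract).  Because the window length (40) is even,
L core samples + 40 pad samples admit L+1 stride-1 windows; the last window
is dropped, which is equivalent to padding 20 samples on the left and 19 on
the right.  Window k then covers padded samples [k, k+40) and is centered
on core sample k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phonetics import ArticulatoryLabel, label_syllable, n_classes
from .preprocess import FEATURE_RATE, FeatureTensor

logger = logging.getLogger(__name__)

WINDOW_S = 0.200
PAD_S = 0.100
WINDOW_SAMPLES = int(round(WINDOW_S * FEATURE_RATE))  # 40
PAD_SAMPLES = int(round(PAD_S * FEATURE_RATE))  # 20


@dataclass(frozen=True)
class SyllableEvent:
    """One spoken syllable: time span within a session plus its pinyin and tone."""

    onset: float
    offset: float
    pinyin: str
    tone: int
    session_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError(
                f"invalid event times onset={self.onset}, offset={self.offset}"
            )

    @property
    def label(self) -> ArticulatoryLabel:
        return label_syllable(self.pinyin, self.tone)


@dataclass
class Segment:
    """Padded feature slab for one syllable.

    ``values`` has shape (channels, bands, n_core + 2 * pad) with ``pad``
    context samples on each side taken from the surrounding recording
    (edge-replicated at session boundaries).
    """

    values: np.ndarray
    n_core: int
    pad: int
    event: SyllableEvent
    channel_ids: list[str]
    band_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape[-1] != self.n_core + 2 * self.pad:
            raise ValueError("segment length inconsistent with n_core and pad")


def validate_events(events: list[SyllableEvent]) -> None:
    """Check that events are sorted and non-overlapping within each session."""
    by_session: dict[str, list[SyllableEvent]] = {}
    for ev in events:
        by_session.setdefault(ev.session_id, []).append(ev)
    for sid, evs in by_session.items():
        for prev, cur in zip(evs, evs[1:]):
            if cur.onset < prev.offset:
                raise ValueError(
                    f"events overlap or are unsorted in session {sid!r}: "
                    f"{prev.pinyin}@{prev.onset:.3f}-{prev.offset:.3f} vs "
                    f"{cur.pinyin}@{cur.onset:.3f}"
                )


def segment_events(features: FeatureTensor, events: list[SyllableEvent],
                   pad_samples: int = PAD_SAMPLES) -> list[Segment]:
    """Cut one padded Segment per event out of a session's feature tensor."""
    T = features.n_times
    rate = features.rate
    out = []
    for ev in events:
        if ev.session_id != features.session_id:
            raise ValueError(
                f"event session {ev.session_id!r} does not match tensor "
                f"session {features.session_id!r}"
            )
        start = int(round(ev.onset * rate))
        stop = int(round(ev.offset * rate))
        if start < 0 or stop > T or stop <= start:
            raise ValueError(
                f"event {ev.pinyin!r} [{ev.onset:.3f}, {ev.offset:.3f}] s exceeds "
                f"recording bounds (0, {T / rate:.3f}) s"
            )
        lo, hi = start - pad_samples, stop + pad_samples
        core = features.values[:, :, max(lo, 0):min(hi, T)]
        # replicate edge values where the pad would run past the session
        left = max(0, -lo)
        right = max(0, hi - T)
        if left or right:
            core = np.pad(core, ((0, 0), (0, 0), (left, right)), mode="edge")
        out.append(Segment(core, stop - start, pad_samples, ev,
                           list(features.channel_ids), tuple(features.band_names)))
    return out


@dataclass(frozen=True)
class WindowedExample:
    """One 200 ms window paired with the one-hot target at its center sample."""

    window: np.ndarray  # (channels, bands, 40)
    target: np.ndarray  # (K,), sums to 1
    timepoint_index: int
    syllable_ref: SyllableEvent


def _one_hot(index: int, k: int) -> np.ndarray:
    v = np.zeros(k)
    v[index] = 1.0
    return v


def make_windows(segment: Segment, label: ArticulatoryLabel, task: str,
                 stride: int = 1) -> list[WindowedExample]:
    """Stride-1 windows give one example per core sample; stride>1 subsamples.

    Zero-initial syllables have no consonant, so for the place/manner tasks
    the segment is skipped (empty list, logged).
    """
    if task in ("place", "manner") and label.zero_initial:
        logger.info("skipping zero-initial syllable %r for task %s",
                    segment.event.pinyin, task)
        return []
    k = n_classes(task)
    target = _one_hot(label.target_index(task), k)
    examples = []
    for t in range(0, segment.n_core, stride):
        examples.append(WindowedExample(
            window=segment.values[:, :, t:t + WINDOW_SAMPLES],
            target=target,
            timepoint_index=t,
            syllable_ref=segment.event,
        ))
    return examples


def segment_to_matrix(segment: Segment, stride: int = 1) -> np.ndarray:
    """All windows of a segment as a (n_windows, 40, channels*bands) array.

    The feature axis flattens channels x bands; this is the decoder's input
    layout.  Stride-1 output has exactly ``n_core`` rows.
    """
    C, B, _ = segment.values.shape
    flat = segment.values.reshape(C * B, -1)  # (F, Lpad)
    win = np.lib.stride_tricks.sliding_window_view(flat, WINDOW_SAMPLES, axis=-1)
    # win: (F, Lpad - 39, 40); keep the first n_core windows, subsampled
    win = win[:, np.arange(0, segment.n_core, stride), :]
    return np.ascontiguousarray(np.transpose(win, (1, 2, 0)))


def build_training_arrays(segments: list[Segment], task: str, stride: int = 1,
                          ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack windows and one-hot targets from many segments.

    Returns (X (N, 40, F), Y (N, K), session_id per example).  Zero-initial
    syllables are skipped for place/manner with a logged count.
    """
    k = n_classes(task)
    xs, ys, sessions = [], [], []
    skipped = 0
    for seg in segments:
        label = seg.event.label
        if task in ("place", "manner") and label.zero_initial:
            skipped += 1
            continue
        x = segment_to_matrix(seg, stride)
        xs.append(x)
        ys.append(np.tile(_one_hot(label.target_index(task), k), (x.shape[0], 1)))
        sessions.extend([seg.event.session_id] * x.shape[0])
    if skipped:
        logger.info("skipped %d zero-initial syllables for task %s", skipped, task)
    if not xs:
        raise ValueError(f"no usable segments for task {task!r}")
    return np.concatenate(xs), np.concatenate(ys), sessions


def split_sessions(session_ids: list[str], train_fraction: float = 0.8,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Assign whole sessions to train or test; deterministic in ``seed``.

    Session-wise splitting prevents temporal leakage between the two sides.
    """
    ids = sorted(set(session_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 sessions for a session-wise split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    return sorted(perm[:n_train]), sorted(perm[n_train:])
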