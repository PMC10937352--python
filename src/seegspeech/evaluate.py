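"""Region and cortical+subcortical pair evaluation of decoding accuracy.

For each repeat a fresh session-wise train/test split is drawn, a decoder is
trained on the selected channels and bands, and syllable-level test accuracy
(majority vote over per-timepoint predictions) is recorded against the
task's chance level (1/7 place, 1/8 manner, 1/4 tone).  Per-timepoint
accuracy is logged alongside.  Repeat seeds are derived deterministically
from the top-level seed, so two evaluations run with the same seed share the
same sequence of splits — band comparisons and pair-vs-alone comparisons are
therefore paired designs.

The cortical+subcortical analysis combines one channel from each side.  The
channel within each region is chosen by validation accuracy on a held-out
training session (never the test set); the improvement ratio is the relative
accuracy gain of the pair over the selected cortical channel alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import phonetics
from .dataset import Segment, SyllableEvent, build_training_arrays, segment_events, split_sessions
from .decoder import DecoderConfig, TrainedDecoder, classify_syllable, predict_sequence, train
from .preprocess import BAND_NAMES, HIGH_GAMMA, FeatureTensor
from .regions import CORTICAL, SUBCORTICAL, ElectrodeMap, region_class

logger = logging.getLogger(__name__)


@dataclass
class EvalData:
    """Preprocessed features per session, events, and the electrode map."""

    features: dict[str, FeatureTensor]
    events: list[SyllableEvent]
    electrodes: ElectrodeMap

    _segments: dict[str, list[Segment]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        sessions = set(self.features)
        for ev in self.events:
            if ev.session_id not in sessions:
                raise ValueError(f"event references unknown session {ev.session_id!r}")

    @property
    def session_ids(self) -> list[str]:
        return sorted(self.features)

    def segments(self, session_id: str) -> list[Segment]:
        """Padded full-channel segments for one session (cached)."""
        if session_id not in self._segments:
            evs = [e for e in self.events if e.session_id == session_id]
            self._segments[session_id] = segment_events(self.features[session_id], evs)
        return self._segments[session_id]


def _subset_segment(seg: Segment, channel_ids: list[str], bands: tuple[str, ...]
                    ) -> Segment:
    rows = [seg.channel_ids.index(c) for c in channel_ids]
    cols = [seg.band_names.index(b) for b in bands]
    return Segment(seg.values[np.ix_(rows, cols)], seg.n_core, seg.pad, seg.event,
                   list(channel_ids), tuple(bands))


@dataclass
class EvalResult:
    task: str
    regions: tuple[str, ...]
    bands: tuple[str, ...]
    accuracy: float
    chance: float
    n_repeats: int
    per_repeat_accuracies: list[float]
    seed: int
    per_repeat_counts: list[tuple[int, int]] = field(default_factory=list)
    timepoint_accuracy: float = float("nan")
    split_hashes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0 <= self.accuracy <= 1


@dataclass
class ImprovementRatio:
    """Relative gain of the cortical+subcortical pair over cortical alone."""

    task: str
    cortical_region: str
    subcortical_region: str
    ratio: float
    pair_accuracy: float
    cortical_accuracy: float
    per_repeat_ratios: list[float] = field(default_factory=list)


def _repeat_seed(seed: int, repeat: int) -> int:
    return int((seed * 100003 + repeat * 7919 + 1) % (2**31))


def _split_hash(test_sessions: list[str]) -> int:
    return hash(tuple(sorted(test_sessions)))


def _score_sessions(model: TrainedDecoder, data: EvalData, sessions: list[str],
                    channel_ids: list[str], bands: tuple[str, ...], task: str
                    ) -> tuple[int, int, int, int]:
    """(correct syllables, total syllables, correct timepoints, total timepoints)."""
    n_ok = n_tot = tp_ok = tp_tot = 0
    for sid in sessions:
        for seg in data.segments(sid):
            label = seg.event.label
            if task in ("place", "manner") and label.zero_initial:
                continue
            sub = _subset_segment(seg, channel_ids, bands)
            scores = predict_sequence(model, sub)
            truth = label.target_index(task)
            n_ok += int(classify_syllable(scores) == truth)
            n_tot += 1
            tp_ok += int(np.sum(np.argmax(scores, axis=1) == truth))
            tp_tot += scores.shape[0]
    if n_tot == 0:
        raise ValueError(f"no test syllables usable for task {task!r}")
    return n_ok, n_tot, tp_ok, tp_tot


def _fit_on_sessions(data: EvalData, sessions: list[str], channel_ids: list[str],
                     bands: tuple[str, ...], task: str, config: DecoderConfig,
                     train_stride: int) -> TrainedDecoder:
    segs = [_subset_segment(s, channel_ids, bands)
            for sid in sessions for s in data.segments(sid)]
    X, Y, ex_sessions = build_training_arrays(segs, task, train_stride)
    return train(X, Y, ex_sessions, config, task)


def _run_repeat(data: EvalData, task: str, channel_ids: list[str],
                bands: tuple[str, ...], repeat_seed: int, config: DecoderConfig,
                train_stride: int, train_fraction: float
                ) -> tuple[tuple[int, int, int, int], int]:
    train_sessions, test_sessions = split_sessions(data.session_ids,
                                                   train_fraction, repeat_seed)
    # per-repeat shuffle of electrode order fed to the decoder
    rng = np.random.default_rng([repeat_seed, 17])
    chans = [channel_ids[i] for i in rng.permutation(len(channel_ids))]
    cfg = replace(config, seed=repeat_seed)
    model = _fit_on_sessions(data, train_sessions, chans, bands, task, cfg,
                             train_stride)
    counts = _score_sessions(model, data, test_sessions, chans, bands, task)
    return counts, _split_hash(test_sessions)


def evaluate_region(data: EvalData, task: str, region: str,
                    bands: tuple[str, ...] = (HIGH_GAMMA,),
                    n_repeats: int = 50, seed: int = 0,
                    config: DecoderConfig | None = None,
                    train_stride: int = 1,
                    train_fraction: float = 0.8) -> EvalResult:
    """Decoding accuracy of one task from one region's channels."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    chance = phonetics.chance_level(task)  # validates task
    config = config or DecoderConfig()
    channels = data.electrodes.channels_for_region(region)
    channels = [c for c in channels if any(c in ft.channel_ids
                                           for ft in data.features.values())]
    if not channels:
        raise ValueError(f"region {region!r} has no channels in the recordings")
    for b in bands:
        if b not in BAND_NAMES:
            raise ValueError(f"unknown band {b!r}")

    accs, counts_list, hashes = [], [], []
    tp_ok = tp_tot = 0
    for r in range(n_repeats):
        counts, h = _run_repeat(data, task, channels, tuple(bands),
                                _repeat_seed(seed, r), config, train_stride,
                                train_fraction)
        n_ok, n_tot, t_ok, t_tot = counts
        accs.append(n_ok / n_tot)
        counts_list.append((n_ok, n_tot))
        hashes.append(h)
        tp_ok += t_ok
        tp_tot += t_tot
    return EvalResult(task, (region,), tuple(bands), float(np.mean(accs)),
                      chance, n_repeats, accs, seed, counts_list,
                      tp_ok / tp_tot, hashes)


def _select_channel(data: EvalData, task: str, channels: list[str],
                    train_sessions: list[str], bands: tuple[str, ...],
                    repeat_seed: int, config: DecoderConfig, train_stride: int,
                    policy: str, rng: np.random.Generator) -> str:
    """Pick one channel of a region without touching the test sessions."""
    if len(channels) == 1:
        return channels[0]
    if policy == "random":
        return channels[rng.integers(len(channels))]
    if policy != "best-val":
        raise ValueError(f"unknown channel policy {policy!r}")
    # hold out one training session for selection
    fit_sessions, val_sessions = train_sessions[:-1], train_sessions[-1:]
    if not fit_sessions:
        fit_sessions, val_sessions = train_sessions, train_sessions
    best, best_acc = channels[0], -1.0
    for ch in channels:
        cfg = replace(config, seed=repeat_seed)
        model = _fit_on_sessions(data, fit_sessions, [ch], bands, task, cfg,
                                 train_stride)
        n_ok, n_tot, _, _ = _score_sessions(model, data, val_sessions, [ch],
                                            bands, task)
        acc = n_ok / n_tot
        if acc > best_acc:
            best, best_acc = ch, acc
    return best


def evaluate_pair(data: EvalData, task: str, cortical_region: str,
                  subcortical_region: str,
                  bands: tuple[str, ...] = (HIGH_GAMMA,),
                  n_repeats: int = 50, seed: int = 0,
                  config: DecoderConfig | None = None,
                  train_stride: int = 1, train_fraction: float = 0.8,
                  channel_policy: str = "best-val"
                  ) -> tuple[EvalResult, ImprovementRatio]:
    """One cortical + one subcortical channel vs the cortical channel alone.

    Both arms share the identical split in every repeat (paired design).
    """
    if region_class(cortical_region) != CORTICAL:
        raise ValueError(f"{cortical_region!r} is not a cortical region")
    if region_class(subcortical_region) != SUBCORTICAL:
        raise ValueError(f"{subcortical_region!r} is not a subcortical region")
    chance = phonetics.chance_level(task)
    config = config or DecoderConfig()
    cort_channels = data.electrodes.channels_for_region(cortical_region)
    sub_channels = data.electrodes.channels_for_region(subcortical_region)
    if not cort_channels or not sub_channels:
        raise ValueError("both regions need at least one channel")

    pair_accs, cort_accs, ratios, hashes = [], [], [], []
    pair_counts = []
    for r in range(n_repeats):
        rseed = _repeat_seed(seed, r)
        train_sessions, test_sessions = split_sessions(data.session_ids,
                                                       train_fraction, rseed)
        rng = np.random.default_rng([rseed, 23])
        c_cort = _select_channel(data, task, cort_channels, train_sessions,
                                 tuple(bands), rseed, config, train_stride,
                                 channel_policy, rng)
        c_sub = _select_channel(data, task, sub_channels, train_sessions,
                                tuple(bands), rseed, config, train_stride,
                                channel_policy, rng)
        cfg = replace(config, seed=rseed)
        pair_model = _fit_on_sessions(data, train_sessions, [c_cort, c_sub],
                                      tuple(bands), task, cfg, train_stride)
        cort_model = _fit_on_sessions(data, train_sessions, [c_cort],
                                      tuple(bands), task, cfg, train_stride)
        p_ok, p_tot, _, _ = _score_sessions(pair_model, data, test_sessions,
                                            [c_cort, c_sub], tuple(bands), task)
        c_ok, c_tot, _, _ = _score_sessions(cort_model, data, test_sessions,
                                            [c_cort], tuple(bands), task)
        pair_acc, cort_acc = p_ok / p_tot, c_ok / c_tot
        pair_accs.append(pair_acc)
        cort_accs.append(cort_acc)
        pair_counts.append((p_ok, p_tot))
        ratios.append((pair_acc - cort_acc) / cort_acc if cort_acc > 0
                      else float("nan"))
        hashes.append(_split_hash(test_sessions))

    pair_result = EvalResult(task, (cortical_region, subcortical_region),
                             tuple(bands), float(np.mean(pair_accs)), chance,
                             n_repeats, pair_accs, seed, pair_counts,
                             split_hashes=hashes)
    mean_cort = float(np.mean(cort_accs))
    ratio = ImprovementRatio(
        task, cortical_region, subcortical_region,
        ratio=(pair_result.accuracy - mean_cort) / mean_cort if mean_cort > 0
        else float("nan"),
        pair_accuracy=pair_result.accuracy,
        cortical_accuracy=mean_cort,
        per_repeat_ratios=ratios,
    )
    return pair_result, ratio


def band_comparison(data: EvalData, task: str, region: str,
                    n_repeats: int = 50, seed: int = 0,
                    config: DecoderConfig | None = None,
                    train_stride: int = 1,
                    train_fraction: float = 0.8) -> dict[str, EvalResult]:
    """Per-band accuracy from one region, with shared splits across bands."""
    return {band: evaluate_region(data, task, region, (band,), n_repeats, seed,
                                  config, train_stride, train_fraction)
            for band in BAND_NAMES}


def chance_test(result: EvalResult) -> float:
    """Two-sided exact binomial test of pooled correct counts against chance."""
    if not result.per_repeat_counts:
        raise ValueError("result carries no per-repeat counts")
    k = sum(c for c, _ in result.per_repeat_counts)
    n = sum(t for _, t in result.per_repeat_counts)
    if n == 0:
        raise ValueError("no test syllables")
    return float(stats.binomtest(k, n, result.chance).pvalue)
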