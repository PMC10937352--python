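"""Mandarin articulatory phonetics: consonant inventory, syllable labeling, chance levels.

Mandarin initials form a 7 (place) x 8 (manner) chart: 21 consonants where
aspiration and voicing variants count as distinct manners.  Every syllable
additionally carries one of 4 lexical tones.  A decoding task over one of
these axes is a balanced K-way classification problem, so uniform guessing
scores 1/K ("chance level").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class Place(enum.Enum):
    """Articulatory place: where in the vocal tract the consonant is formed."""

    BILABIAL = "bilabial"
    LABIODENTAL = "labiodental"
    DENTAL = "dental"
    ALVEOLAR = "alveolar"
    POST_ALVEOLAR = "post-alveolar"
    PALATAL = "palatal"
    VELAR = "velar"


class Manner(enum.Enum):
    """Articulatory manner: how the airstream is shaped (aspiration/voicing split out)."""

    PLOSIVE_UNASPIRATED = "plosive-unaspirated"
    PLOSIVE_ASPIRATED = "plosive-aspirated"
    AFFRICATE_UNASPIRATED = "affricate-unaspirated"
    AFFRICATE_ASPIRATED = "affricate-aspirated"
    FRICATIVE_VOICELESS = "fricative-voiceless"
    FRICATIVE_VOICED = "fricative-voiced"
    NASAL = "nasal"
    LATERAL = "lateral"


class Tone(enum.IntEnum):
    """The four canonical Mandarin lexical tones (neutral tone excluded)."""

    HIGH = 1
    RISING = 2
    DIPPING = 3
    FALLING = 4


#: Task name -> category enum.
TASKS = {"place": Place, "manner": Manner, "tone": Tone}


@dataclass(frozen=True)
class Consonant:
    pinyin: str
    ipa: str
    place: Place
    manner: Manner


# The 21 Mandarin initials with their place/manner cell assignments.
_P, _M = Place, Manner
_INVENTORY_ROWS = [
    ("b", "p", _P.BILABIAL, _M.PLOSIVE_UNASPIRATED),
    ("p", "pʰ", _P.BILABIAL, _M.PLOSIVE_ASPIRATED),
    ("m", "m", _P.BILABIAL, _M.NASAL),
    ("f", "f", _P.LABIODENTAL, _M.FRICATIVE_VOICELESS),
    ("z", "ts", _P.DENTAL, _M.AFFRICATE_UNASPIRATED),
    ("c", "tsʰ", _P.DENTAL, _M.AFFRICATE_ASPIRATED),
    ("s", "s", _P.DENTAL, _M.FRICATIVE_VOICELESS),
    ("d", "t", _P.ALVEOLAR, _M.PLOSIVE_UNASPIRATED),
    ("t", "tʰ", _P.ALVEOLAR, _M.PLOSIVE_ASPIRATED),
    ("n", "n", _P.ALVEOLAR, _M.NASAL),
    ("l", "l", _P.ALVEOLAR, _M.LATERAL),
    ("zh", "tʂ", _P.POST_ALVEOLAR, _M.AFFRICATE_UNASPIRATED),
    ("ch", "tʂʰ", _P.POST_ALVEOLAR, _M.AFFRICATE_ASPIRATED),
    ("sh", "ʂ", _P.POST_ALVEOLAR, _M.FRICATIVE_VOICELESS),
    ("r", "ʐ", _P.POST_ALVEOLAR, _M.FRICATIVE_VOICED),
    ("j", "tɕ", _P.PALATAL, _M.AFFRICATE_UNASPIRATED),
    ("q", "tɕʰ", _P.PALATAL, _M.AFFRICATE_ASPIRATED),
    ("x", "ɕ", _P.PALATAL, _M.FRICATIVE_VOICELESS),
    ("g", "k", _P.VELAR, _M.PLOSIVE_UNASPIRATED),
    ("k", "kʰ", _P.VELAR, _M.PLOSIVE_ASPIRATED),
    ("h", "x", _P.VELAR, _M.FRICATIVE_VOICELESS),
]


def build_inventory() -> list[Consonant]:
    """Return the full 21-consonant Mandarin initial inventory."""
    return [Consonant(*row) for row in _INVENTORY_ROWS]


_BY_PINYIN: dict[str, Consonant] = {c.pinyin: c for c in build_inventory()}

# Digraph initials must be matched before single letters ("zh" before "z").
_DIGRAPHS = ("zh", "ch", "sh")


@dataclass(frozen=True)
class ArticulatoryLabel:
    """Decoding target of one syllable.

    ``place`` and ``manner`` are both None for a zero-initial syllable
    (e.g. "an", "er"), which still carries a tone.
    """

    place: Optional[Place]
    manner: Optional[Manner]
    tone: Tone

    def __post_init__(self) -> None:
        if (self.place is None) != (self.manner is None):
            raise ValueError("place and manner must be both present or both absent")

    @property
    def zero_initial(self) -> bool:
        return self.place is None

    def target_index(self, task: str) -> int:
        """Zero-based class index of this label for ``task``.

        Raises for place/manner on a zero-initial syllable.
        """
        cats = task_categories(task)
        value = {"place": self.place, "manner": self.manner, "tone": self.tone}[task]
        if value is None:
            raise ValueError(f"zero-initial syllable has no {task} category")
        return cats.index(value)


def task_categories(task: str) -> list:
    """Ordered category list for a task (length 7, 8 or 4)."""
    try:
        return list(TASKS[task])
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}") from None


def n_classes(task: str) -> int:
    return len(task_categories(task))


def chance_level(task: str) -> float:
    """Uniform-guessing accuracy 1/K for a task: 1/7 place, 1/8 manner, 1/4 tone."""
    return 1.0 / n_classes(task)


def split_initial(pinyin: str) -> tuple[Optional[Consonant], str]:
    """Split a pinyin syllable into (initial consonant or None, remainder).

    Longest match on {zh, ch, sh} first; "w"/"y" are glide spellings of
    zero-initial syllables, not consonants.
    """
    s = pinyin.strip().lower()
    if not s:
        raise ValueError("empty pinyin syllable")
    if s[:2] in _DIGRAPHS:
        return _BY_PINYIN[s[:2]], s[2:]
    if s[0] in _BY_PINYIN:
        return _BY_PINYIN[s[0]], s[1:]
    if s[0] in "aeiouwy":
        return None, s
    raise ValueError(f"unknown pinyin initial in syllable {pinyin!r}")


def label_syllable(pinyin: str, tone: int) -> ArticulatoryLabel:
    """Map a pinyin syllable + tone to its articulatory classification target.

    Tone must be 1-4; the neutral tone (0/5) is rejected because the tone
    task is a 4-way classification.
    """
    if tone not in (1, 2, 3, 4):
        raise ValueError(f"tone must be in 1..4, got {tone!r}")
    initial, _ = split_initial(pinyin)
    if initial is None:
        return ArticulatoryLabel(None, None, Tone(tone))
    return ArticulatoryLabel(initial.place, initial.manner, Tone(tone))


def inventory_tsv() -> str:
    """The inventory as a byte-stable TSV table (pinyin, ipa, place, manner)."""
    lines = ["pinyin\tipa\tplace\tmanner"]
    for c in build_inventory():
        lines.append(f"{c.pinyin}\t{c.ipa}\t{c.place.value}\t{c.manner.value}")
    return "\n".join(lines) + "\n"
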