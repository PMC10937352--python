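"""Brain-region vocabulary and electrode map.

Eight right-hemisphere regions are sampled by the depth electrodes: three
temporal gyri on the cortical surface and five deep structures.  The
parahippocampal gyrus is archi-/paleocortex but sits beneath the neocortex,
so it is grouped with the subcortical class for cortical-vs-subcortical
comparisons; the class labels here are analysis designations, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"

#: region name -> analysis class
REGION_CLASS: dict[str, str] = {
    "ITG": CORTICAL,
    "MTG": CORTICAL,
    "STG": CORTICAL,
    "thalamus": SUBCORTICAL,
    "insular gyrus": SUBCORTICAL,
    "amygdala": SUBCORTICAL,
    "parahippocampal gyrus": SUBCORTICAL,
    "hippocampus": SUBCORTICAL,
}

REGIONS: tuple[str, ...] = tuple(REGION_CLASS)

#: short labels used in channel ids and figures
REGION_ABBREV: dict[str, str] = {
    "ITG": "ITG",
    "MTG": "MTG",
    "STG": "STG",
    "thalamus": "Th",
    "insular gyrus": "IG",
    "amygdala": "Amy",
    "parahippocampal gyrus": "PhG",
    "hippocampus": "Hipp",
}


def region_class(region: str) -> str:
    try:
        return REGION_CLASS[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; expected one of {list(REGIONS)}"
        ) from None


@dataclass
class ElectrodeMap:
    """channel_id -> region assignment; the class flag follows from the region."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, region in self.entries.items():
            region_class(region)  # validates

    def __contains__(self, channel_id: str) -> bool:
        return channel_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def region_of(self, channel_id: str) -> str:
        return self.entries[channel_id]

    def class_of(self, channel_id: str) -> str:
        return region_class(self.entries[channel_id])

    def channels_for_region(self, region: str) -> list[str]:
        region_class(region)
        return [ch for ch, r in self.entries.items() if r == region]

    def channels_for_class(self, cls: str) -> list[str]:
        if cls not in (CORTICAL, SUBCORTICAL):
            raise ValueError(f"unknown class {cls!r}")
        return [ch for ch in self.entries if self.class_of(ch) == cls]
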