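"""Mandarin articulatory labeling: from pinyin syllables to decoding targets.

Each Mandarin initial occupies one cell of a 7-place x 8-manner consonant
chart, and each syllable carries one of 4 tones; decoding any one of these
axes is a balanced classification problem with chance level 1/K.
"""

from seegspeech import build_inventory, chance_level, label_syllable

inventory = build_inventory()
print(f"{len(inventory)} Mandarin initials, e.g.:")
for c in inventory[:5]:
    print(f"  {c.pinyin:>2} [{c.ipa}]  {c.place.value:<13} {c.manner.value}")

for syllable, tone in [("zhang", 1), ("ma", 3), ("an", 4)]:
    lab = label_syllable(syllable, tone)
    place = lab.place.value if lab.place else "(zero-initial)"
    manner = lab.manner.value if lab.manner else "(zero-initial)"
    print(f"{syllable}{tone}: place={place}, manner={manner}, tone={int(lab.tone)}")

print("chance levels:",
      {task: round(chance_level(task), 3) for task in ("place", "manner", "tone")})
# place 1/7 ~ 0.143, manner 1/8 = 0.125, tone 1/4 = 0.25: any decoder must
# beat these to claim it found information in the neural signal.
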