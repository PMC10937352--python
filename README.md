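# seegspeech

Speech decoding from **stereotactic EEG (sEEG)** — depth-electrode recordings
that sample cortical *and* subcortical structures — for Mandarin Chinese
syllable production.  The package implements the full analysis pipeline:

1. **Feature extraction** — per channel, three band features at 200 Hz from a
   2 kHz recording: the 1–30 Hz and 30–70 Hz Butterworth band-pass series and
   the 70–150 Hz (high-gamma) Hilbert amplitude envelope, all z-scored with a
   running 30 s window.
2. **Articulatory labeling** — each syllable's pinyin initial maps through the
   7 (place) × 8 (manner) Mandarin consonant chart; the tone is one of 4
   classes.  Chance levels are 1/7, 1/8 and 1/4.
3. **Decoding** — a stacked 3-layer bidirectional LSTM (100 hidden units per
   direction, implemented in numpy with hand-written backpropagation) maps
   each 200 ms feature window $x_{t-20:t+19}$ to the one-hot articulatory
   target $y_t$ at the window's center sample, trained with Adam
   (lr $10^{-3}$, $\beta_1=0.9$, $\beta_2=0.999$, $\epsilon=10^{-8}$) on a
   mean-squared-error objective with 50% dropout and early stopping on
   validation loss.  At test time the window slides sample-by-sample over a
   syllable padded with 100 ms of context, yielding one score vector per
   sample; the syllable's class is the majority vote.
4. **Evaluation** — repeated session-wise train/test splits, per brain region
   (ITG/MTG/STG, thalamus, insular gyrus, amygdala, parahippocampal gyrus,
   hippocampus), per band, and for one-cortical + one-subcortical channel
   pairs with the improvement ratio
   $r = (\mathrm{acc}_{pair} - \mathrm{acc}_{cort}) / \mathrm{acc}_{cort}$.
5. **Synthetic sEEG generator** — 1/f background noise plus event-locked,
   class-dependent high-gamma bursts in configurable regions, so the whole
   pipeline can be validated end to end without patient data.

Who is it for: researchers prototyping speech-BCI decoding analyses on
intracranial recordings, and anyone who needs a tested, deterministic
reference implementation of the band-power + bLSTM decoding stack with
honest chance-level statistics.

## Worked example

```python
from seegspeech import (DecoderConfig, default_scenario, evaluate_region,
                        simulate, chance_level)
from seegspeech.evaluate import EvalData, chance_test
from seegspeech.preprocess import preprocess_session

recordings, events, electrodes = simulate(default_scenario(effect_size=3.0, seed=7))
features = {r.session_id: preprocess_session(r) for r in recordings}
data = EvalData(features, events, electrodes)

for region in ("thalamus", "amygdala"):
    res = evaluate_region(data, "tone", region, n_repeats=5, seed=7,
                          config=DecoderConfig.desk_scale(), train_stride=4)
    print(region, round(res.accuracy, 2), round(chance_test(res), 8))
```

prints (the scenario encodes tone only in the thalamus):

```
tone from thalamus : accuracy 0.53 (chance 0.25, p vs chance 1.6e-06, ...)
tone from amygdala : accuracy 0.20 (chance 0.25, p vs chance 0.47, ...)
```

0.53 is the mean syllable-level test accuracy over 5 session-wise splits —
far above the 0.25 four-tone chance level (exact binomial p ≈ 2e-6) — while
the amygdala, which carries no tone code in this scenario, stays at chance.
The `examples/` directory has one short script per capability (labeling,
preprocessing, simulation diagnostics, region decoding, pair analysis), and
the `seegspeech` command line exposes the same pipeline as `simulate`,
`preprocess`, `label`, `train`, `evaluate` and `report` subcommands.

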