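"""Generate a synthetic sEEG study and verify its spectral contract.

The generator produces 1/f background noise per channel plus event-locked
high-gamma bursts whose amplitude encodes each syllable's class in the
targeted region.  verify_spectrum checks the two knobs that matter: the
spectral exponent, and the standardized class contrast (should match the
configured effect size).
"""

from seegspeech import default_scenario, simulate, verify_spectrum

config = default_scenario(effect_size=2.0, seed=42)
recordings, events, electrodes = simulate(config)
print(f"{len(recordings)} sessions x {recordings[0].duration_s:.0f} s, "
      f"{len(electrodes)} channels, {len(events)} syllable events")

report = verify_spectrum(recordings[0], config, events, electrodes)
print(f"fitted PSD slope: {report['psd_slope_median']:.2f} "
      f"(configured exponent {config.noise_exponent} -> slope ~ -1)")
for eff in report["effects"]:
    print(f"  {eff['task']:<6} in {eff['region']:<9} {eff['band']}: "
          f"measured contrast {eff['measured_contrast']:.2f} "
          f"(configured {eff['configured_effect_size']})")
# The measured contrast is the event-locked envelope separation between
# adjacent classes in baseline-sd units; it should sit within ~20% of the
# configured effect size.
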