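"""Extract the acoustic parameter set from a synthetic call and check it
against the generator's ground truth.

The extraction pipeline mirrors a Praat-style measurement script:
autocorrelation f0 tracking (300-1600 Hz search band), contour statistics,
whole-call spectral energy quartiles and centre of gravity, and
amplitude-/frequency-modulation rates.
"""

from dovekie import acoustics, synth

spec = synth.default_specs()["low_trill"]
waveform, truth = synth.synthesize_call(spec, seed=7)
features = acoustics.extract_features(waveform, 48_000,
                                      call_id="low_trill_demo")

print(f"{'parameter':<14}{'extracted':>12}{'generator truth':>18}")
for name in ("duration", "f0_mean", "f0_min", "f0_max", "f0_range",
             "am_rate", "fm_rate"):
    print(f"{name:<14}{getattr(features, name):>12.2f}"
          f"{truth[name]:>18.2f}")
print(f"{'q25/q50/q75':<14}{features.q25:>8.0f} /{features.q50:>6.0f} /"
      f"{features.q75:>6.0f}  (no generator truth: emerges from the "
      "harmonic stack)")

print("\nExtracted values track the realized generator parameters; small "
      "differences reflect framing, voicing decisions at the call edges, "
      "and additive noise at the spec's SNR.")
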