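"""Generate synthetic little auk calls and compare realized values with the
published per-type distributions.

Each call type has published mean +- SD values for its acoustic parameters;
the generator draws per-call parameters from those Gaussians and renders a
harmonic-stack waveform. The ground truth recorded with each call holds the
realized (drawn) values, not the distribution means.
"""

import numpy as np

from dovekie import synth

specs = synth.default_specs()
print(f"{len(specs)} call types: {', '.join(sorted(specs))}\n")

corpus = synth.synthesize_corpus(specs, n_per_type=10, seed=42)
truth = corpus.truth_table()

print(f"{'type':<12}{'dur (s)':>10}{'published':>12}{'f0 (Hz)':>10}{'published':>12}")
for ct in sorted(specs):
    sub = truth[truth.call_type == ct]
    print(f"{ct:<12}{sub.duration.mean():>10.3f}"
          f"{specs[ct].duration_dist[0]:>12.2f}"
          f"{sub.f0_mean.mean():>10.1f}"
          f"{specs[ct].f0_mean_dist[0]:>12.2f}")

print("\nEach row: mean realized duration and f0 over 10 synthetic calls "
      "next to the published distribution mean; with only 10 draws the "
      "agreement is within a couple of SDs/sqrt(10).")
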