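"""Build a binding-affinity landscape from a synthetic replicate pair.

Generates two noisy replicate 8-mer score tables for one transcription
factor, thresholds binding at E-score > 0.35, extracts the dominant genotype
network, estimates the per-TF noise threshold delta from the replicate
regression, and prints the topography summary.
"""

import json

from tfscape import (SynthConfig, build_landscape, estimate_delta,
                     generate_landscape, landscape_summary)

cfg = SynthConfig(gc_skew=-0.6, target_bound_size=150, noise_sd=0.02, seed=1)
rep1, rep2 = generate_landscape(cfg)

L = build_landscape(rep1, bind_threshold=0.35, min_component=100)
L.delta = estimate_delta(rep1, rep2)

print(json.dumps(landscape_summary(L), indent=2))
# "size" is the number of bound 8-mers in the dominant genotype network,
# "composition_bias" is Ti/(Ti + Tv/2) over its edges (0.5 = the null of one
# transition per two transversions; this AT-leaning factor sits below it),
# and "delta" is the score difference that measurement noise can explain.
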