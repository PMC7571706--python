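# tfscape

Mutation bias meets composition bias on transcription-factor binding-affinity
landscapes.

`tfscape` is a Python library for asking how a biased mutation supply — more
transitions (purine↔purine, pyrimidine↔pyrimidine) or more transversions —
interacts with the *composition* of a genotype–phenotype landscape to shape
adaptive evolution. The landscapes are those of transcription-factor (TF)
binding affinity: every double-stranded 8-mer gets a relative affinity score
(a protein-binding-microarray E-score in [−0.5, 0.5]), sequences with
E-score > 0.35 are "bound", and bound sequences connected by single point
mutations form a genotype network whose surface is the affinity itself.
Because the set of bound sequences is compositionally constrained (an
AT-rich factor binds AT-rich sites, whose interconversions are mostly
transversions), landscapes carry a **composition bias** — an enrichment of
one mutation class along adaptive paths that exists independently of any
bias in the mutation process.

Both biases are measured by the same statistic on the unit interval,

```
α = Ti / (Ti + Tv/2),
```

with `Ti`, `Tv` transition/transversion rates (mutation bias) or counts
(composition bias). α = 0.5 is the null of one transition per two
transversions; below 0.5 is transversion-enriched, above is
transition-enriched.

The library covers the full analysis pipeline:

- **genotype_space** — double-stranded (canonical) k-mer identity, reverse
  complementation, point-mutation neighborhoods, transition/transversion
  classification.
- **landscape** — score-table I/O (UniPROBE/CIS-BP-style TSV), binding
  threshold, dominant genotype network extraction, noise threshold δ from
  replicate regression, topography summaries.
- **bias_metrics** — composition bias of whole landscapes and of accessible
  mutational paths (steps gaining more than δ) to the global peak, under
  strict and relaxed accessibility and two counting semantics.
- **origin_fixation** — low-mutation-supply dynamics as a Markov jump chain
  with fixation weight φ·f (φ = α or 1−α by edge class, f the relative
  affinity gain): navigability `P_peak`, exact path-distribution Shannon
  entropy via the chain conditioned on absorption at the peak, quasispecies
  stationary distributions, and sweeps over 19 α values in [0.05, 0.95].
- **wright_fisher** — high-mutation-supply simulation with
  affinity-proportional selection and class-biased mutation
  (P(transition | mutation) = α/(2−α)).
- **population_stats** — multiset overlap coefficient, normalized Shannon
  diversity, nucleotide diversity π, mutational robustness, allele-frequency
  spectra, cross-landscape evolvability.
- **synthetic_data** — a generator of replicate score tables with tunable
  composition skew, bound-set size, ruggedness and replicate noise, plus
  hand-built toy landscapes with exactly known paths.
- **pipeline** / **cli** — ensemble tables over landscape collections and a
  thin `tfscape` command-line wrapper.

## Worked example

A six-node chain landscape whose five accessible steps are four
transversions and one transition:

```python
from tfscape import accessible_graph, path_composition_bias, toy_fixture

L = toy_fixture("single_path")
AG = accessible_graph(L, mode="strict", q=0.1)
b = path_composition_bias(AG)
print(b.value, b.ti, b.tv)   # 0.3333333333333333 1 4
```

The bias 1/(1 + 4/2) = 1/3 < 0.5 marks a transversion-enriched adaptive
path. On a full synthetic AT-rich landscape the same enrichment steers
navigability (`examples/03_navigability_sweep.py`):

```
 alpha p_peak
  0.05 0.9185
  0.50 0.8468
  0.95 0.7172
alpha maximizing P_peak: 0.05
```

`P_peak` is the probability that an origin-fixation walk from the 10%
lowest-affinity binding sites is absorbed at the global peak within 1000
fixation steps: a transversion-biased mutation supply (α < 0.5), aligned
with this landscape's composition bias, navigates best, and a
transition-biased supply loses about a fifth of the walks to local optima.
The other scripts in `examples/` demonstrate path-entropy predictability,
Wright–Fisher polymorphic dynamics, and the population statistics.

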