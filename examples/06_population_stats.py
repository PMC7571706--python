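"""Diversity, robustness, allele spectra and evolvability of evolved populations."""

from tfscape import (SynthConfig, WFConfig, allele_spectrum, evolvability,
                     generate_collection, nucleotide_diversity,
                     population_robustness, shannon_diversity, simulate)

collection = generate_collection(4, SynthConfig(target_bound_size=120, seed=8))
focal, others = collection[0], collection[1:]

cfg = WFConfig(N=2000, mu=0.02, alpha=0.5, generations=300, seed=2)
r = simulate(focal, cfg)
pop = r.final

print(f"Shannon diversity H      : {shannon_diversity(pop, focal.n):.4f}")
print(f"nucleotide diversity pi  : {nucleotide_diversity(pop):.5f}")
print(f"population robustness    : {population_robustness(pop, focal):.4f}")

reference = max(pop, key=pop.get)  # modal genotype of this unbiased run
spectrum = allele_spectrum(pop, reference)
print(f"\nspectrum vs modal genotype {reference} "
      f"(reference freq {spectrum.reference_freq:.3f}, "
      f"multi-hit {spectrum.multi_hit_freq:.3f}):")
print(spectrum.entries.to_string(index=False))

frac, count = evolvability(pop, focal, others)
print(f"\nevolvability: one-mutant neighbors of the evolved sites are bound "
      f"by {count}/{len(others)} other factors (fraction {frac:.2f})")
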