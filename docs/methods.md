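# Methods

## Genotypes and landscapes

A genotype is a double-stranded DNA 8-mer: the unordered pair of a sequence
and its reverse complement, represented by the lexicographically smaller
strand (the canonical form). There are (4^8 − 4^4)/2 + 4^4 = 32,896 such
genotypes. Two genotypes are mutational neighbors if some strand of one
differs from some strand of the other by a single substitution; on canonical
forms this gives 3k neighbors for non-palindromic k-mers and 3k/2 for
palindromes (whose position-i and position-(k+1−i) mutants coalesce).
Substitutions are transitions (A↔G, C↔T) or transversions (the other eight
changes); the classification is invariant under complementing both bases, so
it is well defined on double-stranded edges.

A landscape for one transcription factor starts from a score table assigning
each genotype a relative binding affinity (E-score in [−0.5, 0.5], or
optionally a Z-score through the same code path). Genotypes with score
strictly above the binding threshold (default 0.35) are bound; bound
genotypes and their mutational edges form the genotype network, of which
only the largest connected component (the dominant genotype network) is
kept, with a minimum-size requirement (default 100). Discarded component
sizes are recorded. The global peak is the maximum-score genotype; exact
ties are broken lexicographically (with a warning) so every run is
deterministic.

## Noise threshold δ

Affinity measurements are noisy, so score differences smaller than a
threshold δ are treated as indistinguishable. δ is the residual standard
error, sqrt(SSR/(n−2)), of an ordinary least-squares regression of the
second replicate's scores on the first's, over genotypes bound in **both**
replicates. Conventions fixed here because they are genuinely open: the
regression orientation (rep2 on rep1), and the bound-in-both rule for the
shared set. Because conditioning on bound-in-both censors large negative
residuals at the densely populated near-threshold shell, δ systematically
recovers only ~80% of the true replicate noise on the synthetic generator's
landscapes; the mid-range residual spread matches the injected noise, and
moving the threshold moves rather than removes the censoring. This
attenuation is a property of the estimator's definition, not a defect of
the fit, and the calibration test asserts recovery within [0.6, 1.05] of
the injected standard deviation.

## Bias statistics and accessibility

Mutation bias and composition bias share one statistic,
α = Ti/(Ti + Tv/2) ∈ [0, 1], scale invariant so rates and counts are
interchangeable. α = 0.5 is the null spectrum of one transition per two
transversions — exactly the ratio of transition to transversion
alternatives available at every site.

A mutation is *accessible* (strict mode) if it increases affinity by more
than δ; the strict accessible graph is therefore acyclic. Relaxed mode
instead admits any step that does not decrease affinity by more than δ and
may contain cycles. Start sets are the ⌈q·n⌉ lowest-affinity genotypes
(default q = 0.10; ties resolved by score then identity).

Path composition bias is computed over the edges lying on at least one
start→peak path. Two semantics are exposed: `edge_set` (each such edge
counted once — the default, cheap and unambiguous) and `path_weighted`
(edges weighted by their expected traversal count under the unbiased
origin-fixation chain conditioned on reaching the peak). They agree exactly
on single-path graphs; neither is canonical for multi-path graphs, so both
are kept and can be correlated.

Step gains report 100·(b_v − b_u)/b_u per accessible on-path edge, grouped
by mutation class and by the mutational distance of the source genotype to
the peak along accessible paths.

## Origin-fixation model (low mutation supply)

With Nμ ≪ 1 the population is monomorphic and adaptation is a jump chain:
P[i,j] = φ_ij·f_ij / Σ_k φ_ik·f_ik over improving neighbors, with
f_ij = w_j/w_i − 1 the relative fitness gain and φ_ij = α for transition
edges, 1 − α for transversion edges. Fitness w is the affinity itself
(linear, default) or a Gaussian exp(−((E − E_opt)/σ)²) with defaults
E_opt = 0.35, σ = 0.1 for the selection-for-low-affinity sensitivity
analysis. With `use_delta=True` (default) a move must additionally clear
the noise threshold, |b_j − b_i| > δ and w_j > w_i; for linear fitness this
reduces to b_j − b_i > δ. States with no allowed move are absorbing
(P[i,i] = 1): the walker waits at local peaks. Note the matrix definition
alone would be 0/0 there; the absorbing convention is the natural
completion.

Navigability P_peak is the mean over starts of (P^t)[start, peak] with
t = 1000, computed by repeated sparse matrix–vector products against the
peak indicator (never dense matrix powers). It is non-decreasing in t and
converges once t exceeds the longest accessible path.

### Path entropy

Predictability is the Shannon entropy (bits, base configurable) of the
distribution over mutational paths from a uniform start mixture to the
global peak, conditioned on absorption there — conditioning is necessary
because local peaks absorb probability mass and the unconditioned path
distribution over peak-reaching paths would not normalize. The conditioned
chain is the Doob transform P̃[i,j] = P[i,j]·q_j/q_i with q the absorption
probability at the peak (computed exactly by backward recursion in
decreasing fitness order — the improving chain is a DAG). The entropy is
evaluated exactly through the visit-count identity
H = H(start mixture) + Σ_i ν_i·h_i, with ν the expected visits under the
conditioned chain and h_i the per-state jump entropy. Tests verify the
identity against brute-force path enumeration to 1e−9 on hundreds of random
DAG landscapes.

### Sweeps and quasispecies steady states

α-sweeps use 19 linearly spaced values on [0.05, 0.95] (containing the
unbiased point 0.5) and report per-α P_peak and entropy plus the argmax/
argmin values and the entropy ratios entropy_nobias/entropy_min and
entropy_max/entropy_nobias. The infinite-population steady state is the
dominant left eigenvector of P (power iteration, tolerance 1e−12), compared
across α values by Euclidean distance. For a chain with a single absorbing
peak this eigenvector is degenerate — the peak indicator — and the
implementation reports it as such: a Perron–Frobenius argument for a unique
positive steady state requires an irreducible matrix, which the absorbing
jump chain is not, so the degenerate behavior is kept and documented rather
than patched.

## Wright–Fisher model (high mutation supply)

Each generation: N individuals are resampled with replacement with weights
proportional to binding affinity (off-landscape genotypes have weight 0);
each then mutates with probability μ (at most one substitution per
individual per generation — multi-hit is negligible at the μ used), choosing
among its 3k single-base alternatives with weight α per transition and
1 − α per transversion alternative, so P(transition | mutation) = α/(2−α),
independent of the parent sequence. Mutants leaving the bound set are
"lethal" by default (produced, then eliminated by the next selection round);
a "rejected" convention (mutation discarded) is available, since the fate
of off-landscape mutants is a genuinely open modeling choice. Runs are
bit-reproducible from (config, seed); mutation class counts are tallied for
calibration. Steady state is declared at the first generation after which
normalized Shannon diversity stays within a relative tolerance (default
1e−4) of the final value.

WF navigability is the fraction of replicate runs whose final population
has at least 50% of its individuals at the global peak. The paired
experimental design reuses the replicate index as the seed across α values,
so replicate-to-replicate stochasticity and the effect of mutation bias can
be compared on identical random streams via the overlap coefficient.

## Population statistics

- Overlap: |A ∩ B|/min(|A|, |B|) with min-multiplicity intersection.
- Shannon diversity: H = −Σ p_i log2 p_i / log2 n ∈ [0, 1], n the landscape
  size.
- Nucleotide diversity: π = Σ_{x,y} p_x p_y d(x,y)/k over ordered pairs,
  d the substitution distance minimized over strand orientation; the
  population estimator is the default, the N/(N−1) correction is a flag.
  (No formula is fixed by the source analysis; this is the standard
  population form.)
- Robustness of a genotype: fraction of its distinct canonical neighbors
  inside the dominant network (a flag switches to the full bound set, since
  usage alternates between the two). Population robustness is the
  count-weighted mean over in-landscape individuals.
- Allele spectra are reported against a reference sequence (the modal
  genotype of an unbiased run); each population genotype is oriented to the
  strand closer to the reference so positions are well defined, single-base
  differences are aggregated by (position, ref, alt, class), and genotypes
  more than one substitution away are reported as multi-hit mass. The three
  parts partition to 1.
- Evolvability: the fraction (and count) of other landscapes in a collection
  containing at least one one-mutant neighbor of the evolved population that
  is not itself in the focal landscape.

## Synthetic data generator

The generator emulates protein-binding-microarray exports for factors with
controllable composition preferences. A motif sequence is sampled from base
weights defined by two skews: `gc_skew` (−1 = AT-only … +1 = GC-only; both
extremes are transversion-enriched because A↔T and G↔C are transversions)
and `purine_skew` (+1 = {A,G}-only, whose internal edges are transitions —
the way to obtain transition-enriched landscapes). A genotype's score is
peak_score − slope · mismatch-cost, where a mismatch costs 1 unit for a
composition-favored base and up to 3 for a disfavored one; this makes the
*bound set*, not just the peak, carry the composition, which is the feature
the whole analysis turns on. Costs are evaluated in the motif's own strand
frame (purine content flips under reverse complementation, so a
canonical-frame evaluation would silently invert a purine skew for half the
sampled motifs). The slope is calibrated so the thresholded dominant
component reaches the target size (default 150, widened on bounded
retries), a jitter of 20% of one unit step roughens the surface, and
replicate 2 adds Gaussian noise (default sd 0.02, a typical replicate
scatter on the E-score scale relative to the 0.15-wide bound range).

Ruggedness: `n_local_peaks` (default 10) randomly chosen mid-cost genotypes
are boosted into local optima with scores in (0.45, 0.49). Under a
composition skew they are drawn from *off-motif* sequences carrying exactly
one disfavored base — the analogue of secondary binding preferences — so
the edges entering them are enriched for the landscape's minority mutation
class. This is what couples navigability to the alignment of mutation bias
with composition bias: a mutation supply biased toward the minority class
diverts adaptive walks into the decoys. The default of 10 was chosen to
place origin-fixation P_peak in the broad range reported for empirical
landscape ensembles (roughly 0.5–0.9 at these sizes, lower for larger
landscapes) rather than the ~1.0 of a smooth field.

What the generator does **not** emulate: biophysical energy models
(position interdependence, flanking context), probe-level normalization
artifacts, heteroscedastic noise, or the empirical joint distribution of
landscape size and ruggedness. Tests passing on synthetic ensembles
therefore demonstrate that the machinery correctly propagates
composition-bias structure into dynamics, not that any particular empirical
factor behaves quantitatively as simulated.

Hand-built toy fixtures ("single_path", "fork", "three_paths", "two_peaks")
provide miniature landscapes with exactly known paths, classes and scores
for oracle tests; the three-path fixture has one transversion-first and two
transition-first routes, so its path entropy is minimized at the
transversion extreme of the α grid.

## Problem sizes and numerical choices

Default study conditions: k = 8; binding threshold 0.35; minimum dominant
component 100 (synthetic target 150); α grid of 19 points on [0.05, 0.95];
origin-fixation horizon t = 1000; Wright–Fisher N = 10^4, 1000 generations,
Nμ ∈ {5, 20, 50} at full scale. Test-suite simulations scale N to
500–2500 and generations to 120–300 while keeping μ ≪ s (the selection
coefficient per accessible step, ~0.1–0.15 on synthetic landscapes), which
preserves the mutation–selection-balance regime in which at least half the
population sits on the peak genotype; ensemble checks use 30 landscapes per
composition class and 10 single-peak landscapes for the high-supply
insensitivity check. Power iteration tolerance is 1e−12; row-sum and
entropy identities are verified to 1e−12 and 1e−9 respectively. Seeds fix
every stochastic stage; sweep tables carry their generating seed.

## Known limitations

- Selection is linear in E-score (or the one Gaussian alternative); real
  affinity-to-fitness maps are nonlinear and context dependent.
- The origin-fixation fixation weight is proportional to the relative
  affinity gain, not a population-size-dependent fixation probability.
- The quasispecies steady state of an absorbing chain is degenerate (see
  above); genuinely α-dependent infinite-population steady states would
  require a mutation-selection matrix with backward mutation, which is not
  part of this model.
- Indels, IUPAC ambiguity codes and RNA alphabets are out of scope; k ≠ 8
  is supported for testing but not optimized.
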