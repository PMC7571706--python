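"""Wright-Fisher dynamics with affinity-proportional selection and biased mutation.

High mutation supply (N*mu > 1): many mutations segregate simultaneously and
compete for fixation ("pick the winner"). Each generation, N individuals are
resampled with replacement with probability proportional to binding affinity;
each then mutates with probability mu, choosing one of its 3k single-base
alternatives with weight alpha for the transition alternative at a position
and (1 - alpha) for each transversion alternative, so the per-mutation
transition probability is alpha / (2 - alpha) (1/3 at alpha = 0.5, matching
the null spectrum of one transition per two transversions).

Mutants that leave the landscape's bound set are handled by one of two
conventions: "lethal" (they are produced but carry zero fitness and are
eliminated by the next round of selection — the default) or "rejected" (the
mutation is discarded and the parent retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_space import TRANSITION, canonical, classify_mutation, ALPHABET
from .landscape import Landscape


@dataclass
class WFConfig:
    """Configuration of one Wright-Fisher run; (config, seed) fixes the trajectory."""

    N: int = 10_000
    mu: float = 5e-3
    alpha: float = 0.5
    generations: int = 1000
    seed: int = 0
    initial_genotype: str | None = None  # default: random pick from bottom 10%
    off_landscape: str = "lethal"  # or "rejected"

    @property
    def n_mu(self) -> float:
        return self.N * self.mu


@dataclass
class WFResult:
    """Trajectory summaries of one run.

    final maps genotype -> count at the last generation (off-landscape
    genotypes included under the lethal convention); diversity and
    peak_fraction are per-generation traces (index 0 = initial population).
    """

    config: WFConfig
    tf_name: str
    initial_genotype: str
    final: dict[str, int]
    diversity: np.ndarray
    peak_fraction: np.ndarray
    mutation_events: dict[str, int] = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return len(self.diversity) - 1


def _mutation_tables(L: Landscape):
    """Per-genotype mutation proposal tables, cached on the landscape.

    For genotype i, targets[i] holds the landscape index of each of the 3k
    single-base alternatives of the canonical strand (-1 if the mutant is not
    in the landscape), is_transition[i] marks the transition alternatives, and
    off_seqs[i] maps option slot -> canonical mutant sequence for off-landscape
    targets.
    """
    cache = getattr(L, "_wf_tables", None)
    if cache is not None:
        return cache
    k = L.k
    n_opt = 3 * k
    n = L.n
    targets = np.full((n, n_opt), -1, dtype=np.int64)
    is_tr = np.zeros((n, n_opt), dtype=bool)
    off_seqs: list[dict[int, str]] = []
    for i, g in enumerate(L.genotypes):
        off: dict[int, str] = {}
        slot = 0
        for pos, base in enumerate(g):
            for alt in ALPHABET:
                if alt == base:
                    continue
                mut = canonical(g[:pos] + alt + g[pos + 1 :])
                is_tr[i, slot] = classify_mutation(base, alt) == TRANSITION
                j = L.index.get(mut, -1)
                targets[i, slot] = j
                if j < 0:
                    off[slot] = mut
                slot += 1
        off_seqs.append(off)
    L._wf_tables = (targets, is_tr, off_seqs)
    return L._wf_tables


def _shannon(counts: np.ndarray, off_counts: dict[str, int], N: int, n: int) -> float:
    p = counts[counts > 0] / N
    h = -np.sum(p * np.log2(p))
    for c in off_counts.values():
        q = c / N
        h -= q * np.log2(q)
    return float(h / np.log2(n)) if n >= 2 else 0.0


def simulate(L: Landscape, cfg: WFConfig) -> WFResult:
    """Run one Wright-Fisher trajectory on a landscape.

    Selection weights are the binding scores (zero for off-landscape
    genotypes). Mutation draws at most one substitution per individual per
    generation (Bernoulli(mu)). Fully reproducible under cfg.seed.
    """
    if cfg.off_landscape not in ("lethal", "rejected"):
        raise ValueError("off_landscape must be 'lethal' or 'rejected'")
    rng = np.random.default_rng(cfg.seed)
    targets, is_tr, off_seqs = _mutation_tables(L)
    n, N = L.n, cfg.N
    peak = L.peak_index

    if cfg.initial_genotype is None:
        bottom = L.bottom_fraction()
        init = int(rng.choice(bottom))
    else:
        g0 = canonical(cfg.initial_genotype)
        if g0 not in L.index:
            raise ValueError(f"initial genotype {g0} not in landscape")
        init = L.index[g0]

    # per-option proposal weights for this alpha, normalized per genotype row
    w_opt = np.where(is_tr, cfg.alpha, 1.0 - cfg.alpha)
    w_opt = w_opt / w_opt.sum(axis=1, keepdims=True)

    counts = np.zeros(n, dtype=np.int64)
    counts[init] = N
    off: dict[str, int] = {}
    scores = L.scores
    div = [_shannon(counts, off, N, n)]
    pf = [counts[peak] / N]
    events = {TRANSITION: 0, "transversion": 0}

    for _ in range(cfg.generations):
        # selection: off-landscape individuals have zero weight and vanish
        weights = counts * scores
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("population extinct: no bound genotypes to select")
        counts = rng.multinomial(N, weights / total)
        off = {}
        # mutation: Bernoulli(mu) per individual, one substitution each
        if cfg.mu > 0:
            n_mut = rng.binomial(counts, cfg.mu)
            occupied = np.flatnonzero(n_mut)
            if occupied.size:
                draws = rng.multinomial(n_mut[occupied], w_opt[occupied])
                n_tr = int(np.sum(draws[is_tr[occupied]]))
                events[TRANSITION] += n_tr
                events["transversion"] += int(draws.sum()) - n_tr
                counts[occupied] -= n_mut[occupied]
                tgt = targets[occupied]
                in_mask = tgt >= 0
                np.add.at(counts, tgt[in_mask], draws[in_mask])
                out_rows, out_slots = np.nonzero(~in_mask & (draws > 0))
                for r, s in zip(out_rows, out_slots):
                    c = int(draws[r, s])
                    if cfg.off_landscape == "rejected":
                        counts[occupied[r]] += c
                    else:
                        seq = off_seqs[occupied[r]][s]
                        off[seq] = off.get(seq, 0) + c
        div.append(_shannon(counts, off, N, n))
        pf.append(counts[peak] / N)

    final = {L.genotypes[i]: int(c) for i, c in enumerate(counts) if c > 0}
    final.update(off)
    return WFResult(config=cfg, tf_name=L.tf_name,
                    initial_genotype=L.genotypes[init], final=final,
                    diversity=np.array(div), peak_fraction=np.array(pf),
                    mutation_events=events)


def p_peak_wf(results: list[WFResult], peak: str, N: int | None = None) -> float:
    """Fraction of runs whose final population is >= 50% at the global peak."""
    if not results:
        raise ValueError("need at least one completed run")
    hits = 0
    for r in results:
        total = N if N is not None else r.config.N
        if r.final.get(peak, 0) >= 0.5 * total:
            hits += 1
    return hits / len(results)


def steady_state_reached(diversity: np.ndarray, tol: float = 1e-4) -> int | None:
    """First generation after which diversity stays within ``tol`` (relative)
    of the final value; None only for an empty trace."""
    d = np.asarray(diversity, dtype=float)
    if d.size < 1:
        return None
    final = d[-1]
    band = tol * abs(final)
    inside = np.abs(d - final) <= band
    # last False, then everything after is inside
    bad = np.flatnonzero(~inside)
    return 0 if bad.size == 0 else int(bad[-1] + 1)
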