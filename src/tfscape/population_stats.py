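"""Statistics on evolved populations and landscape collections.

Populations are multisets of genotypes (genotype -> count). The statistics
here quantify similarity between populations (overlap coefficient), genetic
diversity (normalized Shannon index, nucleotide diversity pi), mutational
robustness, allele-frequency spectra relative to a reference sequence, and
evolvability across a collection of landscapes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genotype_space as gs
from .landscape import Landscape


def overlap(a, b) -> float:
    """Multiset overlap coefficient |A ∩ B| / min(|A|, |B|).

    The intersection takes the elementwise minimum multiplicity. Symmetric,
    in [0, 1]; 1 iff one multiset is contained in the other up to capacity,
    0 iff the supports are disjoint.
    """
    ca, cb = Counter(a), Counter(b)
    na, nb = sum(ca.values()), sum(cb.values())
    if na == 0 or nb == 0:
        raise ValueError("overlap of an empty multiset is undefined")
    inter = sum(min(ca[x], cb[x]) for x in ca.keys() & cb.keys())
    return inter / min(na, nb)


def shannon_diversity(pop, n: int) -> float:
    """Normalized Shannon diversity H = -sum p_i log2 p_i / log2 n, in [0, 1].

    ``n`` is the number of sequences in the landscape (the normalizing
    alphabet size); 0 for a monomorphic population, 1 for a uniform
    population over all n landscape genotypes.
    """
    if n < 2:
        raise ValueError("landscape size n must be >= 2")
    c = Counter(pop)
    total = sum(c.values())
    if total == 0:
        raise ValueError("population is empty")
    p = np.array([v / total for v in c.values() if v > 0])
    return float(-np.sum(p * np.log2(p)) / np.log2(n))


def nucleotide_diversity(pop, corrected: bool = False) -> float:
    """Nucleotide diversity pi: expected per-site differences between two
    random individuals.

    pi = sum_{x,y} p_x p_y d(x, y) / k over ordered pairs, with d the
    double-stranded substitution distance (minimized over strand
    orientation). The population (uncorrected) estimator is the default;
    ``corrected`` applies the N/(N-1) sample-size factor.
    """
    c = Counter(pop)
    total = sum(c.values())
    if total == 0:
        raise ValueError("population is empty")
    gens = sorted(c)
    k = len(gens[0])
    p = np.array([c[g] / total for g in gens])
    m = len(gens)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = gs.strand_distance(gens[i], gens[j]) / k
    pi = float(p @ D @ p)
    if corrected:
        if total < 2:
            raise ValueError("sample correction requires N >= 2")
        pi *= total / (total - 1)
    return pi


def robustness(g: str, L: Landscape, member_set=None) -> float:
    """Fraction of all point mutations of ``g`` that stay in the landscape.

    The denominator is the number of distinct canonical neighbors (3k for
    non-palindromes, 3k/2 for palindromes). ``member_set`` overrides the
    membership test (e.g. the full bound set instead of the dominant
    network).
    """
    members = member_set if member_set is not None else L.index
    if g not in L.index and member_set is None:
        raise ValueError(f"{g} is not in the landscape")
    nbrs = gs.neighbors(g)
    return sum(1 for nb, _ in nbrs if nb in members) / len(nbrs)


def population_robustness(pop, L: Landscape, member_set=None) -> float:
    """Count-weighted mean robustness of the in-landscape part of a population."""
    c = Counter(pop)
    total = 0
    acc = 0.0
    for g, cnt in c.items():
        if g in L.index:
            acc += cnt * robustness(g, L, member_set)
            total += cnt
    if total == 0:
        raise ValueError("population contains no landscape genotypes")
    return acc / total


@dataclass
class SpectrumResult:
    """Allele-frequency spectrum of a population relative to a reference.

    entries: one row per segregating single-base difference (position is
    1-based on the reference's stored orientation); multi_hit_freq is the
    aggregate frequency of genotypes more than one substitution away;
    reference_freq + sum(entries.freq) + multi_hit_freq == 1.
    """

    reference: str
    entries: pd.DataFrame
    multi_hit_freq: float
    reference_freq: float


def allele_spectrum(pop, reference: str) -> SpectrumResult:
    """Polymorphism spectrum relative to ``reference`` (typically the modal
    genotype of the unbiased run).

    Each population genotype is oriented to whichever strand is closer to the
    reference, so positions are well defined on the reference's orientation.
    """
    c = Counter(pop)
    total = sum(c.values())
    if total == 0:
        raise ValueError("population is empty")
    agg: dict[tuple[int, str, str], float] = {}
    multi = 0.0
    ref_freq = 0.0
    for g, cnt in c.items():
        freq = cnt / total
        fwd, rev = g, gs.revcomp(g)
        d_f, d_r = gs.hamming(fwd, reference), gs.hamming(rev, reference)
        seq, d = (fwd, d_f) if d_f <= d_r else (rev, d_r)
        if d == 0:
            ref_freq += freq
        elif d == 1:
            pos = next(i for i in range(len(seq)) if seq[i] != reference[i])
            key = (pos + 1, reference[pos], seq[pos])
            agg[key] = agg.get(key, 0.0) + freq
        else:
            multi += freq
    rows = [
        {"position": pos, "ref": rb, "alt": ab,
         "mclass": gs.classify_mutation(rb, ab), "freq": f}
        for (pos, rb, ab), f in sorted(agg.items())
    ]
    entries = pd.DataFrame(rows, columns=["position", "ref", "alt", "mclass", "freq"])
    return SpectrumResult(reference=reference, entries=entries,
                          multi_hit_freq=multi, reference_freq=ref_freq)


def evolvability(pop, focal: Landscape, collection: list[Landscape]):
    """Access of a population's mutational neighborhood to other TF landscapes.

    Collects the one-mutant neighbors of every genotype present in the
    population that are NOT in the focal landscape, and reports (fraction,
    count) of collection landscapes that contain at least one such neighbor.
    """
    if not collection:
        raise ValueError("collection must be nonempty")
    if any(Lc is focal or Lc.tf_name == focal.tf_name for Lc in collection):
        raise ValueError("collection must exclude the focal landscape")
    novel: set[str] = set()
    for g in Counter(pop):
        for nb, _ in gs.neighbors(g):
            if nb not in focal.index:
                novel.add(nb)
    count = sum(1 for Lc in collection if any(nb in Lc.index for nb in novel))
    return count / len(collection), count
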