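"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import tfscape as t


@pytest.fixture(scope="session")
def fork():
    return t.toy_fixture("fork")


@pytest.fixture(scope="session")
def single_path():
    return t.toy_fixture("single_path")


@pytest.fixture(scope="session")
def three_paths():
    return t.toy_fixture("three_paths")


@pytest.fixture(scope="session")
def two_peaks():
    return t.toy_fixture("two_peaks")


def enumerate_paths(M, starts):
    """Independent oracle: all start->absorption paths with raw probabilities.

    Depth-first enumeration over the jump chain's nonzero entries; paths end
    at an absorbing state. Returns [(path tuple, raw probability)] with raw
    probability including the uniform 1/len(starts) start factor.
    """
    P = M.P.toarray()
    n = P.shape[0]
    out = []

    def walk(i, prob, path):
        if M.absorbing[i]:
            out.append((tuple(path), prob))
            return
        for j in range(n):
            if j != i and P[i, j] > 0:
                walk(j, prob * P[i, j], path + [j])

    for s in starts:
        walk(s, 1.0 / len(starts), [s])
    return out


def entropy_by_enumeration(M, starts, peak):
    """Brute-force path entropy: condition enumerated paths on ending at peak."""
    paths = [(p, pr) for p, pr in enumerate_paths(M, starts) if p[-1] == peak]
    z = sum(pr for _, pr in paths)
    if z <= 0:
        raise ValueError("peak unreachable")
    return -sum((pr / z) * math.log2(pr / z) for _, pr in paths)


def mc_p_peak(M, start, t_steps, n_walkers, rng):
    """Monte-Carlo origin-fixation walkers, propagated as multinomial counts."""
    P = M.P.toarray()
    n = P.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    counts[start] = n_walkers
    for _ in range(t_steps):
        new = np.zeros(n, dtype=np.int64)
        for i in np.flatnonzero(counts):
            if M.absorbing[i]:
                new[i] += counts[i]
            else:
                new += rng.multinomial(counts[i], P[i])
        counts = new
    return counts


def brute_canonical_count(k):
    """Canonical genotype count via Biopython's reverse complement."""
    from Bio.Seq import Seq

    seen = set()
    for tup in itertools.product("ACGT", repeat=k):
        s = "".join(tup)
        rc = str(Seq(s).reverse_complement())
        seen.add(min(s, rc))
    return len(seen)


def random_dag_landscape(rng, n_nodes, k=8):
    """A random connected landscape grown by neighbor accretion.

    Scores are distinct uniforms on (0.36, 0.5), delta = 0, so the strict
    accessible moves form a nontrivial DAG.
    """
    genos = t.enumerate_genotypes(k)
    g0 = genos[rng.integers(len(genos))]
    nodes = {g0}
    frontier = [g0]
    while len(nodes) < n_nodes and frontier:
        g = frontier[rng.integers(len(frontier))]
        nbs = [nb for nb, _ in t.neighbors(g) if nb not in nodes]
        if not nbs:
            frontier.remove(g)
            continue
        nb = nbs[rng.integers(len(nbs))]
        nodes.add(nb)
        frontier.append(nb)
    scores = {g: 0.36 + 0.14 * rng.random() for g in sorted(nodes)}
    table = t.ScoreTable(tf_name=f"dag{rng.integers(1 << 30)}", scores=scores)
    L = t.build_landscape(table, min_component=1)
    L.delta = 0.0
    return L
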