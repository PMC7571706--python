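"""Origin-fixation (weak-mutation) dynamics on a binding-affinity landscape.

When the mutation supply is low (N*mu << 1) adaptation proceeds as a Markov
jump chain on the genotype network: at each step the population, monomorphic
at genotype i, fixes one improving neighbor j with probability

    P[i,j] = phi_ij * f_ij / sum_k phi_ik * f_ik,

where f_ij = w_j/w_i - 1 for improving moves (0 otherwise) is the relative
fitness advantage, and phi_ij is alpha for a transition edge and 1 - alpha
for a transversion edge — the mutation-bias parameter alpha on (0, 1), with
0.5 the unbiased supply of one transition per two transversions. Genotypes
with no improving neighbor are absorbing (the walker waits at local peaks).

This module provides the jump matrix, t-step navigability P_peak, the exact
Shannon entropy of the distribution of mutational paths to the global peak
(via the chain conditioned on absorption at the peak), the infinite-
population stationary distribution (dominant eigenvector), and sweeps over
a grid of alpha values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .genotype_space import TRANSITION
from .landscape import Landscape

ALPHA_GRID = np.linspace(0.05, 0.95, 19)
DEFAULT_T = 1000


def fitness_values(L: Landscape, fitness: str = "linear",
                   e_opt: float = 0.35, sigma: float = 0.1) -> np.ndarray:
    """Map binding scores to fitness: identity, or a Gaussian around e_opt."""
    b = L.scores
    if fitness == "linear":
        if np.any(b <= 0):
            raise ValueError("linear fitness requires strictly positive scores")
        return b.astype(float)
    if fitness == "gaussian":
        return np.exp(-(((b - e_opt) / sigma) ** 2))
    raise ValueError(f"unknown fitness kind {fitness!r}")


@dataclass
class MarkovModel:
    """Sparse origin-fixation jump matrix over landscape genotypes."""

    landscape: Landscape
    alpha: float
    P: sparse.csr_matrix
    fitness: np.ndarray
    absorbing: np.ndarray  # bool per state
    use_delta: bool = True
    fitness_kind: str = "linear"

    @property
    def n(self) -> int:
        return self.landscape.n

    @property
    def peak_index(self) -> int:
        return self.landscape.peak_index

    def successors(self, i: int):
        row = self.P.getrow(i)
        for j, p in zip(row.indices, row.data):
            if j != i:
                yield int(j), float(p)


def build_matrix(L: Landscape, alpha: float, fitness: str = "linear",
                 use_delta: bool = True, e_opt: float = 0.35,
                 sigma: float = 0.1) -> MarkovModel:
    """Construct the origin-fixation jump matrix for mutation bias ``alpha``.

    A move i -> j is allowed when it improves fitness; with use_delta=True the
    underlying score difference must additionally exceed the landscape's noise
    threshold (|b_j - b_i| > delta), matching the accessibility criterion.
    For the default linear fitness the two conditions together reduce to
    b_j - b_i > delta. Rows with no allowed move are absorbing.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    w = fitness_values(L, fitness, e_opt, sigma)
    b, d = L.scores, L.delta
    n = L.n
    rows, cols, vals = [], [], []
    absorbing = np.zeros(n, dtype=bool)
    for i in range(n):
        weights = []
        for j, cls in L.adjacency[i]:
            if w[j] <= w[i]:
                continue
            if use_delta and abs(b[j] - b[i]) <= d:
                continue
            phi = alpha if cls == TRANSITION else 1.0 - alpha
            weights.append((j, phi * (w[j] / w[i] - 1.0)))
        total = sum(v for _, v in weights)
        if total <= 0:
            absorbing[i] = True
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
        else:
            for j, v in weights:
                rows.append(i)
                cols.append(j)
                vals.append(v / total)
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return MarkovModel(landscape=L, alpha=alpha, P=P, fitness=w,
                       absorbing=absorbing, use_delta=use_delta,
                       fitness_kind=fitness)


def p_peak(M: MarkovModel, starts: list[int] | None = None,
           t: int = DEFAULT_T) -> float:
    """Mean probability over starts of being at the global peak after t steps.

    Computed as repeated sparse matrix-vector products on the indicator of the
    peak: after the loop x[i] = (P^t)[i, peak]. Non-decreasing in t because
    the peak is absorbing.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if starts is None:
        starts = M.landscape.bottom_fraction()
    if len(starts) == 0:
        raise ValueError("starts must be nonempty")
    x = np.zeros(M.n)
    x[M.peak_index] = 1.0
    for _ in range(t):
        x = M.P @ x
    return float(np.mean(x[starts]))


def absorption_at_peak(M: MarkovModel) -> np.ndarray:
    """q[i] = probability that the chain started at i is absorbed at the peak.

    Exact backward recursion in decreasing-fitness order (allowed moves
    strictly increase fitness, so the chain is a DAG plus absorbing loops).
    """
    q = np.zeros(M.n)
    q[M.peak_index] = 1.0
    order = np.argsort(-M.fitness, kind="stable")
    for i in order:
        if M.absorbing[i]:
            continue
        q[i] = sum(p * q[j] for j, p in M.successors(i))
    return q


def conditioned_chain(M: MarkovModel, starts: list[int]):
    """Doob transform of the chain, conditioned on absorption at the peak.

    Returns (start_weights, P_tilde, visits): start_weights maps start state ->
    probability under the uniform-start mixture conditioned on reaching the
    peak; P_tilde maps transient state i -> {j: conditioned jump probability};
    visits maps state -> expected number of visits under the conditioned
    mixture (the peak itself is terminal and gets no outgoing row).
    """
    if len(starts) == 0:
        raise ValueError("starts must be nonempty")
    q = absorption_at_peak(M)
    total = sum(q[s] for s in starts)
    if total <= 0:
        raise ValueError("global peak unreachable from every start")
    w = {int(s): q[s] / total for s in starts if q[s] > 0}
    Pt: dict[int, dict[int, float]] = {}
    for i in range(M.n):
        if M.absorbing[i] or q[i] <= 0:
            continue
        row = {}
        for j, p in M.successors(i):
            if q[j] > 0:
                row[j] = p * q[j] / q[i]
        Pt[i] = row
    # forward accumulation of expected visits in increasing-fitness order
    visits = {i: w.get(i, 0.0) for i in list(Pt) + [M.peak_index]}
    for s in w:
        visits.setdefault(s, w[s])
    order = sorted(visits, key=lambda i: M.fitness[i])
    for i in order:
        if i not in Pt:
            continue
        vi = visits[i]
        if vi == 0:
            continue
        for j, p in Pt[i].items():
            visits[j] = visits.get(j, 0.0) + vi * p
    return w, Pt, visits


def path_entropy(M: MarkovModel, starts: list[int] | None = None,
                 log_base: float = 2.0) -> float:
    """Shannon entropy of the distribution over mutational paths to the peak.

    The path distribution is that of the origin-fixation chain started from a
    uniform mixture over the start set and conditioned on absorption at the
    global peak. Entropy is computed exactly through the conditioned chain via
    the visit-count identity H = H(start mixture) + sum_i nu_i * h_i, where
    nu_i is the expected number of visits to i and h_i the entropy of i's
    conditioned jump distribution. Base-2 logarithms by default (bits).
    """
    if starts is None:
        starts = M.landscape.bottom_fraction()
    w, Pt, visits = conditioned_chain(M, starts)
    lb = math.log(log_base)
    H = -sum(p * math.log(p) for p in w.values() if p > 0) / lb
    for i, row in Pt.items():
        vi = visits.get(i, 0.0)
        if vi == 0:
            continue
        hi = -sum(p * math.log(p) for p in row.values() if p > 0) / lb
        H += vi * hi
    return H


@dataclass
class SweepResult:
    """Per-alpha navigability and predictability over the mutation-bias grid."""

    tf_name: str
    table: pd.DataFrame  # columns: alpha, p_peak[, entropy]
    alpha_max_ppeak: float
    alpha_min_entropy: float | None = None
    alpha_max_entropy: float | None = None
    entropy_no_bias: float | None = None
    entropy_reduction: float | None = None  # entropy_no_bias / entropy_min
    entropy_gain: float | None = None  # entropy_max / entropy_no_bias
    extras: dict = field(default_factory=dict)


def alpha_sweep(L: Landscape, grid: np.ndarray | None = None, t: int = DEFAULT_T,
                fitness: str = "linear", use_delta: bool = True,
                q: float = 0.10, compute_entropy: bool = True) -> SweepResult:
    """Evaluate P_peak (and optionally path entropy) on a grid of alpha values.

    The default grid is 19 linearly spaced values on [0.05, 0.95], which
    contains the unbiased point alpha = 0.5; entropy ratios are reported
    relative to the grid value closest to 0.5.
    """
    if grid is None:
        grid = ALPHA_GRID
    grid = np.asarray(grid, dtype=float)
    starts = L.bottom_fraction(q)
    rows = []
    for a in grid:
        M = build_matrix(L, alpha=float(a), fitness=fitness, use_delta=use_delta)
        row = {"alpha": float(a), "p_peak": p_peak(M, starts, t)}
        if compute_entropy:
            row["entropy"] = path_entropy(M, starts)
        rows.append(row)
    table = pd.DataFrame(rows)
    res = SweepResult(
        tf_name=L.tf_name, table=table,
        alpha_max_ppeak=float(table.alpha[table.p_peak.idxmax()]),
    )
    if compute_entropy:
        ent = table.entropy.to_numpy()
        i0 = int(np.argmin(np.abs(grid - 0.5)))
        res.alpha_min_entropy = float(grid[np.argmin(ent)])
        res.alpha_max_entropy = float(grid[np.argmax(ent)])
        res.entropy_no_bias = float(ent[i0])
        emin, emax = float(ent.min()), float(ent.max())
        res.entropy_reduction = res.entropy_no_bias / emin if emin > 0 else np.inf
        res.entropy_gain = emax / res.entropy_no_bias if res.entropy_no_bias > 0 else np.inf
    return res


def stationary_distribution(P, tol: float = 1e-12, max_iter: int = 200_000) -> np.ndarray:
    """Dominant left eigenvector of a nonnegative matrix, normalized to sum 1.

    Power iteration on row vectors (x <- xP); this is the quasispecies steady
    state of an infinite population. For a chain with a single absorbing state
    reachable from everywhere this degenerates to the indicator of that state.
    """
    if hasattr(P, "P"):  # accept a MarkovModel
        P = P.P
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("matrix must be square")
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = x @ P
        s = y.sum()
        if s <= 0:
            raise ValueError("matrix has a zero row sum under iteration")
        y = np.asarray(y).ravel() / s
        if np.abs(y - x).sum() < tol:
            return y
        x = y
    raise RuntimeError(f"power iteration did not converge within {max_iter} steps")


def steady_state_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance between two steady-state distributions."""
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have the same dimension")
    return float(np.linalg.norm(v1 - v2))
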