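"""Per-landscape and ensemble analyses as tidy tables.

Each function takes a list of built landscapes (with delta set) and returns
pandas DataFrames mirroring the study's figure panels: composition-bias
reports, navigability and predictability sweeps over the mutation-bias grid,
Wright-Fisher suites, and quasispecies steady states. Stochastic stages
carry their generating seed in the output so every row is regenerable.

Ensemble hypothesis tests (t tests, Kolmogorov-Smirnov, correlations) are
computed with scipy.stats and are descriptive summaries only.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .bias_metrics import (UnreachablePeakError, accessible_graph,
                           landscape_composition_bias, path_composition_bias)
from .landscape import Landscape, landscape_summary
from .origin_fixation import (ALPHA_GRID, alpha_sweep, build_matrix,
                              stationary_distribution, steady_state_distance)
from .population_stats import overlap, population_robustness
from .wright_fisher import WFConfig, p_peak_wf, simulate


def run_bias_report(landscapes: list[Landscape], mode: str = "strict",
                    semantics: str = "edge_set", q: float = 0.10,
                    deltas: list[float] | None = None) -> pd.DataFrame:
    """One row per landscape (or per landscape x delta in delta-sweep mode):
    size, GC content, degree, robustness, whole-landscape and path
    composition bias."""
    if not landscapes:
        raise ValueError("no landscapes given")
    rows = []
    for L in landscapes:
        for d in (deltas if deltas is not None else [L.delta]):
            old = L.delta
            L.delta = d
            summary = landscape_summary(L)
            try:
                AG = accessible_graph(L, mode=mode, q=q)
                pb = path_composition_bias(AG, semantics=semantics)
                path_bias, ti, tv = pb.value, pb.ti, pb.tv
            except UnreachablePeakError:
                path_bias = ti = tv = None
            finally:
                L.delta = old
            rows.append({
                "tf": L.tf_name, "delta": d, "size": summary["size"],
                "mean_gc": summary["mean_gc"],
                "mean_degree": summary["mean_degree"],
                "mean_robustness": summary["mean_robustness"],
                "landscape_bias": summary["composition_bias"],
                "mode": mode, "semantics": semantics,
                "ti": ti, "tv": tv, "path_bias": path_bias,
            })
    return pd.DataFrame(rows)


def run_navigability(landscapes: list[Landscape], grid=None, t: int = 1000,
                     fitness: str = "linear", use_delta: bool = True):
    """P_peak over the alpha grid; returns (per-alpha table, per-landscape summary)."""
    if not landscapes:
        raise ValueError("no landscapes given")
    grid = ALPHA_GRID if grid is None else np.asarray(grid, float)
    tables, summaries = [], []
    for L in landscapes:
        res = alpha_sweep(L, grid=grid, t=t, fitness=fitness,
                          use_delta=use_delta, compute_entropy=False)
        tab = res.table.copy()
        tab.insert(0, "tf", L.tf_name)
        tables.append(tab)
        summaries.append({"tf": L.tf_name, "alpha_max_ppeak": res.alpha_max_ppeak,
                          "p_peak_max": float(res.table.p_peak.max()),
                          "p_peak_no_bias": float(
                              res.table.p_peak[np.argmin(np.abs(grid - 0.5))])})
    return pd.concat(tables, ignore_index=True), pd.DataFrame(summaries)


def run_predictability(landscapes: list[Landscape], grid=None, t: int = 1000,
                       use_delta: bool = True):
    """Path entropy over the alpha grid plus argmin/argmax and entropy ratios."""
    if not landscapes:
        raise ValueError("no landscapes given")
    grid = ALPHA_GRID if grid is None else np.asarray(grid, float)
    tables, summaries = [], []
    for L in landscapes:
        res = alpha_sweep(L, grid=grid, t=t, use_delta=use_delta,
                          compute_entropy=True)
        tab = res.table.copy()
        tab.insert(0, "tf", L.tf_name)
        tables.append(tab)
        summaries.append({
            "tf": L.tf_name, "alpha_min_entropy": res.alpha_min_entropy,
            "alpha_max_entropy": res.alpha_max_entropy,
            "entropy_no_bias": res.entropy_no_bias,
            "entropy_reduction": res.entropy_reduction,
            "entropy_gain": res.entropy_gain,
        })
    return pd.concat(tables, ignore_index=True), pd.DataFrame(summaries)


def run_wf_suite(landscapes: list[Landscape], N: int = 10_000, mu: float = 5e-3,
                 alphas=None, replicates: int = 15, initial_conditions: int = 10,
                 generations: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Wright-Fisher grid: replicates x initial conditions x alpha per landscape.

    Replicate index seeds the generator (shared across alpha values), so rows
    that differ only in alpha used identical random streams — the design that
    lets replicate-to-replicate stochasticity be compared against the effect
    of mutation bias. Returns one row per run with final diversity,
    robustness, peak occupancy and the run's seed.
    """
    if not landscapes:
        raise ValueError("no landscapes given")
    alphas = ALPHA_GRID if alphas is None else np.asarray(alphas, float)
    rows = []
    for li, L in enumerate(landscapes):
        rng = np.random.default_rng(seed + li)
        bottom = L.bottom_fraction()
        inits = [L.genotypes[i] for i in
                 rng.choice(bottom, size=min(initial_conditions, len(bottom)),
                            replace=len(bottom) < initial_conditions)]
        for ic, g0 in enumerate(inits):
            for rep in range(replicates):
                run_seed = seed * 1_000_000 + li * 10_000 + ic * 100 + rep
                for a in alphas:
                    cfg = WFConfig(N=N, mu=mu, alpha=float(a),
                                   generations=generations, seed=run_seed,
                                   initial_genotype=g0)
                    r = simulate(L, cfg)
                    rows.append({
                        "tf": L.tf_name, "initial": g0, "replicate": rep,
                        "alpha": float(a), "seed": run_seed, "N": N, "mu": mu,
                        "diversity": float(r.diversity[-1]),
                        "robustness": population_robustness(r.final, L),
                        "peak_fraction": float(r.peak_fraction[-1]),
                        "reached_peak": bool(r.peak_fraction[-1] >= 0.5),
                        "final": r.final,
                    })
    return pd.DataFrame(rows)


def wf_overlap_comparison(suite: pd.DataFrame) -> pd.DataFrame:
    """Overlap coefficients for pairs of evolved populations.

    "replicates" pairs share everything but the seed (same alpha, same
    initial condition); "mutation_bias" pairs share the seed and initial
    condition but differ in alpha. Mirrors the replicate-versus-bias
    comparison of the polymorphic-population experiment.
    """
    rows = []
    for (tf, init, a), grp in suite.groupby(["tf", "initial", "alpha"]):
        for r1, r2 in itertools.combinations(grp.itertuples(), 2):
            rows.append({"tf": tf, "kind": "replicates", "alpha_diff": 0.0,
                         "overlap": overlap(r1.final, r2.final)})
    for (tf, init, rep), grp in suite.groupby(["tf", "initial", "replicate"]):
        for r1, r2 in itertools.combinations(grp.itertuples(), 2):
            rows.append({"tf": tf, "kind": "mutation_bias",
                         "alpha_diff": abs(r1.alpha - r2.alpha),
                         "overlap": overlap(r1.final, r2.final)})
    return pd.DataFrame(rows)


def wf_navigability(suite: pd.DataFrame) -> pd.DataFrame:
    """Fraction of runs per (tf, alpha) with >= 50% of the population at the peak."""
    return (suite.groupby(["tf", "alpha"])
            .reached_peak.mean().rename("p_peak_wf").reset_index())


def run_quasispecies(landscapes: list[Landscape], grid=None,
                     use_delta: bool = True):
    """Infinite-population steady states over the alpha grid.

    Returns (per-landscape steady-state vectors keyed by alpha, pairwise
    Euclidean distances versus the difference in alpha).
    """
    if not landscapes:
        raise ValueError("no landscapes given")
    grid = ALPHA_GRID if grid is None else np.asarray(grid, float)
    vectors: dict[str, dict[float, np.ndarray]] = {}
    rows = []
    for L in landscapes:
        vecs = {}
        for a in grid:
            M = build_matrix(L, alpha=float(a), use_delta=use_delta)
            vecs[float(a)] = stationary_distribution(M.P)
        vectors[L.tf_name] = vecs
        for a1, a2 in itertools.combinations(sorted(vecs), 2):
            rows.append({"tf": L.tf_name, "alpha_1": a1, "alpha_2": a2,
                         "alpha_diff": abs(a2 - a1),
                         "distance": steady_state_distance(vecs[a1], vecs[a2])})
    return vectors, pd.DataFrame(rows)
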