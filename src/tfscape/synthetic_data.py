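"""Synthetic protein-binding-microarray score tables and hand-built fixtures.

The generator emulates the statistical structure the analysis assumes: a
smooth affinity field around a seeded motif sequence (score decreasing with
a composition-weighted mismatch cost), seeded off-motif local optima for
ruggedness, composition control through base-composition skews, and a pair
of noisy replicate tables for noise-threshold estimation. Scores live on
the E-score scale: bound sequences fall in (0.35, 0.5].

Composition control:

* ``gc_skew`` < 0 concentrates the bound set on AT-rich sequences and > 0 on
  GC-rich sequences; both extremes are transversion-enriched (A<->T and
  G<->C changes are transversions), reproducing the U-shaped relation
  between GC content and composition bias.
* ``purine_skew`` > 0 concentrates the bound set on purine-rich ({A, G})
  sequences, whose internal edges are transitions — the way to build
  transition-enriched landscapes.

No claim of biophysical realism is made; the field is a controllable
surrogate for real microarray exports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import genotype_space as gs
from .landscape import (DEFAULT_BIND_THRESHOLD, Landscape, ScoreTable,
                        build_landscape, estimate_delta)

_BASE_INDEX = {b: i for i, b in enumerate(gs.ALPHABET)}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic landscape; (config, seed) is reproducible."""

    k: int = 8
    gc_skew: float = 0.0  # in [-1, 1]: -1 AT-only ... +1 GC-only bound region
    purine_skew: float = 0.0  # in [-1, 1]: +1 purine-only (transition-rich)
    target_bound_size: int = 150
    noise_sd: float = 0.02  # replicate score noise (E-score units)
    n_local_peaks: int = 10  # ruggedness: seeded local optima
    peak_score: float = 0.5
    bind_threshold: float = DEFAULT_BIND_THRESHOLD
    seed: int = 0
    peak_seq: str | None = None  # override the sampled global-peak sequence
    max_retries: int = 8


@lru_cache(maxsize=4)
def _space(k: int):
    """Canonical genotypes of length k with integer encodings of both strands."""
    genotypes = gs.enumerate_genotypes(k)
    enc = np.array([[_BASE_INDEX[b] for b in g] for g in genotypes], dtype=np.uint8)
    enc_rc = np.array(
        [[_BASE_INDEX[b] for b in gs.revcomp(g)] for g in genotypes], dtype=np.uint8)
    return genotypes, enc, enc_rc


def _base_weights(cfg: SynthConfig) -> np.ndarray:
    gc = np.array([(1 - cfg.gc_skew) / 2, (1 + cfg.gc_skew) / 2,
                   (1 + cfg.gc_skew) / 2, (1 - cfg.gc_skew) / 2])  # A C G T
    pu = np.array([(1 + cfg.purine_skew) / 2, (1 - cfg.purine_skew) / 2,
                   (1 + cfg.purine_skew) / 2, (1 - cfg.purine_skew) / 2])
    w = gc * pu
    if w.sum() <= 0:
        raise ValueError("base weights vanish; relax gc_skew/purine_skew")
    return w / w.sum()


def _mismatch_costs(enc, enc_rc, seq: str,
                    w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Composition-weighted mismatch cost of every genotype against ``seq``.

    Matching the peak base costs 0; a mismatch costs 1 plus an extra penalty
    of up to 2 for bases disfavored by the composition weights ``w``. This is
    what makes an AT-skewed factor bind AT-rich sequences specifically (a
    G/C anywhere is expensive, swapping A for T is cheap), so the bound set —
    not merely the peak — carries the composition and hence the edge-class
    enrichment. Cost is minimized over the two orientations.
    """
    base_cost = 1.0 + 2.0 * (1.0 - w / w.max())  # per-base cost if mismatched
    target = np.array([_BASE_INDEX[b] for b in seq], dtype=np.uint8)
    k = len(seq)
    cost = np.empty((k, 4))
    cost[:] = base_cost[None, :]
    cost[np.arange(k), target] = 0.0
    c1 = cost[np.arange(k)[None, :], enc].sum(axis=1)
    c2 = cost[np.arange(k)[None, :], enc_rc].sum(axis=1)
    # note: ``seq`` must stay in the motif's own strand frame — the weights w
    # are written for that frame, and purine/pyrimidine content flips under
    # reverse complementation
    return np.minimum(c1, c2), c1 <= c2


def generate_landscape(cfg: SynthConfig) -> tuple[ScoreTable, ScoreTable]:
    """Generate two replicate score tables whose thresholded dominant network
    reaches ``target_bound_size``.

    The score of a genotype is peak_score - slope * mismatch_cost, where the
    mismatch cost weights substitutions by how disfavored the substituting
    base is under the composition skew, plus a small jitter (20% of one
    unit-cost step). Ruggedness comes from ``n_local_peaks`` randomly chosen
    mid-cost genotypes boosted to near-peak scores, which act as local optima
    competing with the global peak. Replicate 2 adds Gaussian noise of sd
    ``noise_sd``. The field's spread is widened until the dominant component
    of the thresholded first replicate reaches the target size (bounded
    retries).
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes, enc, enc_rc = _space(cfg.k)
    w = _base_weights(cfg)
    # the motif string stays in its sampled strand frame: the composition
    # weights are frame-specific (purine content flips under revcomp)
    peak = cfg.peak_seq or "".join(rng.choice(list(gs.ALPHABET), p=w, size=cfg.k))
    peak_id = gs.canonical(peak)
    decoy_scores = rng.uniform(0.45, 0.49, size=cfg.n_local_peaks)
    jitter_unit = rng.normal(0.0, 1.0, size=len(genotypes))
    noise = rng.normal(0.0, cfg.noise_sd, size=len(genotypes))

    c_main, fwd_frame = _mismatch_costs(enc, enc_rc, peak, w)
    # cost radius reaching ~1.2x the target count of genotypes
    m = min(int(1.2 * cfg.target_bound_size), len(genotypes) - 1)
    r = max(float(np.partition(c_main, m)[m]), 1.0)

    name = f"synth_k{cfg.k}_seed{cfg.seed}"
    margin = 0.005
    last_err: Exception | None = None
    for _ in range(cfg.max_retries):
        slope = (cfg.peak_score - cfg.bind_threshold - margin) / r
        raw = cfg.peak_score - slope * c_main
        raw = raw + 0.2 * slope * jitter_unit
        # ruggedness: boost a few mid-cost genotypes into local optima that
        # compete with the global peak for adaptive walks; under a
        # composition skew these decoys are drawn from off-motif sequences
        # (carrying at least one disfavored base), the analogue of secondary
        # binding preferences whose composition departs from the main motif
        if cfg.n_local_peaks:
            band = (c_main > 0.35 * r) & (c_main <= r)
            low = w < 0.5 * w.max()
            if low.any():
                # disfavored-base count in the motif frame of the
                # cost-minimizing orientation
                n_low = np.where(fwd_frame, low[enc].sum(axis=1),
                                 low[enc_rc].sum(axis=1))
                off_motif = n_low == 1
                if (band & off_motif).any():
                    band &= off_motif
            cand = np.flatnonzero(band)
            if cand.size:
                decoys = rng.choice(cand, size=min(cfg.n_local_peaks, cand.size),
                                    replace=False)
                raw[decoys] = np.maximum(raw[decoys],
                                         decoy_scores[: len(decoys)])
        raw[c_main == 0] = cfg.peak_score  # keep the seeded peak global
        scores1 = np.clip(raw, -0.5, 0.5)
        scores2 = np.clip(scores1 + noise, -0.5, 0.5)
        rep1 = ScoreTable(tf_name=name, replicate_id="rep1",
                          scores=dict(zip(genotypes, scores1.tolist())))
        rep2 = ScoreTable(tf_name=name, replicate_id="rep2",
                          scores=dict(zip(genotypes, scores2.tolist())))
        try:
            L = build_landscape(rep1, bind_threshold=cfg.bind_threshold,
                                min_component=cfg.target_bound_size)
        except ValueError as err:
            last_err = err
            r += 0.5
            continue
        if peak_id in L.index:
            return rep1, rep2
        last_err = ValueError(f"{name}: seeded peak fell outside the dominant component")
        r += 0.5
    raise ValueError(
        f"{name}: could not reach target bound size within retry budget") from last_err


def synthesize(cfg: SynthConfig) -> Landscape:
    """Generate replicate tables, build the dominant landscape from replicate 1,
    and set delta from the replicate regression."""
    rep1, rep2 = generate_landscape(cfg)
    L = build_landscape(rep1, bind_threshold=cfg.bind_threshold,
                        min_component=cfg.target_bound_size)
    L.delta = estimate_delta(rep1, rep2, bind_threshold=cfg.bind_threshold)
    return L


def generate_collection(m: int, cfg: SynthConfig) -> list[Landscape]:
    """A collection of ``m`` landscapes with partially overlapping bound sets.

    Member peaks are scattered within substitution distance 2 of a common
    center sequence, so bound regions overlap at one-mutant range; members
    differ in derived seeds and are individually reproducible.
    """
    if m < 2:
        raise ValueError("a collection needs at least 2 landscapes")
    rng = np.random.default_rng(cfg.seed)
    w = _base_weights(cfg)
    center = list(rng.choice(list(gs.ALPHABET), p=w, size=cfg.k))
    out = []
    for i in range(m):
        peak = center.copy()
        for pos in rng.choice(cfg.k, size=2, replace=False):
            alts = [b for b in gs.ALPHABET if b != peak[pos]]
            peak[pos] = alts[rng.integers(3)]
        sub = replace(cfg, seed=cfg.seed * 1000 + i + 1, peak_seq="".join(peak))
        L = synthesize(sub)
        L.tf_name = f"{L.tf_name}_m{i}"
        out.append(L)
    return out


def _fixture_table(name: str, scores: dict[str, float]) -> ScoreTable:
    return ScoreTable(tf_name=name,
                      scores={gs.canonical(g): s for g, s in scores.items()})


# Hand-built miniature landscapes with exactly known paths, classes and scores.
# All use delta = 0.005; every listed score gap exceeds delta.
_TOY_SPECS: dict[str, dict[str, float]] = {
    # Single accessible chain of 5 steps: 4 transversions + 1 transition
    # (positions 0..4 of AAAAAAAA mutated to C, T, G, C, T in turn), so the
    # path composition bias is 1/(1 + 4/2) = 1/3.
    "single_path": {
        "AAAAAAAA": 0.36, "CAAAAAAA": 0.385, "CTAAAAAA": 0.41,
        "CTGAAAAA": 0.435, "CTGCAAAA": 0.46, "CTGCTAAA": 0.485,
    },
    # One start with an improving transition neighbor (f = 0.1) and an
    # improving transversion neighbor (f = 0.3); both neighbors absorbing,
    # the transversion one is the global peak. P[start, peak] = 0.75 at
    # alpha = 0.5.
    "fork": {
        "AAAAAAAA": 0.36, "GAAAAAAA": 0.396, "AAAAAAAC": 0.468,
    },
    # Exactly three accessible start->peak paths: two transition-first
    # two-step paths and one transversion-first three-step path. Path
    # entropy is minimized at the transversion extreme of the alpha grid
    # (only the single transversion-first path retains mass).
    "three_paths": {
        "AAAAAAAA": 0.36, "CAAAAAAA": 0.38, "GAAAAAAA": 0.40,
        "AGAAAAAA": 0.40, "GGAAAAAA": 0.48,
    },
    # Global peak two steps away plus an adjacent local peak that absorbs
    # part of the walk: P_peak < 1 for every alpha in (0, 1).
    "two_peaks": {
        "AAAAAAAA": 0.36, "GAAAAAAA": 0.45, "AAAAAAAC": 0.40,
        "AAAAAACC": 0.48,
    },
}


def toy_fixture(name: str) -> Landscape:
    """Hand-built miniature landscape from a fixed registry.

    Names: "single_path", "fork", "three_paths", "two_peaks".
    """
    if name not in _TOY_SPECS:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_TOY_SPECS)}")
    table = _fixture_table(name, _TOY_SPECS[name])
    L = build_landscape(table, min_component=len(table.scores))
    L.delta = 0.005
    return L
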