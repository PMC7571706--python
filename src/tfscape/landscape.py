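"""Genotype-phenotype landscapes of TF binding affinity from k-mer score tables.

A landscape is built from a protein-binding-microarray style score table
(one E-score per 8-mer, range [-0.5, 0.5]) by thresholding binding at
E-score > 0.35, connecting bound genotypes that differ by a single point
mutation, and keeping the largest connected component (the dominant genotype
network). Measurement noise is summarized by a per-TF threshold delta,
estimated as the residual standard error of an OLS regression between the
bound scores of two replicate arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import genotype_space as gs

DEFAULT_BIND_THRESHOLD = 0.35
DEFAULT_MIN_COMPONENT = 100


class ScoreTableError(ValueError):
    """Malformed score table (bad row, conflicting duplicates, bad score)."""


class LandscapeTooSmallError(ValueError):
    """Dominant genotype network below the minimum size requirement."""


@dataclass
class ScoreTable:
    """Canonicalized per-genotype binding scores for one transcription factor.

    scores maps canonical genotype -> E-score; zscores (optional) maps the
    same keys to Z-scores where available.
    """

    tf_name: str
    scores: dict[str, float]
    zscores: dict[str, float] = field(default_factory=dict)
    replicate_id: str | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def values_for(self, score_kind: str) -> dict[str, float]:
        if score_kind == "escore":
            return self.scores
        if score_kind == "zscore":
            if not self.zscores:
                raise ScoreTableError(f"{self.tf_name}: no Z-scores loaded")
            return self.zscores
        raise ValueError(f"unknown score_kind {score_kind!r}")


_DNA = frozenset("ACGT")


def _is_dna(tok: str) -> bool:
    return bool(tok) and set(tok.upper()) <= _DNA


def load_scores(path, score_kind: str = "escore", tf_name: str | None = None,
                replicate_id: str | None = None) -> ScoreTable:
    """Read a UniPROBE/CIS-BP-style tab-separated k-mer score table.

    Expected columns: kmer [, kmer_rc], escore [, median, zscore]. A header
    line and '#' comment lines are tolerated. Both orientations of a site
    (whether given as two columns or as two rows) must carry equal scores;
    disagreements and non-numeric scores are errors that name the line number.
    """
    scores: dict[str, float] = {}
    zscores: dict[str, float] = {}
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not _is_dna(fields[0]):
                if lineno == 1 or not scores:
                    continue  # header line
                raise ScoreTableError(f"{path}:{lineno}: malformed k-mer {fields[0]!r}")
            kmer = fields[0].upper()
            rest = fields[1:]
            if rest and _is_dna(rest[0]):
                rc = rest[0].upper()
                if rc != gs.revcomp(kmer):
                    raise ScoreTableError(
                        f"{path}:{lineno}: second column {rc!r} is not the "
                        f"reverse complement of {kmer!r}"
                    )
                rest = rest[1:]
            if not rest:
                raise ScoreTableError(f"{path}:{lineno}: missing score column")
            nums = []
            for tok in rest:
                tok = tok.strip()
                if not tok:
                    continue
                try:
                    nums.append(float(tok))
                except ValueError as exc:
                    raise ScoreTableError(
                        f"{path}:{lineno}: non-numeric score {tok!r}"
                    ) from exc
            if not nums:
                raise ScoreTableError(f"{path}:{lineno}: missing score column")
            escore = nums[0]
            # UniPROBE exports list escore, median intensity, zscore in order.
            zscore = nums[2] if len(nums) >= 3 else None
            g = gs.canonical(kmer)
            if g in scores and not np.isclose(scores[g], escore, atol=1e-9):
                raise ScoreTableError(
                    f"{path}:{lineno}: conflicting scores for genotype {g}: "
                    f"{scores[g]} vs {escore}"
                )
            scores[g] = escore
            if zscore is not None:
                if g in zscores and not np.isclose(zscores[g], zscore, atol=1e-9):
                    raise ScoreTableError(
                        f"{path}:{lineno}: conflicting Z-scores for genotype {g}"
                    )
                zscores[g] = zscore
    if not scores:
        raise ScoreTableError(f"{path}: no score rows found")
    name = tf_name if tf_name is not None else path.rsplit("/", 1)[-1].split(".")[0]
    return ScoreTable(tf_name=name, scores=scores, zscores=zscores,
                      replicate_id=replicate_id)


def write_score_table(table: ScoreTable, path) -> None:
    """Write a score table in the same dialect ``load_scores`` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = "kmer\tkmer_rc\tescore"
        has_z = bool(table.zscores)
        if has_z:
            cols += "\tmedian\tzscore"
        fh.write(f"# tf={table.tf_name}\n{cols}\n")
        for g in sorted(table.scores):
            row = f"{g}\t{gs.revcomp(g)}\t{table.scores[g]:.6g}"
            if has_z:
                z = table.zscores.get(g, float("nan"))
                row += f"\t0\t{z:.6g}"
            fh.write(row + "\n")


@dataclass
class Landscape:
    """Dominant genotype network plus its affinity surface.

    genotypes are canonical, sorted; scores is the aligned affinity proxy
    (b in the origin-fixation model); edges hold index pairs (i < j) with
    their mutation class; delta is the noise threshold used for
    accessibility decisions.
    """

    tf_name: str
    genotypes: tuple[str, ...]
    scores: np.ndarray
    edges: tuple[tuple[int, int, str], ...]
    delta: float = 0.0
    score_kind: str = "escore"
    nondominant_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.index = {g: i for i, g in enumerate(self.genotypes)}
        adj: list[list[tuple[int, str]]] = [[] for _ in self.genotypes]
        ecls: dict[tuple[int, int], str] = {}
        for i, j, cls in self.edges:
            adj[i].append((j, cls))
            adj[j].append((i, cls))
            ecls[(i, j)] = ecls[(j, i)] = cls
        self.adjacency = adj
        self.edge_class = ecls

    @property
    def n(self) -> int:
        return len(self.genotypes)

    @property
    def k(self) -> int:
        return len(self.genotypes[0])

    @property
    def peak_index(self) -> int:
        """Index of the global peak; score ties break lexicographically."""
        smax = self.scores.max()
        tied = [i for i in np.flatnonzero(np.isclose(self.scores, smax, atol=0))
                if self.scores[i] == smax]
        if len(tied) > 1:
            warnings.warn(
                f"{self.tf_name}: {len(tied)} genotypes tie at the maximum score; "
                "breaking ties lexicographically", stacklevel=2)
        return min(tied, key=lambda i: self.genotypes[i])

    @property
    def peak(self) -> str:
        return self.genotypes[self.peak_index]

    def score_of(self, g: str) -> float:
        return float(self.scores[self.index[g]])

    def bottom_fraction(self, q: float = 0.10) -> list[int]:
        """Indices of the lowest ceil(q*n) genotypes by (score, id)."""
        if not 0 < q <= 1:
            raise ValueError("q must be in (0, 1]")
        m = int(np.ceil(q * self.n))
        order = sorted(range(self.n), key=lambda i: (self.scores[i], self.genotypes[i]))
        return order[:m]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for g, s in zip(self.genotypes, self.scores):
            G.add_node(g, score=float(s))
        for i, j, cls in self.edges:
            G.add_edge(self.genotypes[i], self.genotypes[j], mclass=cls)
        return G


def global_peak(L: Landscape) -> str:
    """Genotype with the maximum score (ties broken lexicographically)."""
    return L.peak


def build_landscape(table: ScoreTable, bind_threshold: float = DEFAULT_BIND_THRESHOLD,
                    min_component: int = DEFAULT_MIN_COMPONENT, delta: float = 0.0,
                    score_kind: str = "escore") -> Landscape:
    """Threshold binding, build the genotype network, keep the dominant component.

    Nodes are genotypes whose score strictly exceeds ``bind_threshold``; edges
    join canonical genotypes at point-mutation distance 1. Only the largest
    connected component is retained and its size must reach ``min_component``;
    the sizes of discarded components are recorded on the result.
    """
    values = table.values_for(score_kind)
    bound = {g: s for g, s in values.items() if s > bind_threshold}
    if not bound:
        raise LandscapeTooSmallError(
            f"{table.tf_name}: no genotypes exceed the binding threshold "
            f"{bind_threshold}")
    G = nx.Graph()
    G.add_nodes_from(bound)
    for g in bound:
        for nb, cls in gs.neighbors(g):
            if nb in bound and g < nb:
                G.add_edge(g, nb, mclass=cls)
    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    dominant = comps[0]
    if len(dominant) < min_component:
        raise LandscapeTooSmallError(
            f"{table.tf_name}: dominant component has {len(dominant)} genotypes "
            f"(< {min_component}); landscape too small")
    genotypes = tuple(sorted(dominant))
    index = {g: i for i, g in enumerate(genotypes)}
    scores = np.array([bound[g] for g in genotypes])
    edges = tuple(sorted(
        (index[u], index[v], d["mclass"]) if index[u] < index[v]
        else (index[v], index[u], d["mclass"])
        for u, v, d in G.edges(data=True) if u in dominant
    ))
    return Landscape(
        tf_name=table.tf_name, genotypes=genotypes, scores=scores, edges=edges,
        delta=delta, score_kind=score_kind,
        nondominant_sizes=tuple(sorted((len(c) for c in comps[1:]), reverse=True)),
    )


def estimate_delta(rep1: ScoreTable, rep2: ScoreTable,
                   bind_threshold: float = DEFAULT_BIND_THRESHOLD,
                   score_kind: str = "escore") -> float:
    """Noise threshold: residual standard error of OLS of rep2 on rep1 scores.

    The regression uses genotypes bound (score > threshold) in *both*
    replicates; the orientation (rep2 regressed on rep1) is fixed by
    convention. delta = sqrt(SSR / (n - 2)).
    """
    v1, v2 = rep1.values_for(score_kind), rep2.values_for(score_kind)
    shared = sorted(g for g in v1.keys() & v2.keys()
                    if v1[g] > bind_threshold and v2[g] > bind_threshold)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 genotypes bound in both replicates, got {len(shared)}")
    x = np.array([v1[g] for g in shared])
    y = np.array([v2[g] for g in shared])
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        # degenerate abscissa: intercept-only fit
        ssr = np.sum((y - y.mean()) ** 2)
    else:
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        ssr = np.sum((y - slope * x - intercept) ** 2)
    return float(np.sqrt(ssr / (len(shared) - 2)))


def gc_content(g: str) -> float:
    return (g.count("G") + g.count("C")) / len(g)


def landscape_summary(L: Landscape) -> dict:
    """Aggregate topography statistics for one landscape.

    Reports size, mean GC content, mean degree, mean per-genotype mutational
    robustness, the whole-landscape composition bias, delta and the peak.
    """
    from .bias_metrics import landscape_composition_bias
    from .population_stats import robustness

    degrees = np.array([len(a) for a in L.adjacency])
    mean_rob = float(np.mean([robustness(g, L) for g in L.genotypes]))
    if L.edges:
        comp_bias = landscape_composition_bias(L).value
    else:
        comp_bias = None
    return {
        "tf_name": L.tf_name,
        "size": L.n,
        "n_edges": len(L.edges),
        "mean_gc": float(np.mean([gc_content(g) for g in L.genotypes])),
        "mean_degree": float(degrees.mean()) if L.n else 0.0,
        "mean_robustness": mean_rob,
        "composition_bias": comp_bias,
        "delta": L.delta,
        "peak": L.peak,
        "peak_score": float(L.scores[L.peak_index]),
        "nondominant_sizes": list(L.nondominant_sizes),
    }


def write_landscape(L: Landscape, nodes_path, edges_path,
                    summary_path=None) -> None:
    """Write node/edge TSVs (and optionally a JSON summary) for a landscape."""
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("genotype\tscore\n")
        for g, s in zip(L.genotypes, L.scores):
            fh.write(f"{g}\t{s:.6g}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("g1\tg2\tclass\n")
        for i, j, cls in L.edges:
            fh.write(f"{L.genotypes[i]}\t{L.genotypes[j]}\t{cls}\n")
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(landscape_summary(L), fh, indent=2)
            fh.write("\n")
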