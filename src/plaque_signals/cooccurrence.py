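"""Compositional cooccurrence networks across disease strata.

Correlations between taxa are estimated from count compositions with a
SparCC-style procedure: relative abundances are repeatedly drawn from a
per-sample Dirichlet posterior (counts + 1), the log-ratio variation
matrix t_ij = var ln(x_i/x_j) is converted to basis variances omega_i^2
by a sparse linear approximation, strongly correlated pairs are
iteratively excluded from that approximation, and the per-pair median
over resampling iterations is reported.  Edge significance comes from
within-taxon permutations; "strong" edges are those above
mean + 1.96 SD of the off-diagonal correlations.  Stratum-level
community structure is compared by Mantel distances between correlation
matrices, clustered agglomeratively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from .io_core import CountMatrix, ValidationError

__all__ = [
    "SparccInternals",
    "CorrelationNetwork",
    "StratumKey",
    "sparcc",
    "basis_correlations_from_fractions",
    "permutation_pvalues",
    "strong_edge_cutoff",
    "build_network",
    "betweenness_ranking",
    "mantel_r",
    "mantel_distance",
    "cluster_strata",
    "layout_fr",
    "stratify_counts",
]


@dataclass
class SparccInternals:
    """Internals of the final inference iteration (for auditing)."""

    variation_matrix: np.ndarray  # t_ij = var ln(x_i/x_j)
    basis_variances: np.ndarray  # omega_i^2
    excluded_pairs: list[tuple[int, int]]


@dataclass(frozen=True)
class StratumKey:
    bop: int
    periodontitis: bool

    def __post_init__(self) -> None:
        if not 0 <= self.bop <= 6:
            raise ValidationError(f"bop {self.bop} outside 0..6")

    def label(self) -> str:
        return f"bop{self.bop}_{'perio' if self.periodontitis else 'noperio'}"


@dataclass
class CorrelationNetwork:
    node_ids: list[str]
    corr: np.ndarray
    pvals: np.ndarray
    threshold: float
    significance: float
    edges: list[tuple[str, str, float]]
    dropped_nodes: list[str]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for a, b, rho in self.edges:
            g.add_edge(a, b, rho=rho, length=1.0 / rho if rho > 0 else np.inf)
        return g


def _variation_matrix(log_frac: np.ndarray) -> np.ndarray:
    """t_ij = var(ln x_i - ln x_j) from log fractions (taxa x samples)."""
    cov = np.cov(log_frac, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations_from_fractions(
    frac: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> tuple[np.ndarray, SparccInternals]:
    """One pass of the basis-correlation solver on fixed fractions.

    Solves the sparse linear approximation
    sum_j t_ij ~= |K_i| omega_i^2 + sum_{j in K_i} omega_j^2 for the
    basis variances, computes
    rho_ij = (omega_i^2 + omega_j^2 - t_ij) / (2 omega_i omega_j), then
    iteratively excludes the strongest pair above the exclusion
    threshold from the approximation and re-solves.
    """
    log_frac = np.log(frac)
    t = _variation_matrix(log_frac)
    d = t.shape[0]
    if d < 3:
        raise ValidationError("need at least 3 taxa for basis inference")
    if max_exclusions is None:
        max_exclusions = (d * (d - 1) // 2) // 2

    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded: list[tuple[int, int]] = []
    var_floor = 1e-12

    while True:
        m = include.astype(float)
        np.fill_diagonal(m, include.sum(axis=1))
        t_sums = (t * include).sum(axis=1)
        try:
            omega2 = np.linalg.solve(m, t_sums)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"basis system singular: {exc}") from exc
        omega2 = np.maximum(omega2, var_floor)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)

        if len(excluded) >= max_exclusions:
            break
        cand = np.abs(rho).copy()
        cand[~include] = 0.0
        np.fill_diagonal(cand, 0.0)
        # keep every taxon attached to at least two partners
        deg = include.sum(axis=1)
        cand[deg <= 2, :] = 0.0
        cand[:, deg <= 2] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        excluded.append((min(i, j), max(i, j)))

    internals = SparccInternals(t, omega2, excluded)
    return rho, internals


def sparcc(
    counts: CountMatrix,
    inference_iters: int = 20,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, SparccInternals]:
    """Estimate basis correlations from a count composition.

    Per inference iteration, relative abundances are drawn from the
    per-sample Dirichlet(counts + 1) posterior (the add-one prior also
    handles zeros); the final correlation matrix is the componentwise
    median over iterations, clamped to [-1, 1] with unit diagonal.
    """
    mat = counts.counts
    zero_taxa = [t for t, row in zip(counts.taxon_ids, mat) if row.sum() == 0]
    if zero_taxa:
        raise ValidationError(
            f"all-zero taxa must be prefiltered: {zero_taxa[:5]}"
        )
    if counts.n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    if inference_iters < 1:
        raise ValidationError("inference_iters must be >= 1")
    rng = np.random.default_rng(seed)
    d, n = mat.shape
    rhos = np.empty((inference_iters, d, d))
    internals = None
    alpha = mat.T + 1.0  # samples x taxa Dirichlet parameters
    for it in range(inference_iters):
        # Dirichlet draw via normalized gammas, vectorized over samples
        g = rng.gamma(alpha)
        frac = (g / g.sum(axis=1, keepdims=True)).T
        rhos[it], internals = basis_correlations_from_fractions(
            frac, exclusion_threshold
        )
    corr = np.median(rhos, axis=0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, internals


def permutation_pvalues(
    counts: CountMatrix,
    observed_corr: np.ndarray,
    n_perm: int = 100,
    inference_iters: int = 20,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided permutation pseudo p-values for each correlation.

    Each permutation shuffles every taxon's counts across samples
    independently (destroying inter-taxon dependence, preserving
    marginals) and re-runs the estimator;
    p_ij = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mat = counts.counts
    d, n = mat.shape
    exceed = np.zeros((d, d))
    for b in range(n_perm):
        perm = np.vstack([row[rng.permutation(n)] for row in mat])
        shuffled = CountMatrix(counts.taxon_ids, counts.sample_ids, perm)
        rho_perm, _ = sparcc(
            shuffled,
            inference_iters=inference_iters,
            exclusion_threshold=exclusion_threshold,
            seed=int(rng.integers(2**31)),
        )
        exceed += np.abs(rho_perm) >= np.abs(observed_corr)
    p = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(p, 0.0)
    return p


def strong_edge_cutoff(corr: np.ndarray) -> float:
    """Strong-correlation threshold: mean + 1.96 SD (population SD) of
    the strict upper-triangle off-diagonal correlations."""
    corr = np.asarray(corr, dtype=float)
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    if vals.size < 2:
        raise ValidationError("need >= 2 off-diagonal entries")
    return float(vals.mean() + 1.96 * vals.std(ddof=0))


def build_network(
    node_ids: list[str],
    corr: np.ndarray,
    pvals: np.ndarray,
    threshold: float,
    significance: float = 0.05,
) -> CorrelationNetwork:
    """Edges where rho > threshold and p < significance; isolated nodes
    are dropped (and reported), mirroring the figure convention."""
    corr = np.asarray(corr, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if corr.shape != pvals.shape or corr.shape[0] != len(node_ids):
        raise ValidationError("corr, pvals and node_ids must be conformable")
    d = len(node_ids)
    edges = []
    connected = set()
    for i in range(d):
        for j in range(i + 1, d):
            if corr[i, j] > threshold and pvals[i, j] < significance:
                edges.append((node_ids[i], node_ids[j], float(corr[i, j])))
                connected.update((node_ids[i], node_ids[j]))
    kept = [n for n in node_ids if n in connected]
    dropped = [n for n in node_ids if n not in connected]
    keep_idx = [node_ids.index(n) for n in kept]
    return CorrelationNetwork(
        node_ids=kept,
        corr=corr[np.ix_(keep_idx, keep_idx)],
        pvals=pvals[np.ix_(keep_idx, keep_idx)],
        threshold=threshold,
        significance=significance,
        edges=edges,
        dropped_nodes=dropped,
    )


def betweenness_ranking(
    net: CorrelationNetwork, weighted: bool = False
) -> list[tuple[str, float]]:
    """Nodes ranked by shortest-path betweenness (Brandes), descending;
    ties broken by node id.  The weighted variant uses 1/rho as edge
    length."""
    g = net.graph()
    if g.number_of_nodes() < 3:
        raise ValidationError("need >= 3 nodes for a meaningful ranking")
    bc = nx.betweenness_centrality(
        g, normalized=False, weight="length" if weighted else None
    )
    return sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))


def mantel_r(corr_a: np.ndarray, corr_b: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two
    conformable correlation matrices."""
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("matrices must share the same node set and order")
    if a.shape[0] < 3:
        raise ValidationError("need >= 3 nodes")
    iu = np.triu_indices_from(a, k=1)
    x, y = a[iu], b[iu]
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("degenerate (constant) off-diagonal entries")
    return float((xc * yc).sum() / denom)


def mantel_distance(corr_a: np.ndarray, corr_b: np.ndarray) -> float:
    return 1.0 - mantel_r(corr_a, corr_b)


def _tree_to_newick(node, labels: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.10g}"
    left = _tree_to_newick(node.left, labels, node.dist)
    right = _tree_to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.10g}"


def cluster_strata(
    networks: dict[StratumKey, np.ndarray], method: str = "complete"
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of stratum correlation matrices on
    pairwise Mantel distances.

    Uses the unadjusted (pre-significance) correlation matrices.
    Returns (scipy linkage matrix, stratum labels in linkage order,
    Newick string with branch lengths derived from merge heights).
    """
    if len(networks) < 2:
        raise ValidationError("need >= 2 strata")
    keys = sorted(networks, key=lambda k: (k.periodontitis, k.bop))
    shapes = {networks[k].shape for k in keys}
    if len(shapes) != 1:
        raise ValidationError("strata must share a common node set")
    condensed = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            condensed.append(mantel_distance(networks[keys[i]], networks[keys[j]]))
    z = linkage(np.asarray(condensed), method=method)
    labels = [k.label() for k in keys]
    root = to_tree(z)
    newick = "(" + ",".join(
        _tree_to_newick(child, labels, root.dist)
        for child in (root.left, root.right)
    ) + ");"
    return z, labels, newick


def layout_fr(
    net: CorrelationNetwork, seed: int = 0, iterations: int = 500
) -> dict[str, np.ndarray]:
    """Deterministic Fruchterman-Reingold coordinates (export only)."""
    g = net.graph()
    if g.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    return nx.spring_layout(g, iterations=iterations, seed=seed)


def stratify_counts(
    counts: CountMatrix, meta, min_samples: int = 10
) -> dict[StratumKey, CountMatrix]:
    """Split a count table into (BoP, periodontitis) strata; strata
    below ``min_samples`` are omitted."""
    out: dict[StratumKey, CountMatrix] = {}
    for (bop, perio), group in meta.groupby(
        ["bop", "periodontitis"], observed=True
    ):
        samples = [s for s in counts.sample_ids if s in set(group["sample_id"].astype(str))]
        if len(samples) < min_samples:
            continue
        out[StratumKey(int(bop), bool(perio))] = counts.select_samples(samples)
    return out
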