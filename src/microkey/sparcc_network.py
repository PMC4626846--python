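"""sparCC correlation inference and binary interaction-network construction.

Relative-abundance (compositional) data make naive Pearson correlations
between taxa spurious: closing counts to a fixed depth induces negative
bias among all components. sparCC sidesteps this by working with the
variances of log-ratios,

    t_ij = Var[ log(x_i / x_j) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

where w_i^2 ("basis variances") are the latent variances of the absolute
abundances. Assuming the true correlation network is sparse (the average
correlation is close to zero), the system becomes linear in the w_i^2 and
can be solved; strongly correlated pairs that violate the sparsity
assumption are iteratively excluded and the system re-solved. Counts are
converted to fractions by Dirichlet resampling (counts + 1 as parameters)
and the estimate is averaged over resamples. Significance is assessed by a
permutation null in which every OTU's counts are shuffled independently
across samples; edges with two-sided pseudo-p below alpha enter the final
binary, undirected interaction network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .otu_io import OtuTable

__all__ = [
    "CorrelationResult",
    "InteractionNetwork",
    "log_ratio_variance",
    "variation_matrix",
    "basis_correlations",
    "sparcc_estimate",
    "permutation_pvalues",
    "sparcc_with_pvalues",
    "build_network",
]

DEFAULT_N_RESAMPLES = 20
DEFAULT_N_PERMUTATIONS = 100
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_MAX_EXCLUSIONS = 10
DEFAULT_ALPHA = 0.05
MIN_COMPONENTS = 4  # the sparsity approximation needs many components
MIN_PERMUTATIONS = 19  # resolution floor: min attainable p = 1/(1+19) = 0.05


@dataclass
class CorrelationResult:
    """sparCC correlation estimates with permutation pseudo-p-values."""

    rho: np.ndarray
    pvals: np.ndarray
    n_resamples: int
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.rho.shape != self.pvals.shape:
            raise ValueError("rho and pvals must have the same shape")


class InteractionNetwork:
    """Binary undirected co-occurrence network over OTU nodes.

    A thin wrapper around :class:`networkx.Graph` that preserves node
    insertion order (the OTU order of the source table), carries group
    labels as node attributes, and records the significance level used
    for edge selection. Isolated OTUs stay in the network as nodes.
    """

    def __init__(
        self,
        nodes: list[str],
        groups: dict[str, str] | None = None,
        edges: list[tuple[str, str]] | None = None,
        alpha: float = DEFAULT_ALPHA,
    ):
        self.graph = nx.Graph()
        groups = groups or {}
        for node in nodes:
            self.graph.add_node(node, group=groups.get(node, "Unclassified"))
        for a, b in edges or []:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            self.graph.add_edge(a, b)
        self.alpha = alpha

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def groups(self) -> dict[str, str]:
        return {n: d["group"] for n, d in self.graph.nodes(data=True)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]


def log_ratio_variance(fractions: np.ndarray, i: int, j: int) -> float:
    """Sample variance of log(x_i / x_j) across samples.

    ``fractions`` is a strictly positive OTU-by-sample matrix. The
    variance uses the n-1 denominator; ``t_ii`` is exactly 0.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[1] < 2:
        raise ValueError("log-ratio variance needs at least 2 samples")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    if i == j:
        return 0.0
    ratios = np.log(fractions[i] / fractions[j])
    return float(np.var(ratios, ddof=1))


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """Full matrix of log-ratio variances t_ij for all component pairs.

    Computed from the covariance matrix of the log fractions:
    Var[log x_i - log x_j] = v_i + v_j - 2 cov_ij.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[1] < 2:
        raise ValueError("log-ratio variance needs at least 2 samples")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    logs = np.log(fractions)
    cov = np.cov(logs, ddof=1)
    v = np.diag(cov)
    T = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(T, 0.0)
    return np.maximum(T, 0.0)


def basis_correlations(
    T: np.ndarray,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> np.ndarray:
    """Solve the sparCC linear system for basis variances and correlations.

    Under the sparsity assumption the row sums of T satisfy

        sum_j t_ij  ~=  d_i w_i^2 + sum_{j in partners(i)} w_j^2,

    a linear system ``M w = t`` with ``M = diag(d) + A`` (A the inclusion
    adjacency, initially all pairs). After solving,
    ``rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j)``, clamped to [-1, 1].
    The most strongly correlated pair with |rho| above
    ``exclusion_threshold`` is then excluded from the system and the
    solve repeated, up to ``max_exclusions`` times — removing pairs that
    break the sparsity assumption.

    Negative basis variances (possible on small or degenerate inputs) are
    clamped to a tiny positive value with a warning rather than aborting.
    """
    T = np.asarray(T, dtype=float)
    D = T.shape[0]
    if T.shape != (D, D):
        raise ValueError("T must be square")
    if D < MIN_COMPONENTS:
        raise ValueError(
            f"sparCC approximation needs at least {MIN_COMPONENTS} components, got {D}"
        )
    if not np.allclose(T, T.T):
        raise ValueError("T must be symmetric")

    include = ~np.eye(D, dtype=bool)  # pair-inclusion mask
    rho = np.eye(D)
    for _ in range(max_exclusions + 1):
        d = include.sum(axis=1).astype(float)
        M = np.diag(d) + include.astype(float)
        t = (T * include).sum(axis=1)
        try:
            w = np.linalg.solve(M, t)
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(M, t, rcond=None)[0]
        if np.any(w <= 0):
            warnings.warn(
                "negative basis variance encountered; clamping (sparsity "
                "assumption likely violated)",
                stacklevel=2,
            )
            floor = max(w[w > 0].min() if np.any(w > 0) else 1.0, 1e-12) * 1e-6
            w = np.maximum(w, floor)
        omega = np.sqrt(w)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (w[:, None] + w[None, :] - T) / (2.0 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)

        # strongest still-included pair violating the sparsity threshold
        masked = np.where(include, np.abs(rho), -np.inf)
        idx = int(np.argmax(masked))
        i, j = divmod(idx, D)
        if masked[i, j] <= exclusion_threshold:
            break
        # never orphan a component out of the system entirely
        if include[i].sum() <= 1 or include[j].sum() <= 1:
            break
        include[i, j] = include[j, i] = False
    return rho


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet(counts + 1) fraction draw per sample, vectorized."""
    gammas = rng.standard_gamma(counts.astype(float) + 1.0)
    return gammas / gammas.sum(axis=0, keepdims=True)


def _sparcc_from_counts(
    counts: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
    exclusion_threshold: float,
    max_exclusions: int,
) -> np.ndarray:
    acc = np.zeros((counts.shape[0], counts.shape[0]))
    for _ in range(n_resamples):
        fractions = _dirichlet_fractions(counts, rng)
        T = variation_matrix(fractions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc += basis_correlations(T, exclusion_threshold, max_exclusions)
    rho = acc / n_resamples
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_estimate(
    table: OtuTable | np.ndarray,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> np.ndarray:
    """sparCC correlation matrix averaged over Dirichlet resamples.

    Each resample draws, per sample, fractions from Dirichlet(counts + 1)
    — the Bayesian treatment of zeros that avoids taking log of zero —
    computes the log-ratio variation matrix and solves for basis
    correlations; the returned rho is the mean over resamples.
    Deterministic given ``seed``.
    """
    counts = table.counts if isinstance(table, OtuTable) else np.asarray(table)
    if counts.shape[0] < MIN_COMPONENTS:
        raise ValueError(
            f"sparCC needs at least {MIN_COMPONENTS} OTUs, got {counts.shape[0]}"
        )
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    return _sparcc_from_counts(
        counts, n_resamples, rng, exclusion_threshold, max_exclusions
    )


def permutation_pvalues(
    table: OtuTable | np.ndarray,
    rho_observed: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> np.ndarray:
    """Two-sided permutation pseudo-p-values for every OTU pair.

    The null is built by shuffling each OTU's counts independently across
    samples (destroying all between-OTU association while preserving each
    OTU's marginal distribution) and re-running the full sparCC estimate.
    The edgewise pseudo-p is ``(1 + #{|rho_null| >= |rho_obs|}) / (1 + P)``
    — never exactly 0 and never above 1. Deterministic given ``seed``.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_permutations must be >= {MIN_PERMUTATIONS}: with fewer "
            f"permutations the minimum attainable p-value exceeds 0.05"
        )
    counts = table.counts if isinstance(table, OtuTable) else np.asarray(table)
    rho_observed = np.asarray(rho_observed)
    if rho_observed.shape != (counts.shape[0], counts.shape[0]):
        raise ValueError("rho_observed shape does not match the table")
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(rho_observed)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_permutations):
        shuffled = rng.permuted(counts, axis=1)
        rho_null = _sparcc_from_counts(
            shuffled, n_resamples, rng, exclusion_threshold, max_exclusions
        )
        exceed += np.abs(rho_null) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    np.fill_diagonal(pvals, 1.0)  # diagonal is undefined; park it at 1
    return pvals


def sparcc_with_pvalues(
    table: OtuTable,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> CorrelationResult:
    """Convenience: estimate correlations, then their permutation p-values."""
    rho = sparcc_estimate(
        table, n_resamples, seed, exclusion_threshold, max_exclusions
    )
    pvals = permutation_pvalues(
        table,
        rho,
        n_permutations,
        seed=seed + 1,
        n_resamples=n_resamples,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
    )
    return CorrelationResult(
        rho=rho,
        pvals=pvals,
        n_resamples=n_resamples,
        n_permutations=n_permutations,
        seed=seed,
    )


def build_network(
    rho: np.ndarray,
    pvals: np.ndarray,
    nodes: list[str],
    groups: dict[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> InteractionNetwork:
    """Binary undirected network of significant correlations.

    Edge (i, j) is present iff ``pvals[i, j] < alpha`` (strict). The sign
    and magnitude of rho are deliberately discarded: edges are unweighted.
    All nodes are retained even if isolated.
    """
    rho = np.asarray(rho)
    pvals = np.asarray(pvals)
    n = len(nodes)
    if rho.shape != (n, n) or pvals.shape != (n, n):
        raise ValueError(
            f"matrix shape {rho.shape}/{pvals.shape} does not match {n} nodes"
        )
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if pvals[i, j] < alpha
    ]
    return InteractionNetwork(nodes=list(nodes), groups=groups, edges=edges, alpha=alpha)
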