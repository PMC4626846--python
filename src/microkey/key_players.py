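"""Key and dominant taxonomic groups from centrality rankings.

A group of OTUs (a genus, family, ...) is a *key* candidate when it is
statistically over-represented among the most central nodes of the
interaction network: given N OTUs of which K belong to the group, and a
top set of the n most central OTUs containing x group members, the
over-representation probability is the strict upper tail of the
hypergeometric distribution, P(X > x). Small p means the group occupies
central positions far more often than a random draw of n OTUs would —
the network analogue of a keystone taxon.

A group is *dominant* when it supplies at least a fixed fraction
(default 10%) of the top-20% set — important by sheer numbers, whether
or not it is statistically over-represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .graph_metrics import CentralityScores

__all__ = [
    "RankCutoff",
    "EnrichmentRow",
    "cutoff_size",
    "top_set",
    "hypergeom_upper",
    "enrich_groups",
    "dominant_groups",
]

DEFAULT_CUTOFFS = (0.05, 0.10, 0.20)
DEFAULT_ALPHA = 0.05
DEFAULT_DOMINANCE_FRACTION = 0.10

TiePolicy = Literal["stable-order", "include-ties"]


@dataclass
class RankCutoff:
    """A top-of-the-rank cutoff: fraction q, realized size, tie policy."""

    q: float
    n_top: int
    tie_policy: TiePolicy = "stable-order"


@dataclass
class EnrichmentRow:
    """One group's representation in one top-centrality set."""

    group: str
    K: int  # group size in the network
    x: int  # group members inside the top set
    n: int  # top-set size
    N: int  # network size
    p: float  # strict upper-tail hypergeometric probability
    significant: bool
    q_bh: float = float("nan")  # supplementary BH-adjusted p; not used for flags
    dominant: bool = False


def cutoff_size(N: int, q: float) -> int:
    """Size of the top-q fraction of an N-node rank.

    Nearest-integer rounding, half away from zero, with a floor of 1 so
    the top set is never empty.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    return max(1, int(np.floor(q * N + 0.5)))


def top_set(
    scores: CentralityScores,
    n_top: int,
    tie_policy: TiePolicy = "stable-order",
) -> set[str]:
    """The n_top highest-scoring nodes.

    Ties at the boundary are broken by the stored node order (default,
    deterministic) or, under ``include-ties``, every node tied with the
    boundary score is included (the set may then exceed n_top).
    """
    nodes = scores.node_order
    if n_top > len(nodes):
        raise ValueError(f"n_top={n_top} exceeds network size {len(nodes)}")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    vals = scores.values()
    # stable sort descending on score, preserving node order within ties
    order = np.argsort(-vals, kind="stable")
    if tie_policy == "stable-order":
        chosen = order[:n_top]
    elif tie_policy == "include-ties":
        boundary = vals[order[n_top - 1]]
        chosen = [i for i in range(len(nodes)) if vals[i] > boundary]
        chosen += [i for i in range(len(nodes)) if vals[i] == boundary]
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return {nodes[i] for i in chosen}


def hypergeom_upper(N: int, K: int, n: int, x: int, strict: bool = True) -> float:
    """Upper-tail probability of the hypergeometric distribution.

    For X ~ Hypergeometric(N, K, n) — x successes in n draws without
    replacement from a population of N with K successes — returns the
    STRICT tail P(X > x) by default, or P(X >= x) with ``strict=False``.
    Computed by exact summation of the p.m.f. in log space.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not 0 <= x <= min(K, n):
        raise ValueError(f"observed x={x} outside [0, min(K, n)={min(K, n)}]")
    lo = x + 1 if strict else x
    hi = min(K, n)
    if lo > hi:
        return 0.0
    k = np.arange(lo, hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def enrich_groups(
    groups: dict[str, str],
    top: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    strict_tail: bool = True,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of every group in a top set.

    ``groups`` maps every network node to its group label; ``top`` is the
    top-centrality node set. One row per distinct group, in order of
    first appearance. The significance flag uses the raw p-value (no
    multiple-testing correction); Benjamini-Hochberg adjusted values are
    attached as a supplementary column.
    """
    groups = dict(groups)
    if not groups:
        raise ValueError("empty network: no nodes with group labels")
    top = set(top)
    unknown = top - groups.keys()
    if unknown:
        raise ValueError(f"top set contains nodes absent from the network: {unknown}")
    N = len(groups)
    n = len(top)
    labels: list[str] = []
    for g in groups.values():  # first-appearance order
        if g not in labels:
            labels.append(g)
    rows: list[EnrichmentRow] = []
    for label in labels:
        members = {node for node, g in groups.items() if g == label}
        K = len(members)
        x = len(members & top)
        p = hypergeom_upper(N, K, n, x, strict=strict_tail)
        rows.append(
            EnrichmentRow(
                group=label, K=K, x=x, n=n, N=N, p=p, significant=p < alpha
            )
        )
    q_bh = multipletests([r.p for r in rows], method="fdr_bh")[1]
    for row, q in zip(rows, q_bh):
        row.q_bh = float(q)
    return rows


def dominant_groups(
    rows: Sequence[EnrichmentRow],
    dominance_fraction: float = DEFAULT_DOMINANCE_FRACTION,
) -> list[EnrichmentRow]:
    """Flag groups supplying at least ``dominance_fraction`` of the top set.

    The boundary is inclusive. Mutates and returns the rows. By
    convention dominance is evaluated on rows computed for the top-20%
    set, whatever cutoffs were used for enrichment.
    """
    for row in rows:
        row.dominant = (row.x / row.n) >= dominance_fraction
    return list(rows)
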