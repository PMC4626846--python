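"""Synthetic OTU tables with planted, recoverable network structure.

Real 16S census tables are compositional (fixed sequencing depth),
heavy-tailed (a few very abundant taxa, a long tail of rare ones) and —
the property this package exists to detect — contain groups of taxa whose
abundances co-vary. The generator emulates exactly those statistical
features: latent absolute abundances are multivariate log-normal with a
block correlation structure (``block_rho`` within each designated hub
group, zero elsewhere), and observed counts are a fixed-depth multinomial
draw over the closed (normalized) latent abundances. Because ground truth
is known, every stage of the pipeline — and in particular whether the hub
groups come out as key groups — is testable without any external data.

The log-normal + multinomial construction (rather than, say, a
Dirichlet-multinomial) is deliberate: the planted correlation structure
passes through compositional closure in a controlled way, so recovery
failures indict the inference, not the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .otu_io import GroupMap, OtuTable

__all__ = ["CommunitySpec", "generate_table", "ground_truth_keys", "DEFAULT_SPEC"]


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    ``groups`` assigns every OTU to a labelled group; ``hub_groups`` are
    the groups given within-block latent correlation ``block_rho`` (all
    pairs inside the block). ``log_mean``/``log_sd`` set the per-sample
    latent log-abundance law; ``mean_spread`` is the SD of per-OTU base
    log-means, producing heavy-tailed relative abundances across roughly
    three orders of magnitude at the default 1.5. ``depth_jitter_sd`` > 0
    adds per-sample log-normal depth variation (overdispersion).
    """

    n_otus: int = 60
    n_samples: int = 300
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"Group{chr(65 + i)}", 10) for i in range(6)]
    )
    hub_groups: frozenset[str] = frozenset({"GroupA"})
    block_rho: float = 0.8
    log_mean: float = 0.0
    log_sd: float = 1.0
    mean_spread: float = 1.5
    depth: int = 5000
    depth_jitter_sd: float = 0.0
    seed: int = 0
    site: str = "synthetic"

    def __post_init__(self) -> None:
        sizes = dict(self.groups)
        if sum(n for _, n in self.groups) != self.n_otus:
            raise ValueError("group sizes must sum to n_otus")
        labels = {label for label, _ in self.groups}
        if not set(self.hub_groups) <= labels:
            raise ValueError("hub_groups must be a subset of group labels")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for hub in self.hub_groups:
            if sizes[hub] < 2:
                raise ValueError(
                    f"hub group {hub!r} has size {sizes[hub]}: planted "
                    f"correlation needs at least one pair"
                )


#: The reference study-condition spec used throughout the test-bench.
DEFAULT_SPEC = CommunitySpec()


def _lineage(label: str, index: int) -> str:
    return (
        f"k__Bacteria;p__Phylum{index};c__Class{index};o__Order{index};"
        f"f__Family{index};g__{label};s__"
    )


def generate_table(
    spec: CommunitySpec,
) -> tuple[OtuTable, GroupMap, np.ndarray]:
    """Draw one community table from a :class:`CommunitySpec`.

    Returns the count table, the OTU-to-group map, and the latent
    log-abundance matrix (OTU x sample) as ground truth for checking the
    planted correlations. Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    D, S = spec.n_otus, spec.n_samples

    labels: list[str] = []
    for label, size in spec.groups:
        labels.extend([label] * size)

    # block-diagonal latent correlation: block_rho inside hub groups
    R = np.eye(D)
    start = 0
    for label, size in spec.groups:
        if label in spec.hub_groups:
            block = np.full((size, size), spec.block_rho)
            np.fill_diagonal(block, 1.0)
            R[start : start + size, start : start + size] = block
        start += size
    L = np.linalg.cholesky(R)

    mu = spec.log_mean + spec.mean_spread * rng.standard_normal(D)
    latent = mu[:, None] + spec.log_sd * (L @ rng.standard_normal((D, S)))
    abundances = np.exp(latent)
    fractions = abundances / abundances.sum(axis=0, keepdims=True)

    if spec.depth_jitter_sd > 0:
        depths = np.maximum(
            1,
            np.round(
                spec.depth * np.exp(spec.depth_jitter_sd * rng.standard_normal(S))
            ).astype(int),
        )
    else:
        depths = np.full(S, spec.depth)

    counts = np.empty((D, S), dtype=np.int64)
    for s in range(S):
        counts[:, s] = rng.multinomial(depths[s], fractions[:, s])

    otu_ids = [f"OTU_{i:04d}" for i in range(D)]
    lineages = []
    group_index = {label: k for k, (label, _) in enumerate(spec.groups)}
    for label in labels:
        lineages.append(_lineage(label, group_index[label]))
    table = OtuTable(counts, otu_ids, lineages, [f"S{j:04d}" for j in range(S)], spec.site)
    gmap = GroupMap(
        mapping=dict(zip(otu_ids, labels)),
        ranks={oid: "genus" for oid in otu_ids},
    )
    return table, gmap, latent


def ground_truth_keys(spec: CommunitySpec) -> set[str]:
    """The group labels the pipeline should recover as key groups."""
    return set(spec.hub_groups)
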