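"""Per-site analysis orchestration: filter -> network -> metrics -> key players.

One body site = one OTU table = one run of the chain. ``analyze_table``
is the in-memory engine; ``run_site`` wraps it with file input/output and
provenance headers; ``run_all`` loops over sites, tolerating per-site
failures, and assembles the combined global-statistics table and the
group-by-site key/dominant matrix.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import graph_metrics, key_players, sparcc_network
from .graph_metrics import CentralityScores, GlobalStats
from .key_players import EnrichmentRow
from .otu_io import (
    GroupMap,
    OtuTable,
    build_group_map,
    prevalence_filter,
    read_group_map,
    read_otu_table,
    write_otu_table,
)
from .sparcc_network import CorrelationResult, InteractionNetwork

logger = logging.getLogger("microkey")

__all__ = ["RunConfig", "SiteResult", "analyze_table", "run_site", "run_all"]

#: Artifact files every completed site bundle contains.
BUNDLE_FILES = (
    "filtered_table.tsv",
    "correlations.tsv",
    "pvalues.tsv",
    "edges.tsv",
    "network.graphml",
    "global_stats.tsv",
    "centrality.tsv",
    "enrichment.tsv",
    "key_groups.tsv",
)


@dataclass
class RunConfig:
    """Configuration for one multi-site run; defaults encode the study choices."""

    sites: dict[str, str]  # site label -> OTU table path
    group_maps: dict[str, str] = field(default_factory=dict)  # optional per-site
    theta: float = 0.20
    n_resamples: int = sparcc_network.DEFAULT_N_RESAMPLES
    n_permutations: int = sparcc_network.DEFAULT_N_PERMUTATIONS
    exclusion_threshold: float = sparcc_network.DEFAULT_EXCLUSION_THRESHOLD
    max_exclusions: int = sparcc_network.DEFAULT_MAX_EXCLUSIONS
    alpha: float = 0.05
    cutoffs: tuple[float, ...] = key_players.DEFAULT_CUTOFFS
    metrics: tuple[str, ...] = ("degree", "betweenness")
    dominance_fraction: float = key_players.DEFAULT_DOMINANCE_FRACTION
    tie_policy: str = "stable-order"
    seed: int = 0
    outdir: str = "microkey_out"

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site is required")
        for q in self.cutoffs:
            if not 0.0 < q <= 1.0:
                raise ValueError(f"cutoff {q} outside (0, 1]")
        for m in self.metrics:
            if m not in ("degree", "betweenness"):
                raise ValueError(f"unknown centrality metric {m!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["cutoffs"] = tuple(raw.get("cutoffs", key_players.DEFAULT_CUTOFFS))
        raw["metrics"] = tuple(raw.get("metrics", ("degree", "betweenness")))
        return cls(**raw)

    def provenance(self, site: str) -> list[str]:
        return [
            f"microkey site={site} seed={self.seed} theta={self.theta} "
            f"alpha={self.alpha} resamples={self.n_resamples} "
            f"permutations={self.n_permutations} "
            f"exclusion_threshold={self.exclusion_threshold} "
            f"max_exclusions={self.max_exclusions} "
            f"cutoffs={','.join(str(q) for q in self.cutoffs)} "
            f"metrics={','.join(self.metrics)} "
            f"dominance={self.dominance_fraction} tie_policy={self.tie_policy}"
        ]


@dataclass
class SiteResult:
    site: str
    filtered: OtuTable
    correlations: CorrelationResult
    network: InteractionNetwork
    stats: GlobalStats
    centralities: dict[str, CentralityScores]
    enrichment: dict[tuple[str, float], list[EnrichmentRow]]
    key_table: pd.DataFrame


def analyze_table(
    table: OtuTable, gmap: GroupMap | None, config: RunConfig
) -> SiteResult:
    """Run the full chain on one in-memory table."""
    site = table.site or "site"

    def _stage(name: str, t0: float) -> None:
        logger.info(
            "site=%s stage=%s elapsed=%.2fs seed=%d", site, name, time.time() - t0, config.seed
        )

    t0 = time.time()
    filtered = prevalence_filter(table, config.theta)
    if filtered.n_otus == 0:
        raise ValueError(f"site {site!r}: no OTUs survive the prevalence filter")
    _stage("prevalence_filter", t0)

    if gmap is None:
        gmap = build_group_map(filtered)
    groups = dict(zip(filtered.otu_ids, gmap.labels_for(filtered)))

    t0 = time.time()
    corr = sparcc_network.sparcc_with_pvalues(
        filtered,
        n_resamples=config.n_resamples,
        n_permutations=config.n_permutations,
        seed=config.seed,
        exclusion_threshold=config.exclusion_threshold,
        max_exclusions=config.max_exclusions,
    )
    _stage("sparcc", t0)

    t0 = time.time()
    net = sparcc_network.build_network(
        corr.rho, corr.pvals, filtered.otu_ids, groups, alpha=config.alpha
    )
    stats = graph_metrics.global_stats(net)
    cents = {}
    for metric in config.metrics:
        fn = graph_metrics.degree if metric == "degree" else graph_metrics.betweenness
        cents[metric] = fn(net)
    _stage("graph_metrics", t0)

    t0 = time.time()
    enrichment: dict[tuple[str, float], list[EnrichmentRow]] = {}
    for metric in config.metrics:
        for q in config.cutoffs:
            n_top = key_players.cutoff_size(net.n_nodes, q)
            top = key_players.top_set(cents[metric], n_top, config.tie_policy)
            enrichment[(metric, q)] = key_players.enrich_groups(
                groups, top, alpha=config.alpha
            )
    # dominance: evaluated on the top-20% degree set by convention
    dom_metric = "degree" if "degree" in config.metrics else config.metrics[0]
    dom_q = 0.20 if 0.20 in config.cutoffs else max(config.cutoffs)
    dom_rows = enrichment.get((dom_metric, dom_q))
    if dom_rows is None:
        n_top = key_players.cutoff_size(net.n_nodes, dom_q)
        top = key_players.top_set(cents[dom_metric], n_top, config.tie_policy)
        dom_rows = key_players.enrich_groups(groups, top, alpha=config.alpha)
    key_players.dominant_groups(dom_rows, config.dominance_fraction)
    dominant = {r.group: r.dominant for r in dom_rows}

    records = []
    labels = list(dict.fromkeys(groups.values()))
    for label in labels:
        rec: dict = {"group": label}
        for (metric, q), rows in enrichment.items():
            row = next(r for r in rows if r.group == label)
            rec["total"] = row.K
            rec[f"{metric}_{int(round(q * 100))}_x"] = row.x
            rec[f"{metric}_{int(round(q * 100))}_p"] = row.p
            rec[f"{metric}_{int(round(q * 100))}_key"] = row.significant
        rec["dominant"] = dominant.get(label, False)
        records.append(rec)
    key_table = pd.DataFrame.from_records(records)
    _stage("key_players", t0)

    return SiteResult(
        site=site,
        filtered=filtered,
        correlations=corr,
        network=net,
        stats=stats,
        centralities=cents,
        enrichment=enrichment,
        key_table=key_table,
    )


def _write_matrix(
    path: Path, matrix: np.ndarray, ids: list[str], comments: list[str]
) -> None:
    with path.open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, oid in enumerate(ids):
            fh.write(oid + "\t" + "\t".join(f"{v:.4f}" for v in matrix[i]) + "\n")


def _write_df(path: Path, df: pd.DataFrame, comments: list[str]) -> None:
    with path.open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_site_bundle(result: SiteResult, outdir: Path, config: RunConfig) -> Path:
    """Write the full artifact bundle for one analyzed site."""
    site_dir = outdir / result.site
    site_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance(result.site)

    write_otu_table(result.filtered, site_dir / "filtered_table.tsv", comments=prov)
    ids = result.filtered.otu_ids
    _write_matrix(site_dir / "correlations.tsv", result.correlations.rho, ids, prov)
    _write_matrix(site_dir / "pvalues.tsv", result.correlations.pvals, ids, prov)

    with (site_dir / "edges.tsv").open("w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        fh.write("otu_a\totu_b\n")
        for a, b in sorted(result.network.edge_list()):
            fh.write(f"{a}\t{b}\n")

    g = result.network.graph.copy()
    g.graph["provenance"] = prov[0]
    nx.write_graphml(g, site_dir / "network.graphml")

    stats_df = pd.DataFrame([{"network": result.site, **result.stats.as_row()}])
    _write_df(site_dir / "global_stats.tsv", stats_df, prov)

    groups = result.network.groups
    cent_df = pd.DataFrame({"otu_id": ids, "group": [groups[o] for o in ids]})
    for metric, scores in result.centralities.items():
        cent_df[metric] = [scores.scores[o] for o in ids]
    _write_df(site_dir / "centrality.tsv", cent_df, prov)

    enr_records = []
    for (metric, q), rows in result.enrichment.items():
        for r in rows:
            enr_records.append(
                {
                    "metric": metric,
                    "cutoff": q,
                    "group": r.group,
                    "total": r.K,
                    "x": r.x,
                    "n_top": r.n,
                    "p": r.p,
                    "q_bh": r.q_bh,
                    "significant": r.significant,
                }
            )
    _write_df(site_dir / "enrichment.tsv", pd.DataFrame.from_records(enr_records), prov)
    _write_df(site_dir / "key_groups.tsv", result.key_table, prov)
    return site_dir


def run_site(config: RunConfig, site: str) -> SiteResult:
    """Analyze one configured site and write its artifact bundle."""
    path = config.sites[site]
    table = read_otu_table(path, site=site)
    gmap = (
        read_group_map(config.group_maps[site])
        if site in config.group_maps
        else None
    )
    result = analyze_table(table, gmap, config)
    write_site_bundle(result, Path(config.outdir), config)
    return result


def run_all(config: RunConfig) -> tuple[dict[str, SiteResult], dict[str, str]]:
    """Analyze every configured site; continue past per-site failures.

    Returns completed results and a site -> error-message map for
    failures. Also writes the combined global-statistics table (one row
    per site) and the group-by-site key/dominant matrix.
    """
    results: dict[str, SiteResult] = {}
    failures: dict[str, str] = {}
    for site in config.sites:
        try:
            results[site] = run_site(config, site)
        except Exception as exc:  # noqa: BLE001 - per-site isolation is the contract
            logger.error("site=%s failed: %s", site, exc)
            failures[site] = str(exc)
    if not results:
        raise RuntimeError(f"no site completed; failures: {failures}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = pd.DataFrame(
        [{"network": site, **res.stats.as_row()} for site, res in results.items()]
    )
    _write_df(outdir / "global_stats_all.tsv", combined, [f"microkey seed={config.seed}"])

    matrix_rows = []
    for site, res in results.items():
        for _, row in res.key_table.iterrows():
            key_cols = [c for c in res.key_table.columns if c.endswith("_key")]
            matrix_rows.append(
                {
                    "site": site,
                    "group": row["group"],
                    "key": bool(any(row[c] for c in key_cols)),
                    "dominant": bool(row["dominant"]),
                }
            )
    _write_df(
        outdir / "key_dominant_matrix.tsv",
        pd.DataFrame.from_records(matrix_rows),
        [f"microkey seed={config.seed}"],
    )
    return results, failures
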