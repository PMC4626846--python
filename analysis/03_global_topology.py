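#!/usr/bin/env python
"""Global topology battery for the inferred networks.

Reads each site's exported edge list and centrality node table back from
the pipeline bundles (no recomputation of the inference) and reports the
standard global battery — N, L, density, diameter, average path length,
transitivity — one row per site, to results/03_global_topology.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from specs import RESULTS, RUN_DIR, SITE_SPECS, ensure_runs  # noqa: E402

from microkey import InteractionNetwork, global_stats  # noqa: E402


def load_network(site: str) -> InteractionNetwork:
    bundle = RUN_DIR / site
    cent = pd.read_csv(bundle / "centrality.tsv", sep="\t", comment="#")
    edges = pd.read_csv(bundle / "edges.tsv", sep="\t", comment="#")
    return InteractionNetwork(
        nodes=list(cent["otu_id"]),
        groups=dict(zip(cent["otu_id"], cent["group"])),
        edges=list(edges.itertuples(index=False, name=None)),
    )


def main() -> None:
    ensure_runs()
    rows = []
    for site in SITE_SPECS:
        stats = global_stats(load_network(site))
        rows.append({"network": site, **stats.as_row()})
    df = pd.DataFrame(rows).round(4)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "03_global_topology.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
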