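"""Shared study conditions for the numbered analysis scripts.

Three synthetic body-site-like communities with known ground truth:

* ``gut_like``     — one 10-OTU hub group (GroupA) at latent correlation 0.8,
                     mirroring a community with a single structural core.
* ``mouth_like``   — two hub groups, a diversity of key players.
* ``neutral``      — no planted structure; the negative control.

All scripts derive every number from these specs through the package, so
the whole analysis regenerates from scratch (seeds fixed here).
"""

from __future__ import annotations

from pathlib import Path

from microkey import CommunitySpec, RunConfig, generate_table
from microkey.otu_io import write_otu_table

REPO = Path(__file__).resolve().parents[1]
SCRATCH = REPO / "scratch"
RESULTS = REPO / "results"
RUN_DIR = SCRATCH / "runs"

SITE_SPECS: dict[str, CommunitySpec] = {
    "gut_like": CommunitySpec(
        groups=[(f"Group{c}", 10) for c in "ABCDEF"],
        hub_groups=frozenset({"GroupA"}),
        seed=11,
        site="gut_like",
    ),
    "mouth_like": CommunitySpec(
        groups=[(f"Group{c}", 10) for c in "ABCDEF"],
        hub_groups=frozenset({"GroupA", "GroupB"}),
        seed=12,
        site="mouth_like",
    ),
    "neutral": CommunitySpec(
        groups=[(f"Group{c}", 10) for c in "ABCDEF"],
        hub_groups=frozenset(),
        seed=13,
        site="neutral",
    ),
}

PIPELINE_SEED = 2015


def table_path(site: str) -> Path:
    return SCRATCH / "sim" / f"{site}.tsv"


def write_tables() -> None:
    (SCRATCH / "sim").mkdir(parents=True, exist_ok=True)
    for site, spec in SITE_SPECS.items():
        table, _, _ = generate_table(spec)
        write_otu_table(table, table_path(site), comments=[f"seed={spec.seed}"])


def run_config() -> RunConfig:
    return RunConfig(
        sites={site: str(table_path(site)) for site in SITE_SPECS},
        seed=PIPELINE_SEED,
        outdir=str(RUN_DIR),
    )


def ensure_runs() -> None:
    """Regenerate simulation tables and pipeline bundles if absent."""
    if not all(table_path(s).exists() for s in SITE_SPECS):
        write_tables()
    from microkey import run_all

    if not all((RUN_DIR / s / "key_groups.tsv").exists() for s in SITE_SPECS):
        run_all(run_config())
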