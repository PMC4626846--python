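from __future__ import annotations

import numpy as np
import pytest

from microkey import CommunitySpec, OtuTable, generate_table

TOY_TSV = """\
#OTU ID\tS1\tS2\tS3\tS4\ttaxonomy
OTU_1\t5\t0\t3\t1\tk__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__
OTU_2\t0\t2\t0\t0\tk__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__;s__
OTU_3\t1\t1\t1\t1\tk__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Faecalibacterium;s__
"""


@pytest.fixture
def toy_table_path(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TSV)
    return path


@pytest.fixture
def toy_table():
    return OtuTable(
        counts=np.array([[5, 0, 3, 1], [0, 2, 0, 0], [1, 1, 1, 1]]),
        otu_ids=["OTU_1", "OTU_2", "OTU_3"],
        lineages=["g__Bacteroides", "f__Lachnospiraceae;g__", "g__Faecalibacterium"],
        sample_ids=["S1", "S2", "S3", "S4"],
        site="toy",
    )


@pytest.fixture(scope="session")
def small_community():
    """A small planted-hub community shared by the slower integration tests."""
    spec = CommunitySpec(
        n_otus=30,
        n_samples=80,
        groups=[(f"Group{c}", 5) for c in "ABCDEF"],
        hub_groups=frozenset({"GroupA"}),
        depth=2000,
        seed=7,
    )
    table, gmap, latent = generate_table(spec)
    return spec, table, gmap, latent
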