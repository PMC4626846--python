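"""Published reference composition of the HMP stool co-occurrence network.

The published per-group table for the 1254-OTU stool network (group size,
observed members in each top-centrality set, and the reported
hypergeometric p-values) ships with the package. Because the
over-representation probability depends only on (N, K, n, x), the
published p-value columns can be recomputed exactly from the counts —
the package's strongest external cross-check.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .key_players import cutoff_size, hypergeom_upper

__all__ = ["load_stool_reference", "recompute_reference_pvalues", "STOOL_N"]

#: Network size of the published stool co-occurrence network.
STOOL_N = 1254

#: (observed column, printed p column, rank fraction) per published column.
REFERENCE_COLUMNS = [
    ("d20_x", "d20_p", 0.20),
    ("b20_x", "b20_p", 0.20),
    ("d10_x", "d10_p", 0.10),
    ("d5_x", "d5_p", 0.05),
]


def load_stool_reference() -> pd.DataFrame:
    """The published stool-network group table as a DataFrame."""
    ref = resources.files("microkey.data").joinpath("stool_network_groups.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    assert df["total"].sum() == STOOL_N
    return df


def recompute_reference_pvalues(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every published p-value column from its (K, x) counts.

    Adds ``*_p_recomputed`` columns next to the published ones, using the
    strict upper hypergeometric tail with N = 1254 and top-set sizes
    derived from the rank fractions (251, 251, 125, 63).
    """
    if df is None:
        df = load_stool_reference()
    df = df.copy()
    for x_col, p_col, q in REFERENCE_COLUMNS:
        n_top = cutoff_size(STOOL_N, q)
        df[p_col + "_recomputed"] = [
            hypergeom_upper(STOOL_N, int(K), n_top, int(x))
            for K, x in zip(df["total"], df[x_col])
        ]
    return df
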