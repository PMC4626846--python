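"""Reading, writing and filtering of OTU count tables.

The pipeline's input is the classic tab-separated OTU table: one row per
OTU, one column per sample, integer counts, plus a taxonomy lineage column
(recognized by name, case-insensitively). Lineages are parsed into group
labels — the most specific named rank at or above genus — so that OTUs can
be aggregated into genera/families/orders for the enrichment stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "OtuTable",
    "GroupMap",
    "read_otu_table",
    "write_otu_table",
    "read_group_map",
    "parse_group",
    "build_group_map",
    "prevalence_filter",
]

#: Column names recognized as the taxonomy column (compared lower-cased).
TAXONOMY_COLUMN_NAMES = frozenset(
    {"taxonomy", "lineage", "consensus lineage", "consensus_lineage", "taxon"}
)

#: Greengenes-style rank prefixes, most general to most specific.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class OtuTable:
    """An OTU-by-sample count matrix with taxonomy and a body-site label.

    Attributes
    ----------
    counts
        Non-negative integer matrix, shape ``(n_otus, n_samples)``.
    otu_ids
        Unique OTU identifiers, one per row.
    lineages
        Taxonomy lineage string per OTU (may be empty).
    sample_ids
        Sample identifiers, one per column.
    site
        Free-text body-site label (e.g. ``"stool"``).
    """

    counts: np.ndarray
    otu_ids: list[str]
    lineages: list[str]
    sample_ids: list[str]
    site: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (OTUs x samples)")
        n_otus, n_samples = self.counts.shape
        if len(self.otu_ids) != n_otus or len(self.lineages) != n_otus:
            raise ValueError(
                f"row mismatch: {n_otus} count rows, {len(self.otu_ids)} OTU ids, "
                f"{len(self.lineages)} lineages"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"column mismatch: {n_samples} count columns, "
                f"{len(self.sample_ids)} sample ids"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        seen: set[str] = set()
        for oid in self.otu_ids:
            if oid in seen:
                raise ValueError(f"duplicate OTU id: {oid!r}")
            seen.add(oid)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def fractions(self, pseudocount: float = 0.0) -> np.ndarray:
        """Per-sample relative abundances, optionally with a pseudocount."""
        x = self.counts.astype(float) + pseudocount
        return x / x.sum(axis=0, keepdims=True)


@dataclass
class GroupMap:
    """Mapping of OTU id to taxonomic group label.

    ``ranks`` records, per OTU, the rank the label was taken from
    (``genus``/``family``/...); ``"user"`` for labels supplied directly.
    """

    mapping: dict[str, str]
    ranks: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, otu_id: str) -> str:
        return self.mapping[otu_id]

    def labels_for(self, table: OtuTable) -> list[str]:
        missing = [oid for oid in table.otu_ids if oid not in self.mapping]
        if missing:
            raise KeyError(f"{len(missing)} OTUs lack a group label, e.g. {missing[0]!r}")
        return [self.mapping[oid] for oid in table.otu_ids]


def parse_group(lineage: str) -> str:
    """Extract the group label from a taxonomy lineage string.

    Returns the most specific *named* rank at or above genus. Species is
    never used as a group: groups in this analysis are genera, families,
    orders and the like. Works on Greengenes-style rank-prefixed lineages
    (``k__Bacteria;...;g__Bacteroides;s__``) and on plain semicolon-
    delimited name lists. A lineage with no named rank above species maps
    to ``"Unclassified"``.
    """
    fields = [f.strip() for f in lineage.split(";")] if lineage else []
    prefixed = any(
        f.lower().startswith(p) for f in fields for p in _RANK_PREFIXES
    )
    names: list[str] = []  # most general -> most specific, species excluded
    if prefixed:
        by_rank: dict[str, str] = {}
        for f in fields:
            low = f.lower()
            for prefix, rank in zip(_RANK_PREFIXES, _RANK_NAMES):
                if low.startswith(prefix):
                    by_rank[rank] = f[len(prefix):].strip()
                    break
        names = [by_rank.get(r, "") for r in _RANK_NAMES[:-1]]  # drop species
    else:
        # Plain names: a full 7-field lineage is assumed to end at species.
        if len(fields) >= 7:
            fields = fields[:6]
        names = fields
    for name in reversed(names):
        cleaned = name.strip().strip("[]")
        if cleaned:
            return cleaned
    return "Unclassified"


def build_group_map(table: OtuTable) -> GroupMap:
    """Derive a :class:`GroupMap` from a table's lineage strings."""
    mapping: dict[str, str] = {}
    ranks: dict[str, str] = {}
    for oid, lineage in zip(table.otu_ids, table.lineages):
        label = parse_group(lineage)
        mapping[oid] = label
        ranks[oid] = "parsed"
    return GroupMap(mapping=mapping, ranks=ranks)


def read_otu_table(path: str | Path, site: str = "") -> OtuTable:
    """Read a classic tab-separated OTU table.

    Layout: a header row of sample ids (optionally beginning with
    ``#OTU ID``), then one row per OTU with the OTU id in the first
    column. A column whose header names a taxonomy field (``taxonomy``,
    ``lineage``, ...; case-insensitive) holds lineages; the remaining
    columns are integer counts. Leading lines starting with ``#`` are
    treated as comments, except a ``#OTU ID`` line which is the header.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    data_rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            if header is None and raw.lower().startswith("#otu id"):
                header = raw.lstrip("#").split("\t")
            continue
        if header is None:
            header = raw.split("\t")
            continue
        data_rows.append((lineno, raw.split("\t")))
    if header is None or not data_rows:
        raise ValueError(f"{path}: no OTUs found")

    lowered = [h.strip().lower() for h in header]
    tax_idx = next(
        (i for i, h in enumerate(lowered) if h in TAXONOMY_COLUMN_NAMES), None
    )
    sample_cols = [
        i for i in range(1, len(header)) if i != tax_idx
    ]
    sample_ids = [header[i].strip() for i in sample_cols]

    otu_ids: list[str] = []
    lineages: list[str] = []
    counts_rows: list[list[int]] = []
    seen: set[str] = set()
    for lineno, fields in data_rows:
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        oid = fields[0].strip()
        if not oid:
            raise ValueError(f"{path}:{lineno}: empty OTU id")
        if oid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate OTU id {oid!r}")
        seen.add(oid)
        row: list[int] = []
        for i in sample_cols:
            cell = fields[i].strip()
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric count {cell!r} "
                    f"in column {header[i]!r}"
                ) from None
            if value != int(value):
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"in column {header[i]!r}"
                )
            row.append(int(value))
        otu_ids.append(oid)
        lineages.append(fields[tax_idx].strip() if tax_idx is not None else "")
        counts_rows.append(row)

    counts = np.array(counts_rows, dtype=np.int64)
    return OtuTable(counts, otu_ids, lineages, sample_ids, site=site)


def write_otu_table(
    table: OtuTable, path: str | Path, comments: list[str] | None = None
) -> None:
    """Write a table in the same classic TSV dialect read_otu_table accepts."""
    path = Path(path)
    with path.open("w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for i, oid in enumerate(table.otu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{oid}\t{row}\t{table.lineages[i]}\n")


def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column OTU-id -> group-label TSV (no header required)."""
    mapping: dict[str, str] = {}
    ranks: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        oid, label = fields[0].strip(), fields[1].strip()
        if not label:
            raise ValueError(f"{path}:{lineno}: empty group label for {oid!r}")
        mapping[oid] = label
        ranks[oid] = "user"
    if not mapping:
        raise ValueError(f"{path}: empty group map")
    return GroupMap(mapping=mapping, ranks=ranks)


def prevalence_filter(table: OtuTable, theta: float = 0.20) -> OtuTable:
    """Keep OTUs present (count > 0) in at least ``theta`` of the samples.

    The boundary is inclusive: an OTU present in exactly ``theta`` of the
    samples survives. Samples with zero total count are dropped first,
    with a warning, so presence fractions are well defined. OTU order is
    preserved.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    col_totals = table.counts.sum(axis=0)
    keep_samples = col_totals > 0
    if not np.all(keep_samples):
        n_drop = int((~keep_samples).sum())
        warnings.warn(
            f"dropping {n_drop} sample(s) with zero total count before "
            f"prevalence filtering",
            stacklevel=2,
        )
        table = replace(
            table,
            counts=table.counts[:, keep_samples],
            sample_ids=[s for s, k in zip(table.sample_ids, keep_samples) if k],
        )
    if table.n_samples == 0:
        raise ValueError("no samples with nonzero total count")
    presence = (table.counts > 0).mean(axis=1)
    keep = presence >= theta
    return replace(
        table,
        counts=table.counts[keep],
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        lineages=[l for l, k in zip(table.lineages, keep) if k],
    )
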