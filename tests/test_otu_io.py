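from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microkey import (
    OtuTable,
    parse_group,
    prevalence_filter,
    read_otu_table,
    write_otu_table,
)


class TestParseGroup:
    @pytest.mark.parametrize(
        ("lineage", "expected"),
        [
            # genus named -> genus is the group
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Ruminococcaceae;g__Faecalibacterium",
                "Faecalibacterium",
            ),
            # unnamed genus falls back to family
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Lachnospiraceae;g__",
                "Lachnospiraceae",
            ),
            # unnamed genus and family fall back to order
            (
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__;g__",
                "Clostridiales",
            ),
            # species never becomes the group, even when named
            (
                "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;"
                "f__Bacteroidaceae;g__Bacteroides;s__fragilis",
                "Bacteroides",
            ),
            # plain semicolon-delimited 7-rank form: last field is species
            (
                "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;"
                "Blautia;producta",
                "Blautia",
            ),
            # plain short form: most specific named field
            ("Bacteria;Proteobacteria;Sutterella", "Sutterella"),
            # bracketed placeholder names are unwrapped
            ("k__Bacteria;f__[Barnesiellaceae];g__", "Barnesiellaceae"),
            (";;;;;;", "Unclassified"),
            ("", "Unclassified"),
        ],
    )
    def test_most_specific_named_rank_above_species(self, lineage, expected):
        assert parse_group(lineage) == expected


class TestReadWrite:
    def test_round_trip_is_exact(self, toy_table_path, tmp_path):
        table = read_otu_table(toy_table_path, site="toy")
        assert table.counts.shape == (3, 4)
        assert table.sample_ids == ["S1", "S2", "S3", "S4"]
        out = tmp_path / "out.tsv"
        write_otu_table(table, out)
        again = read_otu_table(out, site="toy")
        assert np.array_equal(table.counts, again.counts)
        assert table.otu_ids == again.otu_ids
        assert table.lineages == again.lineages
        assert table.sample_ids == again.sample_ids

    def test_duplicate_otu_id_is_an_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("#OTU ID\tS1\ttaxonomy\nA\t1\tg__X\nA\t2\tg__Y\n")
        with pytest.raises(ValueError, match="duplicate OTU id"):
            read_otu_table(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="no OTUs"):
            read_otu_table(path)

    def test_non_integer_count_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#OTU ID\tS1\ttaxonomy\nA\t1.5\tg__X\n")
        with pytest.raises(ValueError, match="bad.tsv:2"):
            read_otu_table(path)

    def test_ragged_row_is_an_error(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("#OTU ID\tS1\tS2\ttaxonomy\nA\t1\tg__X\n")
        with pytest.raises(ValueError, match="expected 4 fields"):
            read_otu_table(path)

    def test_duplicate_ids_rejected_at_construction(self):
        with pytest.raises(ValueError, match="duplicate"):
            OtuTable(
                counts=np.ones((2, 2), dtype=int),
                otu_ids=["A", "A"],
                lineages=["", ""],
                sample_ids=["S1", "S2"],
            )


class TestPrevalenceFilter:
    def _table(self, presence_counts: list[int], n_samples: int = 20) -> OtuTable:
        counts = np.zeros((len(presence_counts), n_samples), dtype=int)
        for i, k in enumerate(presence_counts):
            counts[i, :k] = 1
        counts[-1, :] += 1  # keep every sample nonempty
        return OtuTable(
            counts=counts,
            otu_ids=[f"O{i}" for i in range(len(presence_counts))],
            lineages=[""] * len(presence_counts),
            sample_ids=[f"S{j}" for j in range(n_samples)],
        )

    def test_boundary_is_inclusive(self):
        table = self._table([4, 3, 20])
        kept = prevalence_filter(table, theta=0.20)
        assert kept.otu_ids == ["O0", "O2"]  # 4/20 kept, 3/20 removed

    def test_theta_zero_keeps_everything(self):
        table = self._table([4, 3, 20])
        assert prevalence_filter(table, theta=0.0).otu_ids == table.otu_ids

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError, match="theta"):
            prevalence_filter(self._table([4, 20]), theta=1.5)

    def test_empty_samples_dropped_with_warning(self):
        counts = np.array([[2, 0, 1], [1, 0, 0]])
        table = OtuTable(counts, ["A", "B"], ["", ""], ["S1", "S2", "S3"])
        with pytest.warns(UserWarning, match="zero total count"):
            out = prevalence_filter(table, theta=0.5)
        assert out.sample_ids == ["S1", "S3"]

    @given(
        data=st.data(),
        n_otus=st.integers(2, 8),
        n_samples=st.integers(2, 10),
        theta=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_monotone(self, data, n_otus, n_samples, theta):
        counts = np.array(
            [
                data.draw(
                    st.lists(
                        st.integers(0, 3), min_size=n_samples, max_size=n_samples
                    )
                )
                for _ in range(n_otus)
            ]
        )
        counts[0, :] += 1  # no empty samples
        table = OtuTable(
            counts,
            [f"O{i}" for i in range(n_otus)],
            [""] * n_otus,
            [f"S{j}" for j in range(n_samples)],
        )
        once = prevalence_filter(table, theta)
        twice = prevalence_filter(once, theta)
        assert once.otu_ids == twice.otu_ids
        # monotone: a stricter threshold keeps a subset
        stricter = prevalence_filter(table, min(1.0, theta + 0.25))
        assert set(stricter.otu_ids) <= set(once.otu_ids)
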