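import numpy as np
import pandas as pd
import pytest

from mran.datamodel import (
    CYANOBACTERIAL,
    ENVIRONMENTAL,
    NON_CYANOBACTERIAL,
    ParseError,
    TaxonomyMap,
    ValidationError,
    prevalence_filter,
    read_abundance_table,
    read_taxonomy,
    split_partitions,
    split_series,
    write_abundance_table,
)

from conftest import make_table


def write_tsv(path, rows):
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")


HEADER = ["site", "depth", "date", "OTU1", "OTU2", "OTU3"]


class TestReadAbundanceTable:
    def test_counts_are_closed_to_proportions(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER,
                      ["S1", 0, "2016-06", 2, 3, 5],
                      ["S1", 0, "2016-07", 1, 4, 5]])
        t = read_abundance_table(p)
        np.testing.assert_allclose(t.data.iloc[0].to_numpy(), [0.2, 0.3, 0.5])
        np.testing.assert_allclose(t.data.sum(axis=1).to_numpy(), 1.0)

    def test_proportion_input_is_unchanged(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER,
                      ["S1", 0, "2016-06", 0.2, 0.3, 0.5],
                      ["S1", 0, "2016-07", 0.1, 0.4, 0.5]])
        t = read_abundance_table(p)
        np.testing.assert_allclose(t.data.iloc[0].to_numpy(), [0.2, 0.3, 0.5])

    def test_duplicate_sample_is_rejected_naming_the_key(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER,
                      ["S1", 0, "2016-06", 1, 1, 1],
                      ["S1", 0, "2016-06", 2, 2, 2]])
        with pytest.raises(ValidationError, match="2016-06"):
            read_abundance_table(p)

    def test_missing_metadata_column_is_a_parse_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [["site", "date", "OTU1"], ["S1", "2016-06", 1]])
        with pytest.raises(ParseError, match="depth"):
            read_abundance_table(p)

    def test_negative_value_is_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER, ["S1", 0, "2016-06", 1, -2, 1]])
        with pytest.raises(ValidationError, match="negative"):
            read_abundance_table(p)

    def test_dates_truncate_to_year_month(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER,
                      ["S1", 0, "2016-06-15", 1, 1, 1],
                      ["S1", 0, "2016-07-02", 1, 1, 1]])
        t = read_abundance_table(p)
        assert [k.date for k in t.samples] == ["2016-06", "2016-07"]

    def test_taxonomy_assigns_cyanobacterial_class(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [HEADER, ["S1", 0, "2016-06", 1, 1, 1]])
        tax = TaxonomyMap({"OTU1": ("Bacteria", "Cyanobacteria", "Microcystis")})
        t = read_abundance_table(p, taxonomy=tax)
        assert t.feature_class["OTU1"] == CYANOBACTERIAL
        assert t.feature_class["OTU2"] == NON_CYANOBACTERIAL

    def test_mothur_shared_dialect(self, tmp_path):
        shared = tmp_path / "s.shared"
        write_tsv(shared, [["label", "Group", "numOtus", "OTU1", "OTU2"],
                           ["0.01", "A", 2, 6, 4],
                           ["0.01", "B", 2, 1, 9]])
        meta = tmp_path / "meta.tsv"
        write_tsv(meta, [["group", "site", "depth", "date"],
                         ["A", "S1", 0, "2016-06"],
                         ["B", "S1", 0, "2016-07"]])
        t = read_abundance_table(shared, dialect="mothur_shared", metadata=meta)
        np.testing.assert_allclose(t.data.iloc[0].to_numpy(), [0.6, 0.4])
        assert t.samples[1].date == "2016-07"


def test_write_read_round_trip_to_12_digits(tmp_path, simple_table):
    p = tmp_path / "rt.tsv"
    write_abundance_table(simple_table, p)
    back = read_abundance_table(p, env_features=["chl_a"])
    np.testing.assert_allclose(
        back.data.to_numpy(), simple_table.data.to_numpy(), rtol=1e-11
    )


def test_read_taxonomy_round_trip(tmp_path):
    p = tmp_path / "tax.tsv"
    p.write_text("otu_id\tlineage\nOTU1\tBacteria;Cyanobacteria;Microcystis\n")
    tax = read_taxonomy(p)
    assert tax.is_cyanobacterial("OTU1")
    assert tax.lineage("OTUX") == ("unclassified",)


class TestPrevalenceFilter:
    def _table_with_occurrence(self, n_samples, occurrences):
        """One OTU per requested occurrence count, plus a ubiquitous OTU and chl-a."""
        cols, vals = ["UBIQ"], [np.full(n_samples, 0.5)]
        for k, occ in enumerate(occurrences):
            v = np.zeros(n_samples)
            v[:occ] = 0.01
            cols.append(f"OTU{k}")
            vals.append(v)
        cols.append("chl_a")
        vals.append(np.full(n_samples, 3.0))
        classes = [NON_CYANOBACTERIAL] * (len(cols) - 1) + [ENVIRONMENTAL]
        return make_table(np.column_stack(vals), cols, classes)

    def test_20_percent_of_69_samples_boundary(self):
        # 14/69 = 0.203 passes the 20% rule; 13/69 = 0.188 does not
        t = self._table_with_occurrence(69, [14, 13])
        kept = prevalence_filter(t, 0.20).features
        assert "OTU0" in kept and "OTU1" not in kept

    def test_environmental_features_always_kept(self):
        t = self._table_with_occurrence(69, [1])
        kept = prevalence_filter(t, 0.20).features
        assert "chl_a" in kept

    def test_full_prevalence_keeps_only_ubiquitous(self):
        t = self._table_with_occurrence(10, [5, 9])
        kept = prevalence_filter(t, 1.0).features
        assert kept == ["UBIQ", "chl_a"]

    def test_values_not_renormalized(self):
        t = self._table_with_occurrence(10, [1])
        out = prevalence_filter(t, 0.5)
        np.testing.assert_allclose(out.data["UBIQ"].to_numpy(), 0.5)

    def test_monotone_in_threshold(self):
        t = self._table_with_occurrence(20, [2, 5, 9, 14, 20])
        previous = None
        for thr in (0.05, 0.2, 0.5, 0.8, 1.0):
            kept = set(prevalence_filter(t, thr).features)
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_empty_result_is_an_error(self):
        t = make_table(
            np.zeros((4, 1)) + 1e-12, ["OTU0"], [NON_CYANOBACTERIAL]
        )
        with pytest.raises(ValidationError, match="no features retained"):
            prevalence_filter(t, 1.0, detection_threshold=0.1)


class TestSplitPartitions:
    def test_partition_sizes(self, simple_table):
        cy, nc = split_partitions(simple_table)
        assert cy.features == ["OTU1"]
        assert nc.features == ["OTU2", "OTU3"]

    def test_all_cyano_warns_on_empty_partition(self):
        t = make_table([[0.5, 0.5]], ["A", "B"], [CYANOBACTERIAL] * 2,
                       dates=["2016-06"])
        with pytest.warns(UserWarning, match="empty"):
            cy, nc = split_partitions(t)
        assert nc.features == []

    def test_renormalize_recomputes_proportions(self):
        t = make_table([[0.5, 0.2, 0.3]], ["A", "B", "C"],
                       [CYANOBACTERIAL, NON_CYANOBACTERIAL, NON_CYANOBACTERIAL],
                       dates=["2016-06"])
        _, nc = split_partitions(t, renormalize=True)
        np.testing.assert_allclose(nc.data.iloc[0].to_numpy(), [0.4, 0.6])

    def test_concatenation_restores_original(self, simple_table):
        cy, nc = split_partitions(simple_table)
        merged = pd.concat([cy.data, nc.data], axis=1)
        otus = simple_table.otu_features
        pd.testing.assert_frame_equal(merged[otus], simple_table.data[otus])


class TestSplitSeries:
    def test_one_series_per_site_depth(self):
        t = make_table(
            np.full((4, 1), 1.0), ["A"], [NON_CYANOBACTERIAL],
            sites=["S1", "S1", "S2", "S2"],
            dates=["2016-06", "2016-07", "2016-06", "2016-07"],
        )
        series = split_series(t)
        assert [s.key for s in series] == [("S1", 0.0), ("S2", 0.0)]

    def test_missing_months_are_reported(self):
        t = make_table(
            np.full((3, 1), 1.0), ["A"], [NON_CYANOBACTERIAL],
            dates=["2016-06", "2016-08", "2016-10"],
        )
        (s,) = split_series(t)
        assert s.missing_months == ["2016-07", "2016-09"]

    def test_short_series_is_an_error(self):
        t = make_table([[1.0]], ["A"], [NON_CYANOBACTERIAL], dates=["2016-06"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            split_series(t)
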