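"""Data layer: loading, biotype grouping, filtering, tissue means, breakdown."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from snoclass.data import (
    EXCLUDE,
    AbundanceMatrix,
    TissueProfile,
    biotype_abundance_breakdown,
    filter_expressed,
    group_biotype,
    group_host_biotype,
    mean_conservation,
    read_abundance_table,
    tissue_means,
)
from snoclass.errors import ConfigError, DataError


def _write_matrix(tmp_path, df, tissues):
    mpath = tmp_path / "m.tsv"
    spath = tmp_path / "s.tsv"
    df.rename_axis("gene_id").to_csv(mpath, sep="\t")
    pd.DataFrame({"sample": list(tissues), "tissue": list(tissues.values())}
                 if isinstance(tissues, dict) else tissues).to_csv(
        spath, sep="\t", index=False)
    return mpath, spath


class TestReadAbundance:
    def test_round_trip(self, tmp_path, small_matrix):
        mpath, spath = _write_matrix(
            tmp_path, small_matrix.values,
            pd.DataFrame({"sample": small_matrix.sample_ids,
                          "tissue": list(small_matrix.sample_to_tissue)}))
        loaded = read_abundance_table(mpath, spath)
        assert loaded.gene_ids == ["G1", "G2", "G3"]
        assert loaded.sample_ids == small_matrix.sample_ids
        assert loaded.tissues == ["brain", "liver"]
        np.testing.assert_allclose(loaded.values.values,
                                   small_matrix.values.values)

    def test_gene_with_missing_cell_dropped(self, tmp_path, small_matrix, caplog):
        df = small_matrix.values.copy()
        df.loc["G2", "brain_2"] = np.nan
        mpath, spath = _write_matrix(
            tmp_path, df,
            pd.DataFrame({"sample": small_matrix.sample_ids,
                          "tissue": list(small_matrix.sample_to_tissue)}))
        with caplog.at_level("WARNING"):
            loaded = read_abundance_table(mpath, spath)
        assert loaded.gene_ids == ["G1", "G3"]
        assert "drop_missing_values" in caplog.text

    def test_sample_absent_from_sheet_is_error(self, tmp_path, small_matrix):
        sheet = pd.DataFrame({"sample": small_matrix.sample_ids[:-1],
                              "tissue": list(small_matrix.sample_to_tissue)[:-1]})
        mpath, spath = _write_matrix(tmp_path, small_matrix.values, sheet)
        with pytest.raises(DataError, match="absent from sample sheet"):
            read_abundance_table(mpath, spath)

    def test_duplicate_gene_ids_error(self, tmp_path, small_matrix):
        df = pd.concat([small_matrix.values, small_matrix.values.iloc[[0]]])
        mpath, spath = _write_matrix(
            tmp_path, df,
            pd.DataFrame({"sample": small_matrix.sample_ids,
                          "tissue": list(small_matrix.sample_to_tissue)}))
        with pytest.raises(DataError, match="duplicate gene ids"):
            read_abundance_table(mpath, spath)

    def test_negative_values_rejected(self, small_matrix):
        bad = small_matrix.values.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(DataError, match="negative"):
            AbundanceMatrix(bad, small_matrix.sample_to_tissue)


# Every raw biotype from the Ensembl-style grouping lists and its group.
GROUPING_TABLE = [
    ("IG_C_gene", "protein-coding"), ("IG_D_gene", "protein-coding"),
    ("IG_J_gene", "protein-coding"), ("IG_V_gene", "protein-coding"),
    ("TR_C_gene", "protein-coding"), ("TR_D_gene", "protein-coding"),
    ("TR_J_gene", "protein-coding"), ("TR_V_gene", "protein-coding"),
    ("polymorphic_pseudogene", "protein-coding"),
    ("protein_coding", "protein-coding"),
    ("unitary_pseudogene", "pseudogene"), ("unprocessed_pseudogene", "pseudogene"),
    ("processed_pseudogene", "pseudogene"),
    ("transcribed_unprocessed_pseudogene", "pseudogene"),
    ("transcribed_unitary_pseudogene", "pseudogene"),
    ("transcribed_processed_pseudogene", "pseudogene"),
    ("IG_pseudogene", "pseudogene"), ("IG_C_pseudogene", "pseudogene"),
    ("IG_J_pseudogene", "pseudogene"), ("IG_V_pseudogene", "pseudogene"),
    ("TR_J_pseudogene", "pseudogene"), ("TR_V_pseudogene", "pseudogene"),
    ("pseudogene", "pseudogene"),
    ("3prime_overlapping_ncRNA", "lncRNA"), ("antisense", "lncRNA"),
    ("lincRNA", "lncRNA"), ("macro_lncRNA", "lncRNA"),
    ("bidirectional_promoter_lncRNA", "lncRNA"),
    ("processed_transcript", "lncRNA"), ("sense_intronic", "lncRNA"),
    ("sense_overlapping", "lncRNA"), ("non_coding", "lncRNA"),
    ("lncRNA", "lncRNA"),
    ("Mt_tRNA", "tRNA"), ("tRNA", "tRNA"),
    ("rRNA", "other"), ("Mt_rRNA", "other"), ("ribozyme", "other"),
    ("scRNA", "other"), ("vaultRNA", "other"), ("sRNA", "other"),
    ("snoRNA", "snoRNA"), ("snRNA", "snRNA"), ("miRNA", "miRNA"),
]


class TestBiotypeGrouping:
    @pytest.mark.parametrize("raw,expected", GROUPING_TABLE)
    def test_grouping_table(self, raw, expected):
        assert group_biotype(raw) == expected

    def test_tec_maps_to_exclusion_sentinel(self):
        assert group_biotype("TEC") == EXCLUDE

    def test_unknown_string_falls_back_to_other(self, caplog):
        with caplog.at_level("WARNING"):
            assert group_biotype("made_up_biotype") == "other"
        assert "unknown_biotype" in caplog.text

    @pytest.mark.parametrize("raw,expected", [
        ("protein_coding", "protein-coding"),
        ("IG_C_gene", "protein-coding"),
        ("", "intergenic"),
        (None, "intergenic"),
        ("lincRNA", "non-coding"),
        ("snoRNA", "non-coding"),
    ])
    def test_host_biotype_grouping(self, raw, expected):
        assert group_host_biotype(raw) == expected


class TestFilterExpressed:
    def test_below_threshold_removed_boundary_strict(self, small_matrix):
        # G3 is all-zero; a gene whose max equals the threshold must also go
        v = small_matrix.values.copy()
        v.loc["G4"] = 1.0
        m = AbundanceMatrix(v, small_matrix.sample_to_tissue)
        filtered, counts = filter_expressed(m)
        assert set(filtered.gene_ids) == {"G1", "G2"}
        assert counts["below_threshold"] == 2

    def test_boundary_above_threshold_retained(self, small_matrix):
        v = small_matrix.values.copy()
        v.loc["G4"] = [0, 0, 0, 0, 0, 1.2]
        m = AbundanceMatrix(v, small_matrix.sample_to_tissue)
        filtered, _ = filter_expressed(m)
        assert "G4" in filtered.gene_ids

    def test_scarna_named_snorna_removed(self, small_matrix, small_annotation):
        # SCARNA5 (G3) would fail the threshold anyway; make it abundant
        v = small_matrix.values.copy()
        v.loc["G3"] = 50.0
        m = AbundanceMatrix(v, small_matrix.sample_to_tissue)
        filtered, counts = filter_expressed(m, small_annotation)
        assert "G3" not in filtered.gene_ids
        assert counts["excluded_name_prefix"] == 1

    def test_excluded_biotype_removed(self, small_matrix, small_annotation):
        ann = small_annotation.copy()
        ann.loc["G1", "biotype_group"] = EXCLUDE
        filtered, counts = filter_expressed(small_matrix, ann)
        assert "G1" not in filtered.gene_ids
        assert counts["excluded_biotype"] == 1

    def test_idempotent(self, small_matrix, small_annotation):
        once, _ = filter_expressed(small_matrix, small_annotation)
        twice, counts = filter_expressed(once, small_annotation)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert counts["kept"] == counts["input"]

    def test_nonpositive_threshold_rejected(self, small_matrix):
        with pytest.raises(ConfigError):
            filter_expressed(small_matrix, threshold_tpm=0)


class TestTissueMeans:
    def test_replicate_average(self, small_matrix):
        profile = tissue_means(small_matrix)
        assert profile.values.loc["G1", "brain"] == pytest.approx(4.0)
        assert profile.values.loc["G2", "liver"] == pytest.approx(50.0)
        assert (profile.values.loc["G3"] == 0).all()

    def test_single_replicate_tissue(self):
        values = pd.DataFrame({"a": [3.0], "b": [5.0]}, index=["G"])
        m = AbundanceMatrix(values, pd.Series(["x", "y"], index=["a", "b"]))
        profile = tissue_means(m)
        assert profile.values.loc["G", "x"] == 3.0
        assert profile.values.loc["G", "y"] == 5.0

    def test_commutes_with_gene_subsetting(self, small_matrix):
        sub_then_mean = tissue_means(small_matrix.subset(["G1", "G3"]))
        mean_then_sub = tissue_means(small_matrix).values.loc[["G1", "G3"]]
        pd.testing.assert_frame_equal(sub_then_mean.values, mean_then_sub)


class TestMeanConservation:
    def test_simple_means(self):
        assert mean_conservation([0.5, 0.5, 0.5]) == pytest.approx(0.5)
        assert mean_conservation([1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_independent_accumulation(self):
        scores = np.random.default_rng(7).random(100)
        total = 0.0
        for s in scores:   # second-pass summation oracle
            total += s
        assert mean_conservation(scores) == pytest.approx(total / 100)

    def test_empty_sequence_error(self):
        with pytest.raises(DataError):
            mean_conservation([])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            mean_conservation([0.5, 1.2])


class TestBreakdown:
    def test_two_biotype_shares(self, small_matrix, small_annotation):
        ann = small_annotation.copy()
        # brain sums: G1 (snoRNA) 4, G2 (protein-coding) 11
        bd = biotype_abundance_breakdown(small_matrix, ann)
        brain = bd[bd["tissue"] == "brain"].set_index("biotype_group")
        assert brain.loc["snoRNA", "fraction"] == pytest.approx(4 / 15)
        assert brain.loc["protein-coding", "fraction"] == pytest.approx(11 / 15)

    def test_single_biotype_share_is_one(self, small_matrix, small_annotation):
        ann = small_annotation.copy()
        ann["biotype_group"] = "snoRNA"
        bd = biotype_abundance_breakdown(small_matrix, ann)
        assert (bd["fraction"] == 1.0).all()

    @settings(max_examples=25, deadline=None)
    @given(seed=st_h.integers(0, 10_000))
    def test_fractions_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        values = pd.DataFrame(
            r.uniform(0.1, 100, size=(8, 4)),
            index=[f"G{i}" for i in range(8)],
            columns=["a1", "a2", "b1", "b2"])
        m = AbundanceMatrix(values, pd.Series(
            ["ta", "ta", "tb", "tb"], index=values.columns))
        ann = pd.DataFrame(
            {"biotype_group": r.choice(["snoRNA", "tRNA", "lncRNA"], 8)},
            index=values.index)
        bd = biotype_abundance_breakdown(m, ann)
        sums = bd.groupby("tissue")["fraction"].sum()
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)
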