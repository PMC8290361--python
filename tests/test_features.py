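"""SNP-to-gene mapping and top-k p-value feature blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepgp import features, io
from deepgp.features import (
    GeneSnpMap,
    build_gene_feature,
    feature_matrix,
    filter_genes,
    map_snps_to_genes,
    restrict_eqtl_to_gwas,
    unflatten_feature,
)


def snp_frame(rows):
    """rows: (snp_id, chrom, pos, disease, p, source)."""
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "disease_id", "p_value", "source"]
    )


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def brute_force_map(snps, genes, window):
    """Exhaustive O(|SNPs| * |genes|) interval scan."""
    hits = set()
    for _, s in snps.iterrows():
        for _, g in genes.iterrows():
            if (
                s["chrom"] == g["chrom"]
                and g["start"] - window <= s["pos"] <= g["end"] + window
            ):
                hits.add((g["gene_id"], s["source"], s["disease_id"], s["snp_id"]))
    return hits


def map_as_set(m: GeneSnpMap):
    return {
        (g, src, d, rec[3])
        for g, bucket in m.entries.items()
        for (src, d), recs in bucket.items()
        for rec in recs
    }


class TestMapping:
    GENES = gene_frame([("gA", "chr1", 100, 200)])

    def _snps(self):
        return snp_frame(
            [
                ("rs1", "chr1", 150, "d1", 0.01, io.GWAS),
                ("rs2", "chr1", 250, "d1", 0.02, io.GWAS),
            ]
        )

    def test_window_zero_keeps_only_in_body_snp(self):
        m = map_snps_to_genes(self._snps(), self.GENES, window_bp=0)
        assert [r[3] for r in m.records("gA", io.GWAS, "d1")] == ["rs1"]

    def test_window_extends_interval(self):
        m = map_snps_to_genes(self._snps(), self.GENES, window_bp=50)
        assert [r[3] for r in m.records("gA", io.GWAS, "d1")] == ["rs1", "rs2"]

    def test_chromosome_mismatch_never_maps(self):
        snps = snp_frame([("rs1", "chr2", 150, "d1", 0.01, io.GWAS)])
        m = map_snps_to_genes(snps, self.GENES, window_bp=10_000)
        assert m.records("gA", io.GWAS, "d1") == []

    def test_snp_in_two_overlapping_genes_maps_to_both(self):
        genes = gene_frame(
            [("gA", "chr1", 100, 200), ("gB", "chr1", 150, 300)]
        )
        snps = snp_frame([("rs1", "chr1", 180, "d1", 0.5, io.GWAS)])
        m = map_snps_to_genes(snps, genes, window_bp=0)
        assert m.records("gA", io.GWAS, "d1") and m.records("gB", io.GWAS, "d1")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_snps = 60, 150
        genes = gene_frame(
            [
                (
                    f"g{i}",
                    f"chr{rng.integers(1, 4)}",
                    (s := int(rng.integers(1, 5000))),
                    s + int(rng.integers(0, 800)),
                )
                for i in range(n_genes)
            ]
        )
        snps = snp_frame(
            [
                (
                    f"rs{j}",
                    f"chr{rng.integers(1, 4)}",
                    int(rng.integers(1, 6000)),
                    f"d{rng.integers(1, 3)}",
                    float(1 - rng.random()),
                    io.GWAS if rng.random() < 0.5 else io.EQTL,
                )
                for j in range(n_snps)
            ]
        )
        window = int(rng.integers(0, 100))
        got = map_as_set(map_snps_to_genes(snps, genes, window))
        assert got == brute_force_map(snps, genes, window)


class TestFilterAndRestrict:
    def test_gene_without_snps_dropped(self):
        genes = gene_frame(
            [("gA", "chr1", 1, 10), ("gB", "chr1", 20, 30), ("gC", "chr2", 1, 10)]
        )
        snps = snp_frame(
            [
                ("rs1", "chr1", 5, "d1", 0.5, io.GWAS),
                ("rs2", "chr1", 25, "d1", 0.5, io.EQTL),
            ]
        )
        m = map_snps_to_genes(snps, genes, 0)
        assert filter_genes(m) == ["gA", "gB"]

    def test_all_unmapped_gives_empty_result(self):
        genes = gene_frame([("gA", "chr1", 1, 10)])
        m = map_snps_to_genes(snp_frame([]), genes, 0)
        assert filter_genes(m) == []

    def test_eqtl_only_gene_retained(self):
        genes = gene_frame([("gA", "chr1", 1, 10)])
        snps = snp_frame([("rs1", "chr1", 5, "d1", 0.5, io.EQTL)])
        assert filter_genes(map_snps_to_genes(snps, genes, 0)) == ["gA"]

    def test_restriction_drops_eqtl_loci_absent_from_gwas(self):
        genes = gene_frame([("gA", "chr1", 1, 100)])
        snps = snp_frame(
            [
                ("rs1", "chr1", 10, "d1", 0.3, io.GWAS),
                ("rs1", "chr1", 10, "d1", 0.2, io.EQTL),
                ("rs2", "chr1", 20, "d1", 0.1, io.EQTL),  # not a GWAS locus
            ]
        )
        m = restrict_eqtl_to_gwas(map_snps_to_genes(snps, genes, 0))
        assert [r[3] for r in m.records("gA", io.EQTL, "d1")] == ["rs1"]
        assert [r[3] for r in m.records("gA", io.GWAS, "d1")] == ["rs1"]


def make_map(gene_id, per_layer_disease):
    """Build a GeneSnpMap entry from {(source, disease): [p, ...]}."""
    bucket = {}
    for (src, d), ps in per_layer_disease.items():
        bucket[(src, d)] = sorted(
            (float(p), "chr1", 10 * (i + 1), f"rs{i + 1}") for i, p in enumerate(ps)
        )
    return GeneSnpMap(genes=[gene_id], entries={gene_id: bucket})


class TestGeneFeature:
    DISEASES = ["d1", "d2"]

    def test_fewer_than_k_pads_with_one(self):
        m = make_map("gA", {(io.GWAS, "d1"): [0.01, 0.005]})
        block = build_gene_feature("gA", m, self.DISEASES, k=5)
        assert block[0, 0].tolist() == [0.005, 0.01, 1.0, 1.0, 1.0]

    def test_no_mapped_snps_is_pure_padding(self):
        m = make_map("gA", {})
        block = build_gene_feature("gA", m, self.DISEASES, k=5)
        assert (block == 1.0).all()

    def test_more_than_k_keeps_smallest_ascending(self):
        ps = [0.9, 0.3, 0.5, 0.05, 0.7, 0.2, 0.6]
        m = make_map("gA", {(io.EQTL, "d2"): ps})
        block = build_gene_feature("gA", m, self.DISEASES, k=5)
        assert block[1, 1].tolist() == sorted(ps)[:5]

    def test_unknown_gene_raises(self):
        m = make_map("gA", {})
        with pytest.raises(KeyError):
            build_gene_feature("gGHOST", m, self.DISEASES, k=5)

    def test_ties_break_by_coordinate_then_id(self):
        bucket = {
            (io.GWAS, "d1"): sorted(
                [
                    (0.5, "chr1", 30, "rsC"),
                    (0.5, "chr1", 10, "rsB"),
                    (0.5, "chr1", 10, "rsA"),
                ]
            )
        }
        m = GeneSnpMap(genes=["gA"], entries={"gA": bucket})
        block = build_gene_feature("gA", m, self.DISEASES, k=2)
        # deterministic: the two kept records are (10, rsA) and (10, rsB)
        assert bucket[(io.GWAS, "d1")][:2] == [
            (0.5, "chr1", 10, "rsA"),
            (0.5, "chr1", 10, "rsB"),
        ]
        assert block[0, 0].tolist() == [0.5, 0.5]

    @given(
        ps=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=0, max_size=8
        ),
        extra=st.floats(min_value=1e-6, max_value=0.999),
    )
    @settings(max_examples=50, deadline=None)
    def test_adding_a_snp_never_increases_any_entry(self, ps, extra):
        before = build_gene_feature(
            "gA", make_map("gA", {(io.GWAS, "d1"): ps}), self.DISEASES, k=5
        )
        after = build_gene_feature(
            "gA", make_map("gA", {(io.GWAS, "d1"): ps + [extra]}), self.DISEASES, k=5
        )
        assert (after <= before + 1e-15).all()

    def test_rows_sorted_ascending(self):
        m = make_map("gA", {(io.GWAS, "d1"): [0.4, 0.1, 0.2, 0.3, 0.25, 0.15]})
        block = build_gene_feature("gA", m, self.DISEASES, k=5)
        row = block[0, 0]
        assert (np.diff(row) >= 0).all()


class TestFeatureMatrix:
    def test_default_panel_flattens_to_fifty(self):
        diseases = [f"d{i}" for i in range(5)]
        m = make_map("gA", {(io.GWAS, "d0"): [0.1]})
        _, X = feature_matrix([("gA", build_gene_feature("gA", m, diseases, 5))])
        assert X.shape == (1, 50)

    def test_empty_input_gives_empty_matrix(self):
        gene_ids, X = feature_matrix([])
        assert gene_ids == [] and X.shape[0] == 0

    def test_flatten_round_trip(self):
        rng = np.random.default_rng(3)
        block = rng.random((2, 5, 5))
        _, X = feature_matrix([("g", block)])
        np.testing.assert_array_equal(unflatten_feature(X[0], 5, 5), block)

    def test_layer_major_order(self):
        block = np.ones((2, 2, 2))
        block[0] = [[1, 2], [3, 4]]
        block[1] = [[5, 6], [7, 8]]
        _, X = feature_matrix([("g", block)])
        assert X[0].tolist() == [1, 2, 3, 4, 5, 6, 7, 8]

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(io.ValidationError, match="shape"):
            feature_matrix([("a", np.ones((2, 5, 5))), ("b", np.ones((2, 4, 5)))])


def test_every_retained_gene_has_signal_entry(toy_bundle):
    """After eQTL restriction + filtering, no retained gene is all-padding."""
    m = features.map_snps_to_genes(
        toy_bundle.tables()["snps"], toy_bundle.annotations, 0
    )
    m = features.restrict_eqtl_to_gwas(m)
    gene_ids, X = features.build_feature_matrix(
        m, toy_bundle.similarity.disease_ids, k=5
    )
    assert len(gene_ids) > 0
    assert (X < 1.0).any(axis=1).all()
    assert ((X > 0) & (X <= 1.0)).all()
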