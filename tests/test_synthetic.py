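"""Generators: distributional targets, determinism, and reader round-trips."""

import numpy as np
import pytest
from scipy import stats

from cnvmir.expression import ExpressionMatrix, cv_table
from cnvmir.maf import minor_allele_frequency, read_bed_intervals, read_snp_counts
from cnvmir.network import RegulatoryNetwork, read_cnv_families, read_edge_list
from cnvmir.enrichment import read_annotations, read_der_table
from cnvmir.synthetic import (
    DegreeSpec,
    SyntheticConfig,
    generate_bundle,
    label_cnv,
    make_annotations,
    make_expression,
    make_genotypes,
    make_network,
)


class TestMakeNetwork:
    def test_degenerate_degree_one(self):
        net = make_network(10, 50, DegreeSpec(p=1.0, max_degree=1), seed=0)
        assert net.n_edges == 50
        assert all(d == 1 for d in net.gene_degree().values())

    def test_edge_conservation(self):
        net = make_network(20, 200, DegreeSpec(p=0.3, max_degree=8), seed=1)
        assert sum(net.gene_degree().values()) == net.n_edges

    def test_degree_distribution_goodness_of_fit(self):
        """Empirical regulator-count histogram matches the truncated geometric."""
        spec = DegreeSpec(p=0.5, max_degree=5)
        net = make_network(20, 10_000, spec, seed=2)
        observed = np.bincount(list(net.gene_degree().values()), minlength=6)[1:6]
        expected = spec.pmf() * 10_000
        _, p = stats.chisquare(observed, expected)
        assert p > 1e-3

    def test_max_degree_above_family_pool_rejected(self):
        with pytest.raises(ValueError):
            make_network(3, 10, DegreeSpec(p=0.3, max_degree=5), seed=0)


class TestLabelCnv:
    def test_uniform_inclusion_frequencies(self):
        """bias 0: every family is labelled at rate n_cnv / n_families."""
        net = make_network(12, 60, DegreeSpec(p=0.4, max_degree=4), seed=3)
        n_seeds, n_cnv = 2000, 4
        counts = {f: 0 for f in net.families}
        for seed in range(n_seeds):
            for fam in label_cnv(net, n_cnv, 0.0, seed=seed).cnv_families:
                counts[fam] += 1
        target = n_cnv / 12
        se = np.sqrt(target * (1 - target) / n_seeds)
        for fam, c in counts.items():
            assert abs(c / n_seeds - target) <= 5 * se, fam

    def test_all_families_labelled(self):
        net = make_network(8, 30, DegreeSpec(p=0.4, max_degree=4), seed=4)
        assert label_cnv(net, 8, 99.0, seed=0).cnv_families == net.families

    def test_bias_promotes_colabelling(self):
        """Two families sharing every target co-label more often under bias."""
        shared = {(f, f"g{i}") for f in ("fa", "fb") for i in range(10)}
        others = {(f"f{j}", f"h{j}") for j in range(8)}
        edges = shared | others
        net = RegulatoryNetwork(
            families={f for f, _ in edges}, genes={g for _, g in edges}, edges=edges
        )
        n_seeds = 300
        co = {0.0: 0, 50.0: 0}
        for bias in co:
            for seed in range(n_seeds):
                fams = label_cnv(net, 2, bias, seed=seed).cnv_families
                co[bias] += fams == {"fa", "fb"}
        assert co[50.0] > co[0.0]


class TestMakeExpression:
    def test_zero_cv_constant_rows(self):
        m = make_expression(["g1", "g2"], {"P": 5}, 0.0, seed=0)
        table = cv_table(m).table
        assert (table["cv"] == 0.0).all()

    def test_realized_cv_tracks_target(self):
        m = make_expression([f"g{i}" for i in range(300)], {"P": 90}, 0.025, seed=1)
        realized = cv_table(m).cv_series("P")
        assert abs(np.median(realized) - 0.025) <= 0.1 * 0.025

    def test_cv_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            make_expression(["g"], {"P": 4}, 1.0, seed=0)

    def test_planted_shift_recovered_by_de_detection(self):
        from cnvmir.popde import detect_de_pair

        genes = [f"g{i}" for i in range(500)]
        m = make_expression(
            genes, {"A": 45, "B": 45}, 0.03,
            seed=2, de_genes={"g7": "B"}, de_shift=1.5,
        )
        means = m.population_means()
        res = detect_de_pair(means["A"], means["B"], alpha=0.05)
        assert "g7" in res.de_genes


class TestMakeGenotypes:
    def test_monomorphic_at_zero(self):
        snps = make_genotypes(20, (0.0, 0.0), 50, seed=0)
        assert all(minor_allele_frequency(s.counts["ALL"]) == 0.0 for s in snps)

    def test_heterozygote_fraction_at_half(self):
        snps = make_genotypes(200, (0.5, 0.5), 1000, seed=1)
        het = np.mean([s.counts["ALL"].n_Aa / 1000 for s in snps])
        assert het == pytest.approx(0.5, abs=0.01)

    def test_invalid_maf_range(self):
        with pytest.raises(ValueError):
            make_genotypes(5, (0.2, 0.7), 10, seed=0)


class TestMakeAnnotations:
    def test_zero_base_rate_only_planted(self):
        genes = [f"g{i}" for i in range(50)]
        ann = make_annotations(
            genes, 5, seed=0, base_rate_range=(0.0, 0.0),
            planted=[("T", set(genes[:10]), 1.0, 0.0)],
        )
        assert set(ann) == set(genes[:10])
        assert all(terms == {"T"} for terms in ann.values())

    def test_referential_integrity(self):
        genes = [f"g{i}" for i in range(100)]
        ann = make_annotations(genes, 10, seed=1)
        assert set(ann) <= set(genes)
        assert all(ann.values())


class TestBundle:
    def test_deterministic_under_seed(self):
        a = generate_bundle(SyntheticConfig(seed=5))
        b = generate_bundle(SyntheticConfig(seed=5))
        assert a.network.edges == b.network.edges
        assert a.cnv.cnv_families == b.cnv.cnv_families
        assert a.expression.values.equals(b.expression.values)
        assert a.der.equals(b.der)
        assert [s.counts for s in a.snps] == [s.counts for s in b.snps]

    def test_round_trips_through_readers(self, default_bundle, bundle_dir):
        net = read_edge_list(bundle_dir["edges"], score_threshold=None)
        assert net.edges == default_bundle.network.edges
        cnv = read_cnv_families(bundle_dir["cnv"])
        assert cnv.cnv_families == default_bundle.cnv.cnv_families
        m = ExpressionMatrix.read(bundle_dir["expr"], bundle_dir["pops"])
        assert np.allclose(m.values.values, default_bundle.expression.values.values)
        assert list(m.population_of) == list(default_bundle.expression.population_of)
        snps = {s.snp_id: s for s in read_snp_counts(bundle_dir["snps"])}
        for s in default_bundle.snps:
            assert snps[s.snp_id].counts == s.counts
            assert (snps[s.snp_id].chrom, snps[s.snp_id].pos) == (s.chrom, s.pos)
        ivs = read_bed_intervals(bundle_dir["utrs"])
        assert {(i.chrom, i.start, i.end, i.gene, i.region_tag) for i in ivs} == {
            (i.chrom, i.start, i.end, i.gene, i.region_tag) for i in default_bundle.utrs
        }
        assert read_annotations(bundle_dir["go"]) == default_bundle.annotations
        der = read_der_table(bundle_dir["der"])
        assert np.allclose(der.sort_index(), default_bundle.der.sort_index())

    def test_default_scale_mirrors_tenth_of_full_data(self, default_bundle):
        net = default_bundle.network
        assert len(net.families) == 54
        assert len(net.genes) == 917
        # mean regulator degree ~6.9 (63,428 edges over 9,174 targets)
        assert 5.5 <= net.n_edges / len(net.genes) <= 8.0
        assert len(default_bundle.cnv.cnv_families) == 17
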