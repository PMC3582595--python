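"""Pseudo-CNV relabelling null: simulation, closed form, and tail p-values."""

import numpy as np
import pytest

from cnvmir.network import (
    EXCLUSIVE_CNV,
    EXCLUSIVE_NONCNV,
    CnvAnnotation,
    RegulatoryNetwork,
    classify_targets,
)
from cnvmir.resampling import (
    DegenerateNullError,
    analytic_expected_exclusive,
    enrichment_table,
    simulate_null_distributions,
    tail_probability,
)
from cnvmir.synthetic import DegreeSpec, make_network


def _line_network(n_fams, n_genes_per_fam=1):
    """Each gene has exactly one private regulator (degree-1 everywhere)."""
    edges = {
        (f"f{i}", f"g{i}_{j}") for i in range(n_fams) for j in range(n_genes_per_fam)
    }
    return RegulatoryNetwork(
        families={f for f, _ in edges}, genes={g for _, g in edges}, edges=edges
    )


class TestTailProbability:
    # printed (mean, sd, observed) triples of the full-scale relabelling null
    @pytest.mark.parametrize(
        "observed,mean,sd,expected,places",
        [
            (823, 716.479, 67.633, 0.0576, 4),
            (211, 134.428, 22.810, 0.000392, None),  # checked to +-5e-6 below
            (67, 28.597, 8.115, 0.000001, 6),
            (95, 145.793, 22.981, 0.0135, 4),
        ],
    )
    def test_printed_triples(self, observed, mean, sd, expected, places):
        _, p = tail_probability(observed, mean, sd)
        if places is None:
            assert abs(p - expected) <= 5e-6
        else:
            assert round(p, places) == expected

    def test_observed_at_mean(self):
        z, p = tail_probability(100, 100.0, 5.0)
        assert z == 0.0 and p == 0.5

    def test_degenerate_sd_raises(self):
        with pytest.raises(DegenerateNullError):
            tail_probability(10, 10.0, 0.0)


class TestSimulateNull:
    def test_all_families_pseudo_cnv_is_deterministic(self, default_bundle):
        net = default_bundle.network
        cls = classify_targets(net, CnvAnnotation(cnv_families=set(net.families)))
        tally = cls.per_k_tally(EXCLUSIVE_CNV)
        nulls = simulate_null_distributions(net, len(net.families), reps=5, seed=0)
        for k in range(1, 6):
            nd = nulls[(EXCLUSIVE_CNV, k)]
            assert nd.sd == 0.0 and nd.mean == tally[k]

    def test_zero_pseudo_cnv_is_deterministic(self, default_bundle):
        net = default_bundle.network
        cls = classify_targets(net, CnvAnnotation(cnv_families=set()))
        tally = cls.per_k_tally(EXCLUSIVE_NONCNV)
        nulls = simulate_null_distributions(net, 0, reps=5, seed=0)
        for k in range(1, 6):
            nd = nulls[(EXCLUSIVE_NONCNV, k)]
            assert nd.sd == 0.0 and nd.mean == tally[k]

    def test_closed_form_mean_tiny_network(self):
        # 4 families, 6 degree-1 genes, half the families pseudo-CNV:
        # E[exclusive count] = 6 * (2/4) = 3
        edges = {(f"f{i % 4}", f"g{i}") for i in range(6)}
        net = RegulatoryNetwork(
            families={f for f, _ in edges}, genes={g for _, g in edges}, edges=edges
        )
        nulls = simulate_null_distributions(net, 2, reps=10_000, seed=1)
        nd = nulls[(EXCLUSIVE_CNV, 1)]
        se = nd.sd / np.sqrt(10_000)
        assert abs(nd.mean - 3.0) <= 3 * se

    def test_same_seed_bit_identical(self, default_bundle):
        net = default_bundle.network
        a = simulate_null_distributions(net, 17, reps=50, seed=42)
        b = simulate_null_distributions(net, 17, reps=50, seed=42)
        for cat in a:
            assert np.array_equal(a[cat].replicate_counts, b[cat].replicate_counts)

    def test_replicates_partition_genes(self, default_bundle):
        net = default_bundle.network
        nulls = simulate_null_distributions(net, 17, reps=30, seed=3)
        cls_any = classify_targets(net, CnvAnnotation(cnv_families=set()))
        n_genes = len(net.genes)
        # per replicate: sum of exclusive counts never exceeds the gene total,
        # and the two k=1 vectors sum to the constant degree-1 gene count
        deg1 = cls_any.per_k_tally(EXCLUSIVE_NONCNV)[1]
        k1_sum = (
            nulls[(EXCLUSIVE_CNV, 1)].replicate_counts
            + nulls[(EXCLUSIVE_NONCNV, 1)].replicate_counts
        )
        assert np.all(k1_sum == deg1)
        total = sum(nulls[c].replicate_counts for c in nulls)
        assert np.all(total <= n_genes)

    def test_mirror_symmetry_of_k1_sds(self, default_bundle):
        # forced by complementation on degree-1 genes (the full-scale table
        # prints the same sd, 67.633, for both k=1 rows)
        nulls = simulate_null_distributions(default_bundle.network, 17, reps=200, seed=9)
        assert nulls[(EXCLUSIVE_CNV, 1)].sd == pytest.approx(
            nulls[(EXCLUSIVE_NONCNV, 1)].sd, abs=1e-12
        )

    def test_bad_arguments(self, toy_network):
        with pytest.raises(ValueError):
            simulate_null_distributions(toy_network, 99, reps=10, seed=0)
        with pytest.raises(ValueError):
            simulate_null_distributions(toy_network, 1, reps=1, seed=0)


class TestAnalyticExpected:
    def test_degree1_genes_halved(self):
        net = _line_network(4)
        assert analytic_expected_exclusive(net, 2, 1) == pytest.approx(4 * 2 / 4)

    def test_single_degree2_gene(self):
        edges = {("f0", "g"), ("f1", "g"), ("f2", "x"), ("f3", "x")}
        net = RegulatoryNetwork(
            families={"f0", "f1", "f2", "f3"}, genes={"g", "x"}, edges=edges
        )
        # P(both of g's regulators among 2 of 4) = C(2,2)/C(4,2) = 1/6, twice
        assert analytic_expected_exclusive(net, 2, 2) == pytest.approx(2 / 6)

    def test_full_draw_recovers_tally(self, default_bundle):
        net = default_bundle.network
        cls = classify_targets(net, CnvAnnotation(cnv_families=set(net.families)))
        tally = cls.per_k_tally(EXCLUSIVE_CNV)
        for k in range(1, 6):
            assert analytic_expected_exclusive(net, len(net.families), k) == pytest.approx(tally[k])

    def test_oracle_equivalence_on_synthetic_networks(self):
        """Simulated null means match the hypergeometric closed form."""
        reps = 1000
        for seed, (nf, ng) in enumerate([(20, 150), (50, 500)]):
            net = make_network(nf, ng, DegreeSpec(p=0.3, max_degree=8), seed=seed)
            n_pseudo = nf // 3
            nulls = simulate_null_distributions(net, n_pseudo, reps=reps, seed=seed)
            for k in range(1, 6):
                nd = nulls[(EXCLUSIVE_CNV, k)]
                expected = analytic_expected_exclusive(net, n_pseudo, k)
                se = max(nd.sd, 1e-9) / np.sqrt(reps)
                assert abs(nd.mean - expected) <= max(3 * se, 1e-9), (seed, k)


class TestEnrichmentTable:
    def test_two_family_symmetry(self):
        # with 2 private-target families and 1 pseudo-CNV draw the exclusive
        # count is exactly 1 in every replicate: a degenerate null centred
        # on the observed value (no deviation detectable)
        net = _line_network(2)
        table = enrichment_table(net, CnvAnnotation(cnv_families={"f0"}), reps=2000, seed=5)
        nd = next(t for t in table if t.category == (EXCLUSIVE_CNV, 1))
        assert nd.observed == 1
        assert nd.mean == 1.0 and nd.sd == 0.0 and nd.degenerate

    def test_symmetric_labelling_gives_small_z(self):
        # family i privately targets i+1 genes (sizes 1..8, total 36); a
        # 4-family draw has null mean 36*4/8 = 18.  Labelling families with
        # sizes 1+8+4+5 = 18 puts the observed count at the centre.
        edges = {(f"f{i}", f"g{i}_{j}") for i in range(8) for j in range(i + 1)}
        net = RegulatoryNetwork(
            families={f for f, _ in edges}, genes={g for _, g in edges}, edges=edges
        )
        cnv = CnvAnnotation(cnv_families={"f0", "f7", "f3", "f4"})
        table = enrichment_table(net, cnv, reps=2000, seed=5)
        nd = next(t for t in table if t.category == (EXCLUSIVE_CNV, 1))
        assert nd.observed == 18
        assert nd.mean == pytest.approx(18.0, rel=0.02)
        assert abs(nd.z) < 0.2

    def test_degenerate_when_all_families_cnv(self, default_bundle):
        net = default_bundle.network
        table = enrichment_table(
            net, CnvAnnotation(cnv_families=set(net.families)), reps=10, seed=0
        )
        for nd in table:
            assert nd.degenerate and nd.z is None
            if nd.category[0] == EXCLUSIVE_CNV:
                assert nd.observed == nd.mean

    def test_empirical_p_matches_normal_p_roughly(self, default_bundle):
        table = enrichment_table(default_bundle.network, default_bundle.cnv, reps=400, seed=2)
        nd = next(t for t in table if t.category == (EXCLUSIVE_NONCNV, 1))
        assert 0 < nd.empirical_p() <= 1
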