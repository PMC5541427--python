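"""Filters, aggregation, fold changes, pattern mining and correlation."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from methpath.analysis import (
    FilterSpec,
    apply_filters,
    build_overlays,
    correlation_screen,
    expression_fold,
    find_similar,
    gene_methylation_value,
    match_sites,
    methylation_expression_correlation,
    order_samples,
)
from methpath.io import SampleGrouping, SiteRecord
from methpath.kgml import parse_kgml

from conftest import make_matrix


def site(betas, gene="G", site_id="cg1", location=None):
    return SiteRecord(gene=gene, site_id=site_id, betas=tuple(betas), location=location)


class TestMatchSites:
    def test_case_insensitive_alias_match(self, fixture_kgml):
        graph = parse_kgml(fixture_kgml)
        m = make_matrix([("erbb2_cg1", (0.1, 0.2, 0.3)), ("HER-2_cg2", (0.4, 0.5, 0.6))])
        matched = match_sites(graph, m)
        assert {s.site_id for s in matched["ERBB2"]} == {"cg1", "cg2"}

    def test_unknown_gene_matches_nowhere(self, fixture_kgml):
        graph = parse_kgml(fixture_kgml)
        m = make_matrix([("NOTAGENE_cg1", (0.1, 0.2, 0.3))])
        matched = match_sites(graph, m)
        assert all(not recs for recs in matched.values())

    def test_two_sites_set_multi_site_flag(self, fixture_kgml):
        graph = parse_kgml(fixture_kgml)
        m = make_matrix([("FAS_cg1", (0.1, 0.2, 0.3)), ("FAS_cg2", (0.2, 0.2, 0.2))])
        overlays = build_overlays(graph, m)
        assert overlays["FAS"].multi_site
        assert not overlays["CASP8"].multi_site


class TestApplyFilters:
    def test_sd_closed_form(self):
        s = site([0.1, 0.1, 0.9, 0.9], site_id="cg1")
        expected = math.sqrt(4 * 0.16 / 3)  # brute-force: mean 0.5, deviations +-0.4
        assert s.sample_sd() == pytest.approx(expected, abs=1e-15)
        passing, _ = apply_filters([s], FilterSpec(sd_threshold=0.2))
        assert passing == [s]

    def test_constant_site_fails_sd(self):
        _, excluded = apply_filters(
            [site([0.5, 0.5, 0.5])], FilterSpec(sd_threshold=0.2)
        )
        assert len(excluded) == 1

    def test_vacuous_spec_passes_everything(self):
        sites = [site([0.1], site_id=f"cg{i}") for i in range(5)]
        passing, excluded = apply_filters(sites, FilterSpec())
        assert passing == sites and excluded == []

    def test_fewer_than_two_observations_fail_sd(self):
        s = site([0.4, float("nan"), float("nan")])
        assert not FilterSpec(sd_threshold=0.0).passes(s)

    def test_beta_range_all_vs_any_mode(self):
        s = site([0.1, 0.6, 0.9])
        assert not FilterSpec(beta_range=(0.5, 1.0)).passes(s)
        assert FilterSpec(beta_range=(0.5, 1.0), range_mode="any").passes(s)

    def test_location_filter(self):
        s = site([0.1, 0.2, 0.3], location="UTR5")
        assert FilterSpec(locations=frozenset({"UTR5", "upstream"})).passes(s)
        assert not FilterSpec(locations=frozenset({"exonic"})).passes(s)

    def test_site_list_matches_id_or_position(self):
        s = SiteRecord(gene="G", site_id="cg9", betas=(0.1,), position=("chr1", 100))
        assert FilterSpec(site_list=frozenset({"cg9"})).passes(s)
        assert FilterSpec(site_list=frozenset({"chr1:100"})).passes(s)
        assert not FilterSpec(site_list=frozenset({"cg8"})).passes(s)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(beta_range=(0.9, 0.1))

    def test_partition_and_idempotence(self):
        rng = random.Random(7)
        sites = [
            site([rng.random() for _ in range(6)], site_id=f"cg{i}",
                 location=rng.choice(["UTR5", "exonic", None]))
            for i in range(30)
        ]
        spec = FilterSpec(sd_threshold=0.1, beta_range=(0.05, 0.95))
        passing, excluded = apply_filters(sites, spec)
        assert passing + excluded and len(passing) + len(excluded) == len(sites)
        assert set(id(s) for s in passing).isdisjoint(id(s) for s in excluded)
        again_pass, again_excl = apply_filters(passing, spec)
        assert again_pass == passing and again_excl == []


class TestGeneValue:
    def test_single_site_single_sample_identity(self):
        v = gene_methylation_value([site([0.37])], ["s1"], sample="s1")
        assert v == pytest.approx(0.37)

    def test_mean_over_sites(self):
        v = gene_methylation_value(
            [site([0.2], site_id="a"), site([0.8], site_id="b")], ["s1"], sample="s1"
        )
        assert v == pytest.approx(0.5)

    def test_group_mean_over_member_samples(self):
        sites = [site([0.1, 0.2, 0.9])]
        grouping = SampleGrouping({"s1": "g", "s2": "g", "s3": "g"}, ("g",))
        v = gene_methylation_value(
            sites, ["s1", "s2", "s3"], group="g", grouping=grouping
        )
        assert v == pytest.approx(0.4)

    def test_median_aggregator_option(self):
        sites = [site([0.1, 0.2, 0.9])]
        grouping = SampleGrouping({"s1": "g", "s2": "g", "s3": "g"}, ("g",))
        v = gene_methylation_value(
            sites, ["s1", "s2", "s3"], group="g", grouping=grouping,
            aggregator=np.median,
        )
        assert v == pytest.approx(0.2)

    def test_no_sites_is_undefined_not_error(self):
        assert math.isnan(gene_methylation_value([], ["s1"], sample="s1"))


class TestExpressionFold:
    def test_value_equal_median_is_zero(self):
        assert expression_fold(10.0, [5.0, 10.0, 20.0]) == 0.0

    def test_four_fold_is_two(self):
        vals = [100.0, 100.0, 100.0]
        assert expression_fold(400.0, vals) == pytest.approx(2.0, abs=1e-3)

    def test_clipping_at_scale(self):
        vals = [10.0] * 5
        assert expression_fold(1000.0, vals, scale=4.0) == 4.0
        assert expression_fold(0.0, vals, scale=4.0) == pytest.approx(
            -math.log2(10.01 / 0.01) if math.log2(10.01 / 0.01) < 4 else -4.0
        )

    def test_odd_around_median_in_log_space(self):
        vals = [0.0, 8.0, 64.0]  # median 8
        up = expression_fold(16.0, vals, pseudocount=0.0)
        down = expression_fold(4.0, vals, pseudocount=0.0)
        assert up == pytest.approx(-down)


class TestFindSimilar:
    def test_identical_vector_ranks_first_with_zero_distance(self):
        m = make_matrix(
            [
                ("T_cg1", (0.1, 0.2, 0.3)),
                ("A_cg2", (0.1, 0.2, 0.3)),
                ("B_cg3", (0.9, 0.9, 0.9)),
            ]
        )
        hits = find_similar("T", m, top_k=2)
        assert hits[0].gene == "A" and hits[0].distance == 0.0 and hits[0].rank == 1

    def test_hand_computed_rms_distance(self):
        m = make_matrix(
            [("T_cg1", (0.1, 0.2, 0.3)), ("A_cg2", (0.4, 0.6, 0.3))]
        )
        hits = find_similar("T", m, top_k=1)
        assert hits[0].distance == pytest.approx(
            math.sqrt((0.09 + 0.16 + 0.0) / 3), abs=1e-9
        )
        assert hits[0].distance == pytest.approx(0.2887, abs=5e-5)

    def test_top_k_and_monotone_distances(self):
        rng = random.Random(3)
        rows = [("T_cg0", tuple(rng.random() for _ in range(3)))]
        rows += [
            (f"G{i}_cg{i + 1}", tuple(rng.random() for _ in range(3)))
            for i in range(10)
        ]
        m = make_matrix(rows)
        hits = find_similar("T", m, top_k=3)
        assert len(hits) == 3
        assert all(
            hits[i].distance <= hits[i + 1].distance for i in range(len(hits) - 1)
        )
        assert [h.rank for h in hits] == [1, 2, 3]

    def test_dissimilar_reverses_order(self):
        m = make_matrix(
            [
                ("T_cg1", (0.1, 0.1, 0.1)),
                ("A_cg2", (0.2, 0.2, 0.2)),
                ("B_cg3", (0.9, 0.9, 0.9)),
            ]
        )
        hits = find_similar("T", m, direction="dissimilar")
        assert hits[0].gene == "B"

    def test_brute_force_equivalence_with_missing_values(self):
        rng = np.random.default_rng(11)
        n_genes, n_samples = 20, 15
        rows = []
        for i in range(n_genes):
            betas = rng.random(n_samples)
            betas[rng.random(n_samples) < 0.1] = np.nan
            rows.append((f"G{i:02d}_cg{i:03d}", tuple(betas)))
        m = make_matrix(rows, sample_ids=tuple(f"s{j}" for j in range(n_samples)))

        target = "G00"
        tvec = np.array(rows[0][1])
        # independent brute force: RMS over shared samples, per-gene best site
        expected = []
        for key, betas in rows[1:]:
            gene = key.split("_")[0]
            b = np.array(betas)
            mask = ~np.isnan(tvec) & ~np.isnan(b)
            if mask.sum() < 2:
                continue
            d = math.sqrt(float(np.mean((tvec[mask] - b[mask]) ** 2)))
            expected.append((d, gene.lower(), gene))
        expected.sort()
        hits = find_similar(target, m, top_k=len(expected))
        assert [h.gene for h in hits] == [g for _, _, g in expected]
        np.testing.assert_allclose(
            [h.distance for h in hits], [d for d, _, _ in expected], atol=1e-12
        )

    def test_distance_symmetric_and_zero_iff_equal(self):
        from methpath.analysis import _pairwise_distance

        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = rng.random(8), rng.random(8)
            a[rng.random(8) < 0.2] = np.nan
            b[rng.random(8) < 0.2] = np.nan
            d_ab, n1 = _pairwise_distance(a, b)
            d_ba, n2 = _pairwise_distance(b, a)
            assert n1 == n2
            if n1:
                assert d_ab == d_ba
                mask = ~np.isnan(a) & ~np.isnan(b)
                assert (d_ab == 0.0) == bool(np.all(a[mask] == b[mask]))


class TestSpearman:
    def test_perfect_anti_monotone(self):
        rho, p = methylation_expression_correlation([1, 2, 3], [6, 4, 2])
        assert rho == -1.0

    def test_hand_computed_rank_example(self):
        # ranks (1,3,2,4) vs (4,3,2,1): sum d^2 = 18, rho = 1 - 6*18/(4*15) = -0.8
        rho, _ = methylation_expression_correlation([0.1, 0.3, 0.2, 0.4], [40, 30, 20, 10])
        assert rho == pytest.approx(-0.8, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        rho, p = methylation_expression_correlation([1, 2, 3], [5, 5, 5])
        assert rho is None and p is None

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m, e = rng.random(25), rng.random(25)
            rho, p = methylation_expression_correlation(m, e)
            ref_rho, ref_p = stats.spearmanr(m, e)
            assert rho == pytest.approx(float(ref_rho))
            assert p == pytest.approx(float(ref_p))

    def test_monotone_coupling_and_independence(self):
        rng = np.random.default_rng(8)
        beta = rng.random(40)
        expr = 100.0 * np.power(2.0, -4.0 * beta)  # strictly decreasing
        rho, _ = methylation_expression_correlation(beta, expr)
        assert rho == -1.0
        rho_ind, _ = methylation_expression_correlation(beta, rng.random(40))
        assert abs(rho_ind) < 0.5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            methylation_expression_correlation([1, 2], [2, 1])


class TestCorrelationScreen:
    def test_constant_expression_never_passes(self):
        meth = make_matrix([("A_cg1", (0.1, 0.5, 0.9))])
        import io as _io

        from methpath.io import read_expression_matrix

        expr = read_expression_matrix(_io.StringIO("gene\ts1\ts2\ts3\nA\t5\t5\t5\n"))
        assert correlation_screen(meth, expr, threshold=-0.5) == {}

    def test_anti_correlated_gene_found(self):
        meth = make_matrix([("A_cg1", (0.1, 0.5, 0.9)), ("B_cg2", (0.5, 0.5, 0.6))])
        import io as _io

        from methpath.io import read_expression_matrix

        expr = read_expression_matrix(
            _io.StringIO("gene\ts1\ts2\ts3\nA\t30\t20\t10\nB\t1\t2\t3\n")
        )
        hits = correlation_screen(meth, expr, threshold=-0.7)
        assert set(hits) == {"A"}
        assert hits["A"][1] == -1.0


class TestOrderSamples:
    def test_ascending_by_gene_value(self):
        m = make_matrix([("G_cg1", (0.9, 0.1, 0.5))])
        assert order_samples(m, "G") == ["s2", "s3", "s1"]

    def test_ties_keep_original_order(self):
        m = make_matrix([("G_cg1", (0.5, 0.5, 0.1))])
        assert order_samples(m, "G") == ["s3", "s1", "s2"]

    def test_all_missing_sample_goes_last(self):
        m = make_matrix([("G_cg1", (0.9, None, 0.1))])
        assert order_samples(m, "G") == ["s3", "s1", "s2"]

    def test_absent_gene_is_error(self):
        m = make_matrix([("G_cg1", (0.9, 0.1, 0.5))])
        with pytest.raises(KeyError):
            order_samples(m, "NOPE")


class TestOverlayStatus:
    def test_no_data_vs_no_passing_sites(self, fixture_kgml):
        graph = parse_kgml(fixture_kgml)
        # CASP8 has a constant site (fails SD), ERBB2/FAS have no rows at all
        m = make_matrix([("CASP8_cg1", (0.5, 0.5, 0.5))])
        overlays = build_overlays(graph, m, FilterSpec(sd_threshold=0.2))
        assert overlays["CASP8"].status == "no_passing_sites"
        assert overlays["ERBB2"].status == "no_data"
        assert overlays["FAS"].status == "no_data"

    def test_sd_filter_recovers_planted_difference(self):
        # planted group difference dbeta=0.5 against sigma=0.05 noise
        rng = np.random.default_rng(4)
        n = 40
        rows = []
        planted = {"P1_cg1", "P2_cg2"}
        for key in sorted(planted):
            betas = np.concatenate(
                [
                    np.clip(rng.normal(0.15, 0.05, n // 2), 0, 1),
                    np.clip(rng.normal(0.65, 0.05, n // 2), 0, 1),
                ]
            )
            rows.append((key, tuple(betas)))
        for i in range(10):
            rows.append(
                (f"B{i}_cg{i + 10}", tuple(np.clip(rng.normal(0.4, 0.05, n), 0, 1)))
            )
        m = make_matrix(rows, sample_ids=tuple(f"s{j}" for j in range(n)))
        passing, _ = apply_filters(m.rows, FilterSpec(sd_threshold=0.2))
        assert {f"{s.gene}_{s.site_id}" for s in passing} == planted
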