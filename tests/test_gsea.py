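import numpy as np
import pandas as pd
import pytest

from timepheno import gsea

from _oracles import gsea_es_oracle


def _ranking(scores):
    scores = np.asarray(scores, float)
    genes = [f"G{i:03d}" for i in range(scores.size)]
    return genes, scores


def _random_instance(rng, n_genes=None, set_size=None):
    n = int(n_genes or rng.integers(10, 51))
    k = int(set_size or rng.integers(1, max(2, n // 2)))
    scores = np.sort(rng.normal(size=n))[::-1]
    genes = [f"G{i:03d}" for i in range(n)]
    members = set(rng.choice(genes, size=k, replace=False))
    return genes, scores, members


class TestEnrichmentScore:
    def test_top_block_unweighted_walk(self):
        # 3-member set at the top of 10 equally scored genes, p=0: the walk
        # climbs 1/3 per hit to 1.0 and then decays by 1/7 per miss
        genes, scores = _ranking(np.ones(10))
        members = set(genes[:3])
        es, running, leading = gsea.enrichment_score(genes, scores, members, weight_exponent=0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running[:3], [1 / 3, 2 / 3, 1.0])
        assert running[-1] == pytest.approx(0.0, abs=1e-12)
        assert set(leading) == members
        assert es == pytest.approx(gsea_es_oracle(genes, scores, members, 0))

    def test_bottom_set_with_negative_scores_is_negative(self):
        genes, scores = _ranking(np.linspace(2, -2, 12))
        members = set(genes[-4:])
        es, _, leading = gsea.enrichment_score(genes, scores, members)
        assert es < 0
        assert set(leading) <= members

    def test_reversal_antisymmetry(self, rng):
        """Reversing the ranking and negating scores negates ES (tie-free)."""
        for _ in range(20):
            genes, scores, members = _random_instance(rng)
            es_fwd, _, _ = gsea.enrichment_score(genes, scores, members)
            es_rev, _, _ = gsea.enrichment_score(genes[::-1], -scores[::-1], members)
            assert es_rev == pytest.approx(-es_fwd)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(200):
            genes, scores, members = _random_instance(rng)
            es, _, _ = gsea.enrichment_score(genes, scores, members)
            assert es == pytest.approx(gsea_es_oracle(genes, scores, members))

    def test_es_bounded(self, rng):
        for _ in range(50):
            genes, scores, members = _random_instance(rng)
            es, running, _ = gsea.enrichment_score(genes, scores, members)
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_permuting_non_members_never_changes_es(self, rng):
        genes, scores, members = _random_instance(rng, n_genes=30, set_size=6)
        es, _, _ = gsea.enrichment_score(genes, scores, members)
        non_member_idx = [i for i, g in enumerate(genes) if g not in members]
        shuffled = list(genes)
        perm = rng.permutation(non_member_idx)
        for src, dst in zip(non_member_idx, perm):
            shuffled[dst] = genes[src]
        es2, _, _ = gsea.enrichment_score(shuffled, scores, members)
        assert es2 == pytest.approx(es)

    def test_empty_intersection_rejected(self):
        genes, scores = _ranking(np.arange(5.0)[::-1])
        with pytest.raises(gsea.GseaError, match="empty intersection"):
            gsea.enrichment_score(genes, scores, {"ABSENT"})

    def test_unsorted_scores_rejected(self):
        with pytest.raises(gsea.GseaError, match="non-increasing"):
            gsea.enrichment_score(["A", "B"], [1.0, 2.0], {"A"})


class TestPermutationNull:
    def test_seeded_runs_identical(self):
        scores = np.sort(np.random.default_rng(3).normal(size=100))[::-1]
        a = gsea.permutation_null(scores, 10, 200, np.random.default_rng(42))
        b = gsea.permutation_null(scores, 10, 200, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_null_mean_near_zero_for_symmetric_scores(self):
        scores = np.sort(np.random.default_rng(5).normal(size=200))[::-1]
        nulls = gsea.permutation_null(scores, 15, 2000, np.random.default_rng(7))
        assert abs(nulls.mean()) < 0.05

    def test_batch_es_agrees_with_single_set_path(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        genes = [f"G{i:03d}" for i in range(40)]
        for _ in range(25):
            members = set(rng.choice(genes, size=8, replace=False))
            es_single, _, _ = gsea.enrichment_score(genes, scores, members)
            positions = np.array([[i for i, g in enumerate(genes) if g in members]])
            es_batch = gsea._es_batch(scores, positions, 1.0)[0]
            assert es_batch == pytest.approx(es_single)

    @pytest.mark.parametrize("n_perm, set_size", [(0, 5), (100, 0), (100, 100)])
    def test_contract_violations(self, n_perm, set_size):
        scores = np.linspace(3, -3, 100)
        with pytest.raises(gsea.GseaError):
            gsea.permutation_null(scores, set_size, n_perm, np.random.default_rng(0))


class TestNormalizeAndFdr:
    def test_zero_es_maps_to_nes_zero_p_one(self):
        nulls = {"S": np.array([0.5, -0.5, 0.3, -0.3])}
        table = gsea.normalize_and_fdr({"S": 0.0}, nulls)
        row = table.iloc[0]
        assert row.nes == 0.0 and row.p_nominal == 1.0 and row.fdr_q == 1.0

    def test_no_same_sign_null_flagged(self):
        table = gsea.normalize_and_fdr({"S": 0.8}, {"S": np.array([-0.2, -0.4, -0.1])})
        row = table.iloc[0]
        assert row.p_nominal == pytest.approx(1 / 4)
        assert "no-same-sign-null" in row["flags"]

    def test_nes_sign_matches_es_sign(self, rng):
        scores = np.sort(rng.normal(size=200))[::-1]
        genes = [f"G{i:03d}" for i in range(200)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        sets = {
            f"SET{i}": frozenset(rng.choice(genes, size=15, replace=False)) for i in range(10)
        }
        table = gsea.gsea_preranked(ranked, sets, n_perm=200, seed=1)
        ok = table.dropna(subset=["nes"])
        assert (np.sign(ok.nes) == np.sign(ok.es)).all()

    def test_monotone_q_in_abs_nes_per_sign(self, rng):
        scores = np.sort(rng.normal(size=300))[::-1]
        genes = [f"G{i:03d}" for i in range(300)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        sets = {
            f"SET{i}": frozenset(rng.choice(genes, size=20, replace=False)) for i in range(20)
        }
        table = gsea.gsea_preranked(ranked, sets, n_perm=300, seed=2).dropna(subset=["nes"])
        for sign in (1, -1):
            side = table[np.sign(table.nes) == sign].sort_values(
                "nes", key=np.abs, ascending=False
            )
            assert (np.diff(side.fdr_q) >= -1e-12).all()


class TestGseaPreranked:
    def test_planted_top_decile_set_is_significant(self, rng):
        n = 500
        scores = np.sort(rng.normal(size=n) + np.linspace(3, -3, n))[::-1]
        genes = [f"G{i:03d}" for i in range(n)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        sets = {"TOP_DECILE": frozenset(genes[: n // 10])}
        sets.update(
            {f"RAND{i}": frozenset(rng.choice(genes, size=50, replace=False)) for i in range(15)}
        )
        table = gsea.gsea_preranked(ranked, sets, n_perm=1000, seed=13)
        top = table.set_index("set_name").loc["TOP_DECILE"]
        assert top.fdr_q < 0.01 and top.nes > 1.7
        kept = gsea.significant_sets(table)
        assert "TOP_DECILE" in set(kept.set_name)

    def test_fixed_seed_bit_identical(self, rng):
        scores = np.sort(rng.normal(size=150))[::-1]
        genes = [f"G{i:03d}" for i in range(150)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        sets = {f"S{i}": frozenset(genes[i * 10 : i * 10 + 12]) for i in range(5)}
        a = gsea.gsea_preranked(ranked, sets, n_perm=150, seed=99)
        b = gsea.gsea_preranked(ranked, sets, n_perm=150, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_absent_members_dropped_and_logged(self, caplog, rng):
        scores = np.sort(rng.normal(size=50))[::-1]
        genes = [f"G{i:03d}" for i in range(50)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        sets = {"PARTIAL": frozenset(genes[:5] + ["MISSING1", "MISSING2"])}
        with caplog.at_level("INFO"):
            table = gsea.gsea_preranked(ranked, sets, n_perm=100, seed=3)
        assert table.iloc[0].n_hits == 5 and table.iloc[0].n_dropped == 2

    def test_disjoint_set_reported_as_skipped(self, rng):
        scores = np.sort(rng.normal(size=30))[::-1]
        genes = [f"G{i:03d}" for i in range(30)]
        ranked = pd.DataFrame({"gene": genes, "score": scores})
        table = gsea.gsea_preranked(ranked, {"GONE": frozenset(["X", "Y"])}, n_perm=100, seed=4)
        assert table.iloc[0]["flags"] == "skipped"
        assert np.isnan(table.iloc[0].es)

    def test_worked_fixture_planted_set_matches_oracle(self, fixture_cohort):
        from timepheno import dge

        res = dge.differential_expression(
            fixture_cohort.expression, fixture_cohort.true_labels, ("HTI", "NI")
        )
        ranked = dge.rank_genes(res)
        genes = ranked.gene.tolist()
        scores = ranked.score.to_numpy()
        members = set(fixture_cohort.gene_sets["PSET"]) & set(genes)
        es, _, _ = gsea.enrichment_score(genes, scores, members)
        assert es == pytest.approx(gsea_es_oracle(genes, scores, members))
        assert es > 0.9  # the planted set sits at the very top of the ranking


class TestSignificantSets:
    @pytest.mark.parametrize(
        "nes, q, kept",
        [
            (2.54, 1e-5, True),
            (1.6, 0.001, False),
            (-2.0, 0.02, False),
            (-1.9, 0.005, True),
        ],
    )
    def test_filter_rules(self, nes, q, kept):
        table = pd.DataFrame({"set_name": ["S"], "nes": [nes], "fdr_q": [q]})
        out = gsea.significant_sets(table)
        assert (len(out) == 1) is kept
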