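import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphrank import (
    UNSCORED,
    BaitSet,
    EmptyScorableSet,
    MorphRanker,
    ParameterError,
    ausr,
    run_morph,
    score_candidates,
    select_config,
    self_rank,
)

from _oracles import ausr_threshold_sum, brute_force_scores
from conftest import make_config, random_config


def planted_config(rng, dataset_id="ds", clustering_id="c"):
    """Module 0: strongly co-expressed block; module 1: noise."""
    base = rng.standard_normal(12)
    block = np.vstack([base + 0.05 * rng.standard_normal(12) for _ in range(6)])
    noise = rng.standard_normal((6, 12))
    values = np.vstack([block, noise])
    genes = [f"g{i:03d}" for i in range(12)]
    assignment = {g: (0 if i < 6 else 1) for i, g in enumerate(genes)}
    return make_config(values, assignment, dataset_id=dataset_id,
                       clustering_id=clustering_id, gene_ids=genes)


class TestScoreCandidates:
    def test_clone_of_baits_scores_top(self, rng):
        base = rng.standard_normal(10)
        values = np.vstack([base, base, base, rng.standard_normal((3, 10))])
        genes = [f"g{i}" for i in range(6)]
        config = make_config(values, {g: 0 for g in genes}, gene_ids=genes)
        scores = score_candidates(config, BaitSet("t", {"g0", "g1"}))
        top = scores[0]
        assert top.gene_id == "g2"
        assert top.raw_score == pytest.approx(1.0)
        assert top.rank == 1

    def test_degenerate_module_all_z_zero(self, rng):
        base = rng.standard_normal(8)
        # both candidates identical => identical raw scores => SD 0 => z = 0
        values = np.vstack([base, base + rng.standard_normal(8), base, base])
        genes = ["b0", "b1", "c0", "c1"]
        config = make_config(values, {g: 0 for g in genes}, gene_ids=genes)
        scores = score_candidates(config, BaitSet("t", {"b0", "b1"}))
        assert all(s.z == 0.0 for s in scores)
        # z ties broken lexicographically by gene id
        assert [s.gene_id for s in scores] == ["c0", "c1"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            config = random_config(rng, n_genes=20, n_samples=8, n_modules=2)
            baits = set(rng.choice(config.matrix.gene_ids, size=3, replace=False))
            expected = brute_force_scores(
                config.matrix.values, config.matrix.gene_ids,
                config.clustering.assignment, baits,
            )
            got = score_candidates(config, BaitSet("t", baits))
            assert [(c.gene_id, c.module_id, c.rank) for c in got] == [
                (g, m, r) for g, m, _, _, r in expected
            ]
            np.testing.assert_allclose(
                [c.z for c in got], [z for _, _, _, z, _ in expected], atol=1e-9
            )

    def test_no_bait_in_any_module_raises(self, rng):
        config = random_config(rng, n_genes=10, n_samples=6, n_modules=2)
        with pytest.raises(EmptyScorableSet):
            score_candidates(config, BaitSet("t", {"absent1", "absent2"}))

    def test_affine_transform_invariance(self, rng):
        config = random_config(rng, n_genes=25, n_samples=10, n_modules=3)
        baits = BaitSet("t", set(rng.choice(config.matrix.gene_ids, 4, replace=False)))
        ref = score_candidates(config, baits)
        slopes = rng.uniform(0.5, 3.0, size=25)[:, None]
        offsets = rng.uniform(-5, 5, size=25)[:, None]
        warped = make_config(
            config.matrix.values * slopes + offsets,
            config.clustering.assignment,
            gene_ids=config.matrix.gene_ids,
        )
        out = score_candidates(warped, baits)
        assert [c.gene_id for c in out] == [c.gene_id for c in ref]
        np.testing.assert_allclose(
            [c.z for c in out], [c.z for c in ref], atol=1e-9
        )

    def test_sample_permutation_invariance(self, rng):
        config = random_config(rng, n_genes=25, n_samples=10, n_modules=3)
        baits = BaitSet("t", set(rng.choice(config.matrix.gene_ids, 4, replace=False)))
        ref = score_candidates(config, baits)
        perm = rng.permutation(10)
        shuffled = make_config(
            config.matrix.values[:, perm],
            config.clustering.assignment,
            gene_ids=config.matrix.gene_ids,
        )
        out = score_candidates(shuffled, baits)
        assert [(c.gene_id, c.rank) for c in out] == [(c.gene_id, c.rank) for c in ref]
        np.testing.assert_allclose([c.z for c in out], [c.z for c in ref], atol=1e-9)

    def test_ranks_are_a_permutation(self, rng):
        config = random_config(rng, n_genes=30, n_samples=10, n_modules=3)
        baits = BaitSet("t", set(rng.choice(config.matrix.gene_ids, 5, replace=False)))
        scores = score_candidates(config, baits)
        assert sorted(c.rank for c in scores) == list(range(1, len(scores) + 1))
        assert all(np.isfinite(c.z) for c in scores)


class TestSelfRank:
    def test_planted_left_out_ranks_first(self, rng):
        # left-out gene tracks the remaining baits; every other candidate
        # in the module is uncorrelated noise
        base = rng.standard_normal(12)
        values = np.vstack(
            [base, base + 0.01 * rng.standard_normal(12),
             base + 0.01 * rng.standard_normal(12),
             rng.standard_normal((5, 12))]
        )
        genes = [f"g{i:03d}" for i in range(8)]
        config = make_config(values, {g: 0 for g in genes}, gene_ids=genes)
        baits = BaitSet("t", {"g000", "g001", "g002"})
        assert self_rank(config, baits, "g000") == 1

    def test_unclustered_left_out_is_unscored(self, rng):
        config = random_config(rng, n_genes=12, n_samples=6, n_modules=2)
        genes = config.matrix.gene_ids
        assignment = dict(config.clustering.assignment)
        lone = genes[0]
        assignment.pop(lone, None)
        config2 = make_config(
            config.matrix.values, assignment, gene_ids=genes
        )
        baits = BaitSet("t", {lone, genes[1], genes[2]})
        assert self_rank(config2, baits, lone) is UNSCORED

    def test_module_losing_all_baits_is_unscored(self, rng):
        config = planted_config(rng)
        # g006 is the only bait in module 1
        baits = BaitSet("t", {"g000", "g001", "g006"})
        assert self_rank(config, baits, "g006") is UNSCORED

    def test_left_out_must_be_a_bait(self, rng):
        config = planted_config(rng)
        with pytest.raises(ParameterError):
            self_rank(config, BaitSet("t", {"g000", "g001"}), "g005")


class TestAusr:
    def test_perfect_ranking_scores_one(self):
        assert ausr([1, 1, 1], r_max=1000) == 1.0

    def test_all_beyond_ceiling_scores_zero(self):
        assert ausr([1001, 2000, UNSCORED], r_max=1000) == 0.0

    def test_closed_form_example(self):
        assert ausr([1, 501, UNSCORED], r_max=1000) == pytest.approx(0.5)

    def test_closed_form_equals_threshold_sum(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            ranks = [
                None if rng.random() < 0.2 else int(rng.integers(1, 2000))
                for _ in range(n)
            ]
            r_max = int(rng.integers(1, 1500))
            assert ausr(ranks, r_max) == pytest.approx(
                ausr_threshold_sum(ranks, r_max), abs=1e-12
            )

    @given(
        ranks=st.lists(st.integers(min_value=1, max_value=3000), min_size=1, max_size=20),
        idx=st.integers(min_value=0, max_value=19),
        bump=st.integers(min_value=1, max_value=500),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_when_a_rank_worsens(self, ranks, idx, bump):
        idx %= len(ranks)
        worse = list(ranks)
        worse[idx] += bump
        a, b = ausr(ranks, 1000), ausr(worse, 1000)
        assert 0.0 <= b <= a <= 1.0

    def test_bad_r_max(self):
        with pytest.raises(ParameterError):
            ausr([1], r_max=0)


class TestModelSelection:
    def test_planted_config_beats_noise(self, rng):
        good = planted_config(rng, dataset_id="dsA", clustering_id="good")
        noise_vals = rng.standard_normal((12, 12))
        bad = make_config(
            noise_vals, dict(good.clustering.assignment),
            dataset_id="dsA", clustering_id="noise",
            gene_ids=good.matrix.gene_ids,
        )
        baits = BaitSet("t", {"g000", "g001", "g002", "g003"})
        chosen, score, _ = select_config([bad, good], baits)
        assert chosen.config_id == "dsA/good"

    def test_single_config_returned(self, rng):
        config = random_config(rng)
        baits = BaitSet("t", set(rng.choice(config.matrix.gene_ids, 4, replace=False)))
        chosen, _, _ = select_config([config], baits)
        assert chosen is config

    def test_tie_broken_by_input_order(self, rng):
        c1 = planted_config(rng, clustering_id="first")
        c2 = make_config(
            c1.matrix.values, dict(c1.clustering.assignment),
            clustering_id="second", gene_ids=c1.matrix.gene_ids,
        )
        baits = BaitSet("t", {"g000", "g001", "g002"})
        chosen, _, _ = select_config([c1, c2], baits)
        assert chosen.config_id.endswith("first")

    def test_all_unusable_raises(self, rng):
        config = random_config(rng)
        with pytest.raises(EmptyScorableSet):
            select_config([config], BaitSet("t", {"nope1", "nope2"}))


class TestRunMorph:
    def test_held_out_module_members_top_ranked(self, rng):
        config = planted_config(rng)
        baits = BaitSet("t", {"g000", "g001", "g002"})
        result = run_morph([config], baits)
        top3 = [c.gene_id for c in result.candidates[:3]]
        assert set(top3) == {"g003", "g004", "g005"}

    def test_absent_bait_set_raises(self, rng):
        config = random_config(rng)
        with pytest.raises(EmptyScorableSet):
            run_morph([config], BaitSet("t", {"zz1", "zz2"}))

    def test_ausr_internally_consistent(self, rng):
        config = planted_config(rng)
        baits = BaitSet("t", {"g000", "g001", "g002", "g003"})
        result = run_morph([config], baits)
        assert result.ausr == pytest.approx(ausr(result.self_ranks, 1000))
        assert len(result.self_ranks) == len(baits)

    def test_loocv_evaluates_each_bait_once(self, rng):
        config = planted_config(rng)
        baits = BaitSet("t", {"g000", "g001", "g002", "g003", "g004"})
        result = run_morph([config], baits)
        assert set(result.self_ranks) == set(baits.genes)


class TestMorphRankerEstimator:
    def test_fit_exposes_sklearn_surface(self, rng):
        config = planted_config(rng)
        est = MorphRanker(r_max=500)
        assert est.get_params()["r_max"] == 500
        est.set_params(r_max=1000)
        est.fit([config], BaitSet("t", {"g000", "g001", "g002"}))
        assert 0.0 <= est.ausr_ <= 1.0
        assert est.chosen_config_id_ == config.config_id
        table = est.rank()
        assert list(table["rank"]) == list(range(1, len(table) + 1))
        assert est.predict(top_k=2) == list(table["gene_id"][:2])
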