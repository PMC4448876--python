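"""Generator correctness: birth-death expectations, clock moments, Markov
stationarity, history bookkeeping and fixture determinism."""

import filecmp
import json
import os

import numpy as np
import pytest
from scipy import stats

from disparitree.io_formats import (
    MISSING,
    audit_matrix,
    load_strat_ranges,
    read_character_matrix,
    read_dated_tree,
)
from disparitree.synthetic import (
    FIXTURE_FILES,
    SimConfig,
    generate_fixture,
    simulate_branch_rates,
    simulate_characters,
    simulate_dataset,
    simulate_fbd_tree,
)


class TestFbdTree:
    def test_pure_birth_expected_tip_count(self):
        lam, T = 0.1, 38.0
        counts = [
            len(
                simulate_fbd_tree(
                    SimConfig(
                        birth_rate=lam, death_rate=0.0, fossil_rate=0.0,
                        origin_age=T, min_tips=2, max_tips=None, seed=s,
                    )
                )[0].tips
            )
            for s in range(300)
        ]
        # E[N | N>=2] for a conditioned Yule process barely differs from e^(lam T)
        assert np.mean(counts) == pytest.approx(np.exp(lam * T), rel=0.15)

    def test_same_seed_reproduces_tree(self):
        cfg = SimConfig(seed=17, min_tips=10, max_tips=40)
        t1, r1 = simulate_fbd_tree(cfg)
        t2, r2 = simulate_fbd_tree(cfg)
        assert [n.age for n in t1.nodes] == [n.age for n in t2.nodes]
        assert r1 == r2

    def test_age_invariants(self):
        for seed in range(5):
            cfg = SimConfig(seed=seed, min_tips=10, max_tips=60)
            tree, records = simulate_fbd_tree(cfg)
            for nd in tree.branches():
                assert 0 <= nd.age <= cfg.origin_age
                assert nd.parent.age >= nd.age
            for rec in records:
                tip = tree.node(rec.taxon)
                assert rec.oldest_age >= tip.age >= rec.youngest_age - 1e-9 or tip.age == 0
                if rec.younger_material_age is not None:
                    assert rec.younger_material_age <= rec.youngest_age

    def test_impossible_conditioning_raises(self):
        cfg = SimConfig(
            birth_rate=0.01, death_rate=0.5, fossil_rate=0.0,
            origin_age=5.0, min_tips=50, seed=0,
        )
        with pytest.raises(RuntimeError, match="1000"):
            simulate_fbd_tree(cfg)


class TestBranchRates:
    def test_strict_clock_limit(self, three_taxon_tree):
        mult = simulate_branch_rates(three_taxon_tree, 0.0, seed=1)
        assert set(mult.values()) == {1.0}

    def test_gamma_moments(self):
        rng = np.random.default_rng(3)
        draws = rng.gamma(1 / 0.5, 0.5, size=10_000)
        # documented parametrization: mean 1, variance nu
        se = np.sqrt(0.5 / draws.size)
        tree_draws = []
        from disparitree.synthetic import SimConfig, simulate_fbd_tree

        tree, _ = simulate_fbd_tree(SimConfig(seed=2, min_tips=60, max_tips=130))
        for rep in range(120):
            mult = simulate_branch_rates(tree, 0.5, seed=rep)
            tree_draws.extend(mult.values())
        tree_draws = np.asarray(tree_draws)
        assert abs(tree_draws.mean() - 1) < 3 * np.sqrt(0.5 / tree_draws.size)
        assert tree_draws.var() == pytest.approx(0.5, rel=0.15)

    def test_same_seed_identical(self, three_taxon_tree):
        a = simulate_branch_rates(three_taxon_tree, 0.3, seed=9)
        b = simulate_branch_rates(three_taxon_tree, 0.3, seed=9)
        assert a == b


class TestCharacters:
    def test_zero_clock_freezes_root_state(self, three_taxon_tree):
        cfg = SimConfig(
            seed=4, n_characters=20, clock_mean=0.0, clock_sd=0.0, missing_fraction=0.0
        )
        mult = simulate_branch_rates(three_taxon_tree, 0.0, seed=4)
        matrix, truth = simulate_characters(three_taxon_tree, mult, cfg)
        for j in range(20):
            col = {row[j] for row in matrix.rows}
            assert col == {truth.root_states[j]}
        assert audit_matrix(matrix).invariant_character_ids == matrix.characters

    def test_high_rate_unordered_reaches_uniform_stationary(self, three_taxon_tree):
        cfg = SimConfig(
            seed=5, n_characters=10_000, clock_mean=50.0, clock_sd=0.0,
            missing_fraction=0.0, ordered_fraction=0.0, n_states_unordered=4,
            epoch_multipliers=[],
        )
        mult = {nd.id: 1.0 for nd in three_taxon_tree.branches()}
        matrix, _ = simulate_characters(three_taxon_tree, mult, cfg)
        states = np.array([row for row in matrix.rows])
        counts = np.bincount(states.ravel(), minlength=4)
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4  # uniform within chi-square tolerance

    def test_change_count_matches_poisson_expectation(self):
        tree = read_dated_tree(data="((A:5,B:5):5,C:10);")
        cfg = SimConfig(
            seed=6, n_characters=400, clock_mean=0.05, clock_sd=0.0,
            missing_fraction=0.0, ordered_fraction=0.0, gamma_shape=1.0,
            epoch_multipliers=[],
        )
        mult = {nd.id: 1.0 for nd in tree.branches()}
        matrix, truth = simulate_characters(tree, mult, cfg)
        total_changes = sum(len(h) for h in truth.histories)
        expected = (
            cfg.clock_mean * tree.total_branch_length() * np.sum(truth.character_factors)
        )
        assert abs(total_changes - expected) < 4 * np.sqrt(expected)

    def test_history_replay_reproduces_tip_states(self, small_sim):
        _, tree, _, matrix, truth = small_sim
        masked = set(map(tuple, truth.masked_cells))
        for j, history in enumerate(truth.histories):
            state = {tree.root.id: truth.root_states[j]}
            changes_by_branch: dict[str, list] = {}
            for bid, age, s_from, s_to in history:
                changes_by_branch.setdefault(bid, []).append((age, s_from, s_to))
            for nd in tree.nodes:
                if nd.parent is None:
                    continue
                s = state[nd.parent.id]
                for age, s_from, s_to in sorted(
                    changes_by_branch.get(nd.id, []), key=lambda x: -x[0]
                ):
                    assert s_from == s
                    s = s_to
                state[nd.id] = s
                if nd.is_tip and (nd.label, j) not in masked:
                    assert matrix.cell(nd.label, j) == s

    def test_ordered_characters_step_by_one(self, small_sim):
        _, _, _, _, truth = small_sim
        ordered = set(truth.ordered_indices)
        for j in ordered:
            for _, _, s_from, s_to in truth.histories[j]:
                assert abs(s_from - s_to) == 1

    def test_missing_fraction_hits_target(self):
        cfg = SimConfig(seed=7, min_tips=60, max_tips=130)
        _, _, matrix, _ = simulate_dataset(cfg)
        frac = audit_matrix(matrix).missing_fraction
        assert frac == pytest.approx(0.43, abs=0.02)

    def test_taxon_biased_mode_spreads_unevenly(self):
        cfg = SimConfig(seed=8, min_tips=60, max_tips=130, taxon_biased_missing=True)
        _, _, matrix, _ = simulate_dataset(cfg)
        per_taxon = np.array(
            [sum(c is MISSING for c in row) / matrix.n_characters for row in matrix.rows]
        )
        uniform_sd = np.sqrt(0.43 * 0.57 / matrix.n_characters)
        assert per_taxon.std() > 3 * uniform_sd  # much lumpier than uniform deletion


class TestFixture:
    def test_fixture_files_validate_and_reproduce(self, tmp_path):
        cfg = SimConfig(seed=9, min_tips=20, max_tips=40, n_characters=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths = generate_fixture(cfg, str(d1))
        generate_fixture(cfg, str(d2))
        assert [os.path.basename(p) for p in paths] == list(FIXTURE_FILES)
        match, mismatch, errors = filecmp.cmpfiles(
            d1, d2, FIXTURE_FILES, shallow=False
        )
        assert mismatch == [] and errors == []
        tree = read_dated_tree(str(d1 / "tree.nwk"))
        matrix = read_character_matrix(str(d1 / "matrix.nex"))
        records = load_strat_ranges(str(d1 / "strat.csv"), tree=tree)
        assert sorted(tree.tip_labels) == sorted(matrix.taxa)
        assert len(records) == len(tree.tips)
        truth = json.loads((d1 / "truth.json").read_text())
        assert truth["clock_rate"] > 0

    def test_existing_dir_requires_force(self, tmp_path):
        cfg = SimConfig(seed=9, min_tips=10, max_tips=40, n_characters=5)
        out = tmp_path / "fix"
        generate_fixture(cfg, str(out))
        with pytest.raises(FileExistsError):
            generate_fixture(cfg, str(out))
        generate_fixture(cfg, str(out), force=True)
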