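"""Tree generation, parameter draws, sequence simulation, block archives."""

import json

import numpy as np
import pytest
import scipy.stats

import nemus as nm
from nemus.simulator import BALANCE_CONDITIONS, FITNESS_DRAW_HALF_WIDTH

from oracles import yule_colless_expectation


def colless_index(tree: nm.Phylogeny) -> int:
    sizes = np.zeros(tree.n_nodes, dtype=int)
    total = 0
    for v in tree.postorder:
        if tree.is_leaf(v):
            sizes[v] = 1
        else:
            l, r = tree.children[v]
            sizes[v] = sizes[l] + sizes[r]
            total += abs(int(sizes[l]) - int(sizes[r]))
    return total


class TestSimulateTree:
    def test_shape_invariants(self):
        tree = nm.simulate_tree(10, 0.5, 0.0, seed=0)
        assert tree.n_leaves == 10
        assert len(tree.branches) == 18
        assert tree.is_ultrametric(tol=1e-9)
        assert len(tree.children[tree.root]) == 2

    def test_reproducible(self):
        t1 = nm.write_newick(nm.simulate_tree(8, 1.0, 0.3, seed=99))
        t2 = nm.write_newick(nm.simulate_tree(8, 1.0, 0.3, seed=99))
        assert t1 == t2

    def test_branch_lengths_scale_with_birth_rate(self):
        slow = [nm.simulate_tree(8, 0.5, 0.0, seed=s).max_depth() for s in range(40)]
        fast = [nm.simulate_tree(8, 5.0, 0.0, seed=s).max_depth() for s in range(40)]
        assert np.median(slow) > 5 * np.median(fast)

    def test_yule_colless_mean_matches_recursion(self):
        expect = yule_colless_expectation(8)
        vals = [
            colless_index(nm.simulate_tree(8, 1.0, 0.0, seed=s)) for s in range(1500)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 4 * se

    def test_balance_knob_orders_colless(self):
        def med(balance):
            return np.median(
                [
                    colless_index(nm.simulate_tree(16, 1.0, balance, seed=s))
                    for s in range(150)
                ]
            )

        bal = med(BALANCE_CONDITIONS["BAL"])
        bdp = med(BALANCE_CONDITIONS["BDP"])
        imb = med(BALANCE_CONDITIONS["IMB"])
        assert bal < bdp < imb

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            nm.simulate_tree(2, 1.0)
        with pytest.raises(ValueError):
            nm.simulate_tree(5, 0.0)


class TestDraws:
    def test_fitness_profile_bounds_and_anchor(self):
        for seed in range(50):
            p = nm.draw_fitness_profile(seed)
            assert p.f[-1] == 1.0
            assert np.all(np.abs(p.free - 1.0) <= FITNESS_DRAW_HALF_WIDTH)

    def test_fitness_mean_is_one(self):
        rng = np.random.default_rng(0)
        draws = np.concatenate([nm.draw_fitness_profile(rng).free for _ in range(2000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_root_frequencies_simplex(self):
        rng = np.random.default_rng(1)
        draws = np.stack([nm.draw_root_frequencies(rng) for _ in range(3000)])
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        # symmetric Dirichlet: per-coordinate mean 1/61
        se = draws.std(axis=0).max() / np.sqrt(len(draws))
        assert np.abs(draws.mean(axis=0) - 1 / 61).max() < 5 * se

    def test_high_concentration_near_uniform(self):
        draw = nm.draw_root_frequencies(0, concentration=1e6)
        assert np.abs(draw - 1 / 61).max() < 1e-3


class TestPlaceShift:
    def test_two_stage_marginals_on_fixture(self, five_leaf_tree):
        # levels: 1: {E, AB|CD-ancestor}, 2: {AB-node, CD-node}, 3: {A,B,C,D}
        tree = five_leaf_tree
        rng = np.random.default_rng(0)
        draws = np.array([nm.place_shift(tree, rng) for _ in range(30000)])
        levels = {}
        for v in range(tree.n_nodes):
            if v != tree.root:
                levels.setdefault(tree.node_level(v), []).append(v)
        n_levels = len(levels)
        for lvl, nodes in levels.items():
            for v in nodes:
                p_expected = (1 / n_levels) * (1 / len(nodes))
                p_obs = np.mean(draws == v)
                se = np.sqrt(p_expected * (1 - p_expected) / len(draws))
                assert abs(p_obs - p_expected) < 5 * se

    def test_exclusion_respected(self, five_leaf_tree):
        rng = np.random.default_rng(3)
        excl = {five_leaf_tree.basal_branches[0]}
        for _ in range(200):
            assert nm.place_shift(five_leaf_tree, rng, exclude=excl) not in excl


class TestSimulateAlignment:
    def test_zero_length_tree_copies_root(self):
        tree = nm.read_newick("((A:0,B:0):0,C:0);")
        cfg = nm.ShiftConfiguration(nm.draw_fitness_profile(1))
        aln = nm.simulate_alignment(tree, cfg, 40, seed=0)
        assert np.all(aln.codes == aln.codes[0])

    def test_deterministic_under_seed(self):
        tree = nm.simulate_tree(5, 1.0, 0.0, seed=1)
        cfg = nm.ShiftConfiguration(nm.draw_fitness_profile(1))
        a1 = nm.simulate_alignment(tree, cfg, 30, seed=7)
        a2 = nm.simulate_alignment(tree, cfg, 30, seed=7)
        assert np.array_equal(a1.codes, a2.codes)

    def test_neutral_long_branch_uniform(self):
        tree = nm.read_newick("(A:400,B:400);")
        cfg = nm.ShiftConfiguration(nm.FitnessProfile.neutral())
        aln = nm.simulate_alignment(tree, cfg, 1500, seed=5)
        counts = np.bincount(aln.codes.ravel(), minlength=61)
        res = scipy.stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_ctmc_and_matrix_modes_agree_in_distribution(self):
        # same long-branch model, two simulation algorithms: tip codon
        # frequency tables should be statistically indistinguishable
        tree = nm.read_newick("(A:30,B:30);")
        prof = nm.draw_fitness_profile(11, half_width=1e-5)
        cfg = nm.ShiftConfiguration(prof)
        a1 = nm.simulate_alignment(tree, cfg, 900, seed=1, method="ctmc")
        a2 = nm.simulate_alignment(tree, cfg, 900, seed=2, method="matrix")
        c1 = np.bincount(a1.codes.ravel(), minlength=61)
        c2 = np.bincount(a2.codes.ravel(), minlength=61)
        keep = (c1 + c2) >= 10
        table = np.stack([c1[keep], c2[keep]])
        res = scipy.stats.chi2_contingency(table)
        assert res.pvalue > 0.01

    def test_stationary_no_shift_process(self):
        # equilibrium root + no shifts: tip frequencies match the model's
        # stationary distribution on a long star-like tree
        tree = nm.read_newick("(A:25,B:25);")
        prof = nm.draw_fitness_profile(3, half_width=1e-5)
        cfg = nm.ShiftConfiguration(prof)
        aln = nm.simulate_alignment(tree, cfg, 1200, seed=3)
        pi = nm.stationary_distribution(nm.scaled_generator(nm.MutSelModel(fitness=prof)))
        counts = np.bincount(aln.codes.ravel(), minlength=61)
        n = counts.sum()
        keep = pi * n >= 5
        rest = (~keep).sum()
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(pi[keep] * n, pi[~keep].sum() * n)
        res = scipy.stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert res.pvalue > 0.01


class TestRunBlock:
    def test_archive_contents_and_reproducibility(self, tmp_path):
        spec = nm.SimulationSpec(
            series="ASHIFT", taxa=4, codons=30, n_shifts=1, replicates=3, seed=12
        )
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        nm.run_block(spec, d1)
        nm.run_block(spec, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert "manifest.tsv" in files
        assert sum(f.endswith(".fasta") for f in files) == 3
        manifest = (d1 / "manifest.tsv").read_text().strip().splitlines()
        assert len(manifest) == 4  # header + 3 replicates
        for name in files:
            assert (d1 / name).read_text() == (d2 / name).read_text()

    def test_truth_json_loads_back(self, tmp_path):
        spec = nm.SimulationSpec(
            series="RFREQ", taxa=4, codons=30, replicates=2, seed=5, birth_rate=2.0
        )
        nm.run_block(spec, tmp_path)
        truth = json.loads((tmp_path / "rep_000.truth.json").read_text())
        cfg = nm.ShiftConfiguration.from_json(json.dumps(truth["configuration"]))
        assert cfg.free_root
        aln = nm.read_codon_fasta((tmp_path / "rep_000.fasta").read_text())
        tree = nm.read_newick((tmp_path / "rep_000.nwk").read_text())
        assert set(aln.taxa) == set(tree.leaf_labels.values())
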