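import numpy as np
import pandas as pd
import pytest

from silkshift.phyloexpr.asr import classify_node_state
from silkshift.phyloexpr.trees import DUPLICATION, SPECIATION, read_gene_tree
from silkshift.synthetic_data import (
    NON_SILK,
    SILK_GLANDS,
    ShiftSpec,
    SimulationError,
    StudyDesign,
    default_design,
    generate_study,
    simulate_counts,
    simulate_expression,
    simulate_gene_tree,
    write_bundle,
)

SPECIES_TREE = read_gene_tree("((Lg:0.5,Lh:0.5):0.5,Sg:1.0);")


class TestStudyDesign:
    def test_default_design_valid(self):
        design = default_design()
        assert set(design.species) == {"Lg", "Lh", "Sg"}
        assert design.replicates_per_tissue["Py"] == 1
        assert len(design.tissues) == 10

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(silk_glands=["MA"], non_silk=["MA", "ceph"])

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(replicates_per_tissue={"MA": 0})


class TestSimulateGeneTree:
    def test_zero_rates_match_species_tree(self):
        tree = simulate_gene_tree(SPECIES_TREE, 0.0, 0.0, seed=0)
        assert sorted(t.species for t in tree.tips()) == ["Lg", "Lh", "Sg"]
        assert all(nd.event == SPECIATION for nd in tree.internal_nodes())
        # branch lengths preserved
        sg = next(t for t in tree.tips() if t.species == "Sg")
        assert sg.length == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        from silkshift.phyloexpr.trees import write_gene_tree

        t1 = simulate_gene_tree(SPECIES_TREE, 0.5, 0.1, seed=42)
        t2 = simulate_gene_tree(SPECIES_TREE, 0.5, 0.1, seed=42)
        assert write_gene_tree(t1) == write_gene_tree(t2)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_tree(SPECIES_TREE, -1.0, 0.0)

    def test_high_loss_raises_after_retries(self):
        with pytest.raises(SimulationError):
            simulate_gene_tree(SPECIES_TREE, 0.0, 50.0, seed=0, max_retries=5)

    def test_duplication_fraction_matches_independent_simulation(self):
        """Monte-Carlo oracle: an independent forward simulation of the
        same birth-death process, comparing expected duplication events
        per surviving tree."""
        birth, loss = 0.4, 0.0

        def oracle_dup_count(rng):
            # independent implementation: event-driven walk over the
            # species tree, counting duplications; no losses (loss=0 makes
            # survival certain and the census exact)
            n_dup = 0
            stack = [(SPECIES_TREE.root, 1)]  # (species node, n lineages)
            while stack:
                snode, n_lin = stack.pop()
                for ch in snode.children:
                    # each lineage entering the branch independently
                    # accumulates duplications: pure birth -> lineage count
                    # at branch end is Yule-distributed
                    total = 0
                    for _ in range(n_lin):
                        k = 1
                        t = 0.0
                        while True:
                            t += rng.exponential(1.0 / (birth * k))
                            if t >= ch.length:
                                break
                            k += 1
                        total += k
                    n_dup += total - n_lin
                    if ch.children:
                        stack.append((ch, total))
            return n_dup

        rng = np.random.default_rng(7)
        n_rep = 3000
        oracle = np.array([oracle_dup_count(rng) for _ in range(n_rep)])

        mine = []
        rng2 = np.random.default_rng(8)
        for _ in range(n_rep):
            tree = simulate_gene_tree(SPECIES_TREE, birth, loss, seed=rng2)
            mine.append(sum(nd.event == DUPLICATION for nd in tree.internal_nodes()))
        mine = np.array(mine)

        se = np.sqrt(oracle.var() / n_rep + mine.var() / n_rep)
        assert abs(mine.mean() - oracle.mean()) < 3 * se


class TestSimulateExpression:
    def _tree(self):
        return simulate_gene_tree(SPECIES_TREE, 0.0, 0.0, seed=0)

    def _root_profile(self, value=20.0):
        return pd.Series(value, index=SILK_GLANDS + NON_SILK, dtype=float)

    def test_zero_variance_tips_equal_root(self):
        tips, truth = simulate_expression(self._tree(), self._root_profile(), 0.0, seed=1)
        assert np.allclose(tips.to_numpy(), 20.0)

    def test_identity_multiplier_no_effect(self):
        tree = self._tree()
        tip_label = tree.tips()[0].label
        _, truth_shift = simulate_expression(
            tree, self._root_profile(), 0.1,
            [ShiftSpec(node=tip_label, tissues=["MA"], multiplier=1.0)], seed=2,
        )
        _, truth_plain = simulate_expression(tree, self._root_profile(), 0.1, seed=2)
        assert truth_shift.node_states == truth_plain.node_states

    def test_bm_variance_closed_form(self):
        # star-like check: evolve many single-branch replicates
        sigma2 = 0.2
        rng = np.random.default_rng(3)
        tree = read_gene_tree("('A:t1':1.0,'B:t1':1.0);")
        logs = []
        root = pd.Series(50.0, index=["MA", "ceph"])
        for _ in range(500):
            tips, _ = simulate_expression(
                tree, root, sigma2, seed=rng, silk_glands=["MA"], non_silk=["ceph"]
            )
            logs.extend(np.log1p(tips["MA"].to_numpy()))
        logs = np.array(logs)
        var = logs.var(ddof=1)
        n = len(logs)
        se = sigma2 * np.sqrt(2.0 / (n - 1))  # SE of a normal sample variance
        assert abs(var - sigma2) < 3 * se

    def test_shift_multiplies_target(self):
        tree = self._tree()
        tip = tree.tips()[0]
        tips, truth = simulate_expression(
            tree, self._root_profile(10.0), 0.0,
            [ShiftSpec(node=tip.label, tissues=["MA"], multiplier=8.0)], seed=4,
        )
        assert tips.loc[tip.label, "MA"] == pytest.approx(80.0)
        assert tips.loc[tip.label, "MI"] == pytest.approx(10.0)

    def test_unknown_shift_branch_rejected(self):
        with pytest.raises(KeyError):
            simulate_expression(
                self._tree(), self._root_profile(), 0.1,
                [ShiftSpec(node="nope", tissues=["MA"], multiplier=2.0)],
            )

    def test_truth_states_consistent_with_classifier(self):
        tree = self._tree()
        tips, truth = simulate_expression(
            tree, self._root_profile(5.0), 0.3,
            [ShiftSpec(node=tree.tips()[1].label, tissues=["MA"], multiplier=30.0)],
            seed=5,
        )
        for label, prof in truth.node_profiles.items():
            assert truth.node_states[label] == classify_node_state(
                prof, SILK_GLANDS, NON_SILK
            )


class TestSimulateCounts:
    def _profiles(self, fpkm, n=1):
        design = default_design()
        return pd.DataFrame(
            fpkm, index=[f"t{i}" for i in range(n)], columns=design.tissues
        )

    def test_expected_count_formula(self):
        design = default_design()
        design.library_size = 10_000_000
        prof = self._profiles(5.0)
        lens = pd.Series(2000.0, index=prof.index)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(3000):
            cm = simulate_counts(prof, design, "Lg", lens, 0.0, rng)
            draws.append(cm.counts.iloc[0, 0])
        mean = np.mean(draws)
        # mu = 5 * 2 * 10 = 100; Poisson SE = sqrt(100/3000)
        assert abs(mean - 100.0) < 3 * np.sqrt(100.0 / 3000)

    def test_poisson_limit_variance(self):
        design = default_design()
        prof = self._profiles(50.0, n=1)
        lens = pd.Series(10000.0, index=prof.index)
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [simulate_counts(prof, design, "Lg", lens, 0.0, rng).counts.to_numpy().ravel()
             for _ in range(500)]
        )
        ratio = vals.var(ddof=1) / vals.mean()
        se = np.sqrt(2.0 / (len(vals) - 1))
        assert abs(ratio - 1.0) < 3 * se

    def test_nb_cv2_moment(self):
        phi, mu_target = 1.5, 100.0
        design = StudyDesign(replicates_per_tissue={})
        design.library_size = 1_000_000
        prof = self._profiles(mu_target, n=500)  # FPKM 100 @ len 1000 -> mu 100
        lens = pd.Series(1000.0, index=prof.index)
        cm = simulate_counts(prof, design, "Lg", lens, phi, np.random.default_rng(2))
        vals = cm.counts.to_numpy().ravel().astype(float)
        n = len(vals)
        cv2 = vals.var(ddof=1) / vals.mean() ** 2
        expected = phi + 1.0 / mu_target
        # rough SE of CV^2 by bootstrap-free delta approximation
        boot = np.random.default_rng(3)
        reps = [
            (lambda v: v.var(ddof=1) / v.mean() ** 2)(
                vals[boot.integers(0, n, size=n)]
            )
            for _ in range(200)
        ]
        se = np.std(reps)
        assert abs(cv2 - expected) < 3 * se

    def test_zero_length_rejected(self):
        design = default_design()
        prof = self._profiles(1.0)
        lens = pd.Series(0.0, index=prof.index)
        with pytest.raises(ValueError):
            simulate_counts(prof, design, "Lg", lens, 0.1, 0)


class TestGenerateStudy:
    def test_round_trip_through_readers(self, tmp_path):
        from silkshift import io as sio

        bundle = generate_study({"n_families": 6, "n_shift_families": 2}, seed=0)
        paths = write_bundle(bundle, tmp_path)
        cm = sio.read_count_matrix(
            paths["counts"], paths["effective_lengths"], paths["samples"]
        )
        fmap = sio.read_family_map(paths["families"])
        trees = sio.read_trees(paths["trees"])
        truth = sio.read_json(paths["truth"])
        assert len(trees) == 6
        assert len(fmap) == 6
        assert set(cm.sample_sheet["species"]) == {"Lg", "Lh", "Sg"}
        assert "_oest_truth" in truth

    def test_same_seed_byte_identical(self, tmp_path):
        b1 = generate_study({"n_families": 5, "n_shift_families": 3}, seed=11)
        b2 = generate_study({"n_families": 5, "n_shift_families": 3}, seed=11)
        p1 = write_bundle(b1, tmp_path / "a")
        p2 = write_bundle(b2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_zero_planted_shifts_zero_truth_oests(self):
        bundle = generate_study(
            {
                "n_families": 5,
                "n_shift_families": 0,
                "bm_sigma2": 0.0,
            },
            seed=3,
        )
        assert all(len(v) == 0 for v in bundle.oest_truth.values())

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            generate_study({"n_families": 2, "n_shift_families": 5}, seed=0)

    def test_unknown_config_key_rejected(self, tmp_path):
        from silkshift.synthetic_data import load_config

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError):
            load_config(cfg)

    def test_truth_self_consistency(self):
        bundle = generate_study({"n_families": 8, "n_shift_families": 4}, seed=5)
        design = bundle.design
        for fam, truth in bundle.truths.items():
            for label, prof in truth.node_profiles.items():
                assert truth.node_states[label] == classify_node_state(
                    prof, design.silk_glands, design.non_silk
                )
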