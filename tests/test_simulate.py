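from collections import Counter

import numpy as np
import pytest

from tfatlas.reconcile import reconcile_og
from tfatlas.simulate import (
    SimulationConfig,
    assign_branch_lengths,
    perturb_ils,
    simulate_gene_family,
    simulate_og_batch,
    simulate_presence_matrix,
    simulate_species_timetree,
    simulate_tg_rates,
    simulate_traits,
)
from tfatlas.treeio import OrthologGroup


class TestSpeciesTree:
    def test_shape_and_root_age(self):
        t = simulate_species_timetree(3, 170.0, 0)
        assert t.n_leaves == 3
        assert sum(1 for n in t.postorder() if not n.is_leaf) == 2
        assert t.root_age == pytest.approx(170.0)

    def test_determinism(self):
        a = simulate_species_timetree(10, 50.0, 42).to_newick()
        b = simulate_species_timetree(10, 50.0, 42).to_newick()
        assert a == b

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_timetree(2, 10.0, 0)

    def test_internal_age_order_statistics(self):
        """Mean sorted non-root split ages match the uniform order-statistic
        expectation A*(m+1-k)/(m+1), m = n-2 (k-th largest)."""
        n, A, reps = 8, 100.0, 1000
        m = n - 2
        rng = np.random.default_rng(7)
        sums = np.zeros(m)
        for _ in range(reps):
            t = simulate_species_timetree(n, A, rng)
            ages = sorted(
                (x.age for x in t.postorder() if not x.is_leaf and x.parent is not None),
                reverse=True,
            )
            sums += np.array(ages)
        means = sums / reps
        expected = A * (m + 1 - np.arange(1, m + 1)) / (m + 1)
        se = A / np.sqrt(12 * reps)  # generous per-order-stat MC error
        assert np.all(np.abs(means - expected) < 4 * se + 1.5)


class TestGeneFamily:
    def test_zero_rates_give_congruent_tree(self, stree16):
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        g, truth = simulate_gene_family(stree16, cfg, seed=0)
        assert truth.events == []
        assert g.copy_counts() == {sp: 1 for sp in stree16.leaf_labels}

        # topology congruent: identical sets of species clades
        def clades(root, strip):
            out = set()
            for n in root.postorder():
                if not n.is_leaf:
                    out.add(frozenset(
                        l.label.rsplit("_", 1)[0] if strip else l.label
                        for l in n.leaves()))
            return out

        assert clades(g.root, True) == clades(stree16.root, False)

    def test_truth_totals_equal_event_tallies(self, stree16):
        cfg = SimulationConfig(dup_rate=0.005, loss_rate=0.005)
        rng = np.random.default_rng(3)
        for i in range(20):
            _, truth = simulate_gene_family(stree16, cfg, rng)
            totals = truth.per_branch_totals()
            assert sum(v["gain"] for v in totals.values()) == truth.n_gains
            assert sum(v["loss"] for v in totals.values()) == truth.n_losses

    def test_expected_duplication_count_matches_recursion(self, stree16):
        """Monte-Carlo mean duplication count vs the branching-process
        recursion E[dups] = sum_b lambda * dur(b) * E[lineages entering b]
        (with within-branch growth exp((lam-mu)t) integrated)."""
        lam, mu = 0.004, 0.002
        cfg = SimulationConfig(dup_rate=lam, loss_rate=mu)
        durs = stree16.branch_durations()

        # E[lineage-My on branch] = n_enter * (exp((lam-mu)d)-1)/(lam-mu)
        expected = {}
        n_enter = {}

        def walk(node, n_in):
            for child in node.children:
                d = durs[child.label]
                n_enter[child.label] = n_in
                growth = (np.exp((lam - mu) * d) - 1.0) / (lam - mu)
                expected[child.label] = lam * n_in * growth
                walk(child, n_in * np.exp((lam - mu) * d))

        walk(stree16.root, 1.0)
        exp_total = sum(expected.values())

        rng = np.random.default_rng(11)
        reps = 400
        counts = [simulate_gene_family(stree16, cfg, rng)[1].n_gains for _ in range(reps)]
        mc = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mc - exp_total) < 4 * se + 0.05

    def test_high_terminal_loss_removes_species(self, stree16):
        leaf = "S1"
        dur = stree16.branch_durations()[leaf]
        mu = 0.2  # survival over the terminal branch ~ exp(-mu*dur) << 1
        cfg = SimulationConfig(loss_rate=0.0, dup_rate=0.0,
                               loss_rate_overrides={leaf: mu})
        rng = np.random.default_rng(5)
        present = sum(
            leaf in simulate_gene_family(stree16, cfg, rng)[0].copy_counts()
            for _ in range(300)
        )
        p_survive = np.exp(-mu * dur)
        se = np.sqrt(p_survive * (1 - p_survive) / 300) + 1e-3
        assert abs(present / 300 - p_survive) < 4 * se

    def test_determinism(self, stree16):
        cfg = SimulationConfig(dup_rate=0.004, loss_rate=0.004)
        g1, t1 = simulate_gene_family(stree16, cfg, seed=9)
        g2, t2 = simulate_gene_family(stree16, cfg, seed=9)
        assert g1.to_newick() == g2.to_newick()
        assert t1.events == t2.events


class TestBranchLengths:
    def test_strict_clock(self, stree16):
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        g, _ = simulate_gene_family(stree16, cfg, seed=0)
        g = assign_branch_lengths(g, subst_rate=0.002, sigma_r=0.0, seed=0)
        # all root-to-tip paths equal r * A
        for leaf in g.leaves:
            total, node = 0.0, leaf
            while node.parent is not None:
                total += node.length
                node = node.parent
            assert total == pytest.approx(0.002 * 170.0, rel=1e-9)

    def test_single_branch_value(self, stree16):
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        g, _ = simulate_gene_family(stree16, cfg, seed=0)
        g2 = assign_branch_lengths(g, subst_rate=0.002, sigma_r=0.0, seed=0)
        times = {n.label: n.length for n in g.postorder() if n.is_leaf}
        lens = {n.label: n.length for n in g2.postorder() if n.is_leaf}
        for label in times:
            assert lens[label] == pytest.approx(0.002 * times[label])

    def test_lognormal_mean(self):
        sigma = 0.5
        rng = np.random.default_rng(2)
        draws = rng.lognormal(0.0, sigma, 10_000)
        # identity used by assign_branch_lengths: E[eps] = exp(sigma^2/2)
        assert np.mean(draws) == pytest.approx(np.exp(sigma**2 / 2), rel=0.05)

    def test_negative_rate_rejected(self, stree16):
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        g, _ = simulate_gene_family(stree16, cfg, seed=0)
        with pytest.raises(ValueError):
            assign_branch_lengths(g, -1.0, 0.0, 0)


class TestIlsPerturbation:
    def _clock_tree(self, stree16):
        cfg = SimulationConfig(dup_rate=0.0, loss_rate=0.0)
        g, _ = simulate_gene_family(stree16, cfg, seed=0)
        return assign_branch_lengths(g, 0.002, 0.0, seed=0)

    def test_noop_when_disabled(self, stree16):
        g = self._clock_tree(stree16)
        assert perturb_ils(g, 0.02, 0.0, 1).to_newick() == g.to_newick()
        assert perturb_ils(g, 0.0, 1.0, 1).to_newick() == g.to_newick()

    def test_nni_alternatives_equally_likely(self, stree3):
        """With one short edge and p_ils=1 the two NNI outcomes each occur
        ~half the time, and the original topology never survives."""
        from tfatlas.treeio import GeneTree

        # only the internal edge is short
        g = GeneTree.from_newick("((A_1:0.5,B_1:0.5):0.001,C_1:0.5);")
        seen = Counter()
        for seed in range(400):
            nwk = perturb_ils(g, ils_length=0.01, p_ils=1.0, seed=seed).to_newick()
            cherry = nwk[nwk.rindex("(") + 1 : nwk.index(")")]
            seen[frozenset(p.split(":")[0] for p in cherry.split(","))] += 1
        ab = seen[frozenset({"A_1", "B_1"})]
        ac = seen[frozenset({"A_1", "C_1"})]
        bc = seen[frozenset({"B_1", "C_1"})]
        assert ab == 0  # original cherry always broken at p_ils = 1
        assert abs(ac - bc) < 4 * np.sqrt(400 * 0.25)

    def test_only_short_edges_touched(self, stree16):
        g = self._clock_tree(stree16)
        out = perturb_ils(g, ils_length=1e-9, p_ils=1.0, seed=3)
        assert out.to_newick() == g.to_newick()


class TestTraits:
    def test_null_prevalence(self, rng):
        pm = simulate_presence_matrix(2000, 3, rng)
        y, _ = simulate_traits(pm, [], beta=0.0, beta0=-1.0, seed=rng)
        expected = 1 / (1 + np.exp(1.0))
        assert abs(y.mean() - expected) < 4 * np.sqrt(expected * (1 - expected) / 2000)

    def test_saturated_beta_copies_presence(self, rng):
        pm = simulate_presence_matrix(300, 2, rng)
        col = pm.columns[0]
        y, _ = simulate_traits(pm, [col], beta=20.0, beta0=-10.0, seed=rng)
        assert (y == pm[col]).all()

    def test_probabilities_match_logistic_formula(self, rng):
        pm = simulate_presence_matrix(50, 4, rng)
        cols = list(pm.columns[:2])
        _, probs = simulate_traits(pm, cols, beta=[2.0, -2.0], beta0=0.5, seed=rng)
        eta = 0.5 + 2.0 * pm[cols[0]] - 2.0 * pm[cols[1]]
        assert np.allclose(probs, 1 / (1 + np.exp(-eta)))

    def test_constant_causal_column_warns(self, rng):
        pm = simulate_presence_matrix(20, 2, rng)
        pm[pm.columns[0]] = 1
        with pytest.warns(UserWarning, match="constant"):
            simulate_traits(pm, [pm.columns[0]], 2.0, 0.0, seed=rng)


class TestTgRates:
    def test_exact_deceleration_when_noise_free(self, stree16):
        absent = {"S1", "S2", "S3"}
        rates, _ = simulate_tg_rates(stree16, absent, 0.002, delta=0.3, sigma_g=0.0, seed=0)
        for sp, r in rates.items():
            expected = 0.002 * (0.7 if sp in absent else 1.0)
            assert r == pytest.approx(expected)

    def test_group_ratio_approaches_one_minus_delta(self, stree16):
        rng = np.random.default_rng(8)
        absent = {"S1", "S2", "S3", "S4"}
        ratios = []
        for _ in range(400):
            rates, _ = simulate_tg_rates(stree16, absent, 0.002, 0.3, 0.2, rng)
            a = rates[list(absent)].mean()
            p = rates.drop(list(absent)).mean()
            ratios.append(a / p)
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.02)

    def test_delta_range_validated(self, stree16):
        with pytest.raises(ValueError):
            simulate_tg_rates(stree16, set(), 0.002, 1.0, 0.0, 0)

    def test_emitted_tree_encodes_rates(self, stree16):
        absent = {"S5"}
        rates, tree = simulate_tg_rates(stree16, absent, 0.002, 0.3, 0.0, seed=0)
        durs = stree16.branch_durations()
        for leaf in tree.leaves:
            sp = leaf.label.rsplit("_", 1)[0]
            assert leaf.length == pytest.approx(rates[sp] * durs[sp])


class TestBatchInvariants:
    def test_batch_determinism(self, stree16):
        cfg = SimulationConfig(n_ogs=15, seed=4)
        a, _, _ = simulate_og_batch(stree16, cfg)
        b, _, _ = simulate_og_batch(stree16, cfg)
        assert [og.tree.to_newick() for og in a] == [og.tree.to_newick() for og in b]

    def test_null_end_to_end_identity(self, stree16):
        """lambda = mu = 0 and no ILS noise: reconciliation infers exactly
        zero events on every family."""
        cfg = SimulationConfig(n_ogs=10, dup_rate=0.0, loss_rate=0.0,
                               p_ils=0.0, seed=6)
        ogs, truths, _ = simulate_og_batch(stree16, cfg)
        assert len(ogs) == 10
        for og in ogs:
            rec = reconcile_og(og, stree16, threshold_spec=None)
            assert rec.n_duplications == 0
            assert rec.n_losses == 0
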