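import numpy as np
import pytest

import saturascreen as ss
from saturascreen._felsenstein import TreeIndex
from saturascreen.clock_dating import (Calibration, date_tree,
                                       estimate_branch_lengths, jc_distance,
                                       two_taxon_ml_distance)


def clock_lengths(t: TreeIndex, rate: float) -> np.ndarray:
    lengths = np.zeros(t.n_nodes)
    for i in range(t.n_nodes):
        if t.parent[i] >= 0:
            lengths[i] = rate * t.durations[i]
    return lengths


@pytest.fixture
def tree20():
    cfg = ss.SimulationConfig(n_taxa=20, root_age=390.0, seed=3)
    return ss.simulate_chronogram(cfg)


class TestBranchLengths:
    def test_two_taxon_ml_equals_closed_form_jc(self):
        ch = ss.read_chronogram("(A:50,B:50);")
        aln = ss.simulate_alignment(ch, ss.SubstitutionModel(),
                                    np.full(3000, 0.002), 5)
        p = (aln.data[0] != aln.data[1]).mean()
        d_ml = two_taxon_ml_distance(aln, ss.SubstitutionModel())
        assert d_ml == pytest.approx(jc_distance(p), abs=1e-8)

    def test_zero_rate_data_lengths_at_lower_bound(self, gtr):
        ch = ss.read_chronogram("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        aln = ss.simulate_alignment(ch, gtr, np.zeros(80), 1)
        t, lengths, _ = estimate_branch_lengths(aln, ch, gtr)
        est = [lengths[i] for i in range(t.n_nodes)
               if t.parent[i] >= 0]
        assert max(est) < 1e-6

    def test_optimum_beats_generating_lengths(self, gtr):
        cfg = ss.SimulationConfig(n_taxa=8, root_age=200.0, seed=6)
        ch = ss.simulate_chronogram(cfg)
        rate = 0.004
        aln = ss.simulate_alignment(ch, gtr, np.full(400, rate), 6)
        from saturascreen._felsenstein import LikelihoodEngine
        t, lengths, ll_opt = estimate_branch_lengths(aln, ch, gtr, tol=1e-6)
        engine = LikelihoodEngine(aln, ch, gtr)
        ll_true = engine.loglik_branch_lengths(clock_lengths(t, rate))
        assert ll_opt >= ll_true - 1e-6


class TestDateTree:
    def test_perfect_clock_recovers_ages_and_rate(self, tree20):
        t = TreeIndex(tree20)
        rate = 0.002
        lengths = clock_lengths(t, rate)
        truth = tree20.node_ages()
        root = frozenset(tree20.taxa)
        res = date_tree(t, lengths, [Calibration(root, truth[root],
                                                 kind="fixed")], truth=truth)
        errs = np.array(list(res.errors.values()))
        assert np.abs(errs).max() < 1e-6
        assert res.rate == pytest.approx(rate, abs=1e-8)
        assert res.objective < 1e-12

    def test_length_rescaling_rescales_rate_only(self, tree20):
        t = TreeIndex(tree20)
        lengths = clock_lengths(t, 0.002)
        truth = tree20.node_ages()
        root = frozenset(tree20.taxa)
        cal = [Calibration(root, truth[root], kind="fixed")]
        res1 = date_tree(t, lengths, cal)
        res2 = date_tree(t, lengths * 3.0, cal)
        assert res2.rate == pytest.approx(3 * res1.rate, rel=1e-6)
        for clade, age in res1.ages.items():
            assert res2.ages[clade] == pytest.approx(age, abs=1e-5)

    def test_deep_branch_shrinkage_extends_young_nodes(self, tree20):
        """Compressing all branches older than 145 Ma (saturation-like
        signal loss) pushes every younger node's estimated age upward."""
        t = TreeIndex(tree20)
        lengths = clock_lengths(t, 0.002)
        ages = {i: nd.age for i, nd in enumerate(t.node_objs)}
        shrunk = lengths.copy()
        for i in range(t.n_nodes):
            if t.parent[i] >= 0 and ages[i] >= 145.0:
                shrunk[i] *= 0.7
        truth = tree20.node_ages()
        root = frozenset(tree20.taxa)
        cal = [Calibration(root, truth[root], kind="fixed")]
        base = date_tree(t, lengths, cal)
        pert = date_tree(t, shrunk, cal)
        young = [c for c, a in truth.items() if a < 145.0 and c != root]
        assert young
        assert all(pert.ages[c] > base.ages[c] for c in young)

    def test_objective_not_worse_than_feasible_start(self, tree20):
        rng = np.random.default_rng(0)
        t = TreeIndex(tree20)
        lengths = clock_lengths(t, 0.002) * rng.uniform(0.5, 2.0,
                                                        t.n_nodes)
        root = frozenset(tree20.taxa)
        res = date_tree(t, lengths, [Calibration(root, 390.0, kind="fixed")])
        assert np.isfinite(res.objective)
        # parent >= child ordering holds in the solution
        for i in range(t.n_nodes):
            p = t.parent[i]
            if p >= 0 and t.children[i]:
                c_i = frozenset(
                    lf.taxon.label for lf in t.node_objs[i].leaf_iter())
                c_p = frozenset(
                    lf.taxon.label for lf in t.node_objs[p].leaf_iter())
                assert res.ages[c_p] >= res.ages[c_i] - 1e-8

    def test_taxon_label_permutation_invariance(self):
        n1 = "((A:1,B:1):1,(C:1.2,D:1.2):0.8);"
        n2 = "((D:1.2,C:1.2):0.8,(B:1,A:1):1);"
        ch1, ch2 = ss.read_chronogram(n1), ss.read_chronogram(n2)
        t1, t2 = TreeIndex(ch1), TreeIndex(ch2)
        cal = [Calibration(frozenset("ABCD"), 2.0, kind="fixed")]
        r1 = date_tree(t1, clock_lengths(t1, 0.1), cal)
        r2 = date_tree(t2, clock_lengths(t2, 0.1), cal)
        for clade, age in r1.ages.items():
            assert r2.ages[clade] == pytest.approx(age, abs=1e-8)

    def test_infeasible_calibrations_named(self, tree20):
        t = TreeIndex(tree20)
        lengths = clock_lengths(t, 0.002)
        root = frozenset(tree20.taxa)
        # find one internal non-root clade
        truth = tree20.node_ages()
        child = next(c for c in truth if c != root)
        with pytest.raises(ValueError, match="infeasible|exceeds"):
            date_tree(t, lengths, [
                Calibration(root, 100.0, kind="fixed"),
                Calibration(child, 200.0, max_age=None)])

    def test_requires_finite_age_information(self, tree20):
        t = TreeIndex(tree20)
        with pytest.raises(ValueError, match="unidentifiable|finite"):
            date_tree(t, clock_lengths(t, 0.002),
                      [Calibration(frozenset(tree20.taxa), 10.0)])

    def test_bounded_calibration_respected(self, tree20):
        t = TreeIndex(tree20)
        lengths = clock_lengths(t, 0.002)
        root = frozenset(tree20.taxa)
        res = date_tree(t, lengths, [Calibration(root, 300.0, 350.0)])
        assert 300.0 - 1e-9 <= res.ages[root] <= 350.0 + 1e-9
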