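import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import branchsim as bs
from conftest import fig_style_tree, make_random_model, random_tree


class TestMaxWork:
    def test_threshold_formula(self):
        assert bs.max_work(32.0, 16, 1.8) == pytest.approx(3.6)
        assert bs.max_work(10.0, 4, 1.0) == pytest.approx(2.5)

    def test_unit_k_single_core_keeps_whole_neuron(self):
        assert bs.max_work(42.0, 1, 1.0) == pytest.approx(42.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bs.max_work(-1.0, 4, 1.0)
        with pytest.raises(ValueError):
            bs.max_work(1.0, 0, 1.0)

    def test_default_k_interpolates_core_count_table(self):
        assert bs.default_k(16) == pytest.approx(1.8)
        assert bs.default_k(2) == pytest.approx(0.8)
        assert 1.0 < bs.default_k(6) < 1.5
        assert bs.default_k(64) == pytest.approx(2.0)


def chain_tree(n):
    p = np.arange(-1, n - 1)
    return bs.CompartmentTree(p, np.full(n, 20.0), np.ones(n),
                              np.full(n, 0.01),
                              np.concatenate([[np.inf], np.full(n - 1, 10.0)]))


class TestCluster:
    def test_threshold_above_total_gives_single_subtree(self):
        tree = chain_tree(10)
        plan = bs.cluster(tree, np.ones(10), threshold=100.0)
        assert plan.n_subtrees == 1
        assert plan.subtrees[0].members.tolist() == list(range(10))

    def test_unit_chain_splits_greedily(self):
        tree = chain_tree(10)
        plan = bs.cluster(tree, np.ones(10), threshold=3.0)
        sizes = sorted(s.members.size for s in plan.subtrees)
        assert sizes == [1, 3, 3, 3]

    def test_worked_morphology_splits_into_five_subtrees(self):
        tree, costs, threshold = fig_style_tree()
        plan = bs.cluster(tree, costs, threshold)
        assert tree.n == 17
        assert plan.n_subtrees == 5
        report = bs.validate_plan(plan, tree)
        assert report.ok
        # stem closes at the bifurcation; each branch is independent
        assert plan.subtrees[0].members.tolist() == [0, 1]

    def test_forced_singleton_above_threshold_is_flagged_not_failed(self):
        tree = chain_tree(3)
        costs = np.array([1.0, 10.0, 1.0])
        plan = bs.cluster(tree, costs, threshold=2.0)
        report = bs.validate_plan(plan, tree)
        assert report.ok
        assert any("singleton" in f for f in report.flagged)

    def test_empty_or_invalid_inputs_rejected(self):
        tree = chain_tree(3)
        with pytest.raises(ValueError):
            bs.cluster(tree, np.ones(3), threshold=0.0)
        with pytest.raises(ValueError):
            bs.cluster(tree, -np.ones(3), threshold=1.0)


class TestValidatePlan:
    def test_single_subtree_plan_valid_on_random_trees(self, rng):
        tree = random_tree(rng, 30)
        plan = bs.cluster(tree, np.ones(30), threshold=1e9)
        assert bs.validate_plan(plan, tree).ok

    def test_duplicated_compartment_reported(self):
        tree = chain_tree(4)
        plan = bs.cluster(tree, np.ones(4), threshold=2.0)
        plan.subtrees[0].members = np.array([0, 1, 2])  # 2 also in subtree 1
        report = bs.validate_plan(plan, tree)
        assert not report.ok
        assert any("subtrees" in v for v in report.violations)

    def test_non_leaf_attachment_reported(self):
        tree, costs, threshold = fig_style_tree()
        plan = bs.cluster(tree, costs, threshold)
        # re-root a branch subtree at a mid-stem compartment
        victim = next(s for s in plan.subtrees if s.parent is not None)
        victim.parent_comp = 0
        report = bs.validate_plan(plan, tree)
        assert not report.ok

    @given(seed=st.integers(0, 500))
    @settings(max_examples=60)
    def test_cluster_always_produces_valid_plans(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(2, 60)))
        costs = rng.uniform(0.5, 2.0, tree.n)
        threshold = float(rng.uniform(1.0, costs.sum()))
        plan = bs.cluster(tree, costs, threshold)
        report = bs.validate_plan(plan, tree)
        assert report.ok, report.violations

    def test_subtree_count_monotone_in_threshold(self, rng):
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(5, 60)))
            costs = rng.uniform(0.5, 2.0, tree.n)
            total = costs.sum()
            counts = [bs.cluster(tree, costs, th).n_subtrees
                      for th in np.linspace(0.8, total, 8)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWorkload:
    def test_analytic_base_only(self):
        model = bs.NeuronModel(chain_tree(5))
        plan = bs.plan_for_model(model, bs.CostModel(base=1.0))
        st0 = plan.subtrees[0]
        assert bs.measure_workload(st0, model, bs.CostModel(base=1.0)) == 5.0

    def test_analytic_includes_mechanism_costs(self):
        model = bs.NeuronModel(chain_tree(2))
        model.add_mechanism("leak", [0, 1], g=0.1, e=-65.0)
        cm = bs.CostModel(base=1.0, mech_costs={"leak": 3.0})
        plan = bs.plan_for_model(model, cm)
        assert bs.measure_workload(plan.subtrees[0], model, cm) == 8.0

    def test_measured_mode_reports_positive_runtime(self):
        model = make_random_model(seed=11, target_comps=15)
        plan = bs.plan_for_model(model)
        cm = bs.CostModel(mode="measured", reps=3, sample_tstop=1.0)
        costs = [bs.measure_workload(s, model, cm) for s in plan.subtrees]
        assert all(c > 0 for c in costs)
        # identical repetitions → dispersion is sampling noise; report only
        cv = np.std(costs) / np.mean(costs)
        assert np.isfinite(cv)


def test_plan_json_roundtrip():
    tree, costs, threshold = fig_style_tree()
    plan = bs.cluster(tree, costs, threshold)
    back = bs.DecompositionPlan.from_json(plan.to_json())
    assert back.n_subtrees == plan.n_subtrees
    for a, b in zip(back.subtrees, plan.subtrees):
        assert a.members.tolist() == b.members.tolist()
        assert a.parent == b.parent and a.parent_comp == b.parent_comp
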