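import numpy as np
import pytest

import branchsim as bs
from branchsim.runtime import Placeholder, Scheduler
from conftest import fig_style_tree, make_random_model, small_network, \
    two_soma_network


class TestScheduler:
    def test_blocked_task_resumes_after_set(self):
        sched = Scheduler(workers=1)
        gate = Placeholder("V_UP")
        log = []

        def consumer():
            if not gate.ready(0):
                yield (gate, 0)
            log.append(sched.get_value(gate, 0))

        def producer():
            sched.set_value(gate, 0, 42)
            return
            yield  # make it a generator

        sched.run([consumer(), producer()])
        assert log == [42]

    @pytest.mark.parametrize("workers", [1, 3])
    def test_deadlock_detected(self, workers):
        sched = Scheduler(workers=workers)
        gate = Placeholder("TRI_UP")

        def starving():
            yield (gate, 0)

        with pytest.raises(bs.DeadlockError):
            sched.run([starving()])

    def test_task_exception_propagates(self):
        sched = Scheduler(workers=2)

        def boom():
            raise RuntimeError("task failed")
            yield

        with pytest.raises(RuntimeError, match="task failed"):
            sched.run([boom()])


class TestDecomposedEquivalence:
    def test_single_subtree_equals_reference_engine(self):
        model = make_random_model(seed=41, target_comps=20)
        clock = bs.SimulationClock(tstop=5.0)
        ref = bs.run(bs.Network([make_random_model(seed=41, target_comps=20)]),
                     clock, record="all")
        one = bs.run_network_async(bs.Network([model]), clock, record="all")
        assert np.abs(ref.full_traces[0] - one.full_traces[0]).max() < 1e-12

    def test_chain_split_in_two_matches_monolithic(self):
        n = 10
        p = np.arange(-1, n - 1)
        tree = bs.CompartmentTree(p, np.full(n, 20.0), np.full(n, 2.0),
                                  np.full(n, 0.01),
                                  np.concatenate([[np.inf],
                                                  np.full(n - 1, 5.0)]))
        def build():
            m = bs.NeuronModel(tree)
            m.add_mechanism("leak", np.arange(n), g=0.002, e=-65.0)
            m.add_mechanism("iclamp", [0], amp=0.05, onset=0.5, dur=3.0)
            return m
        clock = bs.SimulationClock(tstop=5.0)
        mono = bs.run_network_async(bs.Network([build()]), clock, record="all")
        model = build()
        plan = bs.cluster(tree, np.ones(n), threshold=5.0)
        assert plan.n_subtrees == 2
        split = bs.run_network_async(bs.Network([model]), clock,
                                     plans=[plan], record="all")
        assert np.abs(mono.full_traces[0] - split.full_traces[0]).max() < 1e-12

    def test_branched_split_matches_monolithic(self):
        tree, costs, threshold = fig_style_tree()
        def build():
            m = bs.NeuronModel(tree)
            m.add_mechanism("leak", np.arange(tree.n), g=0.002, e=-65.0)
            m.add_mechanism("iclamp", [0], amp=0.05, onset=0.5, dur=3.0)
            return m
        clock = bs.SimulationClock(tstop=5.0)
        mono = bs.run_network_async(bs.Network([build()]), clock, record="all")
        plan = bs.cluster(tree, costs, threshold)
        split = bs.run_network_async(bs.Network([build()]), clock,
                                     plans=[plan], record="all")
        assert plan.n_subtrees == 5
        assert np.abs(mono.full_traces[0] - split.full_traces[0]).max() < 1e-9


class TestProtocolAccounting:
    def test_three_messages_per_connection_per_step(self):
        model = make_random_model(seed=55, target_comps=40)
        plan = bs.plan_for_model(model, cores_count=4)
        assert plan.n_subtrees >= 3
        clock = bs.SimulationClock(tstop=2.0)
        engine = bs.AsyncNetworkEngine(bs.Network([model]), clock, plans=[plan])
        res = engine.run()
        n_steps = clock.n_steps
        assert len(res.message_counts) == plan.n_subtrees - 1
        assert all(c == 3 * n_steps for c in res.message_counts.values())

    def test_multi_child_gate_counts(self):
        tree, costs, threshold = fig_style_tree()
        model = bs.NeuronModel(tree)
        model.add_mechanism("leak", np.arange(tree.n), g=0.002, e=-65.0)
        plan = bs.cluster(tree, costs, threshold)
        engine = bs.AsyncNetworkEngine(bs.Network([model]),
                                       bs.SimulationClock(tstop=1.0),
                                       plans=[plan])
        # the stem subtree closes at the bifurcation: three child channels
        n_children = [len(engine.child_channels[b])
                      for b in range(plan.n_subtrees)]
        assert max(n_children) == 3
        engine.run()

    def test_progress_accounting(self):
        model = make_random_model(seed=55, target_comps=40)
        plan = bs.plan_for_model(model, cores_count=4)
        clock = bs.SimulationClock(tstop=2.0)
        res = bs.run_network_async(bs.Network([model]), clock, plans=[plan])
        assert res.steps_executed == plan.n_subtrees * clock.n_steps


@pytest.fixture(scope="module")
def baseline():
    net = small_network(n_neurons=5, seed=3)
    clock = bs.SimulationClock(tstop=15.0)
    plans = [bs.plan_for_model(m, cores_count=4) for m in net.neurons]
    res = bs.run_network_async(net, clock, plans=plans, workers=1)
    assert len(res.raster) >= 1
    return clock, res


class TestWorkerAndLocalityInvariance:
    @pytest.mark.parametrize("workers", [2, 4])
    def test_worker_count_invariance(self, baseline, workers):
        clock, ref = baseline
        net = small_network(n_neurons=5, seed=3)
        plans = [bs.plan_for_model(m, cores_count=4) for m in net.neurons]
        res = bs.run_network_async(net, clock, plans=plans, workers=workers)
        assert res.raster_text() == ref.raster_text()
        for nid in ref.traces:
            np.testing.assert_array_equal(res.traces[nid], ref.traces[nid])

    def test_locality_assignment_invariance(self, baseline):
        clock, ref = baseline
        for localities in (2, 3):
            net = small_network(n_neurons=5, seed=3)
            plans = [bs.plan_for_model(m, cores_count=4) for m in net.neurons]
            engine = bs.AsyncNetworkEngine(net, clock, plans=plans,
                                           workers=2, localities=localities)
            res = engine.run()
            assert res.raster_text() == ref.raster_text()
            assert engine.remote_message_count() >= 0

    def test_two_neurons_on_two_localities_match_single_locality(self):
        clock = bs.SimulationClock(tstop=25.0)
        r1 = bs.run_network_async(two_soma_network(), clock, localities=1)
        r2 = bs.run_network_async(two_soma_network(), clock, localities=2)
        assert r1.raster_text() == r2.raster_text()
        assert len(r1.raster) >= 2  # driver and driven neuron both fire


def test_causality_in_async_engine():
    net = two_soma_network(weight=0.5, delay=1.0)
    res = bs.run_network_async(net, bs.SimulationClock(tstop=30.0))
    a = [s.time for s in res.raster if s.source == 0]
    b = [s.time for s in res.raster if s.source == 1]
    assert a and b
    assert min(b) > min(a) + 1.0
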