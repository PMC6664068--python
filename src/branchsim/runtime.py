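"""Asynchronous producer-consumer execution of a tree of subtrees.

Each subtree advances step by step as an independent task; cross-subtree
read-after-write dependencies are resolved through exactly three value
transfers per connection per timestep, each carried by a counted
synchronization placeholder:

``V_UP``   (child → parent): the child subtree's root voltage at step
           start, needed by the parent's connecting (leaf) row for its
           axial right-hand-side and diagonal terms.
``TRI_UP`` (child → parent): the (δd, δrhs) boundary contribution of the
           child's eliminated root row, folded into the parent's leaf row
           before the parent's own backward triangulation.
``SUB_DOWN`` (parent → child): the Δv of the parent's connecting
           compartment, with which the child completes its forward
           substitution and updates its cached parent boundary voltage for
           the following step's right-hand-side set-up.

Tasks are generators driven by a small scheduler: a task blocked on a
placeholder consumes no worker, and is re-queued when the value arrives.
Results are independent of the worker count because every task's arithmetic
order is fixed and multi-child reductions are folded in ascending child
subtree id.  Neurons synchronize at communication-step boundaries through a
barrier, after which spikes are exchanged as delayed events.

Localities (simulated memory/compute domains of a distributed run) are
logical tags on subtrees: channels between subtrees on different localities
are counted as remote traffic, and results are assignment-invariant.
"""

from __future__ import annotations

import threading
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .decomposition import DecompositionPlan, plan_for_model
from .groups import build_type_groups
from .hines import (apply_boundary, backward_triangulate, forward_substitute,
                    setup_matrix)
from .layout import SubtreeBlock, build_layout
from .network import Network
from .stepping import (Event, NumericalBlowupError, RunResult, SimulationClock,
                       Spike, detect_spike, exchange_spikes)

V_UP, TRI_UP, SUB_DOWN = "V_UP", "TRI_UP", "SUB_DOWN"


class DeadlockError(RuntimeError):
    pass


class Placeholder:
    """Counted synchronization cell for one dependency, one value per step."""

    __slots__ = ("kind", "values", "waiters")

    def __init__(self, kind: str):
        self.kind = kind
        self.values: dict[int, object] = {}
        self.waiters: dict[int, list] = {}

    def ready(self, step: int) -> bool:
        return step in self.values


@dataclass
class ConnectionChannel:
    """The three per-step placeholders between a child subtree root and the
    connecting (leaf) compartment of its parent subtree."""

    child_block: int            # global block index
    parent_block: int
    parent_comp_local: int      # connecting compartment, parent-local index
    child_inv_r: float          # 1/r of the cross-boundary coupling (1/MΩ)
    v_up: Placeholder = field(default_factory=lambda: Placeholder(V_UP))
    tri_up: Placeholder = field(default_factory=lambda: Placeholder(TRI_UP))
    sub_down: Placeholder = field(default_factory=lambda: Placeholder(SUB_DOWN))
    messages: int = 0
    inter_locality: bool = False


class Scheduler:
    """Ready-queue scheduler driving task generators on a worker pool.

    Tasks yield ``(placeholder, step)`` to wait; :meth:`set_value` publishes
    a value and re-queues any waiters.  Any ready task eventually runs; a
    blocked task holds no worker.
    """

    def __init__(self, workers: int = 1):
        if workers < 1:
            raise ValueError("workers must be >= 1")
        self.workers = workers
        self._lock = threading.Lock()
        self._cond = threading.Condition(self._lock)
        self._ready: deque = deque()
        self._unfinished = 0
        self._running = 0
        self._exc: BaseException | None = None

    def set_value(self, gate: Placeholder, step: int, value) -> None:
        with self._lock:
            gate.values[step] = value
            waiters = gate.waiters.pop(step, None)
            if waiters:
                self._ready.extend(waiters)
                self._cond.notify_all()

    def get_value(self, gate: Placeholder, step: int):
        with self._lock:
            return gate.values.pop(step)

    def _drive(self, task) -> bool:
        """Run one task until it finishes (True) or parks on a gate (False)."""
        while True:
            try:
                gate, step = next(task)
            except StopIteration:
                return True
            with self._lock:
                if gate.ready(step):
                    continue
                gate.waiters.setdefault(step, []).append(task)
                return False

    def run(self, tasks) -> None:
        self._ready = deque(tasks)
        self._unfinished = len(tasks)
        self._running = 0
        self._exc = None
        if self.workers == 1:
            while self._ready:
                task = self._ready.popleft()
                if self._drive(task):
                    self._unfinished -= 1
            if self._unfinished:
                raise DeadlockError(
                    f"{self._unfinished} tasks blocked with no producer left")
            return

        def worker():
            while True:
                with self._lock:
                    while (not self._ready and self._unfinished > 0
                           and self._exc is None):
                        if self._running == 0:
                            self._exc = DeadlockError(
                                f"{self._unfinished} tasks blocked with no "
                                "producer left")
                            self._cond.notify_all()
                            return
                        self._cond.wait()
                    if self._unfinished == 0 or self._exc is not None:
                        return
                    task = self._ready.popleft()
                    self._running += 1
                try:
                    finished = self._drive(task)
                except BaseException as exc:  # propagate task failures
                    with self._lock:
                        self._exc = exc
                        self._running -= 1
                        self._cond.notify_all()
                    return
                with self._lock:
                    self._running -= 1
                    if finished:
                        self._unfinished -= 1
                    self._cond.notify_all()

        threads = [threading.Thread(target=worker, daemon=True)
                   for _ in range(self.workers)]
        for th in threads:
            th.start()
        for th in threads:
            th.join()
        if self._exc is not None:
            raise self._exc
        if self._unfinished:
            raise DeadlockError("tasks left unfinished")


def _compute_currents(block: SubtreeBlock, t: float):
    i_total = np.zeros(block.n)
    G = np.zeros(block.n)
    for g in block.groups:
        i, gg = g.current(block.arr.v, t)
        np.add.at(i_total, g.comp_local, i)
        np.add.at(G, g.comp_local, gg)
    return i_total, G


def _deliver_events(block: SubtreeBlock, t: float) -> None:
    for ev in block.events.pop_due(t):
        g = block.groups[ev.group]
        g.mech.on_event(g.params, g.state, ev.slot, ev.weight)


def step_block_isolated(block: SubtreeBlock, dt: float,
                        threshold: float = -20.0) -> None:
    """Advance one subtree a single step with boundaries held constant.

    Used by the measured-workload protocol: cross-subtree voltages are
    frozen at their cached values and the parent Δv is taken as zero, so the
    kernel exercises the same arithmetic as a connected step.
    """
    t = block.step * dt
    _deliver_events(block, t)
    i_total, G = _compute_currents(block, t)
    setup_matrix(block.arr, G, i_total, block.C, dt,
                 parent_boundary_v=block.parent_v_cache)
    backward_triangulate(block.arr)
    if block.arr.has_parent:
        forward_substitute(block.arr, parent_delta_v=0.0)
    else:
        forward_substitute(block.arr)
    v_prev = block.arr.v[0]
    block.arr.v += block.arr.rhs
    t_end = (block.step + 1) * dt
    if block.is_soma_block and detect_spike(v_prev, block.arr.v[0],
                                            threshold, t_end) is not None:
        block.spike_times.append(t_end)
    for g in block.groups:
        g.update_state(block.arr.v, dt)
    block.step += 1


class AsyncNetworkEngine:
    """Builds blocks and channels for a network and runs them to tstop."""

    def __init__(self, network: Network, clock: SimulationClock,
                 plans: list[DecompositionPlan] | None = None,
                 workers: int = 1, assignment=None, vector_width: int = 8,
                 threshold: float = -20.0, record: str = "soma",
                 localities: int = 1):
        self.network = network
        self.clock = clock
        self.threshold = float(threshold)
        self.record = record
        self.t_synch = clock.synch_interval(network.min_delay())
        network.validate(self.t_synch)

        if plans is None:
            plans = [plan_for_model(m, cores_count=1, k=1.0)
                     for m in network.neurons]
        if len(plans) != network.n_neurons:
            raise ValueError("one plan per neuron required")
        self.plans = plans

        self.blocks: list[SubtreeBlock] = []
        self.channels: list[ConnectionChannel] = []
        self.parent_channel: dict[int, ConnectionChannel | None] = {}
        self.child_channels: dict[int, list[ConnectionChannel]] = {}
        self.handle_route: list[dict] = []   # per neuron: handle → (block, g, slot)
        self.soma_block: list[int] = []

        for nid, (model, plan) in enumerate(zip(network.neurons, plans)):
            groups, _ = build_type_groups(model)
            base = len(self.blocks)
            nb = []
            for st in plan.subtrees:
                b = build_layout(st, model, groups=groups,
                                 vector_width=vector_width, neuron_id=nid)
                nb.append(b)
            route = {}
            for bi, b in enumerate(nb):
                gb = base + bi
                self.blocks.append(b)
                self.parent_channel[gb] = None
                self.child_channels[gb] = []
                for h, (gi, slot) in b.handle_slots.items():
                    route[h] = (gb, gi, slot)
            self.handle_route.append(route)
            self.soma_block.append(base)
            for bi, st in enumerate(plan.subtrees):
                if st.parent is None:
                    continue
                gb = base + bi
                pb = base + st.parent
                parent_block = self.blocks[pb]
                ch = ConnectionChannel(
                    child_block=gb, parent_block=pb,
                    parent_comp_local=parent_block.local_index(st.parent_comp),
                    child_inv_r=1.0 / model.tree.r[st.root])
                self.channels.append(ch)
                self.parent_channel[gb] = ch
                self.child_channels[pb].append(ch)
            for gb in range(base, base + len(nb)):
                self.child_channels[gb].sort(key=lambda c: c.child_block)

        # Locality tags (bookkeeping only; results are assignment-invariant).
        self.block_locality = [0] * len(self.blocks)
        if assignment is not None:
            for nid in range(network.n_neurons):
                home = assignment.home.get(nid, 0)
                base = self.soma_block[nid]
                for bi in range(len(self.plans[nid].subtrees)):
                    self.block_locality[base + bi] = home
            for nid, group, loc in getattr(assignment, "delegated", []):
                base = self.soma_block[nid]
                for si in group.subtree_ids:
                    self.block_locality[base + si] = loc
        elif localities > 1:
            for nid in range(network.n_neurons):
                base = self.soma_block[nid]
                for bi in range(len(self.plans[nid].subtrees)):
                    self.block_locality[base + bi] = nid % localities
        for ch in self.channels:
            ch.inter_locality = (self.block_locality[ch.child_block]
                                 != self.block_locality[ch.parent_block])

        self.scheduler = Scheduler(workers)
        self._io_every = max(1, int(round(clock.t_io / clock.dt)))
        self._soma_rec: dict[int, list[float]] = {n: [] for n in
                                                  range(network.n_neurons)}
        self._rec_times: list[float] = []

    def _task(self, gb: int, steps: int):
        block = self.blocks[gb]
        sched = self.scheduler
        dt = self.clock.dt
        pch = self.parent_channel[gb]
        children = self.child_channels[gb]
        n_steps_total = self.clock.n_steps
        record_all = self.record == "all"
        for _ in range(steps):
            s = block.step
            t = s * dt
            if pch is not None:
                sched.set_value(pch.v_up, s, float(block.arr.v[0]))
                pch.messages += 1
            child_axial = []
            for ch in children:
                if not ch.v_up.ready(s):
                    yield (ch.v_up, s)
                child_axial.append((ch.parent_comp_local,
                                    sched.get_value(ch.v_up, s),
                                    ch.child_inv_r))
            _deliver_events(block, t)
            i_total, G = _compute_currents(block, t)
            setup_matrix(block.arr, G, i_total, block.C, dt,
                         parent_boundary_v=block.parent_v_cache,
                         child_axial=child_axial)
            for ch in children:
                if not ch.tri_up.ready(s):
                    yield (ch.tri_up, s)
                apply_boundary(block.arr, ch.parent_comp_local,
                               sched.get_value(ch.tri_up, s))
            bc = backward_triangulate(block.arr)
            if pch is not None:
                sched.set_value(pch.tri_up, s, bc)
                pch.messages += 1
                if not pch.sub_down.ready(s):
                    yield (pch.sub_down, s)
                dvp = sched.get_value(pch.sub_down, s)
                block.parent_v_cache += dvp
                forward_substitute(block.arr, parent_delta_v=dvp)
            else:
                forward_substitute(block.arr)
            for ch in children:
                sched.set_value(ch.sub_down, s,
                                float(block.arr.rhs[ch.parent_comp_local]))
                ch.messages += 1
            v_prev = block.arr.v[0]
            block.arr.v += block.arr.rhs
            if not np.all(np.isfinite(block.arr.v)):
                bad = int(np.argmin(np.isfinite(block.arr.v)))
                raise NumericalBlowupError(
                    t + dt, int(block.global_index[bad]))
            t_end = (s + 1) * dt
            if block.is_soma_block and detect_spike(
                    v_prev, block.arr.v[0], self.threshold, t_end) is not None:
                block.spike_times.append(t_end)
            for g in block.groups:
                g.update_state(block.arr.v, dt)
            if record_all:
                block.trace.append(block.arr.v.copy())
            elif block.is_soma_block and (
                    (s + 1) % self._io_every == 0 or s + 1 == n_steps_total):
                self._soma_rec[block.neuron_id].append(float(block.arr.v[0]))
            block.step += 1

    def run(self) -> RunResult:
        clock = self.clock
        n_steps = clock.n_steps
        steps_per_window = max(1, int(round(self.t_synch / clock.dt)))
        conns = self.network.connections_by_source()
        spikes_done = [0] * self.network.n_neurons
        raster: list[Spike] = []
        emitted = 0

        step = 0
        while step < n_steps:
            window = min(steps_per_window, n_steps - step)
            tasks = [self._task(gb, window) for gb in range(len(self.blocks))]
            self.scheduler.run(tasks)   # returns once all subtrees reach the
            step += window              # boundary: the communication barrier
            for s in range(step - window, step):
                if (s + 1) % self._io_every == 0 or s + 1 == n_steps:
                    self._rec_times.append((s + 1) * clock.dt)
            new_spikes = []
            for nid in range(self.network.n_neurons):
                sb = self.blocks[self.soma_block[nid]]
                for ts in sb.spike_times[spikes_done[nid]:]:
                    new_spikes.append(Spike(nid, ts))
                spikes_done[nid] = len(sb.spike_times)
            raster.extend(new_spikes)
            emitted += sum(len(conns.get(sp.source, [])) for sp in new_spikes)
            self._exchange(new_spikes, conns)

        result = RunResult(
            dt=clock.dt,
            trace_times=np.array(self._rec_times),
            traces={n: np.array(v) for n, v in self._soma_rec.items()},
            raster=raster,
            events_emitted=emitted,
            events_delivered=sum(b.events.delivered for b in self.blocks),
            steps_executed=sum(b.step for b in self.blocks),
            subtree_counts={n: p.n_subtrees for n, p in enumerate(self.plans)},
            message_counts={(ch.child_block, ch.parent_block): ch.messages
                            for ch in self.channels},
        )
        if self.record == "all":
            for nid in range(self.network.n_neurons):
                base = self.soma_block[nid]
                nb = [self.blocks[base + i]
                      for i in range(self.plans[nid].n_subtrees)]
                if not nb[0].trace:
                    continue
                full = np.full((len(nb[0].trace), self.network.neurons[nid].tree.n),
                               np.nan)
                for b in nb:
                    full[:, b.global_index] = np.array(b.trace)
                result.full_traces[nid] = full
        return result

    def _exchange(self, spikes: list[Spike], conns) -> None:
        for sp in sorted(spikes, key=lambda s: (s.time, s.source)):
            for conn in conns.get(sp.source, []):
                gb, gi, slot = self.handle_route[conn.target][conn.handle]
                self.blocks[gb].events.push(Event(
                    sp.time + conn.delay, sp.source, conn.conn_id,
                    gi, slot, conn.weight))

    def remote_message_count(self) -> int:
        return sum(ch.messages for ch in self.channels if ch.inter_locality)


def run_network_async(network: Network, clock: SimulationClock,
                      plans: list[DecompositionPlan] | None = None,
                      workers: int = 1, **kwargs) -> RunResult:
    """Run a network with the asynchronous branch-parallel engine."""
    return AsyncNetworkEngine(network, clock, plans=plans, workers=workers,
                              **kwargs).run()
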