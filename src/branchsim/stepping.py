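"""Fixed-step staggered simulation loop (serial reference engine).

Per timestep, in order: (1) deliver pending synaptic events whose delivery
time has been reached; (2) evaluate mechanism currents at the current
voltage and half-step gating states; (3) set up the Δv system; (4) backward
triangulation and forward substitution; (5) voltage update v ← v + Δv;
(6) gating-state update at the new voltage; (7) soma spike detection.
Voltage and gating states are thereby advanced in interleaved half steps.

Spikes are exchanged between neurons only at communication-step boundaries
(``T_synch``, set to the network's minimum synaptic delay rounded down to a
multiple of dt), which is safe because every synaptic delay is at least
``T_synch``: a spike emitted inside one window can only be delivered in a
strictly later window.

:class:`ReferenceSimulation` is the monolithic array-of-structures engine —
mechanism instances are evaluated one at a time — and serves as the
behavioural reference for the structure-of-arrays subtree engine in
:mod:`branchsim.runtime`.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .groups import build_type_groups
from .hines import (SolverArrays, backward_triangulate, check_diagonal_dominance,
                    forward_substitute, setup_matrix)
from .mechanisms import ConfigurationError
from .network import Network

#: slack used when comparing event delivery times against step boundaries,
#: so that a delay that is an exact multiple of dt lands on its boundary
#: despite round-off in t = k·dt.
TIME_EPS = 1e-9


class NumericalBlowupError(RuntimeError):
    def __init__(self, t: float, comp: int):
        self.t, self.comp = t, comp
        super().__init__(f"non-finite voltage at t={t:.6g} ms, compartment {comp}")


@dataclass
class SimulationClock:
    """Timestep bookkeeping; all fields in ms."""

    dt: float = 0.025
    tstop: float = 0.0
    t_synch: float | None = None   # communication step; None → derive from net
    t_io: float = 0.1              # trace output interval

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.tstop < 0:
            raise ConfigurationError("tstop must be non-negative")
        if self.t_synch is not None:
            k = self.t_synch / self.dt
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise ConfigurationError(
                    "t_synch must be a positive integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.tstop / self.dt))

    def synch_interval(self, min_delay: float | None) -> float:
        """Communication step: configured value, or min delay rounded down."""
        if self.t_synch is not None:
            return self.t_synch
        if min_delay is None:
            return max(self.tstop, self.dt)
        k = max(1, math.floor(min_delay / self.dt + 1e-9))
        return k * self.dt


@dataclass(frozen=True)
class Spike:
    source: int
    time: float


@dataclass(frozen=True)
class Event:
    time: float
    source: int
    conn_id: int
    group: int
    slot: int
    weight: float


class EventQueue:
    """Time-ordered pending events; ties broken by (time, source, conn_id)."""

    def __init__(self, audit: bool = False):
        self._heap: list[tuple[float, int, int, int, int, int, float]] = []
        self._seq = 0
        self.delivered = 0
        self.audit = audit
        #: (conn_id, delivery time, step start at which it was applied)
        self.audit_log: list[tuple[int, float, float]] = []

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, ev: Event) -> None:
        heapq.heappush(self._heap, (ev.time, ev.source, ev.conn_id, self._seq,
                                    ev.group, ev.slot, ev.weight))
        self._seq += 1

    def pop_due(self, t: float) -> list[Event]:
        out = []
        while self._heap and self._heap[0][0] <= t + TIME_EPS:
            time, src, cid, _, g, slot, w = heapq.heappop(self._heap)
            out.append(Event(time, src, cid, g, slot, w))
            self.delivered += 1
            if self.audit:
                self.audit_log.append((cid, time, t))
        return out


def detect_spike(v_prev: float, v_new: float, threshold: float,
                 t: float) -> float | None:
    """Spike time (= step-end time t) iff an upward threshold crossing."""
    if v_prev < threshold <= v_new:
        return t
    return None


class ReferenceSimulation:
    """Monolithic per-instance (array-of-structures) engine for one neuron."""

    def __init__(self, model, dt: float = 0.025, threshold: float = -20.0,
                 euler: bool = False):
        model.validate()
        self.model = model
        self.dt = float(dt)
        self.threshold = float(threshold)
        self.euler = euler
        self.tree = model.tree
        self.arr = SolverArrays.from_tree(self.tree, model.v_init)
        self.C = self.tree.C
        self.groups, self.handle_map = build_type_groups(model)
        self.events = EventQueue()
        self.step_count = 0
        self.spike_times: list[float] = []
        self._dominance_checked = False

    @property
    def t(self) -> float:
        return self.step_count * self.dt

    @property
    def v(self) -> np.ndarray:
        return self.arr.v

    def push_event(self, ev: Event) -> None:
        self.events.push(ev)

    def _deliver_events(self, t: float) -> None:
        for ev in self.events.pop_due(t):
            g = self.groups[ev.group]
            g.mech.on_event(g.params, g.state, ev.slot, ev.weight)

    def step(self) -> None:
        t = self.t
        self._deliver_events(t)
        n = self.tree.n
        i_total = np.zeros(n)
        G = np.zeros(n)
        v = self.arr.v
        for g in self.groups:
            mech = g.mech
            for j in range(g.n_instances):
                pj = {k: a[j:j + 1] for k, a in g.params.items()}
                sj = {k: a[j:j + 1] for k, a in g.state.items()}
                comp = g.comps[j]
                i, gg = mech.current(pj, sj, v[comp], t)
                i_total[comp] += float(i[0])
                G[comp] += float(gg[0])
        setup_matrix(self.arr, G, i_total, self.C, self.dt)
        if not self._dominance_checked:
            check_diagonal_dominance(self.arr)
            self._dominance_checked = True
        backward_triangulate(self.arr)
        forward_substitute(self.arr)
        v_prev_soma = v[0]
        v += self.arr.rhs
        if not np.all(np.isfinite(v)):
            bad = int(np.argmin(np.isfinite(v)))
            raise NumericalBlowupError(t + self.dt, bad)
        t_end = (self.step_count + 1) * self.dt
        if detect_spike(v_prev_soma, v[0], self.threshold, t_end) is not None:
            self.spike_times.append(t_end)
        for g in self.groups:
            mech = g.mech
            for j in range(g.n_instances):
                pj = {k: a[j:j + 1] for k, a in g.params.items()}
                sj = {k: a[j:j + 1] for k, a in g.state.items()}
                mech.update_state(pj, sj, v[g.comps[j]], self.dt,
                                  euler=self.euler)
        self.step_count += 1

    def run_steps(self, n: int, record: list | None = None) -> None:
        for _ in range(n):
            self.step()
            if record is not None:
                record.append(self.arr.v.copy())


def exchange_spikes(spikes: list[Spike], connections_by_source,
                    queues: dict[int, EventQueue] | list,
                    handle_maps: dict[int, dict] | list) -> int:
    """Turn spikes into one event per outgoing connection.

    ``queues[target]`` receives an event with delivery time = spike time +
    connection delay; delivery happens at the first step whose start time is
    at or past that.  Returns the number of events appended.
    """
    appended = 0
    for sp in sorted(spikes, key=lambda s: (s.time, s.source)):
        for conn in connections_by_source.get(sp.source, []):
            g, slot = handle_maps[conn.target][conn.handle]
            queues[conn.target].push(Event(sp.time + conn.delay, sp.source,
                                           conn.conn_id, g, slot, conn.weight))
            appended += 1
    return appended


@dataclass
class RunResult:
    """Traces, spike raster, and execution counters of one simulation run."""

    dt: float
    trace_times: np.ndarray                 # (n_rec,)
    traces: dict[int, np.ndarray]           # neuron id → (n_rec,) soma mV
    raster: list[Spike] = field(default_factory=list)
    full_traces: dict[int, np.ndarray] = field(default_factory=dict)
    events_delivered: int = 0
    events_emitted: int = 0
    steps_executed: int = 0
    subtree_counts: dict[int, int] = field(default_factory=dict)
    message_counts: dict = field(default_factory=dict)

    def raster_text(self) -> str:
        lines = [f"{sp.time:.6f} {sp.source}"
                 for sp in sorted(self.raster, key=lambda s: (s.time, s.source))]
        return "\n".join(lines) + ("\n" if lines else "")


def run(network: Network, clock: SimulationClock, threshold: float = -20.0,
        record: str = "soma") -> RunResult:
    """Serial whole-network run with the reference engine.

    ``record='soma'`` records the soma voltage every ``t_io``;
    ``record='all'`` additionally stores every compartment at every step
    (for equivalence checks).  Deterministic: identical inputs produce a
    bitwise-identical spike raster.
    """
    t_synch = clock.synch_interval(network.min_delay())
    network.validate(t_synch)
    sims = [ReferenceSimulation(m, clock.dt, threshold) for m in network.neurons]
    conns = network.connections_by_source()
    handle_maps = [s.handle_map for s in sims]
    queues = [s.events for s in sims]

    n_steps = clock.n_steps
    steps_per_window = max(1, int(round(t_synch / clock.dt)))
    io_every = max(1, int(round(clock.t_io / clock.dt)))

    rec_times = []
    rec = {i: [] for i in range(network.n_neurons)}
    full = {i: [] for i in range(network.n_neurons)} if record == "all" else None
    emitted = 0
    delivered_total = 0
    spikes_done = [0] * len(sims)
    raster: list[Spike] = []

    step = 0
    while step < n_steps:
        window = min(steps_per_window, n_steps - step)
        for _ in range(window):
            for i, sim in enumerate(sims):
                sim.step()
                if full is not None:
                    full[i].append(sim.arr.v.copy())
            step += 1
            if step % io_every == 0 or step == n_steps:
                rec_times.append(step * clock.dt)
                for i, sim in enumerate(sims):
                    rec[i].append(sim.arr.v[0])
        new_spikes = []
        for i, sim in enumerate(sims):
            for ts in sim.spike_times[spikes_done[i]:]:
                new_spikes.append(Spike(i, ts))
            spikes_done[i] = len(sim.spike_times)
        raster.extend(new_spikes)
        emitted += sum(len(conns.get(sp.source, [])) for sp in new_spikes)
        exchange_spikes(new_spikes, conns, queues, handle_maps)
    delivered_total = sum(q.delivered for q in queues)

    result = RunResult(
        dt=clock.dt,
        trace_times=np.array(rec_times),
        traces={i: np.array(v) for i, v in rec.items()},
        raster=raster,
        events_delivered=delivered_total,
        events_emitted=emitted,
        steps_executed=sum(s.step_count for s in sims),
    )
    if full is not None:
        result.full_traces = {i: np.array(v) for i, v in full.items()}
    return result
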