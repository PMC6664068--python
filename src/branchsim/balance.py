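"""Distributed load balancing: LPT over neurons with terminal-group splitting.

Whole neurons are first assigned to localities by the Least Processing Time
(LPT) greedy rule: sort weights descending and place each on the currently
least-loaded locality (ties to the lowest locality id), which guarantees a
makespan within (4/3 - 1/(3m)) of optimal.  A locality whose accumulated
load exceeds the capacity threshold — the mean load per locality scaled by
a tolerance, default 10% — then sheds *terminal subtree groups* of its most
costly neurons, largest first, to the least-loaded locality until it fits
or nothing terminal remains.

A subtree group is a subtree of the tree-of-subtrees: one subtree plus all
its descendants.  Such groups are the only delegable units because their
removal leaves the rest of the neuron connected, and any delegated group's
single cross-boundary channel necessarily lands on the neuron's home
locality: delegated groups are pairwise disjoint, so no group's parent can
sit inside another delegated group.  The induced inter-locality channel
graph of every neuron is therefore a star centered on its home — transitive
communication (1 → 2 → 3) cannot occur.

Balancing is static, performed once at onset: per-subtree workload is
quasi-constant during a run, so re-balancing would buy little.  Weights come
from the analytic cost model by default, or from the measured protocol
(mean runtime of repeated sample simulations of each subtree).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .decomposition import CostModel, DecompositionPlan, measure_workload


@dataclass(frozen=True)
class SubtreeGroup:
    """A delegable unit: one subtree of the tree-of-subtrees (descendants
    included).  Always terminal: it contains no ancestor of any subtree
    outside the group."""

    root_subtree: int
    subtree_ids: tuple[int, ...]
    cost: float


@dataclass
class NeuronWeight:
    neuron_id: int
    total: float
    groups: list[SubtreeGroup] = field(default_factory=list)


def neuron_weight_from_plan(plan: DecompositionPlan, neuron_id: int,
                            model=None, cost_model: CostModel | None = None
                            ) -> NeuronWeight:
    """Weigh a neuron and enumerate its delegable subtree groups.

    With an analytic cost model (the default) subtree costs recorded in the
    plan are used directly; measured mode re-times each subtree.
    """
    cost_model = cost_model or CostModel()
    if cost_model.mode == "measured":
        if model is None:
            raise ValueError("measured mode needs the neuron model")
        costs = [measure_workload(s, model, cost_model) for s in plan.subtrees]
    else:
        costs = [s.cost for s in plan.subtrees]
    children = [plan.children_of(i) for i in range(plan.n_subtrees)]

    def descendants(i: int) -> list[int]:
        out = [i]
        for c in children[i]:
            out.extend(descendants(c))
        return out

    groups = []
    for s in plan.subtrees:
        if s.parent is None:
            continue  # delegating the root would move the whole neuron
        ids = tuple(sorted(descendants(s.index)))
        groups.append(SubtreeGroup(s.index, ids,
                                   float(sum(costs[i] for i in ids))))
    return NeuronWeight(neuron_id, float(sum(costs)), groups)


def lpt_assign(weights, m: int):
    """Least Processing Time greedy assignment.

    Returns ``(assignment, loads)``: the locality index per weight (in input
    order) and the per-locality accumulated loads.  Weights are sorted
    descending (stable), each placed on the least-loaded locality, ties to
    the lowest locality id.
    """
    if m < 1:
        raise ValueError("need at least one locality")
    weights = list(weights)
    loads = np.zeros(m)
    assignment = [0] * len(weights)
    order = sorted(range(len(weights)), key=lambda i: (-weights[i], i))
    for i in order:
        if weights[i] <= 0:
            raise ValueError("weights must be positive")
        loc = int(np.argmin(loads))  # argmin takes the lowest index on ties
        assignment[i] = loc
        loads[loc] += weights[i]
    return assignment, loads


def compute_locality_threshold(total: float, m: int,
                               tolerance: float = 0.10) -> float:
    """Capacity per locality: mean load scaled by (1 + tolerance)."""
    if m < 1:
        raise ValueError("need at least one locality")
    return (total / m) * (1.0 + tolerance)


@dataclass
class Assignment:
    """Placement of neurons (and delegated terminal groups) on localities."""

    home: dict[int, int]
    delegated: list[tuple[int, SubtreeGroup, int]] = field(default_factory=list)
    loads: np.ndarray = field(default_factory=lambda: np.zeros(1))
    threshold: float = 0.0

    @property
    def split_count(self) -> int:
        return len(self.delegated)

    def imbalance(self) -> float:
        mean = float(np.mean(self.loads))
        if mean == 0:
            return 0.0
        return float((self.loads.max() - mean) / mean)

    def locality_of_subtree(self, neuron_id: int, subtree_id: int) -> int:
        for nid, group, loc in self.delegated:
            if nid == neuron_id and subtree_id in group.subtree_ids:
                return loc
        return self.home[neuron_id]

    def to_json(self) -> str:
        return json.dumps({
            "home": {str(k): v for k, v in self.home.items()},
            "delegated": [{"neuron": nid,
                           "subtrees": list(g.subtree_ids),
                           "cost": g.cost, "locality": loc}
                          for nid, g, loc in self.delegated],
            "loads": self.loads.tolist(),
            "threshold": self.threshold,
        }, indent=1)


def balance_with_splitting(neuron_weights: list[NeuronWeight], m: int,
                           tolerance: float = 0.10,
                           threshold: float | None = None) -> Assignment:
    """LPT over whole neurons, then terminal-group shedding (see module doc)."""
    totals = [w.total for w in neuron_weights]
    if threshold is None:
        threshold = compute_locality_threshold(sum(totals), m, tolerance)
    home_list, loads = lpt_assign(totals, m) if neuron_weights else ([], np.zeros(m))
    home = {w.neuron_id: home_list[i] for i, w in enumerate(neuron_weights)}
    resident = {w.neuron_id: w.total for w in neuron_weights}
    taken: dict[int, set[int]] = {w.neuron_id: set() for w in neuron_weights}
    delegated: list[tuple[int, SubtreeGroup, int]] = []

    for loc in sorted(range(m), key=lambda j: -loads[j]):
        while loads[loc] > threshold + 1e-12:
            moved = False
            # most costly resident neuron first, then its largest free group
            for w in sorted((w for w in neuron_weights if home[w.neuron_id] == loc),
                            key=lambda w: -resident[w.neuron_id]):
                free = [g for g in w.groups
                        if not (set(g.subtree_ids) & taken[w.neuron_id])]
                if not free:
                    continue
                group = max(free, key=lambda g: (g.cost, -g.root_subtree))
                target = int(np.argmin(loads))
                if target == loc:
                    break
                loads[loc] -= group.cost
                loads[target] += group.cost
                resident[w.neuron_id] -= group.cost
                taken[w.neuron_id].update(group.subtree_ids)
                delegated.append((w.neuron_id, group, target))
                moved = True
                break
            if not moved:
                if loads[loc] > threshold + 1e-12:
                    warnings.warn(
                        f"locality {loc} exceeds the capacity threshold and "
                        "has no terminal group left to delegate",
                        RuntimeWarning, stacklevel=2)
                break

    return Assignment(home, delegated, loads, threshold)
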