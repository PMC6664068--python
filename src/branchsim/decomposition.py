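"""Workload-threshold decomposition of a compartment tree into subtrees.

A neuron is split into a *tree of subtrees*: a greedy root-to-leaves
traversal grows the current subtree along the depth-first compartment
ordering while its accumulated workload stays at or below a threshold.  A
compartment that would push the total past the threshold starts the next
subtree.  At a bifurcation the branches below are either absorbed wholesale
(when everything under the bifurcation still fits the budget) or each child
branch starts an independent subtree — all-or-none, which guarantees that a
subtree only ever attaches its root to a *leaf* compartment of its parent
subtree, so cross-subtree synchronization is confined to terminal
compartment connections.

Two kinds of subtree may legitimately miss the threshold: a forced
singleton (one compartment whose own cost exceeds the threshold) and a
terminal leftover (a leaf-ward run that simply has no more compartments to
aggregate).  The validator flags both without failing them.

The threshold for a neuron with total workload ``runtime`` executed on
``cores`` compute cores is ``k·runtime/cores``: at most ``1/k`` subtrees'
worth of work per core, with ``k`` trading multi-core balance against
per-subtree vector width.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentTree, MorphologyError, NeuronModel

#: Empirically useful values of the threshold scale factor k by core count;
#: intermediate core counts are linearly interpolated, >16 cores use 2.0.
K_TABLE = {2: 0.8, 4: 1.0, 8: 1.5, 16: 1.8}


def default_k(cores_count: int) -> float:
    if cores_count <= 1:
        return 1.0
    if cores_count > 16:
        return 2.0
    xs = sorted(K_TABLE)
    return float(np.interp(cores_count, xs, [K_TABLE[x] for x in xs]))


def max_work(runtime_n: float, cores_count: int, k: float) -> float:
    """Per-subtree workload threshold k·runtime/cores."""
    if runtime_n <= 0 or cores_count < 1 or k <= 0:
        raise ValueError("runtime, cores_count and k must be positive")
    return k * runtime_n / cores_count


@dataclass
class Subtree:
    """A connected cluster of compartments executed as one task."""

    index: int
    members: np.ndarray              # global compartment indices, ascending
    parent: int | None = None        # parent subtree index
    parent_comp: int | None = None   # connecting compartment (in parent subtree)
    cost: float = 0.0

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.int64)

    @property
    def root(self) -> int:
        return int(self.members[0])

    def leaves(self, tree: CompartmentTree) -> list[int]:
        """Members with no child member inside this subtree."""
        mem = set(self.members.tolist())
        has_child = set()
        for m in self.members[1:]:
            if int(tree.p[m]) in mem:
                has_child.add(int(tree.p[m]))
        return [int(m) for m in self.members if int(m) not in has_child]


@dataclass
class DecompositionPlan:
    """Tree of subtrees covering a compartment tree."""

    subtrees: list[Subtree]
    n_comps: int
    threshold: float
    k: float | None = None
    cores_count: int | None = None

    @property
    def n_subtrees(self) -> int:
        return len(self.subtrees)

    def children_of(self, index: int) -> list[int]:
        return [s.index for s in self.subtrees if s.parent == index]

    def to_json(self) -> str:
        return json.dumps({
            "n_comps": self.n_comps,
            "threshold": self.threshold,
            "k": self.k,
            "cores_count": self.cores_count,
            "subtrees": [{
                "index": s.index,
                "members": s.members.tolist(),
                "parent": s.parent,
                "parent_comp": s.parent_comp,
                "cost": s.cost,
            } for s in self.subtrees],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecompositionPlan":
        obj = json.loads(text)
        subs = [Subtree(s["index"], np.array(s["members"]), s["parent"],
                        s["parent_comp"], s["cost"]) for s in obj["subtrees"]]
        return cls(subs, obj["n_comps"], obj["threshold"], obj.get("k"),
                   obj.get("cores_count"))


def cluster(tree: CompartmentTree, costs, threshold: float) -> DecompositionPlan:
    """Greedy recursive clustering of a tree into subtrees (see module doc)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    costs = np.asarray(costs, dtype=np.float64)
    if costs.shape != (tree.n,) or np.any(costs <= 0):
        raise ValueError("costs must be positive, one per compartment")

    children = tree.children_lists()
    # workload of the whole subtree under each compartment (post-order sum)
    desc_cost = costs.copy()
    for i in range(tree.n - 1, 0, -1):
        desc_cost[tree.p[i]] += desc_cost[i]

    def descendants_of(node: int) -> list[int]:
        out = []
        todo = list(children[node])
        while todo:
            c = todo.pop()
            out.append(c)
            todo.extend(children[c])
        out.sort()
        return out

    subtrees: list[Subtree] = []
    # (start compartment, parent subtree index, attaching compartment)
    stack: list[tuple[int, int | None, int | None]] = [(0, None, None)]
    while stack:
        start, parent_sub, attach = stack.pop()
        index = len(subtrees)
        members: list[int] = []
        acc = 0.0
        cur = start
        while True:
            c_cost = float(costs[cur])
            if members and acc + c_cost > threshold:
                # close before cur; cur roots a new subtree below members[-1]
                stack.append((cur, index, members[-1]))
                break
            members.append(cur)
            acc += c_cost
            ch = children[cur]
            if not ch:
                break
            if len(ch) == 1:
                cur = ch[0]
                continue
            rem = float(desc_cost[cur] - costs[cur])  # all descendants of cur
            if acc + rem <= threshold:
                members.extend(descendants_of(cur))
                acc += rem
                break
            for child in reversed(ch):
                stack.append((child, index, cur))
            break
        subtrees.append(Subtree(index, np.array(members), parent_sub, attach,
                                cost=acc))
    return DecompositionPlan(subtrees, tree.n, threshold)


@dataclass
class CostModel:
    """How per-compartment workload is estimated.

    ``analytic``: cost = base + Σ mechanism instance costs — deterministic,
    the default for planning and tests.  ``measured``: mean wall time of
    ``reps`` repetitions of a ``sample_tstop`` ms stepping kernel on the
    subtree's vectorized (structure-of-arrays) block.
    """

    mode: str = "analytic"
    base: float = 1.0
    mech_costs: dict[str, float] = field(default_factory=dict)
    default_mech_cost: float = 1.0
    reps: int = 10
    sample_tstop: float = 100.0
    dt: float = 0.025

    def compartment_costs(self, model: NeuronModel) -> np.ndarray:
        if self.base <= 0:
            raise ValueError("base cost must be positive")
        costs = np.full(model.tree.n, self.base)
        for pl in model.placements:
            c = self.mech_costs.get(pl.mech, self.default_mech_cost)
            np.add.at(costs, pl.comps, c)
        return costs


def measure_workload(subtree: Subtree, model: NeuronModel,
                     cost_model: CostModel) -> float:
    """Workload of one subtree under the given cost model.

    Analytic mode sums per-compartment costs.  Measured mode builds the
    subtree's structure-of-arrays block and times ``reps`` repetitions of a
    ``sample_tstop`` ms isolated stepping kernel (boundary voltages held at
    the initial value), returning the mean wall time in seconds.
    """
    if cost_model.mode == "analytic":
        costs = cost_model.compartment_costs(model)
        return float(costs[subtree.members].sum())
    if cost_model.mode != "measured":
        raise ValueError(f"unknown cost model mode {cost_model.mode!r}")
    from .layout import build_layout
    from .runtime import step_block_isolated

    n_steps = max(1, int(round(cost_model.sample_tstop / cost_model.dt)))
    times = []
    for _ in range(cost_model.reps):
        block = build_layout(subtree, model)
        t0 = _time.perf_counter()
        for s in range(n_steps):
            step_block_isolated(block, cost_model.dt)
        times.append(_time.perf_counter() - t0)
    return float(np.mean(times))


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)   # permitted exceptions

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def validate_plan(plan: DecompositionPlan, tree: CompartmentTree) -> ValidationReport:
    """Check partition, connectivity, attachment and threshold invariants."""
    violations: list[str] = []
    flagged: list[str] = []

    seen: dict[int, int] = {}
    for s in plan.subtrees:
        for m in s.members.tolist():
            if m in seen:
                violations.append(
                    f"compartment {m} in subtrees {seen[m]} and {s.index}")
            seen[m] = s.index
    if set(seen) != set(range(tree.n)):
        missing = sorted(set(range(tree.n)) - set(seen))[:5]
        violations.append(f"cover violation; missing compartments {missing}")

    for s in plan.subtrees:
        mem = set(s.members.tolist())
        for m in s.members.tolist():
            if m == s.root:
                continue
            if int(tree.p[m]) not in mem:
                violations.append(
                    f"subtree {s.index}: member {m} disconnected from root")
        if s.parent is None:
            if s.root != 0:
                violations.append(f"subtree {s.index}: no parent but root != 0")
            continue
        q = int(tree.p[s.root])
        parent_sub = plan.subtrees[s.parent]
        if s.parent_comp != q:
            violations.append(
                f"subtree {s.index}: recorded attachment {s.parent_comp} "
                f"differs from tree parent {q}")
        if q not in set(parent_sub.members.tolist()):
            violations.append(
                f"subtree {s.index}: root attaches outside parent subtree")
        elif q not in parent_sub.leaves(tree):
            violations.append(
                f"subtree {s.index}: attaches to non-leaf compartment {q} "
                f"of subtree {parent_sub.index}")

    for s in plan.subtrees:
        if s.cost > plan.threshold + 1e-9:
            if s.members.size == 1:
                flagged.append(
                    f"subtree {s.index}: forced singleton above threshold")
            else:
                violations.append(
                    f"subtree {s.index}: cost {s.cost:.3g} exceeds threshold")
    return ValidationReport(not violations, violations, flagged)


def plan_for_model(model: NeuronModel, cost_model: CostModel | None = None,
                   cores_count: int = 1, k: float | None = None,
                   threshold: float | None = None) -> DecompositionPlan:
    """Convenience: per-compartment costs → threshold → clustered plan."""
    cost_model = cost_model or CostModel()
    costs = cost_model.compartment_costs(model)
    if threshold is None:
        if k is None:
            k = default_k(cores_count)
        threshold = max_work(float(costs.sum()), cores_count, k)
    plan = cluster(model.tree, costs, threshold)
    plan.k = k
    plan.cores_count = cores_count
    report = validate_plan(plan, model.tree)
    if not report.ok:
        raise MorphologyError("internal error: invalid plan: "
                              + "; ".join(report.violations[:3]))
    return plan
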