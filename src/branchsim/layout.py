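"""Structure-of-arrays memory image of one subtree.

A :class:`SubtreeBlock` serializes a subtree for batch (vector) execution:
local solver arrays with compartments renumbered 0..n-1 (preserving the
depth-first order, so local parent indices still satisfy p[i] < i), and,
per mechanism type, one contiguous array per state variable and per
parameter covering all of that type's instances in the subtree, ordered by
local compartment index.  Arrays are padded to a configurable vector width
with inert lanes: padded conductances are zero and padded lanes point at
local compartment 0, so they contribute exactly 0 to every per-compartment
sum and never alter the simulation.

The contract is layout and summation order, not instruction selection:
contiguous arrays let numpy (or any SIMD backend) batch the state updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .groups import TypeGroup, build_type_groups
from .hines import SolverArrays
from .mechanisms import Mechanism
from .morphology import MorphologyError, NeuronModel
from .stepping import EventQueue


@dataclass
class MechGroupBlock:
    """Contiguous per-type arrays for one subtree (padded to vector width)."""

    mech: Mechanism
    comp_local: np.ndarray            # physical length; padding lanes → 0
    params: dict[str, np.ndarray]
    state: dict[str, np.ndarray]
    logical: int                      # number of real instances
    physical: int                     # padded length

    def current(self, v_local: np.ndarray, t: float):
        vi = v_local[self.comp_local]
        return self.mech.current(self.params, self.state, vi, t)

    def update_state(self, v_local: np.ndarray, dt: float, euler=False) -> None:
        vi = v_local[self.comp_local]
        self.mech.update_state(self.params, self.state, vi, dt, euler=euler)


@dataclass
class SubtreeBlock:
    """SoA memory image of one subtree plus its runtime bookkeeping."""

    subtree_index: int
    global_index: np.ndarray          # local → global compartment map
    arr: SolverArrays                 # local solver arrays
    C: np.ndarray                     # nF, local
    groups: list[MechGroupBlock]
    handle_slots: dict[tuple[int, int], tuple[int, int]]  # handle → (group, slot)
    vector_width: int
    parent_v_cache: float | None = None  # voltage of parent connecting comp
    neuron_id: int = 0
    is_soma_block: bool = False
    events: EventQueue = field(default_factory=EventQueue)
    step: int = 0
    spike_times: list[float] = field(default_factory=list)
    trace: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.global_index.size)

    def local_index(self, global_comp: int) -> int:
        i = int(np.searchsorted(self.global_index, global_comp))
        if i >= self.n or self.global_index[i] != global_comp:
            raise MorphologyError(
                f"compartment {global_comp} not in subtree {self.subtree_index}")
        return i


def _pad(values: np.ndarray, physical: int, fill: float) -> np.ndarray:
    out = np.full(physical, fill, dtype=np.float64)
    out[: values.size] = values
    return out


def build_layout(subtree, model: NeuronModel,
                 groups: list[TypeGroup] | None = None,
                 vector_width: int = 8, neuron_id: int = 0) -> SubtreeBlock:
    """Build the SoA block of one subtree of ``model``.

    ``groups`` are the neuron-level canonical type groups; they are rebuilt
    when not supplied.  Instances referencing compartments outside the
    subtree are simply not part of this block; an instance list that cannot
    be restricted consistently raises.  Default vector width is 8 lanes
    (512-bit registers at double precision).
    """
    if vector_width < 1:
        raise ValueError("vector_width must be >= 1")
    if groups is None:
        groups, _ = build_type_groups(model)
    members = np.asarray(subtree.members, dtype=np.int64)
    if members.size == 0:
        raise MorphologyError("empty subtree")
    tree = model.tree

    # Local re-indexing preserving DFS order.
    order = np.argsort(members, kind="stable")
    members_sorted = members[order]
    gl_to_loc = {int(g): i for i, g in enumerate(members_sorted)}

    n = members_sorted.size
    p_loc = np.empty(n, dtype=np.int64)
    has_parent = subtree.parent is not None
    inv_r = np.zeros(n)
    for i, g in enumerate(members_sorted):
        gp = int(tree.p[g])
        if i == 0:
            p_loc[0] = -1
            if has_parent:
                inv_r[0] = 1.0 / tree.r[g]
        else:
            if gp not in gl_to_loc:
                raise MorphologyError(
                    f"member {int(g)} has parent outside the subtree")
            p_loc[i] = gl_to_loc[gp]
            inv_r[i] = 1.0 / tree.r[g]
    coef = -inv_r
    arr = SolverArrays(p_loc, coef.copy(), coef.copy(), np.zeros(n),
                       np.zeros(n), np.full(n, float(model.v_init)),
                       has_parent=has_parent)

    member_set = set(members_sorted.tolist())
    blocks: list[MechGroupBlock] = []
    handle_slots: dict[tuple[int, int], tuple[int, int]] = {}
    for g in groups:
        keep = [j for j in range(g.n_instances) if int(g.comps[j]) in member_set]
        if not keep:
            continue
        logical = len(keep)
        physical = int(math.ceil(logical / vector_width) * vector_width)
        comp_local = np.zeros(physical, dtype=np.int64)
        comp_local[:logical] = [gl_to_loc[int(g.comps[j])] for j in keep]
        params = {}
        for k, a in g.params.items():
            fill = g.mech.pad_values.get(k, 0.0)
            params[k] = _pad(a[keep], physical, fill)
        state = {k: _pad(a[keep], physical, 0.0) for k, a in g.state.items()}
        gi = len(blocks)
        for slot, j in enumerate(keep):
            handle_slots[g.handles[j]] = (gi, slot)
        blocks.append(MechGroupBlock(g.mech, comp_local, params, state,
                                     logical, physical))

    return SubtreeBlock(
        subtree_index=getattr(subtree, "index", 0),
        global_index=members_sorted,
        arr=arr,
        C=tree.C[members_sorted].copy(),
        groups=blocks,
        handle_slots=handle_slots,
        vector_width=vector_width,
        parent_v_cache=float(model.v_init) if has_parent else None,
        neuron_id=neuron_id,
        is_soma_block=(int(members_sorted[0]) == 0),
    )


def gather_voltages(blocks: list[SubtreeBlock], n_comps: int) -> np.ndarray:
    """Scatter block voltages back to the global compartment vector."""
    v = np.full(n_comps, np.nan)
    for b in blocks:
        v[b.global_index] = b.arr.v
    return v


def gather_states(blocks: list[SubtreeBlock]) -> dict[str, dict[int, float]]:
    """Map '<mech>.<state>' → {global compartment: value} (real lanes only)."""
    out: dict[str, dict[int, float]] = {}
    for b in blocks:
        for g in b.groups:
            for name, a in g.state.items():
                key = f"{g.mech.name}.{name}"
                d = out.setdefault(key, {})
                for j in range(g.logical):
                    d[int(b.global_index[g.comp_local[j]])] = float(a[j])
    return out


def scatter_gather_roundtrip(blocks: list[SubtreeBlock],
                             model: NeuronModel) -> bool:
    """True iff mapping block values through the index maps reproduces the
    original model's per-instance values exactly (bijection check)."""
    groups, handle_map = build_type_groups(model)
    v = gather_voltages(blocks, model.tree.n)
    if not np.all(np.isfinite(v)):
        return False
    block_of_handle = {}
    for bi, b in enumerate(blocks):
        for h, (gi, slot) in b.handle_slots.items():
            block_of_handle[h] = (bi, gi, slot)
    for g in groups:
        for j in range(g.n_instances):
            h = g.handles[j]
            if h not in block_of_handle:
                return False
            bi, gi, slot = block_of_handle[h]
            blk = blocks[bi].groups[gi]
            if int(blocks[bi].global_index[blk.comp_local[slot]]) != int(g.comps[j]):
                return False
            for k, a in g.params.items():
                if blk.params[k][slot] != a[j]:
                    return False
    return True
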