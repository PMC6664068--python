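"""Grouping of mechanism instances by type.

Both execution engines (the per-instance reference engine and the
structure-of-arrays subtree engine) iterate mechanism instances in the same
canonical order so their per-compartment current sums are accumulated in an
identical sequence: types in order of first appearance among the model's
placements, instances within a type sorted by (compartment, placement,
instance).  A *handle* ``(placement_index, instance_index)`` identifies one
instance — synaptic events are addressed to handles — and the handle map
translates handles to (group, slot) positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanisms import Mechanism, get_mechanism


@dataclass
class TypeGroup:
    """All instances of one mechanism type on one neuron (or one subtree)."""

    mech: Mechanism
    comps: np.ndarray                    # compartment index per instance
    params: dict[str, np.ndarray]
    state: dict[str, np.ndarray] = field(default_factory=dict)
    handles: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return int(self.comps.size)

    def init_state(self, v_init: float) -> None:
        self.state = {k: np.asarray(s, dtype=np.float64)
                      for k, s in self.mech.init_state(self.params, v_init).items()}


def build_type_groups(model) -> tuple[list[TypeGroup], dict[tuple[int, int], tuple[int, int]]]:
    """Canonical type groups for a :class:`~branchsim.morphology.NeuronModel`.

    Returns ``(groups, handle_map)`` where ``handle_map[(placement, inst)] =
    (group_index, slot)``.  Group state is initialized at ``model.v_init``.
    """
    type_order: list[str] = []
    per_type: dict[str, list[tuple[int, int, int]]] = {}
    for pi, pl in enumerate(model.placements):
        if pl.mech not in per_type:
            per_type[pl.mech] = []
            type_order.append(pl.mech)
        for j in range(pl.comps.size):
            per_type[pl.mech].append((int(pl.comps[j]), pi, j))

    groups: list[TypeGroup] = []
    handle_map: dict[tuple[int, int], tuple[int, int]] = {}
    for name in type_order:
        mech = get_mechanism(name)
        entries = sorted(per_type[name])
        comps = np.array([c for c, _, _ in entries], dtype=np.int64)
        params: dict[str, np.ndarray] = {}
        pnames = set()
        for _, pi, _ in entries:
            pnames.update(model.placements[pi].params.keys())
        defaults = {"e": {"expsyn": 0.0}.get(name, -65.0), "ena": 50.0,
                    "ek": -77.0, "tau": 2.0, "onset": 0.0, "dur": 0.0}
        for par in mech.param_names:
            if par not in pnames and par not in defaults:
                raise KeyError(f"mechanism {name!r} missing parameter {par!r}")
        for par in mech.param_names:
            vals = np.empty(len(entries))
            for k, (_, pi, j) in enumerate(entries):
                pl = model.placements[pi]
                if par in pl.params:
                    vals[k] = pl.params[par][j]
                else:
                    vals[k] = defaults[par]
            params[par] = vals
        group = TypeGroup(mech, comps, params,
                          handles=[(pi, j) for _, pi, j in entries])
        group.init_state(model.v_init)
        gi = len(groups)
        for slot, (_, pi, j) in enumerate(entries):
            handle_map[(pi, j)] = (gi, slot)
        groups.append(group)
    return groups, handle_map
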