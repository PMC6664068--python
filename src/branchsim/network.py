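"""Network description: neurons, synaptic connections, stimuli.

The on-disk format is a JSON dialect documented in the README:

.. code-block:: json

    {
      "neurons": [
        {"id": 0, "swc": "...swc text...", "v_init": -65.0,
         "max_comp_len": 20.0,
         "mechanisms": [
           {"mech": "leak", "where": "all",
            "params": {"g_density": 0.0003, "e": -65.0}},
           {"mech": "hh", "where": "soma",
            "params": {"gna_density": 0.12, "gk_density": 0.036}}
         ]}
      ],
      "connections": [
        {"source": 0, "target": 1, "delay": 1.0, "weight": 0.005,
         "comp": 3, "e": 0.0, "tau": 2.0}
      ],
      "stimuli": [
        {"neuron": 0, "comp": 0, "amp": 0.3, "onset": 2.0, "dur": 10.0}
      ]
    }

Each connection creates one exponential synapse instance on the target
neuron; the connection's handle addresses that instance for event delivery.
Morphologies may be inlined (``"swc"``) or referenced (``"swc_file"``,
resolved relative to the JSON file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mechanisms import ConfigurationError
from .morphology import NeuronModel, attach_density, discretize, parse_swc


@dataclass
class Connection:
    source: int
    target: int
    delay: float      # ms; must be >= the network's communication step
    weight: float     # µS
    conn_id: int
    handle: tuple[int, int]  # synapse instance on the target neuron


@dataclass
class Network:
    neurons: list[NeuronModel]
    connections: list[Connection] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def min_delay(self) -> float | None:
        if not self.connections:
            return None
        return min(c.delay for c in self.connections)

    def connections_by_source(self) -> dict[int, list[Connection]]:
        out: dict[int, list[Connection]] = {i: [] for i in range(self.n_neurons)}
        for c in self.connections:
            out[c.source].append(c)
        return out

    def validate(self, t_synch: float | None = None) -> None:
        for c in self.connections:
            if c.delay <= 0:
                raise ConfigurationError(
                    f"connection {c.conn_id}: delay must be positive")
            if t_synch is not None and c.delay < t_synch - 1e-12:
                raise ConfigurationError(
                    f"connection {c.conn_id}: delay {c.delay} ms is shorter "
                    f"than the communication step {t_synch} ms")
            if not (0 <= c.source < self.n_neurons
                    and 0 <= c.target < self.n_neurons):
                raise ConfigurationError(
                    f"connection {c.conn_id}: neuron id out of range")
        for m in self.neurons:
            m.validate()


def _resolve_comps(model: NeuronModel, where) -> np.ndarray:
    if where == "all":
        return np.arange(model.tree.n)
    if where == "soma":
        return np.array([0])
    if where == "dendrites":
        return np.arange(1, model.tree.n)
    return np.atleast_1d(np.asarray(where, dtype=np.int64))


def neuron_from_spec(spec: dict, base_dir: Path | None = None) -> NeuronModel:
    """Build a :class:`NeuronModel` from one entry of the ``neurons`` list."""
    if "swc" in spec:
        graph = parse_swc(spec["swc"])
    elif "swc_file" in spec:
        path = Path(spec["swc_file"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        graph = parse_swc(path.read_text())
    else:
        raise ConfigurationError("neuron spec needs 'swc' or 'swc_file'")
    tree = discretize(graph,
                      max_len=spec.get("max_comp_len", 20.0),
                      ra=spec.get("ra", 100.0),
                      cm=spec.get("cm", 1.0))
    model = NeuronModel(tree, v_init=spec.get("v_init", -65.0))
    for mspec in spec.get("mechanisms", []):
        comps = _resolve_comps(model, mspec.get("where", "all"))
        params = dict(mspec.get("params", {}))
        if any(k.endswith("_density") for k in params):
            attach_density(model, mspec["mech"], comps, **params)
        else:
            model.add_mechanism(mspec["mech"], comps, **params)
    return model


def load_network(obj_or_path, base_dir: Path | None = None) -> Network:
    """Load a network from a JSON dict, JSON text, or a file path."""
    if isinstance(obj_or_path, dict):
        obj = obj_or_path
    else:
        path = Path(obj_or_path)
        if path.exists():
            base_dir = path.parent
            obj = json.loads(path.read_text())
        else:
            obj = json.loads(obj_or_path)

    specs = sorted(obj.get("neurons", []), key=lambda s: s.get("id", 0))
    ids = [s.get("id", i) for i, s in enumerate(specs)]
    if ids != list(range(len(specs))):
        raise ConfigurationError("neuron ids must be 0..n-1")
    neurons = [neuron_from_spec(s, base_dir) for s in specs]

    for st in obj.get("stimuli", []):
        neurons[st["neuron"]].add_mechanism(
            "iclamp", [st.get("comp", 0)], amp=st["amp"],
            onset=st.get("onset", 0.0), dur=st["dur"])

    connections: list[Connection] = []
    for k, c in enumerate(obj.get("connections", [])):
        target = neurons[c["target"]]
        comp = int(c.get("comp", 0))
        handle = target.add_mechanism("expsyn", [comp],
                                      e=c.get("e", 0.0), tau=c.get("tau", 2.0))
        connections.append(Connection(int(c["source"]), int(c["target"]),
                                      float(c["delay"]), float(c["weight"]),
                                      conn_id=k, handle=handle))
    net = Network(neurons, connections)
    net.validate()
    return net
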