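"""Synthetic morphologies, networks, and canonical test models.

Random branched morphologies emulate the heterogeneity of reconstructed
dendritic trees: log-normal section lengths, geometric branching (each
section end bifurcates with a fixed probability), and diameter taper from
root to tips.  Parameters are knobs, not claims about any particular
species; their defaults produce trees whose compartment counts (at the
default 20 µm discretization) match the recipe target.  All randomness
flows through one seeded generator per recipe: the same seed yields
byte-identical SWC output.

Networks are directed Erdős–Rényi graphs without self-connections; every
synaptic delay is the configured hard minimum plus a non-negative jitter,
so the minimum delay — and hence the communication step — is controlled
exactly.

Also provided are hand-sized canonical models used across the test-suite
and docs: a passive single compartment with known RC response, and a
Hodgkin-Huxley soma (1 nF, classic squid-axon densities scaled to the
membrane area) for spike-threshold experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentTree, NeuronModel


@dataclass
class MorphologyRecipe:
    """Parameters of one random branched morphology."""

    target_compartments: int = 60   # at max_comp_len = 20 µm
    branch_prob: float = 0.35       # bifurcation probability per section end
    n_primary: int = 1              # dendrites leaving the soma
    section_len_mean: float = 60.0  # µm (mean of the log-normal)
    section_len_sigma: float = 0.4  # σ of log(length)
    diam_root: float = 2.0          # µm, primary dendrite diameter
    taper: float = 0.85             # child/parent diameter ratio
    diam_min: float = 0.4           # µm
    soma_radius: float = 10.0       # µm
    sample_spacing: float = 10.0    # µm between SWC samples
    max_comp_len: float = 20.0      # µm, reference discretization
    seed: int = 0


def generate_morphology(recipe: MorphologyRecipe) -> str:
    """Deterministically generate a well-formed SWC morphology."""
    if recipe.target_compartments < 1:
        raise ValueError("target_compartments must be >= 1")
    if recipe.n_primary < 1:
        raise ValueError("need at least one primary dendrite")
    rng = np.random.default_rng(recipe.seed)
    lines = [f"1 1 0.000 0.000 0.000 {recipe.soma_radius:.3f} -1"]
    next_id = 2
    target_length = recipe.target_compartments * recipe.max_comp_len
    total_length = 0.0

    mu = math.log(recipe.section_len_mean) - 0.5 * recipe.section_len_sigma ** 2

    def unit(vec):
        norm = math.sqrt(sum(c * c for c in vec))
        return tuple(c / norm for c in vec)

    # FIFO of growth tips: (parent sample id, position, direction, diameter)
    tips = []
    primaries = 0

    def new_primary():
        nonlocal primaries
        angle = 2.399963  # golden angle: successive primaries spread out
        direction = (math.cos(primaries * angle), math.sin(primaries * angle), 0.0)
        pos = tuple(recipe.soma_radius * c for c in direction)
        tips.append((1, pos, direction, recipe.diam_root))
        primaries += 1

    for _ in range(recipe.n_primary):
        new_primary()

    while total_length < target_length:
        if not tips:
            new_primary()  # geometric branching died out; regrow
        parent, pos, direction, diam = tips.pop(0)
        sec_len = float(rng.lognormal(mu, recipe.section_len_sigma))
        # soma-attached sections need >= 2 samples to carry their own length
        n_samples = max(2 if parent == 1 else 1,
                        math.ceil(sec_len / recipe.sample_spacing))
        step = sec_len / n_samples
        radius = max(diam, 2 * recipe.diam_min) / 2.0
        for _ in range(n_samples):
            jitter = rng.normal(0.0, 0.2, size=3)
            direction = unit(tuple(d + j for d, j in zip(direction, jitter)))
            pos = tuple(p + step * d for p, d in zip(pos, direction))
            lines.append(f"{next_id} 3 {pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} "
                         f"{radius:.3f} {parent}")
            parent = next_id
            next_id += 1
        total_length += sec_len
        if rng.random() < recipe.branch_prob:
            child_diam = max(recipe.diam_min, diam * recipe.taper)
            for sign in (1.0, -1.0):
                perp = unit((-direction[1], direction[0], 0.3 * sign))
                child_dir = unit(tuple(0.8 * d + 0.6 * sign * q
                                       for d, q in zip(direction, perp)))
                tips.append((parent, pos, child_dir, child_diam))
        elif recipe.branch_prob == 0.0:
            tips.append((parent, pos, direction, diam))  # unbranched cable
    return "\n".join(lines) + "\n"


@dataclass
class NetworkRecipe:
    """Parameters of one random network built over given morphologies."""

    n_neurons: int = 10
    p_connect: float = 0.15
    min_delay: float = 1.0          # ms, hard minimum
    delay_jitter: float = 1.0       # ms, mean of exponential extra delay
    weight_mean: float = 0.01       # µS
    weight_sigma: float = 0.5       # σ of log(weight)
    stim_fraction: float = 0.3      # fraction of neurons receiving a stimulus
    stim_amp: float = 0.4           # nA
    stim_onset: float = 1.0         # ms
    stim_dur: float = 10.0          # ms
    leak_density: float = 0.0003    # S/cm²
    leak_e: float = -65.0           # mV
    gna_density: float = 0.12       # S/cm², soma
    gk_density: float = 0.036       # S/cm², soma
    synapse_tau: float = 2.0        # ms
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in [0, 1]")
        if self.min_delay <= 0:
            raise ValueError("min_delay must be positive")


def generate_network(recipe: NetworkRecipe,
                     morphologies: list[str]) -> dict:
    """Generate a network JSON object over the given SWC morphologies.

    Morphologies are assigned round-robin; connection delays are
    ``min_delay`` plus exponential jitter so the configured minimum is the
    network's exact minimum when jitter is zero, and a hard lower bound
    otherwise.  Reproducible per seed.
    """
    if not morphologies:
        raise ValueError("need at least one morphology")
    rng = np.random.default_rng(recipe.seed)
    neurons = []
    for i in range(recipe.n_neurons):
        neurons.append({
            "id": i,
            "swc": morphologies[i % len(morphologies)],
            "v_init": -65.0,
            "mechanisms": [
                {"mech": "leak", "where": "all",
                 "params": {"g_density": recipe.leak_density,
                            "e": recipe.leak_e}},
                {"mech": "hh", "where": "soma",
                 "params": {"gna_density": recipe.gna_density,
                            "gk_density": recipe.gk_density}},
            ],
        })
    connections = []
    lw_mu = math.log(recipe.weight_mean) - 0.5 * recipe.weight_sigma ** 2
    for src in range(recipe.n_neurons):
        for dst in range(recipe.n_neurons):
            if src == dst:
                continue
            if rng.random() < recipe.p_connect:
                delay = recipe.min_delay
                if recipe.delay_jitter > 0:
                    delay += float(rng.exponential(recipe.delay_jitter))
                connections.append({
                    "source": src, "target": dst,
                    "delay": round(delay, 6),
                    "weight": round(float(rng.lognormal(lw_mu,
                                                        recipe.weight_sigma)), 8),
                    "comp": 0, "e": 0.0, "tau": recipe.synapse_tau,
                })
    n_stim = math.ceil(recipe.stim_fraction * recipe.n_neurons)
    stimuli = [{"neuron": i, "comp": 0, "amp": recipe.stim_amp,
                "onset": recipe.stim_onset, "dur": recipe.stim_dur}
               for i in range(n_stim)]
    return {"neurons": neurons, "connections": connections, "stimuli": stimuli}


def network_json_text(obj: dict) -> str:
    return json.dumps(obj, indent=1)


# ---------------------------------------------------------------------------
# Canonical hand-sized models


def single_compartment_tree(C: float = 1.0, length: float = 100.0,
                            diam: float = 100.0) -> CompartmentTree:
    """One isolated compartment with an explicitly chosen capacitance (nF)."""
    tree = CompartmentTree(np.array([-1]), np.array([length]),
                           np.array([diam]), np.array([1.0]),
                           np.array([math.inf]))
    tree.C = np.array([float(C)])
    return tree


def passive_single_compartment(C: float = 1.0, g: float = 0.1,
                               e: float = -65.0, amp: float = 0.0,
                               onset: float = 0.0, dur: float = 0.0,
                               v_init: float | None = None) -> NeuronModel:
    """Passive RC compartment: τ = C/g, steady state e + amp/g under current.

    Defaults give τ = 10 ms and a +5 mV steady-state deflection for a
    0.5 nA step.
    """
    model = NeuronModel(single_compartment_tree(C),
                        v_init=e if v_init is None else v_init)
    model.add_mechanism("leak", [0], g=g, e=e)
    if amp != 0.0:
        model.add_mechanism("iclamp", [0], amp=amp, onset=onset, dur=dur)
    return model


def hh_soma_model(C: float = 1.0, amp: float = 10.0, onset: float = 2.0,
                  dur: float = 5.0, leak_e: float = -54.3) -> NeuronModel:
    """Classic Hodgkin-Huxley soma scaled to a C nF membrane.

    Densities 120/36/0.3 mS/cm² (Na/K/leak) over the membrane area implied
    by C at 1 µF/cm² give absolute conductances 120·C, 36·C and 0.3·C µS.
    A 10 nA, 5 ms pulse is suprathreshold.
    """
    model = NeuronModel(single_compartment_tree(C), v_init=-65.0)
    model.add_mechanism("leak", [0], g=0.3 * C, e=leak_e)
    model.add_mechanism("hh", [0], gna=120.0 * C, gk=36.0 * C,
                        ena=50.0, ek=-77.0)
    if amp != 0.0:
        model.add_mechanism("iclamp", [0], amp=amp, onset=onset, dur=dur)
    return model


def random_solver_tree(n: int, rng: np.random.Generator):
    """A random DFS-numbered tree plus diagonally dominant solver
    coefficients (a = b = -1/r with random positive r, d dominant)."""
    from .hines import SolverArrays

    p = np.empty(n, dtype=np.int64)
    p[0] = -1
    for i in range(1, n):
        p[i] = rng.integers(max(0, i - 4), i)  # mostly chain-like, some forks
    r = np.empty(n)
    r[0] = math.inf
    if n > 1:
        r[1:] = rng.uniform(0.5, 50.0, size=n - 1)
    inv = np.zeros(n)
    inv[1:] = 1.0 / r[1:]
    coef = -inv
    arr = SolverArrays(p, coef.copy(), coef.copy(), np.zeros(n), np.zeros(n),
                       np.zeros(n), has_parent=False)
    off = np.zeros(n)
    for i in range(1, n):
        off[i] += inv[i]
        off[p[i]] += inv[i]
    arr.d[:] = off + rng.uniform(0.1, 10.0, size=n)   # strictly dominant
    arr.rhs[:] = rng.normal(0.0, 5.0, size=n)
    return arr
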