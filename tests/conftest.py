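import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "branchsim",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("branchsim")

import branchsim as bs

# Minimal well-formed SWC: soma + one 100 µm dendrite (two samples).
SWC_MINIMAL = """\
1 1 0 0 0 5 -1
2 3 0 0 10 1 1
3 3 0 0 110 1 2
"""

# Same cell with an axon branch that should be discarded at load.
SWC_WITH_AXON = """\
1 1 0 0 0 5 -1
2 3 0 0 10 1 1
3 3 0 0 110 1 2
4 2 0 10 0 0.5 1
5 2 0 60 0 0.5 4
"""

# Y-shaped: soma, two-sample dendrite stem, two two-sample daughter branches.
SWC_Y = """\
1 1 0 0 0 5 -1
2 3 0 0 10 1 1
3 3 0 0 60 1 2
4 3 0 30 90 1 3
5 3 0 60 120 1 4
6 3 0 -30 90 1 3
7 3 0 -60 120 1 6
"""


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_random_model(seed: int, target_comps: int = 30, amp: float = 0.05,
                      hh_soma: bool = True) -> bs.NeuronModel:
    """A random branched neuron with leak everywhere, HH at the soma, and a
    small (subthreshold) soma current step."""
    swc = bs.generate_morphology(
        bs.MorphologyRecipe(target_compartments=target_comps, seed=seed))
    tree = bs.discretize(bs.parse_swc(swc))
    model = bs.NeuronModel(tree)
    bs.attach_density(model, "leak", np.arange(tree.n),
                      g_density=0.0003, e=-65.0)
    if hh_soma:
        bs.attach_density(model, "hh", [0], gna_density=0.12,
                          gk_density=0.036)
    if amp:
        model.add_mechanism("iclamp", [0], amp=amp, onset=1.0, dur=5.0)
    return model


def fig_style_tree() -> tuple[bs.CompartmentTree, np.ndarray, float]:
    """17-compartment morphology with a 2-compartment stem and three
    5-compartment branches; unit costs except the third branch, whose cost
    profile forces it to split in two.  With threshold 5 the greedy
    clustering yields 5 subtrees (stem, two whole branches, 2+3 split)."""
    p = np.array([-1, 0,
                  1, 2, 3, 4, 5,
                  1, 7, 8, 9, 10,
                  1, 12, 13, 14, 15])
    n = p.size
    tree = bs.CompartmentTree(p, np.ones(n) * 20, np.ones(n),
                              np.ones(n) * 0.01,
                              np.concatenate([[np.inf], np.full(n - 1, 10.0)]))
    costs = np.ones(n)
    costs[12:17] = [2, 2, 3, 1, 1]
    return tree, costs, 5.0


def random_tree(rng: np.random.Generator, n: int) -> bs.CompartmentTree:
    """Random topology with p[i] < i (not necessarily DFS-contiguous)."""
    p = np.empty(n, dtype=np.int64)
    p[0] = -1
    for i in range(1, n):
        p[i] = rng.integers(max(0, i - 5), i)
    return bs.CompartmentTree(p, np.full(n, 20.0), np.ones(n),
                              np.full(n, 0.01),
                              np.concatenate([[np.inf],
                                              rng.uniform(1.0, 20.0, n - 1)]))


def two_soma_network(weight: float = 0.5, delay: float = 1.0) -> bs.Network:
    """Neuron 0 (stimulated HH soma) drives neuron 1 through one synapse."""
    a = bs.hh_soma_model(amp=10.0, onset=2.0, dur=5.0)
    b = bs.hh_soma_model(amp=0.0)
    handle = b.add_mechanism("expsyn", [0], e=0.0, tau=2.0)
    conn = bs.Connection(source=0, target=1, delay=delay, weight=weight,
                         conn_id=0, handle=handle)
    return bs.Network([a, b], [conn])


def small_network(n_neurons: int = 10, seed: int = 7,
                  target_comps: int = 40) -> bs.Network:
    morphs = [bs.generate_morphology(
        bs.MorphologyRecipe(target_compartments=target_comps, seed=100 + i))
        for i in range(4)]
    obj = bs.generate_network(
        bs.NetworkRecipe(n_neurons=n_neurons, seed=seed), morphs)
    return bs.load_network(obj)
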