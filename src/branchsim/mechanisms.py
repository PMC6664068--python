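"""Membrane mechanisms: ionic currents, point processes, and gating kinetics.

Every mechanism contributes an outward membrane current ``i`` (nA) and an
instantaneous conductance ``g`` (µS) per instance; the solver sums both per
compartment.  Gating variables follow first-order voltage-dependent kinetics
dx/dt = (x_inf(v) - x)/tau(v) and are advanced with the analytic exponential
update x' = x + (1 - exp(-dt/tau))·(x_inf - x), which is unconditionally
stable and keeps x in [0, 1] for any voltage trajectory.  A forward-Euler
update is available behind a flag for convergence experiments.

The default kinetics are the classic squid-axon Hodgkin-Huxley rate
functions expressed in the modern resting-potential convention (rest near
-65 mV):

    gate  alpha (1/ms)                              beta (1/ms)
    m     0.1·(v+40)/(1-exp(-(v+40)/10))            4·exp(-(v+65)/18)
    h     0.07·exp(-(v+65)/20)                      1/(1+exp(-(v+35)/10))
    n     0.01·(v+55)/(1-exp(-(v+55)/10))           0.125·exp(-(v+65)/80)

Removable singularities of the form x/(1-exp(-x/k)) are evaluated by their
series limit k + x/2 near x = 0.

New mechanism types can be registered with :func:`register`; a mechanism is
any subclass of :class:`Mechanism` implementing the current/state contract.
"""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """Unknown gate/mechanism or invalid mechanism configuration."""


def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        out = np.where(small, k + x / 2.0, safe / (-np.expm1(-safe / k)))
    if out.ndim == 0:
        return float(out)
    return out


_GATES = ("m", "h", "n")


def rate_functions(v, gate: str):
    """Forward/backward rate constants (1/ms) for HH gate 'm', 'h' or 'n'."""
    v = np.asarray(v, dtype=np.float64)
    if gate == "m":
        alpha = 0.1 * _vtrap(v + 40.0, 10.0)
        beta = 4.0 * np.exp(-(v + 65.0) / 18.0)
    elif gate == "h":
        alpha = 0.07 * np.exp(-(v + 65.0) / 20.0)
        beta = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    elif gate == "n":
        alpha = 0.01 * _vtrap(v + 55.0, 10.0)
        beta = 0.125 * np.exp(-(v + 65.0) / 80.0)
    else:
        raise ConfigurationError(f"unknown gate {gate!r}")
    return alpha, beta


def gate_steady_state(v, gate: str):
    alpha, beta = rate_functions(v, gate)
    return alpha / (alpha + beta)


def gating_state_update(x, v, dt: float, gate: str, euler: bool = False):
    """Advance one HH gating variable by dt (ms) at fixed voltage v (mV)."""
    alpha, beta = rate_functions(v, gate)
    tau = 1.0 / (alpha + beta)
    xinf = alpha * tau
    if euler:
        return x + dt * (xinf - x) / tau
    return x + -np.expm1(-dt / tau) * (xinf - x)


class Mechanism:
    """Contract every mechanism type implements.

    ``params``/``state`` are dicts of equal-length per-instance arrays (a
    scalar engine may pass length-1 views).  ``current`` must be pure;
    ``update_state`` mutates ``state`` in place.
    """

    name: str = ""
    kind: str = "density"            # "density" | "point"
    state_vars: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()
    # Values used for inert SIMD padding lanes (conductances default to 0).
    pad_values: dict[str, float] = {}

    def init_state(self, params, v):
        return {}

    def current(self, params, state, v, t):
        raise NotImplementedError

    def update_state(self, params, state, v, dt, euler=False):
        pass

    def on_event(self, params, state, idx, weight):
        raise ConfigurationError(f"mechanism {self.name!r} does not accept events")


REGISTRY: dict[str, Mechanism] = {}


def register(mech_cls):
    """Class decorator adding a mechanism type to the global registry."""
    inst = mech_cls()
    if not inst.name:
        raise ConfigurationError("mechanism must define a name")
    REGISTRY[inst.name] = inst
    return mech_cls


def get_mechanism(name: str) -> Mechanism:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown mechanism {name!r}") from None


@register
class Leak(Mechanism):
    """Ohmic leak: i = g·(v - e)."""

    name = "leak"
    param_names = ("g", "e")

    def current(self, params, state, v, t):
        i = params["g"] * (v - params["e"])
        return i, params["g"]


@register
class HodgkinHuxley(Mechanism):
    """Transient Na (m³h) and delayed-rectifier K (n⁴) currents.

    Parameters are absolute maximal conductances per instance: ``gna``,
    ``gk`` (µS) with reversal potentials ``ena`` (default +50 mV) and
    ``ek`` (default -77 mV).
    """

    name = "hh"
    state_vars = ("m", "h", "n")
    param_names = ("gna", "gk", "ena", "ek")

    def init_state(self, params, v):
        return {gate: np.broadcast_to(gate_steady_state(v, gate),
                                      np.shape(params["gna"])).astype(float).copy()
                for gate in self.state_vars}

    def current(self, params, state, v, t):
        gna = params["gna"] * state["m"] ** 3 * state["h"]
        gk = params["gk"] * state["n"] ** 4
        i = gna * (v - params["ena"]) + gk * (v - params["ek"])
        return i, gna + gk

    def update_state(self, params, state, v, dt, euler=False):
        for gate in self.state_vars:
            state[gate][...] = gating_state_update(state[gate], v, dt, gate,
                                                   euler=euler)


@register
class ExpSyn(Mechanism):
    """Single-exponential conductance synapse.

    Each delivered event adds its weight (µS) to the synaptic conductance,
    which then decays as g·exp(-dt/tau); the current is g·(v - e).
    Simultaneous events superpose linearly.
    """

    name = "expsyn"
    kind = "point"
    state_vars = ("gsyn",)
    param_names = ("e", "tau")
    pad_values = {"tau": 1.0}

    def init_state(self, params, v):
        return {"gsyn": np.zeros(np.shape(params["tau"]))}

    def current(self, params, state, v, t):
        i = state["gsyn"] * (v - params["e"])
        return i, state["gsyn"].copy()

    def update_state(self, params, state, v, dt, euler=False):
        state["gsyn"] *= np.exp(-dt / params["tau"])

    def on_event(self, params, state, idx, weight):
        if weight < 0:
            raise ConfigurationError("synaptic weight must be non-negative")
        state["gsyn"][idx] += weight


@register
class IClamp(Mechanism):
    """Step current injection: ``amp`` nA for t in [onset, onset + dur)."""

    name = "iclamp"
    kind = "point"
    param_names = ("amp", "onset", "dur")
    pad_values = {"dur": -1.0}

    def current(self, params, state, v, t):
        active = (t >= params["onset"]) & (t < params["onset"] + params["dur"])
        i = -params["amp"] * active  # injected current depolarizes
        return i, np.zeros_like(np.asarray(params["amp"], dtype=float))
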