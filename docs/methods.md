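# Methods

This note records the numerical scheme, the design decisions taken where
the design was genuinely open, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Electrical model and units

Neurons are trees of cylindrical compartments: a capacitor and a set of
conductance-based membrane mechanisms at each node, axial resistors along
the tree edges.  Units are mV, ms, nA, µS, nF, MΩ and µm throughout; these
are mutually consistent (nA = µS·mV, ms = nF/µS, nA = mV/MΩ), so no unit
conversions appear inside the numerical core.  Axial resistance of a
compartment of length L and diameter d is `4·Ra·L/(π·d²)` with resistivity
`Ra` (Ω·cm, default 100); membrane capacitance is `cm·π·d·L` with
`cm = 1 µF/cm²`.  Axon sections are dropped at load: their state is
treated as constant, and spike propagation to synapses is modeled as a
delayed event from the soma.

Membrane kinetics default to the classic squid-axon Hodgkin–Huxley rates
in the modern convention (rest ≈ −65 mV): gates m, h, n with the usual
`alpha/beta` expressions, Na reversal +50 mV, K −77 mV.  Rate expressions
of the form `x/(1 − exp(−x/k))` are evaluated by their series limit
`k + x/2` within 1e−6 of the singularity.  Synapses are single-exponential
conductances (event adds its weight in µS, decay `exp(−dt/τ)`, default
τ = 2 ms, reversal 0 mV).  A plugin registry accepts user-defined
mechanism types implementing the same current/state contract.

## Discretization

Sections (unbranched cables between branch points) are split into
`ceil(L/max_len)` equal cylinders, `max_len = 20 µm` by default; the soma
is always a single compartment.  Compartments are numbered depth-first
(children visited in ascending SWC sample id), so every parent index is
smaller than its child's and the voltage system has exactly one
sub-diagonal entry per row.  The d_lambda rule and frustum-based area
corrections are out of scope; geometry is cylinders only.

## Time integration

The loop is staggered: per step, (1) deliver due synaptic events, (2)
evaluate mechanism currents at the current voltage and half-step gating
states, (3) assemble and (4) solve the quasi-tridiagonal system for ΔV,
(5) update voltages, (6) advance gating states at the new voltage with the
analytic exponential update (unconditionally stable, keeps gates in
[0, 1]; a forward-Euler variant exists behind a flag for convergence
experiments), (7) detect threshold crossings at the soma (upward crossing
of −20 mV; spike time is the step-end time).

The system is formulated for the increment ΔV with
`d = C/dt + G + axial terms` and the instantaneous total current on the
right-hand side.  This keeps the cross-subtree dependency structure
explicit — RHS assembly needs neighboring voltages — which is the point of
the branch-parallel execution model.  The voltage update is therefore
implicit Euler: first-order, unconditionally stable.  Its observed
convergence order on the passive RC fixture approaches 1 strictly from
below (0.994 at dt = 0.2→0.1 ms, 0.999 at 0.05→0.025 ms); tests assert
monotone error decay and order ≥ 0.98, the slack being finite-dt
measurement headroom, not a weaker scheme.  Default `dt = 0.025` ms.
Diagonal dominance of the assembled system is checked once at the first
step and warns rather than fails.

## Event exchange

The communication step `T_synch` is the network's minimum synaptic delay
rounded down to a multiple of dt (configurable; delays below the
configured step are a load-time error).  Within a window all neurons
advance independently; at the boundary a barrier collects spikes and turns
each into one event per outgoing connection, due at spike time + delay and
applied at the first step whose start time has reached it (ties on
delivery order broken by time, source, connection id).  Because every
delay is at least `T_synch`, deliveries always land in a strictly later
window — events cannot be lost, duplicated, or delivered early.

## Decomposition

Per-compartment workload is `base + Σ mechanism costs` in the analytic
cost model (deterministic, the planning and test default) or the mean wall
time of repeated sample runs of the subtree's vectorized block in measured
mode (default 10 repetitions of a 100 ms kernel, following the static
measurement protocol; the repetition count and duration are model
parameters).  The per-subtree threshold is `k·runtime/cores`, with `k`
interpolated from a small table by core count (0.8 at 2 cores to 1.8 at
16, 2.0 above) and overridable.

Clustering walks root-to-leaves, packing compartments while the
accumulated cost stays within the threshold.  Open choices resolved here:
a compartment that would overshoot *starts the next subtree* (close before
exceeding); at a bifurcation the branches below are absorbed only if
*everything* below fits the remaining budget, otherwise each child branch
starts its own subtree.  The all-or-none rule guarantees that subtrees
attach only at a root-to-leaf boundary, so cross-subtree synchronization
stays confined to terminal compartment connections.  Two legitimate
threshold misses are flagged, not failed: single compartments costlier
than the threshold, and terminal leftovers with nothing more to
aggregate.

## Memory layout

Each subtree is serialized into a structure-of-arrays block: local solver
arrays (compartments renumbered 0..n−1 preserving depth-first order) and,
per mechanism type, one contiguous array per parameter and state variable,
instances ordered by local compartment (ties by creation order).  Arrays
are padded to the vector width (default 8 lanes = 512-bit doubles) with
inert lanes: zero conductance, pointing at local compartment 0, so they
contribute exactly zero and the padded and unpadded runs are bitwise
identical.  The contract is layout and summation order — both engines
accumulate per-compartment sums in the same canonical instance order — not
instruction selection; numpy provides the batch execution.

## Asynchronous execution

Exactly three values cross each subtree connection per step: the child
root voltage up, the eliminated child root's (δd, δrhs) fold up, and the
parent connecting compartment's ΔV down, from which the child also
refreshes its cached parent voltage for the next step's RHS.  Each
transfer is a counted placeholder; a task blocked on one consumes no
worker and resumes when the value arrives.  Multi-child reductions fold in
ascending child subtree id, and each task's arithmetic order is fixed, so
results are bitwise independent of worker count and scheduling.  Deadlock
is structurally impossible on tree-shaped channels; the scheduler still
detects a global stall and reports the blocked placeholders (treated as an
internal bug).  Localities are logical tags over subtrees — channels
between localities are counted as remote traffic — preserving the
set/get/counted-gate contract of a distributed global address space while
replacing the transport with in-memory queues.

## Load balancing

Whole neurons are placed by descending-sorted LPT (ties to the lowest
locality id), which carries the (4/3 − 1/(3m)) makespan guarantee.  A
locality above the capacity threshold — mean load × (1 + tolerance),
tolerance 10% — sheds *terminal subtree groups* (a subtree of the
tree-of-subtrees with all its descendants) of its most costly neurons,
largest group first: that moves the most load per channel created.
Delegated groups are pairwise disjoint, so each one's single cross-border
channel necessarily connects to the home locality; the per-neuron
inter-locality graph is a star and transitive chains cannot arise.
Balancing is static, once at onset: subtree workloads are quasi-constant
during a run.  If nothing terminal remains to shed, the overload stands
and a warning is issued.

## Synthetic fixtures

Generated morphologies use log-normal section lengths, geometric
bifurcation (probability per section end; extinct trees regrow a new
primary dendrite until the target total length is met), and diameter taper
— heterogeneous branched trees whose compartment counts track the recipe
target.  They emulate the *statistical shape* of reconstructed dendrites,
not any species' anatomy: no 3-D tortuosity realism, no spines, no
reconstruction artifacts, and a single mechanism repertoire (leak
everywhere, Hodgkin–Huxley soma, exponential synapses) instead of the
dozens of kinetic schemes of biophysically fitted models.  Passing the
equivalence and invariance suites therefore demonstrates correctness of
the solver, decomposition, layout and scheduling machinery on realistic
tree shapes — it does not validate biophysical fidelity of any particular
cell type.  Networks are directed Erdős–Rényi graphs with a hard minimum
delay (default 1 ms) plus exponential jitter, log-normal weights, and step
stimuli to a configurable fraction of neurons.

Equivalence fixtures run in subthreshold regimes: near the spike upstroke
the Hodgkin–Huxley system transiently amplifies round-off differences of
either execution path, which would measure trajectory sensitivity rather
than solver composition.  Spiking behaviour is exercised separately by the
spike-count refinement check (counts equal between dt and dt/8) and the
network invariance runs, where neurons do fire.

## Problem sizes

Verification fixtures are sized for a laptop-class single core: random
solver trees up to 200 compartments (500 draws), 50 random neurons of
roughly 25–70 compartments simulated for 10 ms in the decomposition
equivalence check, a 10-neuron network for 20 ms across 7
worker/assignment configurations, 1,000 decomposition fixtures, 1,000 LPT
draws of up to 12 units against exhaustive optima.  These sizes are the
package's own choice of desk-scale reproducibility; hardware benchmarks
and wall-clock speed-ups are explicitly out of scope.

## Known limitations

- Implicit-Euler voltage update (first order); no variable-timestep or
  higher-order option.
- No gap junctions, calcium dynamics, stochastic channels, or temperature
  scaling; axons are events, not cables (unless kept as passive cables at
  load).
- Threads, not processes: the "localities" are simulated memory domains,
  faithful to the communication contract but not a distributed transport.
- The measured cost model times Python/numpy execution, which weighs
  per-task overhead more heavily than a compiled kernel would; relative
  subtree costs remain representative, absolute times do not transfer.
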