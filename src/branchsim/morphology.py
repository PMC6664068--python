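"""Morphology ingestion and spatial discretization.

Reads SWC reconstructions, groups samples into unbranched sections, and
discretizes sections into cylindrical compartments numbered depth-first so
that every compartment's parent has a smaller index.  The resulting
:class:`CompartmentTree` is the electrical skeleton used by the solver: one
membrane capacitance per compartment and one axial resistance between each
compartment and its parent (a tree of resistors with RC membrane nodes).

Units used throughout the package: mV, ms, nA, µS, nF, MΩ, µm (and Ω·cm for
the axial resistivity input).  These are mutually consistent:
nA = µS·mV, ms = nF/µS, and mV/MΩ = nA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4


class MorphologyError(ValueError):
    """Structural problem in a morphology (multiple roots, empty tree, ...)."""


class SWCParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"SWC line {lineno}: {message}")


@dataclass
class Section:
    """An unbranched cable: a run of samples between branch points."""

    index: int
    stype: int
    sample_ids: list[int]
    samples: list[tuple[float, float, float, float]]  # x, y, z, radius (µm)
    parent: int | None  # parent section index
    parent_point: tuple[float, float, float, float] | None  # attachment sample

    @property
    def is_soma(self) -> bool:
        return self.stype == SOMA

    def path_length(self) -> float:
        pts = self.samples
        if self.parent_point is not None:
            pts = [self.parent_point] + pts
        total = 0.0
        for (x0, y0, z0, _), (x1, y1, z1, _) in zip(pts[:-1], pts[1:]):
            total += math.dist((x0, y0, z0), (x1, y1, z1))
        return total


@dataclass
class SectionGraph:
    """Sections of one neuron; section 0 is the soma root."""

    sections: list[Section]

    @property
    def soma(self) -> Section:
        return self.sections[0]

    def children_of(self, index: int) -> list[int]:
        return [s.index for s in self.sections if s.parent == index]


def parse_swc(text: str, keep_axon: bool = False) -> SectionGraph:
    """Parse SWC text (7-column standard) into a :class:`SectionGraph`.

    Axon-typed samples (and anything attached below them) are discarded by
    default: axonal state is treated as constant and spike propagation is
    modeled as a delayed event, so only soma and dendrites are simulated.
    Set ``keep_axon=True`` to retain axon sections as passive cables.
    """
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(lineno, f"expected 7 columns, got {len(cols)}")
        try:
            sid = int(cols[0])
            stype = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(lineno, str(exc)) from None
        if sid in samples:
            raise SWCParseError(lineno, f"duplicate sample id {sid}")
        if r <= 0:
            raise SWCParseError(lineno, f"non-positive radius {r}")
        samples[sid] = (stype, x, y, z, r, parent)
        order.append(sid)
    if not samples:
        raise MorphologyError("empty SWC file")

    roots = [sid for sid in order if samples[sid][5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"expected a single root sample, found {len(roots)}")
    root = roots[0]
    for sid in order:
        parent = samples[sid][5]
        if parent != -1 and parent not in samples:
            raise MorphologyError(f"sample {sid} references missing parent {parent}")

    dropped: set[int] = set()
    if not keep_axon:
        for sid in order:  # parents precede children in well-formed files
            stype, _, _, _, _, parent = samples[sid]
            if stype == AXON or (parent in dropped):
                if sid == root:
                    raise MorphologyError("root sample is axon-typed")
                dropped.add(sid)

    kept = [sid for sid in order if sid not in dropped]
    children: dict[int, list[int]] = {sid: [] for sid in kept}
    for sid in kept:
        parent = samples[sid][5]
        if parent != -1:
            children[parent].append(sid)
    for sid in kept:
        children[sid].sort()

    # Soma section: contiguous run of soma-typed samples from the root.
    soma_ids = [root]
    frontier = [root]
    while frontier:
        nxt = []
        for sid in frontier:
            for ch in children[sid]:
                if samples[ch][0] == SOMA:
                    soma_ids.append(ch)
                    nxt.append(ch)
        frontier = nxt
    soma_set = set(soma_ids)

    def sample_tuple(sid: int) -> tuple[float, float, float, float]:
        _, x, y, z, r, _ = samples[sid]
        return (x, y, z, r)

    sections: list[Section] = [
        Section(0, SOMA, list(soma_ids), [sample_tuple(s) for s in soma_ids],
                parent=None, parent_point=None)
    ]

    # Neurite sections: depth-first from soma attachment points, visiting
    # children in ascending sample id for deterministic numbering.
    stack: list[tuple[int, int, int]] = []  # (first sample, parent section, attach sample)
    for sid in reversed(soma_ids):
        for ch in reversed(children[sid]):
            if ch not in soma_set:
                stack.append((ch, 0, sid))
    while stack:
        first, parent_sec, attach = stack.pop()
        run = [first]
        cur = first
        while len(children[cur]) == 1:
            nxt = children[cur][0]
            if samples[nxt][0] != samples[first][0]:
                break
            run.append(nxt)
            cur = nxt
        # Sections hanging off the soma start at their own first sample (the
        # soma is a point electrically); at a branch point the stretch from
        # the branch sample to the child's first sample is real cable.
        attach_point = None if attach in soma_set else sample_tuple(attach)
        sec = Section(
            len(sections),
            samples[first][0],
            run,
            [sample_tuple(s) for s in run],
            parent=parent_sec,
            parent_point=attach_point,
        )
        sections.append(sec)
        for ch in reversed(children[cur]):
            if ch not in run:
                stack.append((ch, sec.index, cur))
    return SectionGraph(sections)


def read_swc(path, keep_axon: bool = False) -> SectionGraph:
    with open(path) as fh:
        return parse_swc(fh.read(), keep_axon=keep_axon)


def axial_resistance(length: float, diameter: float, ra: float = 100.0) -> float:
    """Axial resistance of a cylinder, in MΩ.

    r = 4·Ra·L / (π·d²) with Ra in Ω·cm and L, d in µm.  The unit factor is
    1e-4 (µm→cm) for L, 1e-8 for d², and 1e-6 (Ω→MΩ), i.e. ×1e-2 overall.
    """
    if length <= 0 or diameter <= 0 or ra <= 0:
        raise ValueError("length, diameter and Ra must be positive")
    return 4.0 * ra * length / (math.pi * diameter * diameter) * 1e-2


@dataclass
class CompartmentTree:
    """DFS-numbered compartments with parent map and passive parameters.

    ``p[n] < n`` for every non-root compartment; the root (index 0, the soma)
    has ``p[0] == -1``.  ``r[n]`` is the axial resistance (MΩ) between
    compartment ``n`` and ``p[n]``; ``r[0]`` is unused and stored as ``inf``.
    """

    p: np.ndarray          # int parent indices
    length: np.ndarray     # µm
    diam: np.ndarray       # µm
    C: np.ndarray          # nF
    r: np.ndarray          # MΩ

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.int64)
        for name in ("length", "diam", "C", "r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.p.size
        if n == 0:
            raise MorphologyError("empty compartment tree")
        if self.p[0] != -1:
            raise MorphologyError("compartment 0 must be the root")
        if n > 1 and not np.all(self.p[1:] < np.arange(1, n)):
            raise MorphologyError("parent index must be smaller than child index")
        if np.any(self.C <= 0):
            raise MorphologyError("all capacitances must be positive")
        if n > 1 and np.any(self.r[1:] <= 0):
            raise MorphologyError("all axial resistances must be positive")

    @property
    def n(self) -> int:
        return int(self.p.size)

    def children_lists(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(1, self.n):
            ch[self.p[i]].append(i)
        return ch

    def subtree_sizes(self) -> np.ndarray:
        """Size of the subtree rooted at each compartment (DFS-contiguous)."""
        sizes = np.ones(self.n, dtype=np.int64)
        for i in range(self.n - 1, 0, -1):
            sizes[self.p[i]] += sizes[i]
        return sizes

    def area_cm2(self) -> np.ndarray:
        """Lateral cylinder surface per compartment, in cm²."""
        return np.pi * self.diam * self.length * 1e-8

    def to_json(self) -> str:
        return json.dumps({
            "p": self.p.tolist(),
            "length": self.length.tolist(),
            "diam": self.diam.tolist(),
            "C": self.C.tolist(),
            "r": ["inf" if not np.isfinite(v) else v for v in self.r.tolist()],
        })

    @classmethod
    def from_json(cls, text: str) -> "CompartmentTree":
        obj = json.loads(text)
        r = [math.inf if v == "inf" else float(v) for v in obj["r"]]
        return cls(np.array(obj["p"]), np.array(obj["length"]),
                   np.array(obj["diam"]), np.array(obj["C"]), np.array(r))


def _section_geometry(sec: Section) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length and radius profile along a section's polyline."""
    pts = sec.samples
    if sec.parent_point is not None:
        # Attachment point contributes position only; radius is carried from
        # the section's own first sample so a fat soma does not bleed into
        # thin dendrites.
        first = pts[0]
        pts = [(sec.parent_point[0], sec.parent_point[1], sec.parent_point[2],
                first[3])] + pts
    xyz = np.array([(x, y, z) for x, y, z, _ in pts])
    radius = np.array([r for _, _, _, r in pts])
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return arc, radius


def discretize(graph: SectionGraph, max_len: float = 20.0,
               ra: float = 100.0, cm: float = 1.0) -> CompartmentTree:
    """Discretize a section graph into compartments of length ≤ ``max_len``.

    Each non-soma section of length L becomes ``ceil(L / max_len)`` equal
    cylinders whose diameter is the section's radius profile interpolated at
    the cylinder midpoint.  The soma is always a single compartment (length
    and diameter both equal to twice the mean soma radius for a point soma,
    or the soma path length when it is a multi-sample contour).

    ``ra`` is the axial resistivity in Ω·cm and ``cm`` the specific membrane
    capacitance in µF/cm².
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    if not graph.sections:
        raise MorphologyError("empty section graph")

    p: list[int] = []
    length: list[float] = []
    diam: list[float] = []

    soma = graph.soma
    soma_len = soma.path_length()
    mean_r = float(np.mean([s[3] for s in soma.samples]))
    if soma_len <= 0:
        soma_len = 2.0 * mean_r
    p.append(-1)
    length.append(soma_len)
    diam.append(2.0 * mean_r)

    last_comp_of_section = {0: 0}
    order = sorted(range(1, len(graph.sections)),
                   key=lambda i: graph.sections[i].sample_ids[0])
    # Depth-first over sections; children pushed in reverse ascending-id order.
    children_of: dict[int, list[int]] = {i: [] for i in range(len(graph.sections))}
    for i in order:
        children_of[graph.sections[i].parent].append(i)
    stack = list(reversed(children_of[0]))
    while stack:
        si = stack.pop()
        sec = graph.sections[si]
        arc, radius = _section_geometry(sec)
        total = float(arc[-1])
        if total <= 0:
            raise MorphologyError(f"section {si} has zero length")
        ncomp = max(1, math.ceil(total / max_len))
        clen = total / ncomp
        parent_comp = last_comp_of_section[sec.parent]
        for j in range(ncomp):
            mid = (j + 0.5) * clen
            d = 2.0 * float(np.interp(mid, arc, radius))
            idx = len(p)
            p.append(parent_comp)
            length.append(clen)
            diam.append(d)
            parent_comp = idx
        last_comp_of_section[si] = parent_comp
        for ci in reversed(children_of[si]):
            stack.append(ci)

    length_a = np.array(length)
    diam_a = np.array(diam)
    area = np.pi * diam_a * length_a * 1e-8  # cm²
    C = cm * area * 1e3                      # µF/cm² · cm² → µF → nF (×1e3)
    r = np.empty(len(p))
    r[0] = math.inf
    for i in range(1, len(p)):
        r[i] = axial_resistance(length_a[i], diam_a[i], ra)
    return CompartmentTree(np.array(p), length_a, diam_a, C, r)


@dataclass
class MechanismPlacement:
    """Instances of one mechanism type placed on specific compartments."""

    mech: str
    comps: np.ndarray                 # compartment index per instance
    params: dict[str, np.ndarray]     # per-instance parameter arrays

    def __post_init__(self):
        self.comps = np.asarray(self.comps, dtype=np.int64)
        self.params = {k: np.broadcast_to(np.asarray(v, dtype=np.float64),
                                          self.comps.shape).copy()
                       for k, v in self.params.items()}


@dataclass
class NeuronModel:
    """A compartment tree plus mechanism placements and an initial voltage."""

    tree: CompartmentTree
    placements: list[MechanismPlacement] = field(default_factory=list)
    v_init: float = -65.0

    def add_mechanism(self, mech: str, comps, **params) -> tuple[int, int]:
        """Attach instances; returns the handle of the first new instance.

        A handle is ``(placement_index, instance_index)`` and is how synaptic
        events address a specific synapse instance.
        """
        comps = np.atleast_1d(np.asarray(comps, dtype=np.int64))
        if comps.size and (comps.min() < 0 or comps.max() >= self.tree.n):
            raise MorphologyError("mechanism placement outside the tree")
        placement = MechanismPlacement(mech, comps, params)
        self.placements.append(placement)
        return (len(self.placements) - 1, 0)

    def validate(self) -> None:
        for pl in self.placements:
            if pl.comps.size and pl.comps.max() >= self.tree.n:
                raise MorphologyError("placement index out of range")
            for k, v in pl.params.items():
                if v.shape != pl.comps.shape:
                    raise MorphologyError(f"parameter {k} length mismatch")


def attach_density(model: NeuronModel, mech: str, comps, **densities) -> tuple[int, int]:
    """Attach a density mechanism with conductances given in S/cm².

    Parameters named ``*_density`` are multiplied by each compartment's
    membrane area and converted to absolute µS; other parameters pass
    through unchanged.
    """
    comps = np.atleast_1d(np.asarray(comps, dtype=np.int64))
    area = model.tree.area_cm2()[comps]
    params = {}
    for k, v in densities.items():
        if k.endswith("_density"):
            params[k[: -len("_density")]] = np.asarray(v) * area * 1e6  # S → µS
        else:
            params[k] = v
    return model.add_mechanism(mech, comps, **params)
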