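"""Vascular tree data model and synthetic branching-tree generator.

The arterial tree is a rooted directed tree of cylindrical vessel segments.
Each segment joins its parent's distal junction to its own distal junction;
leaves are the outlets. One segment is designated the *target branch*: the
vessel (with its downstream subtree) that embolic material is meant to reach.

Depth convention: the inlet (root) segment has depth level 1 and a child's
depth level is its parent's plus one, i.e. the number of vessels blood has
traversed since entering the domain.

The generator builds binary branching trees that honour Murray's law
(parent_r^k = sum child_r^k, k = 3 by default) with a log-uniform asymmetry
jitter, and places the target branch at a prescribed depth with a prescribed
number of terminal target outlets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

from .errors import ConfigurationError, TreeValidationError

__all__ = [
    "FluidProperties",
    "VesselSegment",
    "VascularTree",
    "TreeGenConfig",
    "generate_tree",
    "reference_fixture",
]

#: Blood density [kg/m^3] and dynamic viscosity [Pa*s] for a Newtonian
#: incompressible model of hepatic arterial blood.
DEFAULT_DENSITY = 1060.0
DEFAULT_VISCOSITY = 0.0035


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Attributes
    ----------
    density : float
        Mass density, kg/m^3 (blood: 1060).
    viscosity : float
        Dynamic viscosity, Pa*s (blood: 0.0035).
    """

    density: float = DEFAULT_DENSITY
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


@dataclass(frozen=True)
class VesselSegment:
    """One cylindrical vessel segment.

    ``parent_id is None`` marks the inlet (root) segment. ``length`` and
    ``radius`` are in meters. ``label`` is free text (e.g. "CS-3").
    """

    segment_id: str
    parent_id: str | None
    length: float
    radius: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.segment_id:
            raise TreeValidationError("segment_id must be non-empty")
        if not (self.length > 0):
            raise TreeValidationError(
                f"segment {self.segment_id!r}: length must be > 0, got {self.length}"
            )
        if not (self.radius > 0):
            raise TreeValidationError(
                f"segment {self.segment_id!r}: radius must be > 0, got {self.radius}"
            )

    @property
    def cross_sectional_area(self) -> float:
        """Lumen area pi*r^2 [m^2]."""
        return math.pi * self.radius**2


class VascularTree:
    """A validated rooted tree of vessel segments with a designated target branch.

    Parameters
    ----------
    segments : iterable of VesselSegment
    target_branch_id : str
        Segment whose subtree's leaves are the target outlets.
    fluid : FluidProperties, optional

    All structural invariants (single root, acyclic and connected, known
    parents, valid target) are checked at construction time; invalid input
    raises :class:`TreeValidationError` naming the offending segment.
    """

    def __init__(
        self,
        segments,
        target_branch_id: str,
        fluid: FluidProperties | None = None,
    ) -> None:
        seg_list = list(segments)
        self.segments: dict[str, VesselSegment] = {}
        for s in seg_list:
            if s.segment_id in self.segments:
                raise TreeValidationError(f"duplicate segment id {s.segment_id!r}")
            self.segments[s.segment_id] = s
        self.target_branch_id = target_branch_id
        self.fluid = fluid if fluid is not None else FluidProperties()
        self._validate()
        self._depth: dict[str, int] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.segments:
            raise TreeValidationError("tree has no segments")
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise TreeValidationError(
                f"tree must have exactly one root, found {len(roots)}: "
                f"{sorted(s.segment_id for s in roots)}"
            )
        self.inlet_id: str = roots[0].segment_id
        g = nx.DiGraph()
        g.add_nodes_from(self.segments)
        for s in self.segments.values():
            if s.parent_id is not None:
                if s.parent_id not in self.segments:
                    raise TreeValidationError(
                        f"segment {s.segment_id!r} references unknown parent "
                        f"{s.parent_id!r}"
                    )
                g.add_edge(s.parent_id, s.segment_id)
        if not nx.is_arborescence(g):
            try:
                cycle = nx.find_cycle(g)
                raise TreeValidationError(
                    "tree contains a cycle through segments: "
                    + " -> ".join(str(e[0]) for e in cycle)
                )
            except nx.NetworkXNoCycle:
                raise TreeValidationError(
                    "segment graph is not a rooted tree (disconnected?)"
                ) from None
        self._graph = g
        if self.target_branch_id not in self.segments:
            raise TreeValidationError(
                f"target_branch_id {self.target_branch_id!r} is not a segment"
            )

    @property
    def children(self) -> Mapping[str, tuple[str, ...]]:
        return {
            sid: tuple(sorted(self._graph.successors(sid))) for sid in self.segments
        }

    def children_of(self, segment_id: str) -> tuple[str, ...]:
        return tuple(self._graph.successors(segment_id))

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        """Outlet segment ids, in deterministic (insertion) order."""
        return tuple(
            sid for sid in self.segments if self._graph.out_degree(sid) == 0
        )

    @property
    def n_outlets(self) -> int:
        return len(self.leaf_ids)

    def subtree_ids(self, segment_id: str) -> tuple[str, ...]:
        """Ids of ``segment_id`` and all its descendants (preorder)."""
        out, stack = [], [segment_id]
        while stack:
            sid = stack.pop()
            out.append(sid)
            stack.extend(reversed(list(self._graph.successors(sid))))
        return tuple(out)

    def subtree_leaf_ids(self, segment_id: str) -> tuple[str, ...]:
        return tuple(
            sid
            for sid in self.subtree_ids(segment_id)
            if self._graph.out_degree(sid) == 0
        )

    @property
    def target_leaf_ids(self) -> tuple[str, ...]:
        """The target outlets: leaves of the target branch's subtree."""
        return self.subtree_leaf_ids(self.target_branch_id)

    def is_target_member(self, segment_id: str) -> bool:
        """True if the segment lies within the target branch subtree."""
        return segment_id in set(self.subtree_ids(self.target_branch_id))

    @property
    def depth_levels(self) -> dict[str, int]:
        """Depth level per segment; inlet = 1, +1 per bifurcation passed."""
        if self._depth is None:
            depth = {self.inlet_id: 1}
            for sid in nx.topological_sort(self._graph):
                if sid != self.inlet_id:
                    depth[sid] = depth[self.segments[sid].parent_id] + 1
            self._depth = depth
        return dict(self._depth)

    def path_to_target(self) -> tuple[str, ...]:
        """Segment ids on the unique inlet -> target-branch path, inclusive."""
        path = [self.target_branch_id]
        while path[-1] != self.inlet_id:
            path.append(self.segments[path[-1]].parent_id)
        return tuple(reversed(path))

    def outlet_areas(self, leaf_ids=None) -> dict[str, float]:
        """Cross-sectional area pi*r^2 of each outlet [m^2]."""
        ids = self.leaf_ids if leaf_ids is None else leaf_ids
        return {sid: self.segments[sid].cross_sectional_area for sid in ids}

    # -- editing -----------------------------------------------------------

    def with_radii(self, radii: Mapping[str, float]) -> "VascularTree":
        """Return a copy with the given segments' radii replaced."""
        segs = [
            replace(s, radius=radii[s.segment_id]) if s.segment_id in radii else s
            for s in self.segments.values()
        ]
        return VascularTree(segs, self.target_branch_id, self.fluid)

    def __iter__(self) -> Iterator[VesselSegment]:
        return iter(self.segments.values())

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VascularTree):
            return NotImplemented
        return (
            self.segments == other.segments
            and self.target_branch_id == other.target_branch_id
            and self.fluid == other.fluid
        )

    def __repr__(self) -> str:
        return (
            f"VascularTree({len(self.segments)} segments, "
            f"{self.n_outlets} outlets, target={self.target_branch_id!r})"
        )


@dataclass(frozen=True)
class TreeGenConfig:
    """Configuration of the stochastic binary branching-tree generator.

    Defaults replicate the study topology: 43 outlets in total, a target
    branch at depth level 5 subdividing into 10 target outlets, inlet radius
    2.31 mm (diameter 4.62 mm, sized so the inlet Reynolds number at
    5 cm^3/s is ~417), Murray exponent 3, segment length = 20 radii.

    ``branching_asymmetry`` in [0, 1): each bifurcation's radius split is
    weighted by downstream outlet counts times a log-uniform jitter drawn
    from [1-a, 1/(1-a)]; 0 gives count-proportional (symmetric when counts
    are equal) splits.
    """

    total_outlet_count: int = 43
    target_outlet_count: int = 10
    target_depth: int = 5
    inlet_radius: float = 2.31e-3
    murray_exponent: float = 3.0
    length_to_radius_ratio: float = 20.0
    branching_asymmetry: float = 0.3
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_outlet_count < 1:
            raise ConfigurationError("target_outlet_count must be >= 1")
        if self.target_outlet_count >= self.total_outlet_count:
            raise ConfigurationError(
                "target_outlet_count must be < total_outlet_count"
            )
        if self.target_depth < 2:
            raise ConfigurationError("target_depth must be >= 2")
        if self.inlet_radius <= 0:
            raise ConfigurationError("inlet_radius must be > 0")
        if self.murray_exponent <= 0:
            raise ConfigurationError("murray_exponent must be > 0")
        if self.length_to_radius_ratio <= 0:
            raise ConfigurationError("length_to_radius_ratio must be > 0")
        if not (0 <= self.branching_asymmetry < 1):
            raise ConfigurationError("branching_asymmetry must be in [0, 1)")


def _split_weights(n1: int, n2: int, asym: float, rng: np.random.Generator):
    """Radius weights (w1, w2), w1 + w2 = 1, for a bifurcation whose children
    feed n1 and n2 outlets, with log-uniform asymmetry jitter."""
    hi = -math.log1p(-asym)
    j = math.exp(rng.uniform(-hi, hi)) if hi > 0 else 1.0
    w1 = n1 * j / (n1 * j + n2)
    return w1, 1.0 - w1


def generate_tree(config: TreeGenConfig) -> VascularTree:
    """Generate a seeded random binary arterial tree.

    The inlet->target path is laid down first: at each of the
    ``target_depth - 1`` bifurcations above the target branch, a sibling
    subtree peels off a share of the non-target outlets, so the target
    branch sits at exactly the requested depth level. Child radii satisfy
    Murray's law exactly: ``r_child = r_parent * w**(1/k)`` with weights
    summing to one. Deterministic for a fixed ``random_seed``.

    Raises
    ------
    ConfigurationError
        If the requested topology is infeasible (too few non-target outlets
        to populate one sibling subtree per path bifurcation).
    """
    cfg = config
    rng = np.random.default_rng(cfg.random_seed)
    n_sib = cfg.target_depth - 1
    n_nontarget = cfg.total_outlet_count - cfg.target_outlet_count
    if n_nontarget < n_sib:
        raise ConfigurationError(
            f"target_depth={cfg.target_depth} needs at least {n_sib} non-target "
            f"outlets (one sibling subtree per path bifurcation), "
            f"got {n_nontarget}"
        )
    # random composition of the non-target outlets over the sibling subtrees
    sib_counts = 1 + rng.multinomial(n_nontarget - n_sib, [1.0 / n_sib] * n_sib)

    counter = iter(range(10**6))
    segments: list[VesselSegment] = []
    k = cfg.murray_exponent
    ratio = cfg.length_to_radius_ratio

    def new_segment(parent: str | None, radius: float, label: str | None = None) -> str:
        sid = f"v{next(counter):03d}"
        segments.append(
            VesselSegment(sid, parent, length=ratio * radius, radius=radius, label=label)
        )
        return sid

    def build_subtree(n_leaves: int, parent: str, radius: float) -> None:
        """Attach a random binary subtree with n_leaves leaves below parent."""
        sid = new_segment(parent, radius)
        _expand(sid, n_leaves, radius)

    def _expand(sid: str, n_leaves: int, radius: float) -> None:
        if n_leaves == 1:
            return
        n1 = int(rng.integers(1, n_leaves))
        n2 = n_leaves - n1
        w1, w2 = _split_weights(n1, n2, cfg.branching_asymmetry, rng)
        build_subtree(n1, sid, radius * w1 ** (1.0 / k))
        build_subtree(n2, sid, radius * w2 ** (1.0 / k))

    # inlet -> target path
    path_leaves = cfg.total_outlet_count
    parent = None
    radius = cfg.inlet_radius
    for depth in range(1, cfg.target_depth):
        sid = new_segment(parent, radius, label=f"CS-{depth}")
        n_down = path_leaves - int(sib_counts[depth - 1])
        w_path, w_sib = _split_weights(
            n_down, int(sib_counts[depth - 1]), cfg.branching_asymmetry, rng
        )
        r_path = radius * w_path ** (1.0 / k)
        build_subtree(int(sib_counts[depth - 1]), sid, radius * w_sib ** (1.0 / k))
        parent, radius, path_leaves = sid, r_path, n_down
    # the target branch itself
    target_id = new_segment(parent, radius, label=f"CS-{cfg.target_depth} target branch")
    _expand(target_id, cfg.target_outlet_count, radius)

    tree = VascularTree(segments, target_branch_id=target_id)
    assert tree.n_outlets == cfg.total_outlet_count
    return tree


def reference_fixture() -> VascularTree:
    """Load the packaged calibrated reference tree.

    The fixture replicates the study topology and baseline hemodynamics:
    one inlet (diameter 4.62 mm, Reynolds number ~417 at 5 cm^3/s), 43
    outlets, target branch at depth level 5 with 10 target outlets, and
    non-target terminal radii pre-calibrated so the target branch's
    flow-cessation pressure is 5000 Pa (inlet 5 cm^3/s, non-target outlets
    at 300 Pa). The file is packaged verbatim and byte-stable across
    releases; see ``scripts/make_reference_tree.py`` for its provenance.
    """
    from importlib.resources import files

    from .io import read_tree_json

    text = (files("emboflow.data") / "reference_tree.json").read_text()
    return read_tree_json(text)
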