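"""Embolization Efficiency Index (EEI) analysis.

The EEI at a candidate injection site is the percentage of the flow
passing that site which reaches the designated target outlets:

    EEI(s) = 100 * sum(Q_target below s) / Q(s)

with perfect-mixing advective transport at bifurcations (an embolic agent
follows the flow split). Retrograde target-outlet flows are clamped to
zero inside the numerator — embolic material cannot be delivered by
reverse outflow — while the raw signed flows remain available on the
FlowSolution. Sites carrying no forward flow (Q(s) below tolerance) are
reported as *undefined*, distinct from 0, so near-stall maps are not
polluted by ill-conditioned ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .solver import FlowSolution
from .tree import VascularTree

__all__ = [
    "EEIMap",
    "CrossSection",
    "CrossSectionSeries",
    "PressureFit",
    "compute_eei",
    "time_averaged_eei",
    "cross_section_flows",
    "eei_pressure_fit",
]

#: Minimum forward carrier flow [m^3/s] below which EEI is undefined.
FLOW_TOLERANCE = 1e-12


@dataclass(frozen=True)
class EEIMap:
    """Per-segment EEI values — the scalar form of an EEI "cloud map".

    ``values`` holds defined sites only (percent, in [0, 100]);
    ``undefined`` lists sites with no forward carrier flow.
    """

    values: Mapping[str, float]
    undefined: frozenset[str] = frozenset()
    time_averaged: bool = False
    condition_id: str = ""

    def __getitem__(self, segment_id: str) -> float:
        return self.values[segment_id]

    def is_defined(self, segment_id: str) -> bool:
        return segment_id in self.values


class CrossSection(NamedTuple):
    label: str
    segment_id: str
    flow: float  # m^3/s


#: Ordered cross-sections CS-1 (inlet) .. CS-k (target branch) on the
#: inlet->target path; each monitors its segment's flow.
CrossSectionSeries = tuple


def _clamped_target_inflow(
    tree: VascularTree, leaf_flows: Mapping[str, float]
) -> dict[str, float]:
    """Per-segment sum of non-negative flows into descendant target outlets."""
    target_leaves = set(tree.target_leaf_ids)
    sums: dict[str, float] = {}

    def visit(sid: str) -> float:
        kids = tree.children_of(sid)
        if not kids:
            val = max(leaf_flows[sid], 0.0) if sid in target_leaves else 0.0
        else:
            val = sum(visit(k) for k in kids)
        sums[sid] = val
        return val

    visit(tree.inlet_id)
    return sums


def compute_eei(
    tree: VascularTree,
    solution: FlowSolution,
    flow_tolerance: float = FLOW_TOLERANCE,
) -> EEIMap:
    """EEI at every segment of ``tree`` for one flow solution.

    Raises ``ValueError`` if the solution does not cover the tree's
    segments.
    """
    if set(solution.segment_flows) != set(tree.segments):
        raise ValueError("solution does not match tree (segment ids differ)")
    numerators = _clamped_target_inflow(tree, solution.segment_flows)
    values, undefined = {}, set()
    for sid in tree.segments:
        q = solution.segment_flows[sid]
        if q <= flow_tolerance:
            undefined.add(sid)
        else:
            values[sid] = min(100.0, 100.0 * numerators[sid] / q)
    return EEIMap(values=values, undefined=frozenset(undefined))


def time_averaged_eei(
    tree: VascularTree,
    solutions: Sequence[FlowSolution],
    flow_tolerance: float = FLOW_TOLERANCE,
) -> EEIMap:
    """EEI from period-integrated flows over a pulsatile solve.

    ``EEI(s) = 100 * mean_t[sum clamped target inflow below s] / mean_t[Q(s)]``.
    With uniform outlet pressures the flow split is constant in time, so
    this equals the instantaneous EEI at every sample.
    """
    if len(solutions) == 0:
        raise ValueError("need at least one flow solution to average")
    if set(solutions[0].segment_flows) != set(tree.segments):
        raise ValueError("solutions do not match tree (segment ids differ)")
    num_acc = {sid: 0.0 for sid in tree.segments}
    den_acc = {sid: 0.0 for sid in tree.segments}
    for sol in solutions:
        numerators = _clamped_target_inflow(tree, sol.segment_flows)
        for sid in tree.segments:
            num_acc[sid] += numerators[sid]
            den_acc[sid] += sol.segment_flows[sid]
    n = len(solutions)
    values, undefined = {}, set()
    for sid in tree.segments:
        q = den_acc[sid] / n
        if q <= flow_tolerance:
            undefined.add(sid)
        else:
            values[sid] = min(100.0, 100.0 * (num_acc[sid] / n) / q)
    return EEIMap(values=values, undefined=frozenset(undefined), time_averaged=True)


def cross_section_flows(
    tree: VascularTree, solution: FlowSolution
) -> tuple[CrossSection, ...]:
    """Flows at the monitoring cross-sections along the inlet->target path.

    Returns (label, segment_id, flow) triples labeled CS-1 (inlet) through
    CS-k (target branch) in path order; in the forward regime CS-k equals
    the summed target-outlet flow by mass conservation.
    """
    path = tree.path_to_target()
    return tuple(
        CrossSection(f"CS-{i}", sid, solution.segment_flows[sid])
        for i, sid in enumerate(path, start=1)
    )


class PressureFit(NamedTuple):
    slope: float  # percent per Pa
    intercept: float  # percent at 0 Pa
    max_abs_residual: float  # percent


def eei_pressure_fit(sweep, site: str) -> PressureFit:
    """Least-squares line EEI(site) vs target total pressure over a sweep.

    Only conditions where the site's EEI is defined enter the fit; at
    least three are required. For the linear network the relation is
    exactly affine below stall, so residuals sit at solver tolerance and
    the slope is negative at any on-path site.
    """
    pts = [
        (bc.target_total_pressure, m.values[site])
        for bc, m in zip(sweep.conditions, sweep.eei_maps)
        if bc.target_total_pressure is not None and m.is_defined(site)
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 sweep conditions with defined EEI at {site!r}, got {len(pts)}"
        )
    p = np.array([x for x, _ in pts])
    e = np.array([y for _, y in pts])
    slope, intercept = np.polyfit(p, e, 1)
    resid = e - (slope * p + intercept)
    return PressureFit(float(slope), float(intercept), float(np.abs(resid).max()))
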