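"""Flow-cessation (stall) pressure: finder, analytic form, calibration.

The stall pressure is the target outlet total pressure at which net flow
through the target branch ceases; above it the branch flow is retrograde.
Operationally "cessation" is defined at a small residual fraction of the
zero-pressure baseline flow (``rel_threshold``, default 1%), because the
approach to zero is asymptotically linear and an exact zero is a set of
measure zero under any pressure sweep.

Because the network is linear, the target-branch flow is exactly affine in
the target total pressure: Q(P) = Q0 * (1 - P/P*), where P* is the
zero-flow stall. P* has a closed form obtained by Thevenin reduction of
the tree — no linear solve involved — which serves as the independent
cross-check of the bisection finder:

- reduce the target subtree (leaves at the unit area-partitioned
  pressures) to its open-circuit pressure coefficient kappa, so the
  subtree presents pressure kappa*P at the target branch's upstream node;
- with the target subtree carrying no flow, the rest of the tree (uniform
  non-target outlet pressure) determines that node's pressure P_J by a
  conductance-split descent;
- zero branch flow requires kappa*P* = P_J, i.e. P* = P_J / kappa, and
  the residual-threshold stall is (1 - rel_threshold) * P*.

Calibration rescales the non-target *terminal* radii by one global factor
(target subtree and topology untouched, so the EEI geometry is preserved)
until the stall matches a requested value; the scale is found by Brent
root finding on the analytic stall.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .errors import BracketError, CalibrationError, ConfigurationError
from .solver import BoundaryConditions, solve_steady
from .tree import VascularTree

__all__ = [
    "find_stall_pressure",
    "analytic_stall_pressure",
    "calibrate_stall_pressure",
]


def _target_branch_flow(
    tree: VascularTree, bc: BoundaryConditions, target_pressure: float
) -> float:
    from dataclasses import replace

    sol = solve_steady(tree, replace(bc, target_total_pressure=target_pressure))
    return sol.segment_flows[tree.target_branch_id]


def find_stall_pressure(
    tree: VascularTree,
    bc: BoundaryConditions,
    rel_threshold: float = 0.01,
    tol: float = 1.0,
) -> float:
    """Bisection for the target total pressure at which the target-branch
    flow falls to ``rel_threshold`` times its zero-pressure baseline.

    Parameters
    ----------
    bc : BoundaryConditions
        Steady inlet flow and non-target outlet pressures; its
        ``target_total_pressure`` is the swept variable and is ignored.
    rel_threshold : float
        Residual flow fraction defining "cessation"; must be in (0, 1).
    tol : float
        Bisection interval tolerance, Pa.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ConfigurationError(
            f"rel_threshold must be in (0, 1), got {rel_threshold}"
        )
    q0 = _target_branch_flow(tree, bc, 0.0)
    if q0 <= 0:
        raise BracketError(
            f"baseline (0 Pa) target-branch flow is {q0:.3g} m^3/s; "
            "stall search requires positive forward baseline flow"
        )
    threshold = rel_threshold * q0

    lo, hi = 0.0, max(2.0 * bc.non_target_pressure, 1000.0)
    f_hi = _target_branch_flow(tree, bc, hi) - threshold
    n_expand = 0
    while f_hi > 0:
        hi *= 2.0
        n_expand += 1
        if n_expand > 40:
            raise BracketError(
                f"could not bracket stall below {hi:.3g} Pa "
                f"(residual flow still {f_hi + threshold:.3g} m^3/s)"
            )
        f_hi = _target_branch_flow(tree, bc, hi) - threshold
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _target_branch_flow(tree, bc, mid) - threshold > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _uniform_non_target_pressure(tree: VascularTree, bc: BoundaryConditions) -> float:
    from dataclasses import replace

    expanded = replace(bc, target_total_pressure=0.0).expand(tree)
    target_leaves = set(tree.target_leaf_ids)
    p_nt = {expanded[l] for l in tree.leaf_ids if l not in target_leaves}
    if len(p_nt) != 1:
        raise ConfigurationError(
            "analytic stall pressure requires a uniform non-target outlet "
            f"pressure; found {sorted(p_nt)}"
        )
    return p_nt.pop()


def _conductance(tree: VascularTree, sid: str) -> float:
    from .solver import segment_resistance

    s = tree.segments[sid]
    return 1.0 / segment_resistance(s.length, s.radius, tree.fluid.viscosity)


def _reduce_subtree(tree: VascularTree, sid: str, leaf_pressure) -> tuple[float, float]:
    """Thevenin (conductance, open-circuit pressure) of the subtree at
    ``sid`` seen from its upstream node. ``leaf_pressure`` maps leaf ids to
    their Dirichlet pressures."""
    g = _conductance(tree, sid)
    kids = tree.children_of(sid)
    if not kids:
        return g, leaf_pressure[sid]
    parts = [_reduce_subtree(tree, k, leaf_pressure) for k in kids]
    g_par = math.fsum(gi for gi, _ in parts)
    p_par = math.fsum(gi * pi for gi, pi in parts) / g_par
    return 1.0 / (1.0 / g + 1.0 / g_par), p_par


def _nontarget_conductance(tree: VascularTree, sid: str) -> float:
    """Equivalent conductance from the upstream node of ``sid`` to the
    (uniform-pressure) non-target outlets, excluding the target subtree."""
    g = _conductance(tree, sid)
    if not tree.children_of(sid):
        return g
    kids = [k for k in tree.children_of(sid) if k != tree.target_branch_id]
    if not kids:
        raise BracketError(
            f"segment {sid!r} feeds only the target branch; the inlet flow "
            "has no non-target drainage path and no finite stall exists"
        )
    g_par = math.fsum(_nontarget_conductance(tree, k) for k in kids)
    return 1.0 / (1.0 / g + 1.0 / g_par)


def analytic_stall_pressure(
    tree: VascularTree, bc: BoundaryConditions, rel_threshold: float = 0.0
) -> float:
    """Closed-form stall pressure by Thevenin reduction (no linear solve).

    With ``rel_threshold = 0`` this is the exact zero-flow stall; a nonzero
    threshold returns the pressure at which the target-branch flow equals
    that fraction of its baseline, ``(1 - rel_threshold) * P*`` — exact
    because the flow is affine in the target total pressure. Requires a
    uniform non-target outlet pressure.
    """
    if not (0.0 <= rel_threshold < 1.0):
        raise ConfigurationError("rel_threshold must be in [0, 1)")
    p_nt = _uniform_non_target_pressure(tree, bc)
    q_in = bc.steady_flow()

    # kappa: open-circuit pressure coefficient of the target subtree under
    # a unit target total pressure.
    from .solver import distribute_outlet_pressure

    target_leaves = tree.target_leaf_ids
    if bc.target_pressure_mode == "partition":
        unit = distribute_outlet_pressure(1.0, tree.outlet_areas(target_leaves))
    else:
        unit = {l: 1.0 for l in target_leaves}
    _, kappa = _reduce_subtree(tree, tree.target_branch_id, unit)

    # P_J: pressure at the target branch's upstream node when the target
    # subtree carries no flow and the whole inlet flow drains through the
    # non-target outlets at p_nt.
    path = tree.path_to_target()
    parent = tree.segments[tree.target_branch_id].parent_id
    if parent is None:
        raise BracketError(
            "target branch is the root: all inlet flow must pass it, "
            "so no finite stall pressure exists"
        )
    g_total = _nontarget_conductance(tree, tree.inlet_id)
    p_node = p_nt + q_in / g_total  # inlet-face pressure
    q_node = q_in
    for i, sid in enumerate(path[:-1]):
        # flow through this path segment, then its distal-node pressure
        p_node = p_node - q_node / _conductance(tree, sid)
        if sid == parent:
            break
        kids = [k for k in tree.children_of(sid) if k != tree.target_branch_id]
        g_kids = [_nontarget_conductance(tree, k) for k in kids]
        g_next = g_kids[kids.index(path[i + 1])]
        q_node = q_node * g_next / math.fsum(g_kids)
    p_star = p_node / kappa
    return (1.0 - rel_threshold) * p_star


def calibrate_stall_pressure(
    tree: VascularTree,
    bc: BoundaryConditions,
    desired_stall: float,
    rel_threshold: float = 0.01,
) -> VascularTree:
    """Rescale non-target terminal radii so the stall pressure matches
    ``desired_stall`` (same ``rel_threshold`` convention as
    :func:`find_stall_pressure`, so the two round-trip within the finder's
    tolerance).

    Returns a new tree differing from the input only by one multiplicative
    factor on the radii of non-target outlet segments; the target subtree
    and the topology are untouched. Raises :class:`CalibrationError` when
    no positive scale can reach the requested stall (with the bracket
    diagnostics).
    """
    p_nt = _uniform_non_target_pressure(tree, bc)
    if desired_stall <= p_nt:
        raise CalibrationError(
            f"desired stall {desired_stall} Pa must exceed the non-target "
            f"outlet pressure {p_nt} Pa"
        )
    target_members = set(tree.subtree_ids(tree.target_branch_id))
    nt_leaves = [l for l in tree.leaf_ids if l not in target_members]
    if not nt_leaves:
        raise CalibrationError("tree has no non-target outlets to rescale")
    base_radii = {l: tree.segments[l].radius for l in nt_leaves}

    def scaled(s: float) -> VascularTree:
        return tree.with_radii({l: r * s for l, r in base_radii.items()})

    def f(log_s: float) -> float:
        return (
            analytic_stall_pressure(scaled(math.exp(log_s)), bc, rel_threshold)
            - desired_stall
        )

    lo, hi = math.log(1e-4), math.log(1e4)
    f_lo, f_hi = f(lo), f(hi)
    # stall decreases as the non-target periphery widens: f_lo > 0 > f_hi
    if not (f_lo > 0 > f_hi):
        raise CalibrationError(
            f"desired stall {desired_stall} Pa not bracketed by terminal-radius "
            f"scales [{math.exp(lo):.2g}, {math.exp(hi):.2g}]: stall range "
            f"[{f_hi + desired_stall:.6g}, {f_lo + desired_stall:.6g}] Pa"
        )
    log_s = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    return scaled(math.exp(log_s))
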