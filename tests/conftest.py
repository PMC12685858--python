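"""Shared fixtures: hand-built analytic networks, the packaged reference
tree, and an independent brute-force dense solver used as the oracle for
the sparse network solver."""

import math

import numpy as np
import pytest

from emboflow import (
    BoundaryConditions,
    FluidProperties,
    VascularTree,
    VesselSegment,
    reference_fixture,
    segment_resistance,
)

MU = 0.0035
RHO = 1060.0


def make_two_outlet(
    r_root=1.0e-3,
    r_target=0.7e-3,
    r_other=0.8e-3,
    l_root=10e-3,
    l_target=8e-3,
    l_other=12e-3,
):
    """Root segment splitting into a target leaf and a non-target leaf.

    The flow split has the closed form
    Q_target = (Q * R_other + (P_other - P_target)) / (R_target + R_other),
    independent of the root resistance.
    """
    segs = [
        VesselSegment("root", None, l_root, r_root),
        VesselSegment("tgt", "root", l_target, r_target),
        VesselSegment("oth", "root", l_other, r_other),
    ]
    return VascularTree(segs, target_branch_id="tgt", fluid=FluidProperties())


def two_outlet_resistances(tree):
    r = {}
    for sid in ("tgt", "oth"):
        s = tree.segments[sid]
        r[sid] = segment_resistance(s.length, s.radius, tree.fluid.viscosity)
    return r["tgt"], r["oth"]


@pytest.fixture
def two_outlet():
    return make_two_outlet()


@pytest.fixture
def y_tree():
    """Symmetric Y: root plus two identical leaves, left one the target."""
    segs = [
        VesselSegment("root", None, 10e-3, 1.0e-3),
        VesselSegment("L", "root", 8e-3, 0.8e-3),
        VesselSegment("R", "root", 8e-3, 0.8e-3),
    ]
    return VascularTree(segs, target_branch_id="L")


@pytest.fixture(scope="session")
def fixture_tree():
    return reference_fixture()


def dense_flows(tree, bc):
    """Brute-force dense nodal solve (independent of the sparse solver).

    Builds the full conductance matrix over every node including the
    Dirichlet outlets (identity rows), solves with numpy, and returns
    signed segment flows.
    """
    q_in = float(bc.inlet_flow)
    outlet_p = bc.expand(tree)
    nodes = ["inlet"] + list(tree.segments)
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    b = np.zeros(n)
    g = {}
    for s in tree:
        g[s.segment_id] = 1.0 / segment_resistance(
            s.length, s.radius, tree.fluid.viscosity
        )
        u = s.parent_id if s.parent_id is not None else "inlet"
        v = s.segment_id
        for x, y in ((u, v), (v, u)):
            a[idx[x], idx[x]] += g[s.segment_id]
            a[idx[x], idx[y]] -= g[s.segment_id]
    b[idx["inlet"]] += q_in
    for leaf in tree.leaf_ids:
        a[idx[leaf], :] = 0.0
        a[idx[leaf], idx[leaf]] = 1.0
        b[idx[leaf]] = outlet_p[leaf]
    p = np.linalg.solve(a, b)
    flows = {}
    for s in tree:
        u = s.parent_id if s.parent_id is not None else "inlet"
        flows[s.segment_id] = g[s.segment_id] * (p[idx[u]] - p[idx[s.segment_id]])
    return flows


@pytest.fixture
def dense_oracle():
    return dense_flows


@pytest.fixture
def baseline_bc():
    """Study baseline: 5 cm^3/s steady inlet, 300 Pa outlets."""
    return BoundaryConditions(inlet_flow=5e-6, non_target_pressure=300.0)
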