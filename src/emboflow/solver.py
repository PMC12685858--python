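"""Laminar Poiseuille-network flow solver.

The arterial tree is treated as a lumped (0D) hydraulic network: each
segment is a Poiseuille resistance ``R = 8*mu*L/(pi*r^4)``, junctions
enforce pressure continuity and mass conservation (Kirchhoff's current
law), the inlet carries a prescribed volumetric flow, and every outlet
holds a Dirichlet pressure. This is the exact steady solution of the
laminar incompressible problem on a network of rigid cylinders, and it is
the reduced-order surrogate this package uses in place of 3D CFD: every
quantity the analysis needs (flow splits, junction pressures, Reynolds
numbers, the embolization efficiency index) lives on the network.

Pulsatile inflow is handled quasi-steadily — one steady solve per time
sample at the instantaneous inlet flow — which is appropriate for
flow-ratio quantities at the Reynolds numbers of interest (~400);
inertance, compliance and Womersley effects are out of scope.

Sign convention: positive segment flow points away from the inlet
(rootward-to-leafward); negative flow is retrograde ("backflow").

Node naming: each segment's distal junction carries the segment's own id;
the inlet face is the node ``"inlet"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError
from .tree import VascularTree

__all__ = [
    "PulsatileWaveform",
    "BoundaryConditions",
    "FlowSolution",
    "LaminarFlowWarning",
    "segment_resistance",
    "distribute_outlet_pressure",
    "solve_steady",
    "solve_pulsatile",
    "reynolds",
    "detect_backflow",
]

#: Transition Reynolds number; above it the laminar closure is invalid.
RE_LAMINAR_LIMIT = 2300.0

INLET_NODE = "inlet"


class LaminarFlowWarning(UserWarning):
    """Emitted when a segment Reynolds number exceeds the laminar limit."""


def segment_resistance(length: float, radius: float, viscosity: float) -> float:
    """Poiseuille hydraulic resistance ``8*mu*L/(pi*r^4)`` [Pa*s/m^3].

    All arguments must be strictly positive (meters, meters, Pa*s).
    """
    if length <= 0 or radius <= 0 or viscosity <= 0:
        raise ValueError(
            "length, radius and viscosity must all be > 0, got "
            f"L={length}, r={radius}, mu={viscosity}"
        )
    return 8.0 * viscosity * length / (math.pi * radius**4)


def distribute_outlet_pressure(
    total_pressure: float, outlet_areas: Mapping[str, float]
) -> dict[str, float]:
    """Partition a total pressure over outlets proportionally to lumen area.

    ``P_i = total * A_i / sum(A)``; the parts sum to the total exactly.
    """
    if not outlet_areas:
        raise ValueError("outlet_areas must be non-empty")
    if total_pressure < 0:
        raise ValueError("total_pressure must be >= 0")
    areas = dict(outlet_areas)
    for sid, a in areas.items():
        if a <= 0:
            raise ValueError(f"outlet {sid!r}: area must be > 0, got {a}")
    total_area = math.fsum(areas.values())
    return {sid: total_pressure * a / total_area for sid, a in areas.items()}


@dataclass(frozen=True)
class PulsatileWaveform:
    """Strictly positive periodic inlet flow built from sinusoidal harmonics.

    ``Q(t) = mean_flow * (1 + sum_m a_m * sin(2*pi*(m+1)*t/period + phi_m))``

    The zero-mean harmonic form makes the period average equal ``mean_flow``
    exactly. Positivity over one period is checked at construction on a
    dense grid.

    Attributes
    ----------
    mean_flow : float
        Period-averaged flow, m^3/s.
    period : float
        Cardiac period, s (default 0.8 s, ~75 bpm).
    harmonic_amplitudes, harmonic_phases : tuple of float
        Dimensionless fractional amplitudes and phases (radians) of
        harmonics 1, 2, ...
    """

    mean_flow: float
    period: float = 0.8
    harmonic_amplitudes: tuple[float, ...] = (0.45, 0.18)
    harmonic_phases: tuple[float, ...] = (0.0, math.pi / 2)

    def __post_init__(self) -> None:
        if self.mean_flow <= 0 or self.period <= 0:
            raise ConfigurationError("mean_flow and period must be > 0")
        if len(self.harmonic_amplitudes) != len(self.harmonic_phases):
            raise ConfigurationError("amplitudes and phases must align")
        q = self.flow_at(np.linspace(0.0, self.period, 4096, endpoint=False))
        if q.min() <= 0:
            raise ConfigurationError(
                f"waveform must stay positive; minimum {q.min():.3g} m^3/s"
            )

    def flow_at(self, t):
        """Instantaneous inlet flow at time(s) ``t`` [m^3/s]."""
        t = np.asarray(t, dtype=float)
        q = np.ones_like(t)
        for m, (a, phi) in enumerate(
            zip(self.harmonic_amplitudes, self.harmonic_phases), start=1
        ):
            q = q + a * np.sin(2.0 * math.pi * m * t / self.period + phi)
        return self.mean_flow * q

    def sample(self, n_steps: int, n_periods: int = 1) -> np.ndarray:
        """Uniform left-endpoint sample times over ``n_periods`` periods."""
        return np.arange(n_steps * n_periods) * (self.period / n_steps)

    @property
    def pulsatility_index(self) -> float:
        """(Qmax - Qmin) / Qmean over one period (dense-grid estimate)."""
        q = self.flow_at(np.linspace(0.0, self.period, 8192, endpoint=False))
        return float((q.max() - q.min()) / self.mean_flow)

    @classmethod
    def default(
        cls,
        mean_flow: float = 5e-6,
        period: float = 0.8,
        pulsatility_index: float = 1.0,
    ) -> "PulsatileWaveform":
        """Two-harmonic arterial-like waveform rescaled to a target
        pulsatility index (default 1.0)."""
        base = cls(mean_flow=mean_flow, period=period)
        scale = pulsatility_index / base.pulsatility_index
        return cls(
            mean_flow=mean_flow,
            period=period,
            harmonic_amplitudes=tuple(a * scale for a in base.harmonic_amplitudes),
            harmonic_phases=base.harmonic_phases,
        )


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet flow prescription plus per-outlet pressures.

    The per-outlet pressure map is assembled by :meth:`expand`:

    - outlets named in ``outlet_pressures`` take that value;
    - otherwise target outlets share ``target_total_pressure`` (partitioned
      proportionally to outlet lumen area, the default, or every target
      outlet at the full total with ``target_pressure_mode="common"``);
    - all remaining outlets sit at ``non_target_pressure`` (default 300 Pa).

    ``inlet_flow`` is a steady flow in m^3/s or a :class:`PulsatileWaveform`.
    """

    inlet_flow: float | PulsatileWaveform
    outlet_pressures: Mapping[str, float] | None = None
    target_total_pressure: float | None = None
    non_target_pressure: float = 300.0
    target_pressure_mode: str = "partition"

    def __post_init__(self) -> None:
        if isinstance(self.inlet_flow, (int, float)) and self.inlet_flow < 0:
            raise ConfigurationError("inlet_flow must be >= 0")
        if self.target_pressure_mode not in ("partition", "common"):
            raise ConfigurationError(
                "target_pressure_mode must be 'partition' or 'common'"
            )

    def expand(self, tree: VascularTree) -> dict[str, float]:
        """Full leaf_id -> pressure map for ``tree`` (Pa)."""
        pressures: dict[str, float] = {}
        target_leaves = set(tree.target_leaf_ids)
        explicit = dict(self.outlet_pressures or {})
        unknown = set(explicit) - set(tree.leaf_ids)
        if unknown:
            raise ConfigurationError(
                f"outlet_pressures names non-leaf segments: {sorted(unknown)}"
            )
        if self.target_total_pressure is not None:
            free_targets = [t for t in tree.target_leaf_ids if t not in explicit]
            if free_targets:
                if self.target_pressure_mode == "partition":
                    pressures.update(
                        distribute_outlet_pressure(
                            self.target_total_pressure,
                            tree.outlet_areas(free_targets),
                        )
                    )
                else:  # every target outlet at the full total
                    pressures.update(
                        {t: self.target_total_pressure for t in free_targets}
                    )
        for leaf in tree.leaf_ids:
            if leaf in explicit:
                pressures[leaf] = explicit[leaf]
            elif leaf not in pressures:
                pressures[leaf] = self.non_target_pressure
        for leaf, p in pressures.items():
            if not math.isfinite(p):
                raise ConfigurationError(f"outlet {leaf!r}: non-finite pressure {p}")
        return pressures

    def steady_flow(self) -> float:
        if isinstance(self.inlet_flow, PulsatileWaveform):
            raise ConfigurationError(
                "boundary conditions carry a pulsatile waveform; "
                "use solve_pulsatile or pass the mean flow explicitly"
            )
        return float(self.inlet_flow)


@dataclass(frozen=True)
class FlowSolution:
    """One steady (or one-time-sample) network solution.

    ``node_pressures`` maps junction ids (segment ids for distal junctions
    plus ``"inlet"``) to Pa; ``segment_flows`` are signed m^3/s, positive
    leafward; velocities are mean lumen velocities Q/(pi r^2) in m/s;
    ``segment_reynolds`` uses Re = 4*rho*|Q| / (pi*mu*D).
    """

    time: float
    node_pressures: Mapping[str, float]
    segment_flows: Mapping[str, float]
    segment_velocities: Mapping[str, float]
    segment_reynolds: Mapping[str, float]


def _segment_conductances(tree: VascularTree) -> dict[str, float]:
    mu = tree.fluid.viscosity
    return {
        s.segment_id: 1.0 / segment_resistance(s.length, s.radius, mu)
        for s in tree
    }


def solve_steady(tree: VascularTree, bc: BoundaryConditions) -> FlowSolution:
    """Solve the steady Poiseuille network exactly.

    Assembles the sparse symmetric positive-definite nodal conductance
    system (Kirchhoff current law at the inlet face and every internal
    junction; Dirichlet pressures at outlets), solves it, and back-computes
    signed segment flows, velocities and Reynolds numbers. Mass is conserved
    at every junction to solver precision and the leaf flows sum to the
    inlet flow.

    Warns with :class:`LaminarFlowWarning` if any segment Reynolds number
    exceeds 2300 (outside the laminar validity regime).
    """
    q_in = bc.steady_flow()
    outlet_p = bc.expand(tree)
    g = _segment_conductances(tree)
    leaf_set = set(tree.leaf_ids)

    unknown = [INLET_NODE] + [sid for sid in tree.segments if sid not in leaf_set]
    idx = {node: i for i, node in enumerate(unknown)}
    n = len(unknown)
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    b[idx[INLET_NODE]] = q_in

    for s in tree:
        gu = g[s.segment_id]
        up = s.parent_id if s.parent_id is not None else INLET_NODE
        down = s.segment_id
        iu = idx[up]
        if down in idx:
            iv = idx[down]
            rows += [iu, iv, iu, iv]
            cols += [iu, iv, iv, iu]
            vals += [gu, gu, -gu, -gu]
        else:  # Dirichlet outlet
            rows.append(iu)
            cols.append(iu)
            vals.append(gu)
            b[iu] += gu * outlet_p[down]

    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        p_unknown = spla.spsolve(a, b)
    except RuntimeError as e:  # pragma: no cover - degenerate geometry
        raise SolverError(f"singular nodal system: {e}") from e
    if not np.all(np.isfinite(p_unknown)):
        raise SolverError("nodal solve produced non-finite pressures")

    node_pressures = {node: float(p_unknown[i]) for node, i in idx.items()}
    node_pressures.update(outlet_p)

    flows, velocities, reynolds_nums = {}, {}, {}
    rho, mu = tree.fluid.density, tree.fluid.viscosity
    for s in tree:
        up = s.parent_id if s.parent_id is not None else INLET_NODE
        q = g[s.segment_id] * (node_pressures[up] - node_pressures[s.segment_id])
        flows[s.segment_id] = q
        velocities[s.segment_id] = q / (math.pi * s.radius**2)
        reynolds_nums[s.segment_id] = 2.0 * rho * abs(q) / (math.pi * mu * s.radius)

    max_re = max(reynolds_nums.values())
    if max_re > RE_LAMINAR_LIMIT:
        warnings.warn(
            f"maximum segment Reynolds number {max_re:.0f} exceeds the laminar "
            f"limit {RE_LAMINAR_LIMIT:.0f}; the Poiseuille closure is invalid",
            LaminarFlowWarning,
            stacklevel=2,
        )
    return FlowSolution(
        time=0.0,
        node_pressures=node_pressures,
        segment_flows=flows,
        segment_velocities=velocities,
        segment_reynolds=reynolds_nums,
    )


def solve_pulsatile(
    tree: VascularTree,
    bc: BoundaryConditions,
    n_steps: int = 64,
    n_periods: int = 1,
) -> list[FlowSolution]:
    """Quasi-steady pulsatile solve: one steady solve per time sample.

    The inlet waveform is sampled at ``n_steps`` uniform left-endpoint
    times per period over ``n_periods`` periods, so period averages of the
    harmonics vanish exactly and time-averaged flows match the steady
    solution at the mean inlet flow when outlet pressures are uniform.
    """
    if not isinstance(bc.inlet_flow, PulsatileWaveform):
        raise ConfigurationError("solve_pulsatile requires a PulsatileWaveform")
    if n_steps < 16:
        raise ConfigurationError("n_steps must be >= 16")
    wf = bc.inlet_flow
    solutions = []
    for t in wf.sample(n_steps, n_periods):
        bc_t = replace(bc, inlet_flow=float(wf.flow_at(t)))
        sol = solve_steady(tree, bc_t)
        solutions.append(replace(sol, time=float(t)))
    return solutions


def reynolds(solution: FlowSolution, tree: VascularTree) -> dict[str, float]:
    """Per-segment Reynolds number Re = 4*rho*|Q|/(pi*mu*D), D = 2r."""
    rho, mu = tree.fluid.density, tree.fluid.viscosity
    out = {}
    for s in tree:
        q = solution.segment_flows[s.segment_id]
        out[s.segment_id] = 2.0 * rho * abs(q) / (math.pi * mu * s.radius)
    return out


def detect_backflow(
    solutions: FlowSolution | Sequence[FlowSolution],
    tolerance: float = 1e-12,
) -> set[tuple[str, float]]:
    """All retrograde (segment_id, time) pairs with flow < -tolerance.

    Accepts a single solution or a sequence (pulsatile). Empty when all
    outlet pressures are uniform and inflow is positive: a passive tree
    then carries purely leafward flow.
    """
    if isinstance(solutions, FlowSolution):
        solutions = [solutions]
    return {
        (sid, sol.time)
        for sol in solutions
        for sid, q in sol.segment_flows.items()
        if q < -tolerance
    }
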