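"""Study orchestration: pressure sweep, inflow sweep, backflow study, report.

These functions reproduce the study design on any valid tree: a steady
target-pressure sweep (default 0..5000 Pa in 1000 Pa steps), an inlet-flow
sweep under uniform outlet pressures (the configuration under which the
EEI is provably invariant to inflow in the linear network), and a
pulsatile backflow study. ``report`` renders tables, plots and a
machine-readable, byte-deterministic JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .eei import EEIMap, compute_eei, cross_section_flows, time_averaged_eei
from .errors import ConfigurationError
from .io import eei_map_to_frame, tree_to_json
from .solver import (
    BoundaryConditions,
    FlowSolution,
    PulsatileWaveform,
    detect_backflow,
    solve_pulsatile,
    solve_steady,
)
from .stall import find_stall_pressure
from .tree import VascularTree

__all__ = [
    "SweepResult",
    "InflowSweepResult",
    "BackflowReport",
    "run_pressure_sweep",
    "run_inflow_sweep",
    "run_backflow_study",
    "report",
    "DEFAULT_PRESSURES",
]

#: The six target total-pressure conditions of the default sweep [Pa].
DEFAULT_PRESSURES = (0.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0)

#: Baseline steady inlet flow [m^3/s] (5 cm^3/s).
DEFAULT_INLET_FLOW = 5e-6


def tree_hash(tree: VascularTree) -> str:
    """SHA-256 of the canonical JSON serialization."""
    return hashlib.sha256(tree_to_json(tree).encode()).hexdigest()


@dataclass(frozen=True)
class SweepResult:
    """One result bundle per boundary condition, in condition order."""

    conditions: tuple[BoundaryConditions, ...]
    solutions: tuple  # FlowSolution or tuple[FlowSolution, ...] per condition
    eei_maps: tuple[EEIMap, ...]
    cross_sections: tuple
    backflow: tuple[frozenset, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conditions)


def run_pressure_sweep(
    tree: VascularTree,
    pressures: Sequence[float] = DEFAULT_PRESSURES,
    inlet_flow: float = DEFAULT_INLET_FLOW,
    non_target_pressure: float = 300.0,
) -> SweepResult:
    """Steady sweep over target total pressures.

    For each condition the total pressure is partitioned over the target
    outlets by lumen area, the network is solved, and the EEI map,
    cross-section flows and backflow set are extracted. Below stall the
    target-branch flow decreases strictly (and exactly linearly) across
    conditions.
    """
    pressures = [float(p) for p in pressures]
    if any(p < 0 for p in pressures):
        raise ConfigurationError("sweep pressures must be non-negative")
    if any(b <= a for a, b in zip(pressures, pressures[1:])):
        raise ConfigurationError("sweep pressures must be strictly increasing")

    conditions, solutions, maps, sections, backflows = [], [], [], [], []
    for p in pressures:
        bc = BoundaryConditions(
            inlet_flow=inlet_flow,
            target_total_pressure=p,
            non_target_pressure=non_target_pressure,
        )
        sol = solve_steady(tree, bc)
        conditions.append(bc)
        solutions.append(sol)
        maps.append(replace(compute_eei(tree, sol), condition_id=f"P{p:g}"))
        sections.append(cross_section_flows(tree, sol))
        backflows.append(frozenset(detect_backflow(sol)))
    return SweepResult(
        conditions=tuple(conditions),
        solutions=tuple(solutions),
        eei_maps=tuple(maps),
        cross_sections=tuple(sections),
        backflow=tuple(backflows),
        metadata={
            "tree_hash": tree_hash(tree),
            "inlet_flow_m3s": inlet_flow,
            "non_target_pressure_Pa": non_target_pressure,
        },
    )


@dataclass(frozen=True)
class InflowSweepResult:
    """Inflow sweep bundle plus the EEI-invariance verdict."""

    sweep: SweepResult
    max_delta_eei: float  # max |dEEI| over segments and scale pairs, % points
    invariant: bool  # max_delta_eei < tolerance

    #: Invariance tolerance in percentage points.
    TOLERANCE = 1e-6


def run_inflow_sweep(
    tree: VascularTree,
    inlet_scales: Sequence[float],
    base_flow: float = DEFAULT_INLET_FLOW,
    waveform: PulsatileWaveform | None = None,
    outlet_pressure: float = 300.0,
    target_total_pressure: float | None = None,
    n_steps: int = 64,
) -> InflowSweepResult:
    """Sweep the inlet flow and test EEI-map invariance.

    The study configuration is uniform outlet pressures (no target pressure
    elevation), under which the flow split — hence the EEI map — is exactly
    independent of the inlet flow magnitude. Passing a
    ``target_total_pressure`` breaks that uniformity and the verdict is
    expected to fail.
    """
    if any(s <= 0 for s in inlet_scales):
        raise ConfigurationError("inlet scales must be positive")
    conditions, solutions, maps, sections, backflows = [], [], [], [], []
    for s in inlet_scales:
        if waveform is not None:
            wf = replace(waveform, mean_flow=waveform.mean_flow * s)
            bc = BoundaryConditions(
                inlet_flow=wf,
                target_total_pressure=target_total_pressure,
                non_target_pressure=outlet_pressure,
            )
            sols = tuple(solve_pulsatile(tree, bc, n_steps=n_steps))
            emap = time_averaged_eei(tree, sols)
            sol_repr: object = sols
            cs = cross_section_flows(tree, sols[0])
            bf = frozenset(detect_backflow(sols))
        else:
            bc = BoundaryConditions(
                inlet_flow=base_flow * s,
                target_total_pressure=target_total_pressure,
                non_target_pressure=outlet_pressure,
            )
            sol = solve_steady(tree, bc)
            emap = compute_eei(tree, sol)
            sol_repr = sol
            cs = cross_section_flows(tree, sol)
            bf = frozenset(detect_backflow(sol))
        conditions.append(bc)
        solutions.append(sol_repr)
        maps.append(replace(emap, condition_id=f"x{s:g}"))
        sections.append(cs)
        backflows.append(bf)

    # verdict: largest EEI shift at any site defined under every scale
    common = set(tree.segments)
    for m in maps:
        common &= set(m.values)
    max_delta = 0.0
    for sid in common:
        vals = [m.values[sid] for m in maps]
        max_delta = max(max_delta, max(vals) - min(vals))
    sweep = SweepResult(
        conditions=tuple(conditions),
        solutions=tuple(solutions),
        eei_maps=tuple(maps),
        cross_sections=tuple(sections),
        backflow=tuple(backflows),
        metadata={"tree_hash": tree_hash(tree), "inlet_scales": tuple(inlet_scales)},
    )
    return InflowSweepResult(
        sweep=sweep,
        max_delta_eei=max_delta,
        invariant=max_delta < InflowSweepResult.TOLERANCE,
    )


@dataclass(frozen=True)
class BackflowReport:
    """Per-segment retrograde time fractions under pulsatile inflow."""

    retrograde_fraction: Mapping[str, float]  # target-subtree segments
    episodes: frozenset  # (segment_id, time) pairs, whole tree
    n_samples: int
    target_pressure: float

    @property
    def any_backflow(self) -> bool:
        return any(f > 0 for f in self.retrograde_fraction.values())


def run_backflow_study(
    tree: VascularTree,
    waveform: PulsatileWaveform,
    target_pressure: float,
    non_target_pressure: float = 300.0,
    n_steps: int = 64,
    n_periods: int = 1,
) -> BackflowReport:
    """Pulsatile solve with an elevated target pressure; reports the
    fraction of the cycle each target-subtree segment spends retrograde.

    Retrograde episodes appear exactly when the target pressure exceeds
    the instantaneous (zero-flow) stall pressure at the waveform minimum.
    """
    bc = BoundaryConditions(
        inlet_flow=waveform,
        target_total_pressure=target_pressure,
        non_target_pressure=non_target_pressure,
    )
    sols = solve_pulsatile(tree, bc, n_steps=n_steps, n_periods=n_periods)
    episodes = frozenset(detect_backflow(sols))
    target_ids = tree.subtree_ids(tree.target_branch_id)
    retro_counts = {sid: 0 for sid in target_ids}
    for sol in sols:
        for sid in target_ids:
            if sol.segment_flows[sid] < -1e-12:
                retro_counts[sid] += 1
    n = len(sols)
    return BackflowReport(
        retrograde_fraction={sid: c / n for sid, c in retro_counts.items()},
        episodes=episodes,
        n_samples=n,
        target_pressure=target_pressure,
    )


def _eei_by_site(tree: VascularTree, sweep: SweepResult) -> dict:
    """EEI at each cross-section site, per sweep condition."""
    path = tree.path_to_target()
    out: dict[str, dict[str, float | None]] = {}
    for i, sid in enumerate(path, start=1):
        site = f"CS-{i}"
        out[site] = {}
        for bc, m in zip(sweep.conditions, sweep.eei_maps):
            key = (
                f"{bc.target_total_pressure:g}"
                if bc.target_total_pressure is not None
                else "uniform"
            )
            out[site][key] = m.values.get(sid)
    return out


def report(
    pressure_sweep: SweepResult,
    output_dir,
    *,
    tree: VascularTree | None = None,
    inflow_sweep: InflowSweepResult | None = None,
    stall_pressure: float | None = None,
    backflow: BackflowReport | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write CSV tables, plots and a deterministic JSON summary.

    Returns a name -> path map of everything written. Rerunning with the
    same inputs reproduces the summary JSON byte for byte.
    """
    if len(pressure_sweep) == 0:
        raise ValueError("cannot report an empty sweep")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # cross-section flows per condition
    rows = []
    for bc, sections in zip(pressure_sweep.conditions, pressure_sweep.cross_sections):
        for cs in sections:
            rows.append(
                {
                    "target_total_pressure_Pa": bc.target_total_pressure,
                    "cross_section": cs.label,
                    "segment_id": cs.segment_id,
                    "flow_cm3s": cs.flow * 1e6,
                }
            )
    cs_frame = pd.DataFrame(rows)
    written["cross_section_flows"] = outdir / "cross_section_flows.csv"
    cs_frame.to_csv(written["cross_section_flows"], index=False)

    # EEI maps, one long table
    eei_frame = pd.concat(
        [eei_map_to_frame(m, m.condition_id) for m in pressure_sweep.eei_maps],
        ignore_index=True,
    )
    written["eei_maps"] = outdir / "eei_maps.csv"
    eei_frame.to_csv(written["eei_maps"], index=False)

    summary: dict[str, object] = {
        "n_conditions": len(pressure_sweep),
        "metadata": dict(pressure_sweep.metadata),
        "stall_pressure_Pa": stall_pressure,
        "invariance_verdict": None
        if inflow_sweep is None
        else {
            "max_delta_eei_percent": inflow_sweep.max_delta_eei,
            "invariant": inflow_sweep.invariant,
        },
        "backflow": None
        if backflow is None
        else {
            "target_pressure_Pa": backflow.target_pressure,
            "any_backflow": backflow.any_backflow,
            "max_retrograde_fraction": max(
                backflow.retrograde_fraction.values(), default=0.0
            ),
        },
    }
    if tree is not None:
        summary["eei_by_site"] = _eei_by_site(tree, pressure_sweep)
        summary["n_outlets"] = tree.n_outlets
        summary["n_target_outlets"] = len(tree.target_leaf_ids)
    written["summary"] = outdir / "summary.json"
    written["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    if make_plots:
        written.update(_plots(pressure_sweep, tree, outdir))
    return written


def _plots(sweep: SweepResult, tree: VascularTree | None, outdir: Path) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    pressures = [bc.target_total_pressure for bc in sweep.conditions]

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = [cs.label for cs in sweep.cross_sections[0]]
    for j, label in enumerate(labels):
        ax.plot(
            pressures,
            [sections[j].flow * 1e6 for sections in sweep.cross_sections],
            marker="o",
            label=label,
        )
    ax.set_xlabel("target total pressure [Pa]")
    ax.set_ylabel("cross-section flow [cm$^3$/s]")
    ax.legend(fontsize=8)
    fig.tight_layout()
    written["plot_cs_flows"] = outdir / "cross_section_flows.png"
    fig.savefig(written["plot_cs_flows"], dpi=110)
    plt.close(fig)

    if tree is not None:
        path = tree.path_to_target()
        fig, ax = plt.subplots(figsize=(5, 4))
        for bc, m in zip(sweep.conditions, sweep.eei_maps):
            ax.plot(
                range(1, len(path) + 1),
                [m.values.get(sid, float("nan")) for sid in path],
                marker="s",
                label=f"{bc.target_total_pressure:g} Pa",
            )
        ax.set_xlabel("cross-section (inlet $\\to$ target)")
        ax.set_ylabel("EEI [%]")
        ax.legend(fontsize=8)
        fig.tight_layout()
        written["plot_eei"] = outdir / "eei_vs_site.png"
        fig.savefig(written["plot_eei"], dpi=110)
        plt.close(fig)
    return written
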