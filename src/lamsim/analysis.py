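"""Postprocessing of equilibrium states into regional stress reports.

Summaries mirror the form of the published results: per head-descent level,
volume-weighted mean / min / max / SD of element von Mises stress in three
anatomical zones of the levator,

* ``ICm``                — the upper dorsal (iliococcygeal) plate,
* ``pubic_attachment``   — pubovisceral + puborectal elements near the pubic
  origin (reported per side; the left side is the conventional column),
* ``prm_posteromedial``  — the distal posteromedial puborectal sling,

together with the mediosagittal elongation of the shell (deformed /
reference midline arc length) and the maximal caudal excursion of the
distal puborectal loop.  Standard deviations are population SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import LabeledTetMesh, REGION_NAMES
from .errors import InvalidInputError, UnknownLandmarkError

__all__ = ["RegionStressSummary", "ElongationReport", "ANALYSIS_REGIONS",
           "region_element_mask", "region_summary", "summarize_states",
           "loading_order", "elongation_report", "export_table", "read_table"]

ANALYSIS_REGIONS = ("ICm", "pubic_attachment_left", "pubic_attachment_right",
                    "prm_posteromedial")


@dataclass(frozen=True)
class RegionStressSummary:
    station: float
    region: str
    mean: float
    minimum: float
    maximum: float
    sd: float

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum and self.sd >= 0):
            raise InvalidInputError(
                f"inconsistent summary for {self.region}: "
                f"min {self.minimum}, mean {self.mean}, max {self.maximum}")


@dataclass(frozen=True)
class ElongationReport:
    initial_arc_length: float            # mm
    arc_lengths: np.ndarray              # per frame, mm
    stretch_ratios: np.ndarray           # per frame
    max_stretch_ratio: float
    frame_of_max: int
    max_caudal_displacement: float       # mm, distal PRm loop


def region_element_mask(mesh: LabeledTetMesh, region, pubic_radius=45.0):
    """Element mask of an analysis region.

    ``pubic_attachment_left``/``_right`` are PVm/PRm elements whose centroid
    lies within ``pubic_radius`` mm of the pubic attachment nodes (45 mm spans the muscle belly from the pubic origin toward the hiatal margin) on that
    side (x > 0 is the anatomical left); ``prm_posteromedial`` is the
    posterior half of the PRm sling.  Plain ``ICm``/``PVm``/``PRm`` label
    masks are accepted too.
    """
    if region in REGION_NAMES:
        return mesh.region_mask(region)
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    if region in ("pubic_attachment_left", "pubic_attachment_right"):
        pubic = mesh.nodes[mesh.node_set("pubic_attachment")]
        side = 1.0 if region.endswith("left") else -1.0
        pubic = pubic[side * pubic[:, 0] >= 0]
        if len(pubic) == 0:
            pubic = mesh.nodes[mesh.node_set("pubic_attachment")]
        d = np.linalg.norm(centroids[:, None, :] - pubic[None, :, :],
                           axis=2).min(axis=1)
        sling = mesh.region_mask("PVm") | mesh.region_mask("PRm")
        return sling & (d <= pubic_radius) & (side * centroids[:, 0] >= 0)
    if region == "prm_posteromedial":
        prm = mesh.region_mask("PRm")
        y_mid = centroids[prm, 1].mean() if prm.any() else 0.0
        return prm & (centroids[:, 1] <= y_mid)
    raise UnknownLandmarkError(
        f"unknown region {region!r}; have {ANALYSIS_REGIONS + REGION_NAMES}")


def region_summary(state, mesh: LabeledTetMesh, region, pubic_radius=45.0):
    """Volume-weighted von Mises statistics of one region at one state."""
    mask = region_element_mask(mesh, region, pubic_radius)
    if not mask.any():
        raise UnknownLandmarkError(f"region {region!r} selects no elements")
    vm = np.asarray(state.von_mises)[mask]
    w = mesh.volumes()[mask]
    mean = float(np.average(vm, weights=w))
    var = float(np.average((vm - mean) ** 2, weights=w))
    return RegionStressSummary(
        station=float(state.station), region=str(region), mean=mean,
        minimum=float(vm.min()), maximum=float(vm.max()), sd=float(np.sqrt(var)))


def summarize_states(states, mesh, regions=ANALYSIS_REGIONS, pubic_radius=45.0):
    """List of per-frame, per-region summaries for a whole state sequence."""
    return [region_summary(st, mesh, r, pubic_radius)
            for st in states for r in regions]


def loading_order(summaries, threshold_rel=0.01):
    """Regions ordered by first engagement.

    A region engages at the first frame where its mean von Mises exceeds
    ``threshold_rel`` times the run's maximum regional mean.  Ties are
    broken by region name.  Returns [(region, station), ...]; an empty list
    means nothing ever engaged.
    """
    if not summaries:
        return []
    peak = max(s.mean for s in summaries)
    if peak <= 0:
        return []
    thr = threshold_rel * peak
    first = {}
    for k, s in enumerate(summaries):
        if s.mean > thr and s.region not in first:
            first[s.region] = (k, s.station)
    return [(r, first[r][1])
            for r in sorted(first, key=lambda r: (first[r][0], r))]


def _polyline_length(points):
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def elongation_report(states, mesh: LabeledTetMesh):
    """Mediosagittal stretch ratio and distal-loop caudal excursion.

    The ratio is deformed / reference arc length of the ordered
    ``mediosagittal_trace`` polyline; the caudal displacement is the
    maximum of (reference z - current z) over the ``distal_prm_loop`` node
    set and all frames.  Both are invariant under rigid motion of the
    reference mesh (the trace is material).
    """
    trace = mesh.node_set("mediosagittal_trace")
    loop = mesh.node_set("distal_prm_loop")
    if len(trace) < 2:
        raise InvalidInputError("mediosagittal trace needs at least two nodes")
    ref = _polyline_length(mesh.nodes[trace])
    lengths, caudal = [], 0.0
    for st in states:
        x = mesh.nodes + st.displacements
        lengths.append(_polyline_length(x[trace]))
        drop = (mesh.nodes[loop, 2] - x[loop, 2]).max() if len(loop) else 0.0
        caudal = max(caudal, float(drop))
    lengths = np.asarray(lengths)
    ratios = lengths / ref
    k = int(np.argmax(ratios)) if len(ratios) else 0
    return ElongationReport(
        initial_arc_length=ref, arc_lengths=lengths, stretch_ratios=ratios,
        max_stretch_ratio=float(ratios[k]) if len(ratios) else 1.0,
        frame_of_max=k, max_caudal_displacement=caudal)


_TABLE_COLUMNS = ("station", "region", "mean_mpa", "min_mpa", "max_mpa", "sd_mpa")


def export_table(summaries, path):
    """Write regional summaries as a CSV in the standard column layout."""
    df = pd.DataFrame(
        [{"station": s.station, "region": s.region, "mean_mpa": s.mean,
          "min_mpa": s.minimum, "max_mpa": s.maximum, "sd_mpa": s.sd}
         for s in summaries], columns=list(_TABLE_COLUMNS))
    df.to_csv(path, index=False)
    return df


def read_table(path):
    """Round-trip reader for :func:`export_table` output."""
    df = pd.read_csv(path)
    return [RegionStressSummary(station=r.station, region=r.region,
                                mean=r.mean_mpa, minimum=r.min_mpa,
                                maximum=r.max_mpa, sd=r.sd_mpa)
            for r in df.itertuples()]
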