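"""Prescribed fetal-head rigid-body trajectory: the cardinal movements.

The head enters the pelvis flexed, in the left occiput anterior (LOA)
position, laterally deviated, and then

* descends along the curve of Carus (a circular arc in the mediosagittal
  plane, giving the anterior drift of the descent path),
* straightens its initial lateral deviation during early descent,
* rotates internally about the craniocaudal (z) axis, linearly with
  descent, completing at a configurable station (+3 by default),
* extends about the lateral (x) axis only after the last descent station,
  while continuing caudally and anteriorly past the pubic arch.

Station is obstetric bookkeeping: the signed distance, in cm, of the head
vertex below the interspinous plane (z = 0), negative above.

The orientation at time t is composed as

    R(t) = Rx(theta_ext) . Ry(theta_lat) . Rz(theta_rot) . R_flex

with theta_lat: -lateral_deviation -> 0, theta_rot: -internal_rotation -> 0,
theta_ext: 0 -> extension_angle, so the net rotation between the first and
last frames is exactly Rx(ext) . Rz(rot) . Ry(lat) — lateral straightening
first, then internal rotation about z, then extension about x.  The total
anterior (y) translation of the head centroid is exactly the configured
displacement, and the lateral (x) translation is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GimbalAmbiguityError, InvalidInputError
from .geometry import RigidTransform

__all__ = ["TrajectoryConfig", "TrajectoryFrame", "HeadTrajectory",
           "build_trajectory", "station_of", "decompose_net_rotation",
           "trajectory_to_frame_table"]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Cardinal-movement trajectory parameters (mm, degrees, stations in cm)."""

    start_station: float = -3.0
    end_descent_station: float = 5.0
    rotation_complete_station: float = 3.0
    lateral_straight_station: float = 0.0    # deviation gone by this station
    frames_per_station: int = 2
    extension_frames: int = 10
    anterior_displacement: float = 100.0     # net centroid y translation, mm
    extension_angle: float = 80.25           # deg about the lateral (x) axis
    lateral_deviation: float = 28.66         # initial deviation, deg
    internal_rotation: float = 40.13         # deg about the z axis
    carus_radius: float = 200.0              # mm, arc of the descent path
    extension_descent_mm: float = 50.0       # extra vertex descent in extension

    def __post_init__(self):
        if not np.all(np.isfinite([self.extension_angle, self.lateral_deviation,
                                   self.internal_rotation])):
            raise InvalidInputError("trajectory angles must be finite")
        if self.end_descent_station <= self.start_station:
            raise InvalidInputError("descent must end below its start station")
        if not (self.start_station <= self.rotation_complete_station
                <= self.end_descent_station):
            raise InvalidInputError(
                "rotation completion station must lie within the descent schedule")
        if self.frames_per_station < 1 or self.extension_frames < 1:
            raise InvalidInputError("frame counts must be >= 1")
        if self.carus_radius <= 0:
            raise InvalidInputError("carus_radius must be positive")


@dataclass(frozen=True)
class TrajectoryFrame:
    time: float                  # s (delivery scaled in seconds, 1 s per frame)
    station: float               # vertex level, cm below the interspinous plane
    transform: RigidTransform


@dataclass(frozen=True)
class HeadTrajectory:
    frames: tuple

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def _rx(deg):
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


def _ry(deg):
    return Rotation.from_euler("y", deg, degrees=True).as_matrix()


def _rz(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


# flexed cephalic presentation: the head is inverted about the lateral axis
# so the vertex leads caudally and the occiput faces anteriorly
_R_FLEX = _rx(180.0)


def _vertex_local(head):
    if head is None:
        from .anatomy import build_fetal_head

        head = build_fetal_head()
    return np.asarray(head.landmarks["vertex"], float)


def build_trajectory(config: TrajectoryConfig = None, head=None):
    """Frame sequence of head poses implementing the cardinal movements.

    ``head`` supplies the vertex landmark used for station bookkeeping (the
    default fetal head if omitted).  The returned transforms move the head
    from its local frame (origin at the centroid of its landmark layout)
    into the pelvis frame.
    """
    config = config or TrajectoryConfig()
    if head is None:
        from .anatomy import build_fetal_head

        head = build_fetal_head()
    v_local = np.asarray(head.landmarks["vertex"], float)
    of = float(head.landmarks["sinciput"][1] - head.landmarks["occiput"][1])
    # suboccipital (nape) point: the region braced against the pubic arch
    # during extension, used as the extension pivot
    pivot_local = np.array([0.0, -0.43 * of, 0.24 * of])

    n_desc = int(round((config.end_descent_station - config.start_station)
                       * config.frames_per_station))
    n_ext = config.extension_frames
    stations_desc = np.linspace(config.start_station, config.end_descent_station,
                                n_desc + 1)
    vertex_z_desc = -10.0 * stations_desc
    n_frames = n_desc + 1 + n_ext

    def progress(value, start, stop):
        if stop == start:
            return np.ones_like(np.asarray(value, float))
        return np.clip((value - start) / (stop - start), 0.0, 1.0)

    p_rot = progress(stations_desc, config.start_station,
                     config.rotation_complete_station)
    p_lat = progress(stations_desc, config.start_station,
                     config.lateral_straight_station)
    theta_rot = -config.internal_rotation * (1.0 - p_rot)
    theta_lat = -config.lateral_deviation * (1.0 - p_lat)
    rot_desc = [_ry(l) @ _rz(r) @ _R_FLEX
                for l, r in zip(theta_lat, theta_rot)]

    # descent: vertex follows the station schedule exactly; anterior drift
    # along the curve-of-Carus arc
    zc = np.array([vz - (R @ v_local)[2]
                   for vz, R in zip(vertex_z_desc, rot_desc)])
    z0 = zc[0]
    drop = max(z0 - zc[-1], 0.0)
    R_arc = config.carus_radius
    if R_arc <= drop:
        raise InvalidInputError(
            f"carus_radius {R_arc:g} mm shorter than the descent drop {drop:g} mm")
    y_desc = R_arc - np.sqrt(R_arc ** 2 - np.clip(z0 - zc, 0.0, None) ** 2)
    dy_desc = float(y_desc[-1])
    if dy_desc > config.anterior_displacement:
        raise InvalidInputError(
            "curve-of-Carus arc already exceeds the configured anterior "
            f"displacement ({dy_desc:.1f} > {config.anterior_displacement:g} mm)")

    rotations = list(rot_desc)
    translations = [np.array([0.0, y, z]) for y, z in zip(y_desc, zc)]

    # extension: rotate about the drifting suboccipital pivot (braced on
    # the pubic arch), which descends by extension_descent_mm and drifts
    # anteriorly so the net centroid displacement is exactly as configured
    R_d = rot_desc[-1]
    t_d = translations[-1]
    pivot0 = R_d @ pivot_local + t_d
    theta_ext = config.extension_angle * np.linspace(0.0, 1.0, n_ext + 1)[1:]
    R_end = _rx(float(config.extension_angle)) @ R_d
    # pivot anterior drift solved so the final centroid lands on target
    target_cy = config.anterior_displacement  # centroid starts at y = 0
    dy_piv = target_cy - (pivot0[1] - (R_end @ pivot_local)[1])
    th_max = np.deg2rad(config.extension_angle)
    for j, th in enumerate(theta_ext):
        thr = np.deg2rad(th)
        # caudal slip leads (sin), anterior slip trails (1 - cos): the head
        # clears the pubic arch downward before sweeping forward under it
        s_lin = (j + 1.0) / n_ext
        s_y = (1.0 - np.cos(thr)) / (1.0 - np.cos(th_max))
        # mostly sine-led (clears the arch early) with a linear tail so the
        # vertex keeps descending to the crowning depth
        s_z = 0.65 * np.sin(thr) / np.sin(th_max) + 0.35 * s_lin
        pivot = pivot0 + np.array([0.0, dy_piv * s_y,
                                   -config.extension_descent_mm * s_z])
        R = _rx(float(th)) @ R_d
        rotations.append(R)
        translations.append(pivot - R @ pivot_local)

    frames = []
    for k in range(n_frames):
        tr = RigidTransform(rotations[k], translations[k])
        station = -(tr.apply(v_local)[2]) / 10.0
        frames.append(TrajectoryFrame(time=float(k), station=float(station),
                                      transform=tr))
    return HeadTrajectory(tuple(frames))


def station_of(transform: RigidTransform, pelvis=None, head=None):
    """Station (cm below the interspinous plane) of the head vertex.

    Station 0 is at the plane; 10 mm above is station -1.  Returns the
    continuous value; round to the schedule granularity for labels.
    """
    v = transform.apply(_vertex_local(head))
    if pelvis is not None and "interspinous" in getattr(pelvis, "planes", {}):
        point, normal = pelvis.planes["interspinous"]
        point = pelvis.pose.apply(point)
        normal = pelvis.pose.rotation @ np.asarray(normal, float)
        return float(-np.dot(v - point, normal) / 10.0)
    return float(-v[2] / 10.0)


def decompose_net_rotation(trajectory: HeadTrajectory, gimbal_tol=1e-6):
    """Decompose the net rotation into (extension, internal rotation,
    lateral straightening) degrees.

    The net rotation between the last and first frames is factored as
    Rx(ext) . Rz(rot) . Ry(lat) (lateral first, rotation about z second,
    extension about x last).  At the gimbal-degenerate configuration
    (|rot| = 90 deg) the pair (ext, lat) is not unique and a
    :class:`GimbalAmbiguityError` carrying both solutions is raised.
    """
    if len(trajectory) < 2:
        raise InvalidInputError("need at least two frames to decompose")
    R_net = trajectory[-1].transform.rotation @ trajectory[0].transform.rotation.T
    rot = Rotation.from_matrix(R_net)
    lat, rz, ext = rot.as_euler("yzx", degrees=True)
    if abs(abs(rz) - 90.0) < np.rad2deg(gimbal_tol):
        other = (ext + 180.0, rz, lat + 180.0)
        raise GimbalAmbiguityError(
            "internal rotation at 90 deg: extension/lateral split is ambiguous",
            solutions=[(ext, rz, lat), other])
    return float(ext), float(rz), float(lat)


def trajectory_to_frame_table(trajectory: HeadTrajectory):
    """Frame table (time, station, translation, quaternion) as a DataFrame."""
    rows = []
    for fr in trajectory:
        q = Rotation.from_matrix(fr.transform.rotation).as_quat()  # x, y, z, w
        t = fr.transform.translation
        rows.append({"time_s": fr.time, "station": fr.station,
                     "tx_mm": t[0], "ty_mm": t[1], "tz_mm": t[2],
                     "qx": q[0], "qy": q[1], "qz": q[2], "qw": q[3]})
    return pd.DataFrame(rows)
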