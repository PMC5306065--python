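"""Parametric synthetic anatomy: fetal head, bony pelvis, levator ani shell.

Real childbirth models segment these structures from subject MRI.  Here the
geometry is generated parametrically from the published principal dimensions
so the whole pipeline is reproducible without imaging data:

* fetal head — a star-shaped ovoid (ellipsoid cranium with occipital and
  facial prolongations) whose named landmark pairs realize the four
  obstetric diameters (suboccipitobregmatic, occipitofrontal,
  occipitomental, biparietal) exactly;
* bony pelvis — a lofted elliptical canal carrying the inlet, outlet,
  transverse-inlet and interspinous diameters as landmark pairs, with the
  interspinous plane at z = 0;
* levator ani — a funnel ("hammock") shell spanning the canal with an
  anterior urogenital hiatus, meshed with tetrahedra and partitioned into
  the iliococcygeal (ICm), pubovisceral (PVm) and puborectal (PRm)
  subdivisions, plus the attachment node sets the boundary conditions need.

Global frame: x = left lateral, y = anterior, z = cranial, millimetres.
Landmark coordinates are analytic, so measured landmark distances are
independent of mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidInputError, UnknownLandmarkError
from .geometry import RigidTransform, triangle_areas_normals

__all__ = [
    "HeadDimensions", "PelvisDimensions", "RigidSurface", "LabeledTetMesh",
    "LevatorShellParams", "REGION_NAMES",
    "build_fetal_head", "build_pelvis", "build_levator", "build_sphere",
    "build_annulus", "measure_landmark_distance",
]

REGION_NAMES = ("ICm", "PVm", "PRm")


@dataclass(frozen=True)
class HeadDimensions:
    """Principal fetal-head diameters, mm (50th-percentile reference values)."""

    suboccipitobregmatic: float = 100.3
    occipitofrontal: float = 105.7
    occipitomental: float = 131.9
    biparietal: float = 93.7

    def __post_init__(self):
        vals = (self.suboccipitobregmatic, self.occipitofrontal,
                self.occipitomental, self.biparietal)
        if any(v <= 0 for v in vals):
            raise InvalidInputError(f"head diameters must be positive, got {vals}")
        if not (self.occipitomental >= self.occipitofrontal
                >= self.suboccipitobregmatic):
            raise InvalidInputError(
                "expected occipitomental >= occipitofrontal >= suboccipitobregmatic, "
                f"got {vals[:3]}"
            )


@dataclass(frozen=True)
class PelvisDimensions:
    """Principal bony-pelvis diameters, mm."""

    inlet_ap: float = 113.4
    outlet_ap: float = 145.1
    transverse_inlet: float = 148.8
    interspinous: float = 146.7

    def __post_init__(self):
        vals = (self.inlet_ap, self.outlet_ap, self.transverse_inlet,
                self.interspinous)
        if any(v <= 0 for v in vals):
            raise InvalidInputError(f"pelvis diameters must be positive, got {vals}")


@dataclass
class RigidSurface:
    """Triangulated rigid body with named landmarks and a pose.

    ``landmarks`` map names to local-frame coordinates; ``radial_fn``, when
    present, gives the local star-shape radius in a unit direction (used for
    fast inside/outside tests in contact).  ``planes`` holds named
    (point, unit-normal) pairs in the local frame.
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str
    landmarks: dict
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    radial_fn: object = None
    planes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        triangle_areas_normals(self.vertices, self.faces)  # degeneracy check

    def landmark_position(self, name):
        if name not in self.landmarks:
            raise UnknownLandmarkError(
                f"unknown landmark {name!r}; have {sorted(self.landmarks)}")
        return self.pose.apply(self.landmarks[name])

    def posed_vertices(self):
        return self.pose.apply(self.vertices)

    def with_pose(self, pose: RigidTransform):
        return RigidSurface(self.vertices, self.faces, self.role,
                            dict(self.landmarks), pose, self.radial_fn,
                            dict(self.planes))


def measure_landmark_distance(surface: RigidSurface, landmark_a, landmark_b):
    """Euclidean distance (mm) between two named landmarks in current pose."""
    return float(np.linalg.norm(surface.landmark_position(landmark_a)
                                - surface.landmark_position(landmark_b)))


# ---------------------------------------------------------------------------
# star-shaped triangulated surfaces (head, sphere)

def _uv_sphere_topology(n_lat, n_lon):
    """Vertices (unit directions) and faces of a closed lat-lon sphere."""
    thetas = np.linspace(0.0, np.pi, n_lat + 1)
    dirs = [np.array([0.0, 0.0, 1.0])]
    rows = []
    for th in thetas[1:-1]:
        phis = np.arange(n_lon) * (2 * np.pi / n_lon)
        ring = np.stack([np.sin(th) * np.cos(phis),
                         np.sin(th) * np.sin(phis),
                         np.full(n_lon, np.cos(th))], axis=1)
        rows.append(np.arange(len(dirs), len(dirs) + n_lon))
        dirs.extend(ring)
    south = len(dirs)
    dirs.append(np.array([0.0, 0.0, -1.0]))
    dirs = np.asarray(dirs)

    faces = []
    top = rows[0]
    for k in range(n_lon):                       # north cap (outward CCW)
        faces.append((0, top[k], top[(k + 1) % n_lon]))
    for r in range(len(rows) - 1):
        a, b = rows[r], rows[r + 1]
        for k in range(n_lon):
            k2 = (k + 1) % n_lon
            faces.append((a[k], b[k], b[k2]))
            faces.append((a[k], b[k2], a[k2]))
    bot = rows[-1]
    for k in range(n_lon):
        faces.append((south, bot[(k + 1) % n_lon], bot[k]))
    return dirs, np.asarray(faces, int)


def _star_surface(radial_fn, mean_radius, target_edge, role, landmarks):
    n_lat = max(8, int(round(np.pi * mean_radius / target_edge)))
    n_lon = max(12, int(round(2 * np.pi * mean_radius / target_edge)))
    dirs, faces = _uv_sphere_topology(n_lat, n_lon)
    radii = radial_fn(dirs)
    verts = dirs * radii[:, None]
    return RigidSurface(verts, faces, role, landmarks, radial_fn=radial_fn)


def build_sphere(radius, target_edge=4.0, center=(0.0, 0.0, 0.0)):
    """Rigid sphere fixture (local frame centred at the origin)."""
    if radius <= 0 or target_edge <= 0:
        raise InvalidInputError("radius and target_edge must be positive")

    def radial(dirs):
        return np.full(np.atleast_2d(dirs).shape[0], float(radius))

    surf = _star_surface(radial, radius, target_edge, "sphere",
                         {"center": np.zeros(3)})
    surf.pose = RigidTransform(np.eye(3), np.asarray(center, float))
    return surf


def _head_landmarks(dims: HeadDimensions):
    """Analytic landmark layout realizing the four diameters exactly.

    Local head frame: z toward the vertex (cranial for a flexed head),
    y toward the face, x toward the left parietal bone.
    """
    of, bp = dims.occipitofrontal, dims.biparietal
    lm = {
        "parietal_left": np.array([bp / 2.0, 0.0, 0.0]),
        "parietal_right": np.array([-bp / 2.0, 0.0, 0.0]),
        "occiput": np.array([0.0, -of / 2.0, 0.0]),
        "sinciput": np.array([0.0, of / 2.0, 0.0]),
        "vertex": np.array([0.0, 0.0, 0.52 * of]),
    }
    lm["subocciput"] = np.array([0.0, -0.40 * of, -0.22 * of])
    u_bregma = np.array([0.0, 0.648, 0.762])
    u_bregma /= np.linalg.norm(u_bregma)
    lm["bregma"] = lm["subocciput"] + dims.suboccipitobregmatic * u_bregma
    u_mentum = np.array([0.0, np.cos(np.deg2rad(25.0)), -np.sin(np.deg2rad(25.0))])
    lm["mentum"] = lm["occiput"] + dims.occipitomental * u_mentum
    return lm


def build_fetal_head(dims: HeadDimensions = None, target_edge=4.0):
    """Rigid fetal-head ovoid whose landmark pairs realize the diameters.

    The surface is a star-shaped radial field: an ellipsoid cranium modulated
    by Gaussian bumps solved so the surface passes through every landmark.
    Landmark coordinates themselves are analytic, so the measured diameters
    are exact at any mesh resolution.
    """
    dims = dims or HeadDimensions()
    if target_edge <= 0:
        raise InvalidInputError("target_edge must be positive")
    lm = _head_landmarks(dims)
    semi = np.array([dims.biparietal / 2.0, dims.occipitofrontal / 2.0,
                     0.52 * dims.occipitofrontal])

    def ellipsoid_radius(dirs):
        d = np.atleast_2d(dirs)
        return 1.0 / np.sqrt(((d / semi) ** 2).sum(axis=1))

    names = sorted(lm)
    lm_dirs = np.array([lm[n] / np.linalg.norm(lm[n]) for n in names])
    lm_radii = np.array([np.linalg.norm(lm[n]) for n in names])
    sigma = 0.45  # bump angular width, rad

    def bumps(dirs):
        d = np.atleast_2d(dirs)
        cosang = np.clip(d @ lm_dirs.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        return np.exp(-0.5 * (ang / sigma) ** 2)

    B = bumps(lm_dirs)
    base = ellipsoid_radius(lm_dirs)
    weights = np.linalg.solve(B * base[:, None], lm_radii - base)

    def radial(dirs):
        d = np.atleast_2d(dirs)
        r0 = ellipsoid_radius(d)
        return r0 * (1.0 + bumps(d) @ weights / 1.0)

    mean_r = float(np.mean(lm_radii))
    return _star_surface(radial, mean_r, target_edge, "head", lm)


# ---------------------------------------------------------------------------
# pelvis

def build_pelvis(dims: PelvisDimensions = None, target_edge=4.0,
                 inlet_z=55.0, outlet_z=-55.0):
    """Rigid bony birth canal lofted through inlet, midpelvic and outlet rings.

    The interspinous plane sits at z = 0 (point (0,0,0), normal +z); ischial
    spine, inlet and outlet landmark pairs realize the printed diameters.
    """
    dims = dims or PelvisDimensions()
    if target_edge <= 0:
        raise InvalidInputError("target_edge must be positive")
    # semi-axes (transverse, AP) at the three control rings
    ctrl_z = np.array([inlet_z, 0.0, outlet_z])
    ctrl_a = np.array([dims.transverse_inlet, dims.interspinous,
                       0.80 * dims.interspinous]) / 2.0
    ctrl_b = np.array([dims.inlet_ap,
                       0.5 * (dims.inlet_ap + dims.outlet_ap),
                       dims.outlet_ap]) / 2.0

    def quad_interp(z, vals):
        # Lagrange interpolation through the three control rings
        z0, z1, z2 = ctrl_z
        l0 = (z - z1) * (z - z2) / ((z0 - z1) * (z0 - z2))
        l1 = (z - z0) * (z - z2) / ((z1 - z0) * (z1 - z2))
        l2 = (z - z0) * (z - z1) / ((z2 - z0) * (z2 - z1))
        return vals[0] * l0 + vals[1] * l1 + vals[2] * l2

    height = inlet_z - outlet_z
    n_rings = max(4, int(round(height / target_edge))) + 1
    mean_circ = 2 * np.pi * float(np.mean(np.concatenate([ctrl_a, ctrl_b])))
    n_u = max(12, int(round(mean_circ / target_edge)))
    zs = np.linspace(inlet_z, outlet_z, n_rings)
    us = np.arange(n_u) * (2 * np.pi / n_u)
    verts = np.empty((n_rings, n_u, 3))
    for i, z in enumerate(zs):
        a, b = quad_interp(z, ctrl_a), quad_interp(z, ctrl_b)
        verts[i, :, 0] = a * np.sin(us)
        verts[i, :, 1] = b * np.cos(us)
        verts[i, :, 2] = z
    verts = verts.reshape(-1, 3)
    faces = []
    for i in range(n_rings - 1):
        for k in range(n_u):
            k2 = (k + 1) % n_u
            a0, a1 = i * n_u + k, i * n_u + k2
            b0, b1 = (i + 1) * n_u + k, (i + 1) * n_u + k2
            faces.append((a0, b0, b1))   # inward-facing canal wall
            faces.append((a0, b1, a1))
    lm = {
        "inlet_pubis": np.array([0.0, dims.inlet_ap / 2.0, inlet_z]),
        "inlet_promontory": np.array([0.0, -dims.inlet_ap / 2.0, inlet_z]),
        "inlet_lateral_left": np.array([dims.transverse_inlet / 2.0, 0.0, inlet_z]),
        "inlet_lateral_right": np.array([-dims.transverse_inlet / 2.0, 0.0, inlet_z]),
        "ischial_spine_left": np.array([dims.interspinous / 2.0, 0.0, 0.0]),
        "ischial_spine_right": np.array([-dims.interspinous / 2.0, 0.0, 0.0]),
        "outlet_anterior": np.array([0.0, dims.outlet_ap / 2.0, outlet_z]),
        "outlet_posterior": np.array([0.0, -dims.outlet_ap / 2.0, outlet_z]),
    }
    surf = RigidSurface(verts, np.asarray(faces, int), "pelvis", lm)
    surf.planes["interspinous"] = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    surf.dims = dims
    return surf


# ---------------------------------------------------------------------------
# levator ani tetrahedral shell

@dataclass(frozen=True)
class LevatorShellParams:
    """Calibrated default geometry of the synthetic levator funnel (mm).

    The muscle's thickness, hiatal opening and rim heights are not published
    for the reference subject; these defaults were calibrated so the shell's
    cranial ICm plate engages the descending head near station -3 and the
    hiatus is small enough that the head must distend it.
    """

    rim_scale: float = 0.95          # rim ellipse as fraction of canal semi-axes
    rim_scale_y: float = 1.04        # anterior semi-axis factor (clears the
                                     # head's swept volume at the pubic rim)
    rim_z_anterior: float = -12.0    # pubic side of the attachment rim
    rim_z_posterior: float = 40.0    # sacral side (cranial ICm plate)
    hiatus_center_y: float = 18.0
    hiatus_center_z: float = -25.0
    sag: float = 0.0                 # mid-funnel caudal sag amplitude
    plate_exponent: float = 3.0      # >1 keeps the dorsal plate shelf-like
    pvm_v_min: float = 0.55          # pubovisceral band: v >= this, anterior
    prm_v_min: float = 0.80          # puborectal sling: v >= this
    sling_phi: float = 1.2           # azimuth (rad) separating PVm / PRm arcs


# Freudenthal 6-tet decomposition of a hex (translation-invariant, conforming)
_HEX_TETS = ((0, 1, 3, 7), (0, 1, 7, 5), (0, 2, 3, 7),
             (0, 2, 7, 6), (0, 4, 5, 7), (0, 4, 7, 6))


@dataclass
class LabeledTetMesh:
    """Deformable tetrahedral mesh with region labels and named node sets."""

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray               # int codes into REGION_NAMES
    node_sets: dict                  # name -> index array (trace sets ordered)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.tets = np.asarray(self.tets, int)
        self.region = np.asarray(self.region)
        if self.region.dtype.kind in "US":
            codes = {n: i for i, n in enumerate(REGION_NAMES)}
            self.region = np.array([codes[r] for r in self.region], dtype=np.int8)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_tets(self):
        return len(self.tets)

    def region_mask(self, name):
        if name not in REGION_NAMES:
            raise UnknownLandmarkError(
                f"unknown region {name!r}; have {REGION_NAMES}")
        return self.region == REGION_NAMES.index(name)

    def node_set(self, name):
        if name not in self.node_sets:
            raise UnknownLandmarkError(
                f"unknown node set {name!r}; have {sorted(self.node_sets)}")
        return self.node_sets[name]

    def volumes(self, nodes=None):
        x = self.nodes if nodes is None else nodes
        t = x[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]),
            t[:, 3] - t[:, 0]) / 6.0

    def boundary_faces(self):
        faces = self.tets[:, [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]]
        faces = faces.reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        return faces[counts[inv] == 1]

    def validate(self):
        vols = self.volumes()
        if np.any(vols <= 0):
            raise GeometryError(f"{int((vols <= 0).sum())} non-positive tet volume(s)")
        if self.region.shape != (self.n_tets,):
            raise GeometryError("every element must carry exactly one region label")
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise GeometryError(f"node set {name!r} references missing nodes")
        # watertight outer boundary: every boundary edge on exactly two faces
        bf = self.boundary_faces()
        edges = np.sort(bf[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise GeometryError("shell boundary is not watertight")
        return True


def _fix_orientation(nodes, tets):
    t = nodes[tets]
    vol = np.einsum("ij,ij->i",
                    np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]),
                    t[:, 3] - t[:, 0])
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def build_levator(pelvis: RigidSurface = None, shell_thickness=6.0,
                  hiatus_dims=(75.0, 60.0), target_edge=6.0,
                  shell: LevatorShellParams = None):
    """Levator ani funnel shell as a labeled tetrahedral mesh.

    ``hiatus_dims`` is the (anteroposterior, transverse) extent of the
    urogenital hiatus in mm.  The shell spans from an attachment rim on the
    pelvic sidewall (pubis anteriorly, ATML laterally, sacrum posteriorly)
    down to the free hiatal margin, and is extruded through its thickness.

    Node sets: ``pubic_attachment`` / ``sacral_attachment`` (fixed),
    ``atml_coupling`` (elastically tied toward the internal obturator),
    ``cranial_plane_constrained`` (upper cranial third of the ICm),
    ``distal_prm_loop`` and the ordered ``mediosagittal_trace``.
    """
    pelvis = pelvis or build_pelvis()
    shell = shell or LevatorShellParams()
    if shell_thickness <= 0:
        raise InvalidInputError("shell thickness must be positive")
    if target_edge <= 0:
        raise InvalidInputError("target_edge must be positive")
    hx, hy = float(hiatus_dims[1]) / 2.0, float(hiatus_dims[0]) / 2.0
    if hx <= 0 or hy <= 0:
        raise InvalidInputError("hiatus dimensions must be positive")
    dims = getattr(pelvis, "dims", PelvisDimensions())
    rim_x = shell.rim_scale * dims.interspinous / 2.0
    rim_y = shell.rim_scale_y * 0.5 * (dims.inlet_ap + dims.outlet_ap) / 2.0
    if hx >= rim_x or hy >= rim_y:
        raise InvalidInputError(
            f"hiatus ({2*hy:g} x {2*hx:g} mm) does not fit inside the canal")

    hc = np.array([0.0, shell.hiatus_center_y, shell.hiatus_center_z])

    def midsurface(u, v):
        """u: azimuth (0 = anterior), v in [0,1] rim->hiatus.

        In-plane coordinates blend linearly between the attachment rim and
        the hiatal margin; the height drops as v**plate_exponent, keeping
        the dorsal (ICm) portion a near-horizontal shelf that the
        descending head meets first.
        """
        z_rim = (shell.rim_z_anterior
                 + (shell.rim_z_posterior - shell.rim_z_anterior)
                 * (1 - np.cos(u)) / 2.0)
        rim = np.stack([rim_x * np.sin(u), rim_y * np.cos(u)], axis=-1)
        hia = hc[:2] + np.stack([hx * np.sin(u), hy * np.cos(u)], axis=-1)
        xy = (1 - v)[..., None] * rim + v[..., None] * hia
        z = z_rim + (hc[2] - z_rim) * v ** shell.plate_exponent \
            - shell.sag * np.sin(np.pi * v)
        return np.concatenate([xy, z[..., None]], axis=-1)

    # grid resolution from the target edge length
    mid_circ = 2 * np.pi * 0.5 * (0.5 * (rim_x + rim_y) + 0.5 * (hx + hy))
    n_u = max(16, int(round(mid_circ / target_edge)))
    vgrid_probe = np.linspace(0, 1, 33)
    probe = midsurface(np.full(33, np.pi), vgrid_probe)
    meridian_len = np.linalg.norm(np.diff(probe, axis=0), axis=1).sum()
    n_v = max(4, int(round(meridian_len / target_edge)))
    n_layers = max(1, int(shell_thickness / target_edge))

    us = np.arange(n_u) * (2 * np.pi / n_u)
    vs = np.linspace(0.0, 1.0, n_v + 1)
    uu, vv = np.meshgrid(us, vs, indexing="ij")      # (n_u, n_v+1)
    mid = midsurface(uu, vv)
    # unit normals of the mid-surface (oriented caudally: layer 0 = inferior)
    du = np.gradient(mid, axis=0)
    dv = np.gradient(mid, axis=1)
    nrm = np.cross(du, dv)
    nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)
    flip = nrm[..., 2] > 0
    nrm[flip] *= -1.0

    offsets = (np.arange(n_layers + 1) / n_layers - 0.5) * shell_thickness
    # node index (layer, iv, iu)
    nodes = (mid[None, ...] + offsets[:, None, None, None] * nrm[None, ...])
    nodes = np.transpose(nodes, (0, 2, 1, 3))        # (layers+1, n_v+1, n_u)

    def nid(l, j, i):
        return (l * (n_v + 1) + j) * n_u + (i % n_u)

    coords = nodes.reshape(-1, 3)
    tets, regions = [], []
    phi_grid = (us + np.pi) % (2 * np.pi) - np.pi    # wrapped, 0 = anterior
    for l in range(n_layers):
        for j in range(n_v):
            for i in range(n_u):
                # hex corners by binary index di + 2*dj + 4*dl
                corner = {}
                for dl in (0, 1):
                    for dj in (0, 1):
                        for di in (0, 1):
                            corner[di + 2 * dj + 4 * dl] = nid(l + dl, j + dj, i + di)
                hexv = [corner[k] for k in range(8)]
                v_mid = (vs[j] + vs[j + 1]) / 2.0
                u_mid = us[i] + np.pi / n_u
                phi = abs((u_mid + np.pi) % (2 * np.pi) - np.pi)
                if v_mid >= shell.prm_v_min and phi > shell.sling_phi:
                    reg = REGION_NAMES.index("PRm")
                elif v_mid >= shell.pvm_v_min and phi <= shell.sling_phi:
                    reg = REGION_NAMES.index("PVm")
                else:
                    reg = REGION_NAMES.index("ICm")
                for tet in _HEX_TETS:
                    tets.append([hexv[k] for k in tet])
                    regions.append(reg)
    tets = _fix_orientation(coords, np.asarray(tets, int))
    regions = np.asarray(regions, np.int8)
    hex_patch = np.repeat(np.arange(len(tets) // 6), 6)

    # --- node sets -------------------------------------------------------
    iu = np.arange(n_u)
    phi_u = np.abs((us + np.pi) % (2 * np.pi) - np.pi)
    all_layers = np.arange(n_layers + 1)

    def rim_nodes(mask_u):
        sel = iu[mask_u]
        return np.concatenate([[nid(l, 0, i) for i in sel] for l in all_layers])

    pubic = rim_nodes(phi_u < 0.35)
    sacral = rim_nodes(phi_u > np.pi - 0.80)
    atml = rim_nodes((phi_u >= 0.35) & (phi_u <= np.pi - 0.80))

    hiatus_sel = iu[phi_u > np.pi - 0.9]
    distal = np.concatenate([[nid(l, n_v, i) for i in hiatus_sel]
                             for l in all_layers])

    i_post = int(np.argmin(np.abs(phi_u - np.pi)))
    trace = np.array([nid(0, j, i_post) for j in range(n_v + 1)])

    # cranial plane constraint: upper cranial third of the ICm, minus the
    # already-fixed/tethered rim nodes (sets must stay disjoint per node)
    icm_mask = regions == REGION_NAMES.index("ICm")
    icm_nodes = np.unique(np.asarray(tets)[icm_mask])
    z = coords[icm_nodes, 2]
    z_cut = z.max() - (z.max() - z.min()) / 3.0
    taken = set(np.concatenate([pubic, sacral, atml]).tolist())
    cranial = np.array([n for n in icm_nodes[z >= z_cut] if n not in taken],
                       dtype=int)

    gamma = np.deg2rad(55.0)   # sacral wall inclination: in-plane inferior
    # motion carries a substantial anterior component
    plane_normal = np.array([0.0, np.cos(gamma), np.sin(gamma)])

    mesh = LabeledTetMesh(
        coords, tets, regions,
        node_sets={
            "pubic_attachment": np.unique(pubic),
            "sacral_attachment": np.unique(sacral),
            "atml_coupling": np.unique(atml),
            "cranial_plane_constrained": np.unique(cranial),
            "distal_prm_loop": np.unique(distal),
            "mediosagittal_trace": trace,          # ordered rim -> hiatus
        })
    mesh.plane = (coords[cranial].mean(axis=0) if len(cranial) else np.zeros(3),
                  plane_normal)
    mesh.shell_thickness = float(shell_thickness)
    mesh.patch = hex_patch                     # generating hex of each tet
    mesh.validate()
    return mesh


def build_annulus(inner_radius=20.0, outer_radius=45.0, thickness=5.0,
                  target_edge=4.0, z0=0.0):
    """Flat annular plate fixture (all-ICm) with the outer rim as a node set."""
    if not 0 < inner_radius < outer_radius:
        raise InvalidInputError("need 0 < inner_radius < outer_radius")
    n_u = max(12, int(round(np.pi * (inner_radius + outer_radius) / target_edge)))
    n_v = max(2, int(round((outer_radius - inner_radius) / target_edge)))
    n_layers = max(1, int(thickness / target_edge))
    us = np.arange(n_u) * (2 * np.pi / n_u)
    rs = np.linspace(outer_radius, inner_radius, n_v + 1)
    offsets = (np.arange(n_layers + 1) / n_layers - 0.5) * thickness + z0
    coords = np.empty(((n_layers + 1) * (n_v + 1) * n_u, 3))

    def nid(l, j, i):
        return (l * (n_v + 1) + j) * n_u + (i % n_u)

    for l, zz in enumerate(offsets):
        for j, r in enumerate(rs):
            for i, u in enumerate(us):
                coords[nid(l, j, i)] = (r * np.cos(u), r * np.sin(u), zz)
    tets = []
    for l in range(n_layers):
        for j in range(n_v):
            for i in range(n_u):
                corner = {}
                for dl in (0, 1):
                    for dj in (0, 1):
                        for di in (0, 1):
                            corner[di + 2 * dj + 4 * dl] = nid(l + dl, j + dj, i + di)
                hexv = [corner[k] for k in range(8)]
                for tet in _HEX_TETS:
                    tets.append([hexv[k] for k in tet])
    tets = _fix_orientation(coords, np.asarray(tets, int))
    outer = np.concatenate([[nid(l, 0, i) for i in range(n_u)]
                            for l in range(n_layers + 1)])
    mesh = LabeledTetMesh(coords, tets, np.zeros(len(tets), np.int8),
                          node_sets={"outer_rim": np.unique(outer)})
    mesh.shell_thickness = float(thickness)
    mesh.patch = np.repeat(np.arange(len(tets) // 6), 6)
    mesh.validate()
    return mesh
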