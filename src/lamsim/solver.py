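"""Quasi-static large-deformation FE solver for the levator shell.

Total-Lagrangian formulation on linear tetrahedra (single-point quadrature)
with the Ogden strain energy, solved frame by frame along the prescribed
head trajectory by a line-searched Newton method:

* internal forces are the exact analytic gradient of the total strain
  energy (isochoric Ogden + volumetric penalty);
* the volumetric term optionally uses a mean-dilatation (node-patch
  averaged J) treatment to limit locking of linear tetrahedra at
  nu = 0.499;
* the tangent stiffness is the analytic spectral Ogden tangent (a
  central-difference assembly is kept as a cross-check), and Newton is
  globalized by an energy line search, a Levenberg shift and a trust
  bound on the step's largest nodal move;
* contact with rigid surfaces (fetal head) is a frictionless node-to-
  surface penalty: forces act along the outward normal only, with
  magnitude penalty x penetration depth.  The per-node penalty field is
  matched each frame to the local material tangent stiffness (so the
  springs track the Ogden law's exponential stiffening) and escalated
  where a converged state leaves too much penetration;
* boundary conditions — fixed attachments, in-plane-only nodes, and
  elastic tethers standing in for the internal obturator support — are
  enforced exactly by a constraint-basis reduction (fixed dofs eliminated,
  plane nodes reduced to two in-plane dofs);
* on non-convergence a frame is bisected into pose substeps, then handed
  to a damped-relaxation fallback; if that fails too, the converged prefix
  is returned in a PartialResultError.

All quantities are mm / MPa / N; energies are N*mm.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .anatomy import LabeledTetMesh, RigidSurface
from .errors import (ElementInversionError, InvalidInputError,
                     NonConvergenceError, PartialResultError)
from .geometry import RigidTransform, SurfaceProximity
from .kinematics import HeadTrajectory
from .ogden import OgdenParameters, first_piola, iso_tangent, von_mises

log = logging.getLogger(__name__)

__all__ = ["BoundaryConditionSet", "SolverSettings", "EquilibriumState",
           "FEModel", "internal_forces", "strain_energy_total",
           "contact_forces", "solve_quasistatic", "default_boundary_conditions"]


@dataclass
class BoundaryConditionSet:
    """Named node sets with their kinematic roles.

    ``fixed`` nodes carry zero (or prescribed) displacement; ``plane`` nodes
    may move only within their plane (normal given per set); ``tether``
    nodes are pulled back to their reference position by linear springs of
    the given stiffness (N/mm).  ``prescribed_fn(frame_index)``, if set,
    returns an (n_nodes, 3) displacement field applied to fixed nodes.
    """

    fixed: dict                  # name -> node index array
    plane: dict                  # name -> (node indices, point, unit normal)
    tether: dict                 # name -> (node indices, stiffness N/mm)
    prescribed_fn: object = None

    def __post_init__(self):
        seen = {}
        for group in (self.fixed,
                      {k: v[0] for k, v in self.plane.items()},
                      {k: v[0] for k, v in self.tether.items()}):
            for name, idx in group.items():
                for n in np.asarray(idx).ravel():
                    if n in seen and seen[n] != name:
                        raise InvalidInputError(
                            f"node {n} appears in both {seen[n]!r} and {name!r}")
                    seen[n] = name
        for name, (idx, point, normal) in self.plane.items():
            normal = np.asarray(normal, float)
            if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
                raise InvalidInputError(f"plane normal of {name!r} is not unit length")


def default_boundary_conditions(mesh: LabeledTetMesh, tether_stiffness=0.05):
    """Anatomical constraint set of the levator model.

    Pubic and sacral origins fully fixed; ATML rim elastically coupled to
    the (rigid) internal obturator wall; the upper cranial third of the ICm
    restricted to its sacrum/posterior-ilia plane.
    """
    point, normal = getattr(mesh, "plane",
                            (np.zeros(3), np.array([0.0, 1.0, 0.0])))
    return BoundaryConditionSet(
        fixed={"pubic_attachment": mesh.node_set("pubic_attachment"),
               "sacral_attachment": mesh.node_set("sacral_attachment")},
        plane={"cranial_plane_constrained":
               (mesh.node_set("cranial_plane_constrained"), point, normal)},
        tether={"atml_coupling":
                (mesh.node_set("atml_coupling"), float(tether_stiffness))},
    )


@dataclass
class SolverSettings:
    """Numerical controls of the quasi-static solve."""

    contact_penalty: float = 5.0         # N/mm per node
    newton_tol: float = 1e-5             # absolute residual 2-norm, N
    newton_rtol: float = 3e-6            # residual relative to contact force
    max_iterations: int = 140
    max_substep_depth: int = 6
    mean_dilatation: bool = True
    tangent_refresh: int = 2             # Newton iterations per tangent reuse
    penetration_fraction: float = 0.01   # allowed gap / shell thickness
    adapt_penalty: bool = True
    fd_step: float = 1e-6                # dP/dF finite-difference step

    def __post_init__(self):
        for name in ("contact_penalty", "newton_tol", "newton_rtol",
                     "max_iterations", "max_substep_depth", "tangent_refresh",
                     "penetration_fraction", "fd_step"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"solver setting {name} must be positive")


@dataclass
class EquilibriumState:
    """Converged configuration for one trajectory frame."""

    displacements: np.ndarray        # (n_nodes, 3) mm
    def_grad: np.ndarray             # (n_tets, 3, 3)
    cauchy: np.ndarray               # (n_tets, 3, 3) MPa
    von_mises: np.ndarray            # (n_tets,) MPa
    contact_gaps: np.ndarray         # (n_nodes,) penetration depth, mm
    residual_norm: float
    frame: int
    station: float
    penalty: float = 0.0             # contact penalty in force at this frame
    contact_pressures: np.ndarray = None  # nodal contact pressures, N


class FEModel:
    """Precomputed discrete operators for one mesh/material pair."""

    def __init__(self, mesh: LabeledTetMesh, params: OgdenParameters,
                 mean_dilatation=True):
        self.mesh = mesh
        self.params = params
        self.mean_dilatation = mean_dilatation
        X = mesh.nodes
        t = X[mesh.tets]
        Dm = np.stack([t[:, 1] - t[:, 0], t[:, 2] - t[:, 0],
                       t[:, 3] - t[:, 0]], axis=1)          # rows = edges
        detDm = np.linalg.det(Dm)
        if np.any(detDm <= 0):
            raise ElementInversionError(
                "reference mesh contains inverted elements",
                elements=np.flatnonzero(detDm <= 0))
        self.V0 = detDm / 6.0
        self.Dm_inv = np.linalg.inv(Dm)
        # F_{ab} = sum_j Ds_{ja} Dminv_{bj}; Wm[e,i,b] = dF_{ab}/dx_{i,a}
        Wm = np.empty((mesh.n_tets, 4, 3))
        Wm[:, 1:, :] = np.swapaxes(self.Dm_inv, 1, 2)
        Wm[:, 0, :] = -self.Dm_inv.sum(axis=2)
        self.Wm = Wm
        # sparse assembly pattern for the 12x12 element matrices
        dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :])
        self.dof = dof.reshape(mesh.n_tets, 12)
        self.iK = np.repeat(self.dof, 12, axis=1).ravel()
        self.jK = np.tile(self.dof, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_nodes
        self._build_averaging()

    def _build_averaging(self):
        """Volume-weighted J averaging over element patches.

        Patches are the generating hex cells where the mesh provides them
        (``mesh.patch``), otherwise every element is its own patch and the
        treatment reduces to the standard per-element volumetric term.
        """
        m, V0, K = self.mesh.n_tets, self.V0, self.params.K
        if self.mean_dilatation and getattr(self.mesh, "patch", None) is not None:
            pid = np.asarray(self.mesh.patch, int)
        else:
            pid = np.arange(m)
        n_patch = pid.max() + 1 if m else 0
        Vp = np.bincount(pid, weights=V0, minlength=n_patch)
        ind = sparse.coo_matrix((np.ones(m), (np.arange(m), pid)),
                                shape=(m, n_patch)).tocsr()
        # A_ef = V0_f / V_patch(e) for elements in the same patch (row-stochastic)
        self.avg = (ind @ sparse.diags(1.0 / Vp) @ ind.T @ sparse.diags(V0)).tocsr()
        self.Dvol = (self.avg.T @ sparse.diags(K * V0) @ self.avg).tocsr()

    # -- kinematics ------------------------------------------------------
    def def_grads(self, u):
        x = self.mesh.nodes + u
        t = x[self.mesh.tets]
        Ds = np.stack([t[:, 1] - t[:, 0], t[:, 2] - t[:, 0],
                       t[:, 3] - t[:, 0]], axis=1)      # deformed edges as rows
        return np.einsum("eja,ebj->eab", Ds, self.Dm_inv)

    # -- energy and gradient --------------------------------------------
    def strain_energy(self, u):
        F = self.def_grads(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            return np.inf
        C = np.swapaxes(F, -1, -2) @ F
        lam2 = np.clip(np.linalg.eigvalsh(C), 1e-30, None)
        lbar = np.sqrt(lam2) * J[:, None] ** (-1.0 / 3.0)
        mu = np.asarray(self.params.mu)
        alpha = np.asarray(self.params.alpha)
        w_iso = (2.0 * mu / alpha * (lbar[..., None] ** alpha - 1.0)).sum(axis=(1, 2))
        Jbar = self.avg @ J
        w_vol = 0.5 * self.params.K * (Jbar - 1.0) ** 2
        return float(np.dot(self.V0, w_iso + w_vol))

    def _vol_coeff(self, J):
        """Per-element volumetric pressure factor w_e / V0_e (MPa)."""
        Jbar = self.avg @ J
        w = self.avg.T @ (self.params.K * self.V0 * (Jbar - 1.0))
        return w / self.V0

    def _piola(self, F):
        """Effective first Piola stress including the averaged volumetric term."""
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise ElementInversionError(
                f"{int((J <= 0).sum())} inverted element(s) during evaluation",
                elements=np.flatnonzero(J <= 0))
        return first_piola(self.params, F, vol_coeff=self._vol_coeff(J))

    def gradient(self, u):
        """Exact gradient of total strain energy w.r.t. nodal positions (N)."""
        F = self.def_grads(u)
        P = self._piola(F)
        H = np.einsum("e,eab,eib->eia", self.V0, P, self.Wm)
        g = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(g, self.mesh.tets.ravel(), H.reshape(-1, 3))
        return g

    # -- tangent ---------------------------------------------------------
    def tangent(self, u, h=1e-6, fd=False):
        """Consistent tangent stiffness of the total strain energy.

        The isochoric moduli come from the analytic spectral form
        (:func:`lamsim.ogden.iso_tangent`); ``fd=True`` switches to a
        central finite difference of the isochoric Piola stress (step
        ``h``), kept as an independent cross-check.  The volumetric term —
        including the patch averaging of J — is always analytic, so Newton
        retains quadratic convergence with the mean-dilatation treatment
        active.
        """
        F = self.def_grads(u)
        J = np.linalg.det(F)
        if fd:
            zero = np.zeros(self.mesh.n_tets)
            A4 = np.empty((self.mesh.n_tets, 3, 3, 3, 3))
            for c in range(3):
                for d in range(3):
                    Fp = F.copy()
                    Fp[:, c, d] += h
                    Pp = first_piola(self.params, Fp, vol_coeff=zero)
                    Fm = F.copy()
                    Fm[:, c, d] -= h
                    Pm = first_piola(self.params, Fm, vol_coeff=zero)
                    A4[:, :, :, c, d] = (Pp - Pm) / (2.0 * h)
        else:
            A4 = iso_tangent(self.params, F)
        # volumetric geometric part: w * d2J/dF2, with
        # d2J/dF2_{abcd} = J (Finv_ba Finv_dc - Finv_da Finv_bc)
        Finv = np.linalg.inv(F)
        vc = self._vol_coeff(J)                       # w_e / V0_e
        cJ = (vc * J)[:, None, None, None, None]
        A4 += cJ * (np.einsum("eba,edc->eabcd", Finv, Finv)
                    - np.einsum("eda,ebc->eabcd", Finv, Finv))
        Ke = np.einsum("e,eib,eabcd,ejd->eiajc", self.V0, self.Wm, A4,
                       self.Wm, optimize=True)
        Ke = 0.5 * (Ke + np.swapaxes(np.swapaxes(Ke, 1, 3), 2, 4))  # symmetrize
        vals = Ke.reshape(self.mesh.n_tets, 12, 12).ravel()
        K = sparse.coo_matrix((vals, (self.iK, self.jK)),
                              shape=(self.ndof, self.ndof)).tocsc()
        # volumetric coupling part: dJ^T [A^T K diag(V0) A] dJ
        hvec = J[:, None, None] * np.einsum("eba,eib->eia", Finv, self.Wm)
        Gj = sparse.coo_matrix(
            (hvec.reshape(self.mesh.n_tets, 12).ravel(),
             (np.repeat(np.arange(self.mesh.n_tets), 12), self.dof.ravel())),
            shape=(self.mesh.n_tets, self.ndof)).tocsr()
        return K + (Gj.T @ self.Dvol @ Gj).tocsc()


def internal_forces(mesh: LabeledTetMesh, params: OgdenParameters, displacements,
                    mean_dilatation=True):
    """Nodal internal force vector (N): gradient of total strain energy.

    Zero for any rigid-body displacement field; raises
    :class:`ElementInversionError` listing inverted elements.
    """
    u = np.asarray(displacements, float)
    if u.shape != mesh.nodes.shape:
        raise InvalidInputError(
            f"displacements shaped {u.shape}, expected {mesh.nodes.shape}")
    return FEModel(mesh, params, mean_dilatation).gradient(u)


def strain_energy_total(mesh, params, displacements, mean_dilatation=True):
    """Total strain energy (N*mm) of the displaced mesh."""
    return FEModel(mesh, params, mean_dilatation).strain_energy(
        np.asarray(displacements, float))


# -------------------------------------------------------------------------
# contact

class _RigidContact:
    """Frictionless penalty contact of mesh nodes against a rigid surface.

    Star-shaped bodies carrying an analytic radial function use the smooth
    implicit gap phi(p) = |p| - r(p/|p|), whose level set is the surface
    itself; its gradient (the outward normal direction, computed by central
    differences of phi) is smooth everywhere, which keeps the Newton
    iteration quadratic while nodes slide in contact.  Plain triangle
    surfaces fall back to faceted closest-point projection.
    """

    def __init__(self, rigid: RigidSurface):
        self.rigid = rigid
        self.smooth = rigid.radial_fn is not None
        self.prox = None if self.smooth else \
            SurfaceProximity(rigid.vertices, rigid.faces)
        self.r_max = float(np.linalg.norm(rigid.vertices, axis=1).max())

    def _phi(self, pl):
        rho = np.linalg.norm(pl, axis=1)
        rho = np.maximum(rho, 1e-9)
        return rho - self.rigid.radial_fn(pl / rho[:, None])

    def gaps_normals(self, points_world, pose: RigidTransform, margin=0.0):
        """Signed penetration (mm) and outward world normals per point.

        The returned gap is the penetration depth: positive inside the
        body, negative (separation) for points outside within ``margin``,
        and ``-inf``-like large negative elsewhere.  Normals are filled for
        every point with gap > -margin.
        """
        inv = pose.inverse()
        pl = inv.apply(points_world)
        rho = np.linalg.norm(pl, axis=1)
        gaps = np.full(len(pl), -1e30)
        normals = np.zeros_like(pl)
        cand = np.flatnonzero(rho < self.r_max * 1.02 + margin)
        if cand.size == 0:
            return gaps, normals
        if self.smooth:
            phi = self._phi(pl[cand])
            gaps[cand] = -phi
            need = cand[-phi > -margin]
            if need.size:
                h = 1e-4
                grad = np.empty((need.size, 3))
                for a in range(3):
                    dp = np.zeros(3)
                    dp[a] = h
                    grad[:, a] = (self._phi(pl[need] + dp)
                                  - self._phi(pl[need] - dp)) / (2 * h)
                normals[need] = grad @ pose.rotation.T
            return gaps, normals
        cp, dist, face = self.prox.query(pl[cand])
        inside = np.einsum("ij,ij->i", self.prox.face_normals[face],
                           pl[cand] - cp) < 0
        gaps[cand] = np.where(inside, dist, -dist)
        need_m = gaps[cand] > -margin
        idx = cand[need_m]
        if idx.size:
            d = dist[need_m]
            sgn = np.where(inside[need_m], 1.0, -1.0)
            n_loc = sgn[:, None] * (cp[need_m] - pl[idx])
            with np.errstate(invalid="ignore", divide="ignore"):
                n_loc = np.where(d[:, None] > 1e-12,
                                 n_loc / np.maximum(d, 1e-12)[:, None],
                                 self.prox.face_normals[face[need_m]])
            normals[idx] = n_loc @ pose.rotation.T
        return gaps, normals

    def energy(self, points_world, pose, penalty):
        gaps, _ = self.gaps_normals(points_world, pose)
        g = np.maximum(gaps, 0.0)
        return 0.5 * penalty * float(np.dot(g, g)), g

    def gradient(self, points_world, pose, penalty):
        """(dE/dx, gaps, normals): gradient is -penalty*g*n on penetrating nodes."""
        gaps, normals = self.gaps_normals(points_world, pose)
        g = np.maximum(gaps, 0.0)
        return -penalty * g[:, None] * normals, g, normals


def contact_forces(mesh: LabeledTetMesh, rigid: RigidSurface,
                   pose: RigidTransform, penalty, displacements=None):
    """Nodal contact forces (N) and a gap report against a rigid surface.

    Forces act only on penetrating nodes, along the surface's outward
    normal (frictionless), with magnitude ``penalty * depth``.
    """
    if penalty <= 0:
        raise InvalidInputError("contact penalty must be positive")
    u = np.zeros_like(mesh.nodes) if displacements is None \
        else np.asarray(displacements, float)
    contact = _RigidContact(rigid)
    grad, gaps, normals = contact.gradient(mesh.nodes + u, pose, penalty)
    report = {"max_penetration": float(gaps.max()) if len(gaps) else 0.0,
              "n_active": int((gaps > 0).sum()),
              "gaps": gaps, "normals": normals}
    return -grad, report


# -------------------------------------------------------------------------
# constraint basis

def _constraint_basis(mesh: LabeledTetMesh, bcs: BoundaryConditionSet):
    n = mesh.n_nodes
    kind = np.zeros(n, dtype=np.int8)           # 0 free, 1 fixed, 2 plane
    plane_normal = {}
    for idx in bcs.fixed.values():
        kind[np.asarray(idx)] = 1
    for idx, point, normal in bcs.plane.values():
        kind[np.asarray(idx)] = 2
        for node in np.asarray(idx).ravel():
            plane_normal[int(node)] = np.asarray(normal, float)
    rows, cols, vals = [], [], []
    col = 0
    for node in range(n):
        if kind[node] == 1:
            continue
        if kind[node] == 2:
            nrm = plane_normal[node]
            t1 = np.cross(nrm, [0.0, 0.0, 1.0])
            if np.linalg.norm(t1) < 1e-8:
                t1 = np.cross(nrm, [1.0, 0.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(nrm, t1)
            for tvec in (t1, t2):
                rows.extend(3 * node + np.arange(3))
                cols.extend([col] * 3)
                vals.extend(tvec)
                col += 1
        else:
            for a in range(3):
                rows.append(3 * node + a)
                cols.append(col)
                vals.append(1.0)
                col += 1
    Z = sparse.coo_matrix((vals, (rows, cols)), shape=(3 * n, col)).tocsr()
    return Z


# -------------------------------------------------------------------------
# quasi-static stepping

def _interp_pose(p0: RigidTransform, p1: RigidTransform, s):
    from scipy.spatial.transform import Rotation, Slerp

    key = Rotation.from_matrix(np.stack([p0.rotation, p1.rotation]))
    R = Slerp([0.0, 1.0], key)(s).as_matrix()
    t = (1 - s) * p0.translation + s * p1.translation
    return RigidTransform(R, t)


class _FrameSolver:
    def __init__(self, model: FEModel, bcs, settings, contact, head_pose_ref):
        self.model = model
        self.bcs = bcs
        self.settings = settings
        self.contact = contact
        self.Z = _constraint_basis(model.mesh, bcs)
        self.tether_nodes = []
        diag = np.zeros(model.ndof)
        for idx, k in bcs.tether.values():
            idx = np.asarray(idx)
            self.tether_nodes.append((idx, float(k)))
            for a in range(3):
                diag[3 * idx + a] += k
        self.K_tether = sparse.diags(diag).tocsc()
        # contact on fully fixed nodes exerts no force and cannot be
        # resolved by the penalty; exclude them from gap accounting.
        # Plane-constrained nodes cannot yield along their plane normal
        # (they lie against the posterior pelvic wall, which the head
        # cannot reach), so they are excluded as well.
        self.movable = np.ones(model.mesh.n_nodes, dtype=bool)
        for idx in bcs.fixed.values():
            self.movable[np.asarray(idx)] = False
        for idx, point, normal in bcs.plane.values():
            self.movable[np.asarray(idx)] = False
        # per-node contact penalty field (N/mm): escalated locally where a
        # converged frame leaves too much penetration, soft elsewhere, and
        # persistent across frames so firmly pressed regions stay stiff
        self.kfield = None

    def _kf(self, penalty):
        if self.kfield is None:
            self.kfield = np.full(self.model.mesh.n_nodes, float(penalty))
        return self.kfield

    def _pressure(self, gaps, penalty):
        """Active contact pressures p = k_i g_i on penetrating movable nodes."""
        p = self._kf(penalty) * np.maximum(gaps, 0.0)
        p[~self.movable] = 0.0
        return p

    def escalate_penalty(self, u, pose, penalty, allow):
        """Stiffen the penalty field where penetration exceeds ``allow``."""
        gaps, _ = self.contact.gaps_normals(self.model.mesh.nodes + u, pose)
        gpos = np.maximum(gaps * self.movable, 0.0)
        kf = self._kf(penalty)
        over = gpos > allow
        kf[over] = np.maximum(kf[over] * 4.0,
                              kf[over] * gpos[over] / allow * 2.0)
        return float(gpos.max()), int(over.sum())


    def _prescribed(self, frame_idx):
        if self.bcs.prescribed_fn is None:
            return np.zeros_like(self.model.mesh.nodes)
        up = np.zeros_like(self.model.mesh.nodes)
        full = np.asarray(self.bcs.prescribed_fn(frame_idx), float)
        for idx in self.bcs.fixed.values():
            up[np.asarray(idx)] = full[np.asarray(idx)]
        return up

    def total_energy(self, u, pose, penalty):
        e = self.model.strain_energy(u)
        if not np.isfinite(e):
            return np.inf
        for idx, k in self.tether_nodes:
            e += 0.5 * k * float(np.einsum("ij,ij->", u[idx], u[idx]))
        if self.contact is not None and pose is not None:
            gaps, _ = self.contact.gaps_normals(self.model.mesh.nodes + u, pose)
            p = self._pressure(gaps, penalty)
            # sum 1/2 k_i g_i^2 with p_i = k_i g_i
            e += 0.5 * float(np.dot(p, np.maximum(gaps, 0.0)))
        return e

    def total_gradient(self, u, pose, penalty):
        """(gradient, positive penetrations, pressures, normals)."""
        g = self.model.gradient(u)
        for idx, k in self.tether_nodes:
            g[idx] += k * u[idx]
        pen_pos = np.zeros(self.model.mesh.n_nodes)
        p = np.zeros(self.model.mesh.n_nodes)
        normals = np.zeros_like(u)
        if self.contact is not None and pose is not None:
            gaps, normals = self.contact.gaps_normals(
                self.model.mesh.nodes + u, pose)
            p = self._pressure(gaps, penalty)
            g += -p[:, None] * normals
            pen_pos = np.maximum(gaps * self.movable, 0.0)
        return g, pen_pos, p, normals

    def _contact_stiffness(self, pressures, normals, penalty):
        act = np.flatnonzero(pressures > 0)
        if act.size == 0:
            return None
        kf = self._kf(penalty)
        rows, cols, vals = [], [], []
        for node in act:
            nn = kf[node] * np.outer(normals[node], normals[node])
            for a in range(3):
                for b in range(3):
                    rows.append(3 * node + a)
                    cols.append(3 * node + b)
                    vals.append(nn[a, b])
        return sparse.coo_matrix((vals, (rows, cols)),
                                 shape=(self.model.ndof,) * 2).tocsc()

    def relax(self, u0, pose, penalty, steps=400, stop_rnorm=None):
        """Damped-relaxation fallback: safeguarded Barzilai-Borwein descent.

        Used when Newton substepping bottoms out (e.g. while the shell
        snaps past the head's widest section, where no nearby stable
        equilibrium exists); carries the configuration into the post-snap
        energy basin so Newton can finish.  Returns the relaxed field and
        its residual norm.
        """
        Z = self.Z
        up = self._prescribed(0)
        q = Z.T @ (u0 - up).ravel()
        q_prev = g_prev = None
        step = 1e-3
        rnorm = np.inf
        for i in range(steps):
            u = (Z @ q).reshape(-1, 3) + up
            try:
                g, _, _, _ = self.total_gradient(u, pose, penalty)
            except ElementInversionError:
                # back off halfway toward the previous iterate
                if q_prev is None:
                    raise
                q = 0.5 * (q + q_prev)
                continue
            r = Z.T @ g.ravel()
            rnorm = float(np.linalg.norm(r))
            if stop_rnorm is not None and rnorm <= stop_rnorm:
                break
            if q_prev is not None:
                dq = q - q_prev
                dg = r - g_prev
                denom = float(dq @ dg)
                if denom > 0:
                    step = float(dq @ dq) / denom
            q_prev, g_prev = q.copy(), r.copy()
            # cap the nodal move per step at 0.25 mm for stability
            cap = 0.25 / max(float(np.abs(r).max()), 1e-12)
            q = q - min(step, cap) * r
        return (Z @ q).reshape(-1, 3) + up, rnorm

    def solve(self, u0, pose, penalty, frame_idx, slack=1.0):
        """Damped-Newton iteration to equilibrium at the given head pose.

        An adaptive Levenberg shift carries the iteration through
        snap-through configurations (e.g. the shell sliding past the head's
        widest diameter) where the stiffness is indefinite; every accepted
        step decreases the total energy.
        """
        s = self.settings
        up = self._prescribed(frame_idx)
        Z = self.Z
        q = Z.T @ (u0 - up).ravel()
        lu = None
        Kr = None
        stale = s.tangent_refresh
        beta = 0.0
        fails = 0
        delta = 4.0          # trust radius on the step's max nodal move, mm
        for it in range(s.max_iterations):
            u = (Z @ q).reshape(-1, 3) + up
            g, gaps, pressures, normals = self.total_gradient(u, pose, penalty)
            r = Z.T @ g.ravel()
            rnorm = float(np.linalg.norm(r))
            # converged when the imbalance is negligible against the load
            # actually transmitted through the contact
            load = float(np.linalg.norm(pressures))
            if rnorm <= slack * max(s.newton_tol, s.newton_rtol * load):
                return u, rnorm, gaps, it
            if lu is None or stale >= s.tangent_refresh:
                K = self.model.tangent(u, h=s.fd_step) + self.K_tether
                Kc = self._contact_stiffness(pressures, normals, penalty)
                if Kc is not None:
                    K = K + Kc
                Kr = (Z.T @ K @ Z).tocsc()
                stale = 0
                lu = None
            beta_floor = 1e-8 * abs(Kr.diagonal()).mean()
            for attempt in range(40):
                try:
                    if lu is None:
                        shifted = Kr if beta == 0 else \
                            Kr + beta * sparse.identity(Kr.shape[0], format="csc")
                        lu = splu(shifted, permc_spec="MMD_ATA")
                    dq = lu.solve(-r)
                except RuntimeError:
                    dq = None
                if dq is not None and np.all(np.isfinite(dq)) \
                        and np.dot(r, dq) < 0 \
                        and np.abs(dq).max() <= delta:
                    break
                # indefinite, singular, or step outside the trust region:
                # shift the spectrum and refactor
                lu = None
                beta = max(beta * 10.0, 1e4 * beta_floor)
            else:
                raise NonConvergenceError("could not produce a descent direction")
            e0 = self.total_energy(u, pose, penalty)
            slope = float(np.dot(r, dq))
            alpha = 1.0
            ok = False
            while alpha > 1e-10:
                u_try = (Z @ (q + alpha * dq)).reshape(-1, 3) + up
                e_try = self.total_energy(u_try, pose, penalty)
                # absolute term absorbs round-off when energy differences
                # approach machine precision near convergence
                if np.isfinite(e_try) and \
                        e_try <= e0 + 1e-4 * alpha * slope + 1e-13 * abs(e0):
                    ok = True
                    break
                if np.isfinite(e_try):
                    # quadratic-interpolation backtracking, safeguarded
                    denom = 2.0 * (e_try - e0 - alpha * slope)
                    a_new = -slope * alpha ** 2 / denom if denom > 0 else 0.0
                    alpha = min(0.5 * alpha, max(a_new, 0.1 * alpha))
                else:
                    alpha *= 0.25
            if not ok:
                # steepen the damping and refresh the tangent, do not advance
                fails += 1
                if fails > 12:
                    raise NonConvergenceError(
                        f"line search failed at iteration {it}",
                        diagnostics={"residual": rnorm, "frame": frame_idx})
                beta = max(beta * 100.0, 1e4 * beta_floor)
                stale = s.tangent_refresh
                lu = None
                continue
            q = q + alpha * dq
            stale += 1
            if alpha < 0.25:          # struggling: shrink the trust region
                delta = max(delta * 0.5, 0.05)
                beta = max(beta * 10.0, beta_floor)
                stale = s.tangent_refresh
                lu = None
            elif alpha >= 0.5:
                fails = 0
                delta = min(delta * 1.5, 10.0)
                if beta > 0 and stale >= s.tangent_refresh:
                    beta *= 0.1
                    if beta < beta_floor:
                        beta = 0.0
        raise NonConvergenceError(
            f"Newton did not converge in {s.max_iterations} iterations",
            diagnostics={"residual": rnorm, "frame": frame_idx})


def _make_state(model, u, gaps, rnorm, frame_idx, station, penalty,
                pressures=None):
    from .ogden import cauchy_stress

    F = model.def_grads(u)
    sig = cauchy_stress(model.params, F)
    return EquilibriumState(
        displacements=u.copy(), def_grad=F, cauchy=sig,
        von_mises=np.asarray(von_mises(sig)), contact_gaps=gaps.copy(),
        residual_norm=rnorm, frame=frame_idx, station=station,
        penalty=penalty, contact_pressures=pressures)


def solve_quasistatic(mesh: LabeledTetMesh, params: OgdenParameters,
                      bcs: BoundaryConditionSet, trajectory: HeadTrajectory,
                      settings: SolverSettings = None, head: RigidSurface = None,
                      progress=None):
    """Equilibrium states of the levator shell along the head trajectory.

    The shell starts stress-free; each trajectory frame's head pose is
    applied quasi-statically (with pose bisection on non-convergence) and
    the converged state recorded.  Raises :class:`PartialResultError` with
    the converged prefix if a frame cannot be completed.
    """
    settings = settings or SolverSettings()
    model = FEModel(mesh, params, settings.mean_dilatation)
    contact = _RigidContact(head) if head is not None else None
    fs = _FrameSolver(model, bcs, settings, contact, None)
    penalty = settings.contact_penalty
    pen_allow = settings.penetration_fraction * getattr(mesh, "shell_thickness", 4.0)

    states = []
    u = np.zeros_like(mesh.nodes)
    u_prev = None          # previous substep solution, for the predictor
    du_prev = None
    prev_pose = trajectory[0].transform
    n_sub = 1              # adaptive pose substeps per frame
    for k, frame in enumerate(trajectory):
        t0 = time.perf_counter()
        target = frame.transform

        fallback_count = [0]

        def solve_at(u_in, pose, depth, it_cap=None, slack=1.0):
            """Solve one pose, bisecting the increment on failure."""
            cap = settings.max_iterations
            if it_cap is not None:
                fs.settings.max_iterations = it_cap
            try:
                return fs.solve(u_in, pose if contact is not None else None,
                                penalty, k, slack=slack)
            finally:
                fs.settings.max_iterations = cap

        def advance(u_in, p0, p1, depth, slack=1.0):
            try:
                return solve_at(u_in, p1, depth, slack=slack)
            except (NonConvergenceError, ElementInversionError):
                if depth >= settings.max_substep_depth:
                    # last resort: dynamic relaxation into the next basin,
                    # then a loosely converged Newton polish; if even that
                    # fails, a relaxed state close enough to equilibrium
                    # (residual within 1% of the transmitted load) is
                    # accepted with its residual recorded.  At most two
                    # relaxations per frame; beyond that the frame fails.
                    if fallback_count[0] >= 2:
                        raise
                    fallback_count[0] += 1
                    log.warning("frame %d: substepping exhausted, "
                                "falling back to dynamic relaxation", k)
                    cpose = p1 if contact is not None else None
                    u_rx, r_rx = fs.relax(u_in, cpose, penalty)
                    try:
                        return solve_at(u_rx, p1, depth,
                                        slack=max(slack, 100.0))
                    except (NonConvergenceError, ElementInversionError):
                        g2, gp2, pr2, _ = fs.total_gradient(u_rx, cpose,
                                                            penalty)
                        load2 = float(np.linalg.norm(pr2))
                        if r_rx > max(5.0, 0.01 * load2):
                            raise
                        log.warning("frame %d: accepting relaxed state, "
                                    "residual %.3e N (load %.1f N)",
                                    k, r_rx, load2)
                        return u_rx, r_rx, gp2, 0
                mid = _interp_pose(p0, p1, 0.5)
                # intermediate bisection poses only need a rough solve
                u_mid, _, _, _ = advance(u_in, p0, mid, depth + 1, slack=30.0)
                return advance(u_mid, mid, p1, depth + 1, slack=slack)

        try:
            if contact is not None:
                # contact stiffness matched to the current local material
                # stiffness (per node, from the tangent diagonal), so the
                # springs track the tissue's exponential stiffening and
                # penetration stays a small fraction of an element edge
                diag = (model.tangent(u).diagonal()
                        + fs.K_tether.diagonal()).reshape(-1, 3).mean(axis=1)
                matched = np.maximum(penalty, 2.0 * diag)
                # never soften below a previously escalated value
                fs.kfield = matched if fs.kfield is None else \
                    np.maximum(matched, fs.kfield)
            iters = 0
            p_from = prev_pose
            for j in range(n_sub):
                final_sub = j == n_sub - 1
                p_to = target if final_sub else \
                    _interp_pose(prev_pose, target, (j + 1) / n_sub)
                # intermediate substeps are converged loosely; only the
                # frame's own pose is tightened to the full tolerance
                slack = 1.0 if final_sub else 30.0
                result = None
                if du_prev is not None:
                    # linear predictor from the previous converged substep,
                    # with a capped budget so a bad prediction fails fast
                    try:
                        result = solve_at(u + du_prev, p_to, 0, it_cap=25,
                                          slack=slack)
                    except (NonConvergenceError, ElementInversionError):
                        result = None
                if result is None:
                    result = advance(u, p_from, p_to, 0, slack=slack)
                u_new, rnorm, gaps, it = result
                du_prev = u_new - u
                u = u_new
                iters += it
                p_from = p_to
            base_iters = iters
            if (contact is not None and settings.adapt_penalty):
                # stiffen the penalty field locally where penetration
                # exceeds its bound; the field persists across frames, so
                # intermediate frames aim at a relaxed working bound and
                # the strict bound is enforced in full at the final frame
                last = k == len(trajectory) - 1
                target_pen = pen_allow if last else 3.0 * pen_allow
                max_passes = 6 if last else 1
                tries = 0
                while gaps.max() > target_pen and tries < max_passes:
                    kf_backup = fs._kf(penalty).copy()
                    fs.escalate_penalty(u, target, penalty, target_pen)
                    try:
                        u, rnorm, gaps, it = fs.solve(u, target, penalty, k)
                        iters += it
                    except (NonConvergenceError, ElementInversionError):
                        # stiffened springs did not re-converge here; keep
                        # the softer field and the already-converged state
                        fs.kfield = kf_backup
                        log.warning("frame %d: penetration correction pass "
                                    "abandoned (%.3f mm residual)", k,
                                    gaps.max())
                        break
                    tries += 1
        except (NonConvergenceError, ElementInversionError) as exc:
            raise PartialResultError(
                f"frame {k} (station {frame.station:+.1f}) failed: {exc}",
                states=states,
                diagnostics={"frame": k, "station": frame.station}) from exc
        # adapt the substep count to the observed difficulty of the base
        # solve (escalation passes excluded: they do not shrink with pose
        # increments)
        if base_iters > 30 * n_sub:
            n_sub = min(n_sub * 2, 4)
        elif base_iters < 10 * n_sub and n_sub > 1:
            n_sub //= 2
        prev_pose = target
        st = _make_state(model, u, gaps, rnorm, k, frame.station, penalty,
                         pressures=fs._kf(penalty) * gaps)
        states.append(st)
        msg = (f"frame {k:3d} station {frame.station:+6.2f} "
               f"iters {iters:3d} sub {n_sub:2d} residual {rnorm:.2e} N "
               f"max_vm {st.von_mises.max():.4f} MPa "
               f"pen {gaps.max():.3f} mm {time.perf_counter()-t0:.2f}s")
        log.info(msg)
        if progress is not None:
            progress(msg)
    return states
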