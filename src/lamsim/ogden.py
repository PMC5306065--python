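"""N-term Ogden hyperelastic constitutive model.

The strain-energy density is expressed in principal stretches,

    W = sum_{i=1..3} sum_{j=1..N} (2 mu_j / alpha_j) (lbar_i^alpha_j - 1)
        + (K/2) (J - 1)^2,        lbar_i = J^(-1/3) lambda_i,  J = det F,

with shear-like moduli ``mu_j`` (MPa), dimensionless exponents ``alpha_j``
and a bulk modulus ``K`` (MPa) penalizing volume change.  Near-incompressible
behaviour is obtained from a Poisson ratio of 0.499; on the incompressible
uniaxial path (lambda_2 = lambda_3 = lambda^(-1/2), J = 1) the nominal
(first Piola-Kirchhoff) stress is

    P(lambda) = sum_j 2 mu_j (lambda^(alpha_j - 1) - lambda^(-alpha_j/2 - 1)).

Small-deformation stability requires sum_j mu_j alpha_j > 0; that sum is the
small-strain shear modulus of this parameterization.

Units throughout the package: mm - MPa - N - tonne.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "OgdenParameters",
    "DEFAULT_MU",
    "DEFAULT_ALPHA",
    "DEFAULT_POISSON",
    "DENSITY_TONNE_PER_MM3",
    "strain_energy",
    "uniaxial_nominal_stress",
    "cauchy_stress",
    "first_piola",
    "von_mises",
    "stability_check",
    "small_strain_shear_modulus",
    "bulk_modulus_from_poisson",
]

# Reference two-term parameter set for levator ani tissue (mm-MPa units).
DEFAULT_MU = (8.0e-5, 1.7e-4)
DEFAULT_ALPHA = (1.81, 17.25)
DEFAULT_POISSON = 0.499
# 1.06 kg/l of skeletal muscle expressed in tonne/mm^3.
DENSITY_TONNE_PER_MM3 = 1.06e-9


def stability_check(mu, alpha):
    """Small-deformation stability test ``sum(mu_j alpha_j) > 0``.

    Returns ``(stable, margin)`` where ``margin`` is the sum itself (MPa);
    the boundary ``margin == 0`` counts as unstable.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if mu.shape != alpha.shape or mu.ndim != 1 or mu.size == 0:
        raise InvalidInputError(
            f"mu and alpha must be matching 1-d sequences, got shapes "
            f"{mu.shape} and {alpha.shape}"
        )
    margin = float(np.dot(mu, alpha))
    return margin > 0.0, margin


def small_strain_shear_modulus(mu, alpha):
    """Shear modulus of the linearized model, computed numerically.

    Obtained from the slope of the uniaxial nominal stress at lambda = 1 via
    a central difference: for an incompressible material E = 3 G, so
    G = P'(1) / 3.  (Analytically this equals sum(mu_j alpha_j); computing it
    from the energy keeps the linearization honest.)
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    h = 1e-6
    p_plus = _uniaxial_p(mu, alpha, 1.0 + h)
    p_minus = _uniaxial_p(mu, alpha, 1.0 - h)
    return float((p_plus - p_minus) / (2.0 * h) / 3.0)


def bulk_modulus_from_poisson(mu, alpha, poisson=DEFAULT_POISSON):
    """Bulk modulus K (MPa) consistent with the given Poisson ratio."""
    if not 0.0 < poisson < 0.5:
        raise InvalidInputError(f"Poisson ratio must lie in (0, 0.5), got {poisson}")
    g = small_strain_shear_modulus(mu, alpha)
    if g <= 0:
        raise InvalidInputError("cannot derive K: non-positive shear modulus")
    return 2.0 * g * (1.0 + poisson) / (3.0 * (1.0 - 2.0 * poisson))


@dataclass(frozen=True)
class OgdenParameters:
    """Ogden parameter set: moduli ``mu`` (MPa), exponents ``alpha``, bulk ``K``.

    Stability (``sum mu_j alpha_j > 0``) and ``K > 0`` are enforced on
    construction.
    """

    mu: tuple
    alpha: tuple
    K: float

    def __post_init__(self):
        mu = tuple(float(m) for m in np.atleast_1d(self.mu))
        alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "K", float(self.K))
        stable, margin = stability_check(mu, alpha)
        if not stable:
            raise InvalidInputError(
                f"unstable Ogden parameters: sum(mu*alpha) = {margin:g} <= 0"
            )
        if not self.K > 0:
            raise InvalidInputError(f"bulk modulus must be positive, got {self.K}")

    @property
    def n_terms(self):
        return len(self.mu)

    @property
    def stability_margin(self):
        return stability_check(self.mu, self.alpha)[1]

    @property
    def shear_modulus(self):
        return small_strain_shear_modulus(self.mu, self.alpha)

    @classmethod
    def default(cls):
        """Reference two-term levator ani parameter set (K from nu = 0.499)."""
        return cls.from_poisson(DEFAULT_MU, DEFAULT_ALPHA, DEFAULT_POISSON)

    @classmethod
    def from_poisson(cls, mu, alpha, poisson=DEFAULT_POISSON):
        return cls(tuple(mu), tuple(alpha), bulk_modulus_from_poisson(mu, alpha, poisson))


def _check_stretches(stretches):
    lam = np.asarray(stretches, dtype=float)
    if lam.shape[-1] != 3:
        raise InvalidInputError(f"expected 3 principal stretches, got shape {lam.shape}")
    if not np.all(lam > 0):
        raise InvalidInputError("principal stretches must be strictly positive")
    return lam


def strain_energy(params: OgdenParameters, stretches):
    """Strain-energy density W (MPa) at principal stretches (lam1, lam2, lam3).

    Accepts a trailing-axis-3 array of stretch triples and broadcasts.
    """
    lam = _check_stretches(stretches)
    j = np.prod(lam, axis=-1)
    lbar = lam * j[..., None] ** (-1.0 / 3.0)
    mu = np.asarray(params.mu)
    alpha = np.asarray(params.alpha)
    # sum over the three stretches and the N terms
    terms = 2.0 * mu / alpha * (lbar[..., :, None] ** alpha - 1.0)
    w_iso = terms.sum(axis=(-1, -2))
    w_vol = 0.5 * params.K * (j - 1.0) ** 2
    return w_iso + w_vol


def _uniaxial_p(mu, alpha, lam):
    lam = np.asarray(lam, dtype=float)
    return (2.0 * mu * (lam[..., None] ** (alpha - 1.0)
                        - lam[..., None] ** (-alpha / 2.0 - 1.0))).sum(axis=-1)


def uniaxial_nominal_stress(params: OgdenParameters, lam):
    """Nominal stress P (MPa) in incompressible uniaxial tension at stretch lam."""
    lam = np.asarray(lam, dtype=float)
    if not np.all(lam > 0):
        raise InvalidInputError("stretch must be strictly positive")
    out = _uniaxial_p(np.asarray(params.mu), np.asarray(params.alpha), lam)
    return out if out.shape else float(out)


def _spectral_stress(params: OgdenParameters, F, vol_coeff=None):
    """Batched first Piola-Kirchhoff stress P(F).

    ``F`` has shape (..., 3, 3) with det F > 0.  ``vol_coeff``, if given,
    replaces the volumetric pressure-like factor K*(J-1) per entry (used by
    the mean-dilatation treatment in the FE solver).
    """
    F = np.asarray(F, dtype=float)
    j = np.linalg.det(F)
    if not np.all(j > 0):
        from .errors import ElementInversionError

        bad = np.flatnonzero(np.atleast_1d(j) <= 0)
        raise ElementInversionError(
            f"{bad.size} deformation gradient(s) with det F <= 0", elements=bad
        )
    C = np.swapaxes(F, -1, -2) @ F
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, 1e-30, None)
    lam = np.sqrt(evals)                      # principal stretches, ascending
    lbar = lam * j[..., None] ** (-1.0 / 3.0)
    mu = np.asarray(params.mu)
    alpha = np.asarray(params.alpha)
    pow_ = lbar[..., :, None] ** alpha        # (..., 3, N)
    dev = pow_ - pow_.mean(axis=-2, keepdims=True)
    tau_iso = (2.0 * mu * dev).sum(axis=-1)   # principal Kirchhoff stresses
    # S_iso = sum_i tau_i / lam_i^2  N_i x N_i   (second Piola-Kirchhoff)
    s_diag = tau_iso / evals
    S = np.einsum("...ik,...k,...jk->...ij", evecs, s_diag, evecs,
                  optimize=True)
    P = F @ S
    if vol_coeff is None:
        vol_coeff = params.K * (j - 1.0)
    Finv_T = np.swapaxes(np.linalg.inv(F), -1, -2)
    P = P + (vol_coeff * j)[..., None, None] * Finv_T
    return P, j


def first_piola(params: OgdenParameters, F, vol_coeff=None):
    """First Piola-Kirchhoff stress tensor(s) P(F), shape like ``F``."""
    return _spectral_stress(params, F, vol_coeff)[0]


def _iso_s_and_dsdc(params: OgdenParameters, c, J):
    """Principal 2nd Piola values s_i of the isochoric term and ds_i/dc_k.

    ``c``: (..., 3) eigenvalues of C = F^T F (squared stretches); ``J``:
    determinant of F.  Everything follows from p_ij = lbar_i^alpha_j with
    lbar_i = J^(-1/3) sqrt(c_i):  tau_i = 2 sum_j mu_j (p_ij - mean_k p_kj),
    s_i = tau_i / c_i.
    """
    mu = np.asarray(params.mu)
    alpha = np.asarray(params.alpha)
    lbar = np.sqrt(c) * J[..., None] ** (-1.0 / 3.0)
    p = lbar[..., :, None] ** alpha                        # (..., 3, N)
    pbar = p.mean(axis=-2, keepdims=True)
    tau = 2.0 * (mu * (p - pbar)).sum(axis=-1)             # (..., 3)
    s = tau / c
    # dtau_i/dc_k = 2 sum_j mu_j a_j [p_ij (d_ik/(2c_i) - 1/(6c_k))
    #                                 - (p_kj - pbar_j)/(6 c_k)]
    #            = d_ik t_i/c_i - t_i/(3c_k) - (t_k - tbar)/(3c_k)
    # with t_i = sum_j mu_j a_j p_ij, tbar = sum_j mu_j a_j pbar_j.
    ma = mu * alpha
    t = (ma * p).sum(axis=-1)                              # (..., 3)
    tbar = (ma * pbar[..., 0, :]).sum(axis=-1)             # (...,)
    invc = 1.0 / c
    eye = np.eye(3)
    dtau = (eye * (t * invc)[..., :, None]
            - t[..., :, None] * invc[..., None, :] / 3.0
            - (t - tbar[..., None])[..., None, :] * invc[..., None, :] / 3.0)
    ds = dtau / c[..., :, None]
    ds -= eye * (tau / c ** 2)[..., :, None]
    return s, ds


def iso_tangent(params: OgdenParameters, F):
    """Analytic moduli A[..., a, A, c, C] = dP_iso/dF of the isochoric term.

    Spectral form with divided differences (s_i - s_k)/(c_i - c_k); for
    (near-)repeated eigenvalues the difference quotient is replaced by its
    limit ds_i/dc_i - ds_i/dc_k.  Matches a central finite difference of
    :func:`first_piola` to FD accuracy, at the cost of one
    eigendecomposition.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    C = np.swapaxes(F, -1, -2) @ F
    c, N = np.linalg.eigh(C)
    c = np.clip(c, 1e-30, None)
    s, ds = _iso_s_and_dsdc(params, c, J)
    # dS/dC as a 4th-order tensor in the eigenbasis
    # diagonal part: sum_ik ds_ik N_i N_i x N_k N_k
    CS = np.einsum("...ik,...ai,...bi,...ck,...dk->...abcd", ds, N, N, N, N,
                   optimize=True)
    # off-diagonal part: sum_{i!=k} g_ik (N_i N_k) x sym(N_i N_k)
    ci = c[..., :, None]
    ck = c[..., None, :]
    si = s[..., :, None]
    sk = s[..., None, :]
    diff = ci - ck
    near = np.abs(diff) < 1e-9 * np.maximum(ci, ck)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(near, 0.0, (si - sk) / np.where(near, 1.0, diff))
    # degenerate limit: ds_i/dc_i - ds_i/dc_k
    dii = np.einsum("...ii->...i", ds)
    g_lim = dii[..., :, None] - ds
    g = np.where(near, g_lim, g)
    off = ~np.eye(3, dtype=bool)
    g = g * off
    CS = CS + 0.5 * np.einsum("...ik,...ai,...bk,...ci,...dk->...abcd",
                              g, N, N, N, N, optimize=True)
    CS = CS + 0.5 * np.einsum("...ik,...ai,...bk,...ck,...di->...abcd",
                              g, N, N, N, N, optimize=True)
    # chain rule: dP_aA/dF_cC = d_ac S_CA + F_aB CS_BADE (d_CD F_cE + d_CE F_cD)
    S = np.einsum("...ai,...i,...bi->...ab", N, s, N)
    eye3 = np.eye(3)
    A = np.einsum("ac,...CA->...aAcC", eye3, S)
    FCS = F @ CS.reshape(F.shape[:-2] + (3, 27))
    FCS = FCS.reshape(F.shape[:-2] + (3, 3, 3, 3))        # (..., a, A, D, E)
    A = A + np.einsum("...aACE,...cE->...aAcC", FCS, F, optimize=True)
    A = A + np.einsum("...aADC,...cD->...aAcC", FCS, F, optimize=True)
    return A


def cauchy_stress(params: OgdenParameters, F):
    """Cauchy stress sigma = J^-1 P F^T for deformation gradient(s) F (MPa)."""
    P, j = _spectral_stress(params, F)
    sigma = P @ np.swapaxes(np.asarray(F, dtype=float), -1, -2) / j[..., None, None]
    # symmetrize away round-off
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def von_mises(sigma, check_symmetry=True, tol=1e-8):
    """Von Mises invariant sqrt(3/2 s:s) of symmetric stress tensor(s) (MPa)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[-2:] != (3, 3):
        raise InvalidInputError(f"expected (...,3,3) tensor, got shape {sigma.shape}")
    asym = np.abs(sigma - np.swapaxes(sigma, -1, -2)).max()
    if check_symmetry and asym > tol * max(1.0, np.abs(sigma).max()):
        raise InvalidInputError(f"stress tensor not symmetric (max asymmetry {asym:g})")
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    s = sigma - (tr / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij->...", s, s))
    return vm if vm.shape else float(vm)
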