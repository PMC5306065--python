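"""Ogden parameter identification from uniaxial stress-stretch data.

The identification minimizes the stress error

    E = 1/2 * sum_i (P_i^test - P_i^model)^2        [MPa^2]

over the moduli mu_j and exponents alpha_j of the N-term Ogden model,
subject to the small-deformation stability constraint sum mu_j alpha_j > 0.

Because the nominal stress is linear in the moduli, the solver uses variable
projection: for each trial exponent vector the optimal non-negative moduli
follow from a linear least-squares subproblem (scipy ``nnls``), and only the
exponents are iterated with ``least_squares``.  Multi-start initialization
makes the recovery robust to the non-convex exponent landscape.

A synthetic uniaxial-test generator stands in for cadaver tensile data: it
evaluates the model stress on a stretch grid and adds Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidInputError, NonConvergenceError
from .ogden import OgdenParameters, bulk_modulus_from_poisson, stability_check

__all__ = [
    "UniaxialDataset",
    "FitResult",
    "generate_uniaxial_data",
    "sse",
    "fit_ogden",
    "read_uniaxial_csv",
    "write_uniaxial_csv",
]

CSV_COLUMNS = ("stretch", "nominal_stress_mpa")


@dataclass(frozen=True)
class UniaxialDataset:
    """Uniaxial nominal stress-stretch samples (stretch >= 1, MPa)."""

    stretch: np.ndarray
    stress: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        lam = np.asarray(self.stretch, dtype=float)
        p = np.asarray(self.stress, dtype=float)
        if lam.ndim != 1 or lam.shape != p.shape or lam.size == 0:
            raise InvalidInputError("stretch and stress must be matching 1-d arrays")
        if lam[0] < 1.0:
            raise InvalidInputError(f"stretch grid must start at >= 1, got {lam[0]}")
        if lam.size > 1 and not np.all(np.diff(lam) > 0):
            raise InvalidInputError("stretch grid must be strictly increasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", p)

    def __len__(self):
        return self.stretch.size


@dataclass(frozen=True)
class FitResult:
    params: OgdenParameters
    sse: float
    n_restarts_used: int
    converged: bool


def generate_uniaxial_data(params: OgdenParameters, lam_grid, noise_sd=0.0, seed=0):
    """Synthetic uniaxial tensile test: model stress plus Gaussian noise.

    ``noise_sd`` is the noise standard deviation in MPa; zero reproduces the
    model exactly.  The same seed always yields the same dataset.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise InvalidInputError("empty stretch grid")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    from .ogden import uniaxial_nominal_stress

    p = np.asarray(uniaxial_nominal_stress(params, lam_grid), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sd, size=p.shape)
    return UniaxialDataset(lam_grid, np.atleast_1d(p), provenance="synthetic")


def sse(dataset: UniaxialDataset, params: OgdenParameters):
    """Stress error E = 1/2 sum (P_test - P_model)^2 in MPa^2."""
    from .ogden import uniaxial_nominal_stress

    resid = dataset.stress - uniaxial_nominal_stress(params, dataset.stretch)
    return 0.5 * float(np.dot(resid, resid))


def _design_matrix(lam, alpha):
    """Columns 2*(lam^(a-1) - lam^(-a/2-1)) of the mu-linear stress model."""
    lam = lam[:, None]
    alpha = np.asarray(alpha)[None, :]
    return 2.0 * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))


def _mu_for_alpha(lam, p, alpha):
    A = _design_matrix(lam, alpha)
    scale = np.maximum(np.abs(A).max(axis=0), 1e-300)
    mu_scaled, _ = optimize.nnls(A / scale, p)
    return mu_scaled / scale


def fit_ogden(dataset: UniaxialDataset, n_terms=2, alpha_bounds=(0.05, 30.0),
              n_restarts=8, seed=0, mu_floor=1e-12):
    """Fit an N-term Ogden model to uniaxial data by nonlinear least squares.

    Exponents are constrained to ``alpha_bounds`` and moduli to be
    non-negative, which together enforce the stability inequality
    ``sum mu_j alpha_j > 0``; any candidate violating it is rejected.
    Terms are reported with alpha sorted ascending (Ogden terms are
    exchangeable, so the sorted order makes the result well defined).
    """
    if len(dataset) < 2 * n_terms:
        raise InvalidInputError(
            f"need at least {2 * n_terms} data points for {n_terms} terms, "
            f"got {len(dataset)}"
        )
    lo, hi = alpha_bounds
    if not (0 < lo < hi):
        raise InvalidInputError(f"infeasible alpha bounds {alpha_bounds}")
    lam, p = dataset.stretch, dataset.stress
    if np.allclose(lam, 1.0):
        raise InvalidInputError("degenerate dataset: all stretches at the reference state")

    def residuals(alpha):
        mu = _mu_for_alpha(lam, p, alpha)
        return _design_matrix(lam, alpha) @ mu - p

    rng = np.random.default_rng(seed)
    # deterministic textbook start plus randomized restarts
    inits = [np.linspace(2.0, 12.0, n_terms)]
    while len(inits) < max(1, n_restarts):
        inits.append(np.sort(rng.uniform(max(lo, 0.5), min(hi, 25.0), size=n_terms)))

    best = None
    tried = 0
    for x0 in inits:
        tried += 1
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400,
            )
        except (ValueError, FloatingPointError):
            continue
        alpha = sol.x
        mu = _mu_for_alpha(lam, p, alpha)
        stable, _ = stability_check(np.maximum(mu, mu_floor), alpha)
        if not stable:
            continue
        err = float(sol.cost)  # least_squares cost = 1/2 sum r^2 = E
        if best is None or err < best[0]:
            best = (err, alpha, np.maximum(mu, mu_floor))

    if best is None:
        raise NonConvergenceError(
            "all fit restarts diverged or violated stability",
            diagnostics={"n_restarts": tried},
        )
    err, alpha, mu = best
    order = np.argsort(alpha)
    alpha, mu = alpha[order], mu[order]
    params = OgdenParameters(tuple(mu), tuple(alpha),
                             bulk_modulus_from_poisson(mu, alpha))
    return FitResult(params=params, sse=err, n_restarts_used=tried, converged=True)


def read_uniaxial_csv(path):
    """Read a two-column ``stretch,nominal_stress_mpa`` CSV (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"CSV {path} missing required column(s) {missing}; "
            f"expected header {','.join(CSV_COLUMNS)}"
        )
    return UniaxialDataset(df[CSV_COLUMNS[0]].to_numpy(float),
                           df[CSV_COLUMNS[1]].to_numpy(float),
                           provenance="user-file")


def write_uniaxial_csv(dataset: UniaxialDataset, path):
    pd.DataFrame({CSV_COLUMNS[0]: dataset.stretch,
                  CSV_COLUMNS[1]: dataset.stress}).to_csv(path, index=False)
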