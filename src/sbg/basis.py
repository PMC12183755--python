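"""Gaussian basis functions with widths set by the local potential curvature.

Each basis is a normalized multivariate Gaussian

    G_i(Q) = exp[-(Q - Q_i)^T alpha_i (Q - Q_i) + zeta_i]

centered at a structure Q_i in mass-weighted coordinates.  By analogy with
the ground state of a multidimensional harmonic oscillator, the width matrix
is taken as alpha_i = 1/2 * sqrt(V''(Q_i)) (atomic units, hbar = 1), where
the matrix square root requires a positive-definite Hessian.  Real Hessians
are not positive definite along a reaction path: translations and rotations
contribute (near-)zero eigenvalues, and structures around a saddle carry
negative curvature along the reaction coordinate.  The regularization step
therefore replaces near-zero eigenvalues by a finite positive constant
omega_c^2 and flips the sign of negative eigenvalues — a narrow basis in a
direction of steep negative curvature captures the sharply peaked
wavefunction there better than a wide one.  The raw Hessian is *not*
modified for potential matrix elements; regularization affects only the
basis shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import HARTREE_TO_CM

__all__ = [
    "GaussianBasis",
    "RegularizedHessian",
    "regularize_hessian",
    "width_from_hessian",
    "make_basis",
    "DEFAULT_ZERO_TOL",
    "STRICT_ZERO_TOL",
]

# strict nullspace threshold for callers that want only the exact
# translation/rotation zero modes replaced: |lambda| < (10 cm^-1)^2
STRICT_ZERO_TOL = (10.0 / HARTREE_TO_CM) ** 2
# kept under the old name for backward compatibility of call sites
DEFAULT_ZERO_TOL = None


@dataclass(frozen=True)
class RegularizedHessian:
    """Positive-definitized Hessian plus bookkeeping of what was changed."""

    matrix: np.ndarray
    flipped_count: int
    replaced_count: int
    v_const: float  # omega_c^2 in a.u., the inserted eigenvalue

    def __post_init__(self):
        evals = np.linalg.eigvalsh(self.matrix)
        if evals.min() <= 0:
            raise ValueError("regularized Hessian must be positive definite")


@dataclass(frozen=True)
class GaussianBasis:
    """Normalized anisotropic Gaussian in mass-weighted coordinates."""

    center: np.ndarray
    width: np.ndarray      # alpha_i, symmetric positive definite (a.u.)
    log_norm: float        # zeta_i
    point_id: str = ""

    def __post_init__(self):
        c = np.asarray(self.center, float)
        w = np.asarray(self.width, float)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "width", 0.5 * (w + w.T))
        if np.linalg.eigvalsh(self.width).min() <= 0:
            raise ValueError("width matrix must be positive definite")

    @property
    def dim(self) -> int:
        return self.center.size

    def __call__(self, q: np.ndarray) -> float:
        d = np.asarray(q, float) - self.center
        return float(np.exp(-d @ self.width @ d + self.log_norm))


def regularize_hessian(hessian: np.ndarray, v_const_wavenumber: float = 700.0,
                       zero_tol: float | None = None) -> RegularizedHessian:
    """Positive-definitize a Hessian for width determination.

    Negative eigenvalues have their sign flipped; eigenvalues close to zero
    are replaced by omega_c^2, where omega_c is ``v_const_wavenumber``
    converted to hartree.  By default "close to zero" is measured against
    the inserted constant itself (|lambda| < omega_c^2), so omega_c^2 acts
    as a curvature floor: no basis direction becomes wider than a mode of
    frequency omega_c.  This is what makes the choice of the constant
    matter — it should sit somewhat below the frequency of the mode of
    interest.  Passing an explicit ``zero_tol`` (e.g. ``STRICT_ZERO_TOL``)
    restricts the replacement to the exact translation/rotation nullspace
    instead.  Eigenvectors are kept; the operation is idempotent.
    """
    h = np.atleast_2d(np.asarray(hessian, float))
    scale = max(1.0, np.abs(h).max())
    if np.abs(h - h.T).max() > 1e-10 * scale:
        raise ValueError("hessian must be symmetric")
    if v_const_wavenumber <= 0:
        raise ValueError("v_const_wavenumber must be positive")
    omega_c = v_const_wavenumber / HARTREE_TO_CM
    tol = omega_c**2 if zero_tol is None else zero_tol
    evals, vecs = np.linalg.eigh(0.5 * (h + h.T))
    out = evals.copy()
    near_zero = np.abs(evals) < tol
    negative = (evals < 0) & ~near_zero
    out[near_zero] = omega_c**2
    out[negative] = -evals[negative]
    return RegularizedHessian(
        matrix=(vecs * out) @ vecs.T,
        flipped_count=int(negative.sum()),
        replaced_count=int(near_zero.sum()),
        v_const=omega_c**2,
    )


def width_from_hessian(reg: RegularizedHessian) -> np.ndarray:
    """Width matrix alpha = 1/2 * principal square root of the PD Hessian."""
    evals, vecs = np.linalg.eigh(reg.matrix)
    return 0.5 * (vecs * np.sqrt(evals)) @ vecs.T


def log_normalization(width: np.ndarray) -> float:
    """zeta with <G|G> = 1: self-overlap integral is e^{2 zeta} (pi^D / det 2 alpha)^{1/2}."""
    sign, logdet = np.linalg.slogdet(2.0 * np.atleast_2d(width) / np.pi)
    if sign <= 0:
        raise ValueError("width matrix must be positive definite")
    return 0.25 * logdet


def save_bases(path, bases: list[GaussianBasis]) -> None:
    """Write a basis set to HDF5 (group 'bases': centers, widths, norms, IDs)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("bases")
        g.create_dataset("centers", data=np.array([b.center for b in bases]))
        g.create_dataset("widths", data=np.array([b.width for b in bases]))
        g.create_dataset("log_norms", data=np.array([b.log_norm for b in bases]))
        g.create_dataset("point_ids",
                         data=np.array([b.point_id for b in bases], dtype="S64"))


def load_bases(path) -> list[GaussianBasis]:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["bases"]
        centers = g["centers"][:]
        widths = g["widths"][:]
        norms = g["log_norms"][:]
        pids = [s.decode() for s in g["point_ids"][:]]
    return [GaussianBasis(c, w, float(z), pid)
            for c, w, z, pid in zip(centers, widths, norms, pids)]


def make_basis(center, hessian_raw, v_const_wavenumber: float = 700.0,
               zero_tol: float | None = None, point_id: str = "") -> GaussianBasis:
    """Basis at ``center`` with width derived from the raw local Hessian."""
    reg = regularize_hessian(hessian_raw, v_const_wavenumber, zero_tol)
    width = width_from_hessian(reg)
    return GaussianBasis(
        center=np.atleast_1d(np.asarray(center, float)),
        width=width,
        log_norm=log_normalization(width),
        point_id=point_id,
    )
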