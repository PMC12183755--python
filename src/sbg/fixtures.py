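"""Synthetic systems and independent oracles.

Everything here exists to check the Gaussian-expansion machinery against
methods that share none of its code paths:

* a sinc-DVR (Colbert-Miller) grid eigensolver for 1D/2D potentials,
* adaptive Gauss-Hermite quadrature of matrix-element integrands,
* a steepest-descent reaction-path generator for analytic model potentials,
* a pseudo-triatomic molecule with a quadratic internal potential, whose
  Cartesian Hessian has an exact 6-dimensional rigid-body nullspace — the
  test bed for the translational/rotational projections.

The default double-well parameters put the ground-state tunneling doublet
at a few percent of the well frequency, the same tunneling-dominated regime
as an umbrella inversion, so the fixtures exercise the physics the method
is built for at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import GaussianBasis
from .geometry import (ISOTOPE_MASSES, IrcPath, Molecule, path_from_points,
                       to_mass_weighted)
from .pes import DoubleWellProvider, PotentialInfo, Provider
from .units import AMU_TO_ME

__all__ = [
    "DvrSpec",
    "dvr_eigenvalues",
    "quadrature_matrix_element",
    "synthetic_irc",
    "pseudo_triatomic",
    "default_double_well",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20250607

# desk-scale double well: doublet splitting a few % of the well frequency
DEFAULT_DW = dict(v0=1.6e-2, a=25.0, omegas=(4e-3,))
# width-floor constant slightly below the well frequency (~3141 cm^-1),
# following the rule that it should sit somewhat under the mode of interest
DOUBLE_WELL_V_CONST_CM = 2800.0


def default_double_well(couplings=None) -> DoubleWellProvider:
    return DoubleWellProvider(DEFAULT_DW["v0"], DEFAULT_DW["a"],
                              DEFAULT_DW["omegas"], couplings)


@dataclass(frozen=True)
class DvrSpec:
    """Sinc-DVR grid: per-dimension bounds and point counts (mass = 1)."""

    grid_min: tuple[float, ...]
    grid_max: tuple[float, ...]
    n_points: tuple[int, ...]

    def __post_init__(self):
        if len(self.grid_min) != len(self.grid_max) or len(self.grid_min) != len(self.n_points):
            raise ValueError("per-dimension specs must have equal length")
        if any(n < 32 for n in self.n_points):
            raise ValueError("use at least 32 DVR points per dimension")

    @property
    def ndim(self) -> int:
        return len(self.n_points)


def _sinc_dvr_1d(x_min: float, x_max: float, n: int):
    """Colbert-Miller sinc-DVR kinetic matrix and grid for unit mass, hbar=1."""
    x = np.linspace(x_min, x_max, n)
    dx = x[1] - x[0]
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0, np.pi**2 / 3.0,
                     2.0 * (-1.0) ** diff / np.where(diff == 0, 1, diff) ** 2)
    return t / (2.0 * dx**2), x


def dvr_eigenvalues(pes_callable, spec: DvrSpec, n_states: int,
                    check_convergence: bool = False) -> np.ndarray:
    """Lowest eigenvalues of -1/2 Laplacian + V on a sinc-DVR grid (1D/2D)."""
    if spec.ndim == 1:
        t, x = _sinc_dvr_1d(spec.grid_min[0], spec.grid_max[0], spec.n_points[0])
        v = np.array([pes_callable(np.array([xi])) for xi in x])
        h = t + np.diag(v)
        e = scipy.linalg.eigh(h, eigvals_only=True,
                              subset_by_index=(0, n_states - 1))
    elif spec.ndim == 2:
        t1, x1 = _sinc_dvr_1d(spec.grid_min[0], spec.grid_max[0], spec.n_points[0])
        t2, x2 = _sinc_dvr_1d(spec.grid_min[1], spec.grid_max[1], spec.n_points[1])
        n1, n2 = len(x1), len(x2)
        v = np.array([[pes_callable(np.array([a, b])) for b in x2] for a in x1])
        h = (np.kron(t1, np.eye(n2)) + np.kron(np.eye(n1), t2)
             + np.diag(v.ravel()))
        e = scipy.linalg.eigh(h, eigvals_only=True,
                              subset_by_index=(0, n_states - 1))
    else:
        raise ValueError("DVR oracle supports 1D and 2D only")

    if check_convergence:
        finer = DvrSpec(spec.grid_min, spec.grid_max,
                        tuple(2 * n for n in spec.n_points))
        e2 = dvr_eigenvalues(pes_callable, finer, n_states)
        rel = np.abs(e - e2) / np.maximum(np.abs(e2), 1e-300)
        if rel.max() > 1e-8:
            import warnings

            warnings.warn(f"DVR not converged: max relative change {rel.max():.2e}")
        return e2
    return e


# ---------------------------------------------------------------------------
# Gauss-Hermite quadrature oracle for matrix elements, D <= 3


def _gh_nodes(dim: int, n: int, a_matrix: np.ndarray, center: np.ndarray):
    """Nodes/weights for int f(Q) exp(-(Q-m)^T A (Q-m)) dQ via tensor Gauss-Hermite."""
    y, w = np.polynomial.hermite.hermgauss(n)
    evals, vecs = np.linalg.eigh(a_matrix)
    l = vecs / np.sqrt(evals)  # Q = m + L y maps the exponent to -y^T y
    grids = np.meshgrid(*([y] * dim), indexing="ij")
    ys = np.stack([g.ravel() for g in grids], axis=1)
    ws = np.ones(ys.shape[0])
    for k in range(dim):
        wk = np.meshgrid(*([w] * dim), indexing="ij")[k].ravel()
        ws *= wk
    pts = center[None, :] + ys @ l.T
    jac = np.prod(1.0 / np.sqrt(evals))
    return pts, ws * jac, ys


def quadrature_matrix_element(operator_tag: str, g1: GaussianBasis,
                              g2: GaussianBasis, pes_callable=None,
                              ab: tuple[int, int] | None = None,
                              info: PotentialInfo | None = None,
                              n_start: int = 24, tol: float = 1e-10) -> float:
    """Adaptive Gauss-Hermite quadrature of <G1|op|G2> for D <= 3.

    operator_tag: 'overlap', 'kinetic_ab' (needs ab), 'potential_exact'
    (needs pes_callable) or 'potential_lha' (needs info at the midpoint).
    The node count doubles until successive estimates differ by < tol.
    """
    dim = g1.dim
    if dim > 3:
        raise ValueError("quadrature oracle supports D <= 3")
    a = g1.width + g2.width
    m = np.linalg.solve(a, g1.width @ g1.center + g2.width @ g2.center)

    def integrand(pts):
        d1 = pts - g1.center
        d2 = pts - g2.center
        quad1 = np.einsum("pi,ij,pj->p", d1, g1.width, d1)
        quad2 = np.einsum("pi,ij,pj->p", d2, g2.width, d2)
        dm = pts - m
        quadm = np.einsum("pi,ij,pj->p", dm, a, dm)
        # G1*G2 with the product-Gaussian exponent factored out
        base = np.exp(-quad1 - quad2 + quadm + g1.log_norm + g2.log_norm)
        if operator_tag == "overlap":
            return base
        if operator_tag == "kinetic_ab":
            ia, ib = ab
            # -d2 G2/dQa dQb = (2 alpha2_ab - 4 [alpha2 d2]_a [alpha2 d2]_b) G2
            ad = d2 @ g2.width.T
            poly = 2.0 * g2.width[ia, ib] - 4.0 * ad[:, ia] * ad[:, ib]
            return poly * base
        if operator_tag == "potential_exact":
            v = np.array([pes_callable(p) for p in pts])
            return v * base
        if operator_tag == "potential_lha":
            dm2 = pts - m
            vq = info.energy + 0.5 * np.einsum(
                "pi,ij,pj->p", dm2, info.hessian, dm2)
            return vq * base
        raise ValueError(f"unknown operator tag {operator_tag!r}")

    prev = None
    n = n_start
    while n <= 200:
        pts, ws, _ = _gh_nodes(dim, n, a, m)
        val = float(np.sum(ws * integrand(pts)))
        if prev is not None and abs(val - prev) < tol:
            return val
        prev = val
        n *= 2
    return prev


# ---------------------------------------------------------------------------
# Steepest-descent reaction path on an analytic model potential


def synthetic_irc(model_pes: Provider, step: float = 0.05,
                  max_points: int = 20000) -> IrcPath:
    """Mass-weighted steepest-descent path saddle -> both minima.

    Starting from the model's saddle point displaced by +/- 1e-4 along the
    negative-curvature eigenvector, normalized-gradient Euler steps of size
    ``step`` are taken until the gradient norm falls below 1e-8.  The two
    branches are concatenated minima-to-minima and arc lengths accumulated.
    """
    saddle = model_pes.saddle
    info = model_pes.evaluate(saddle, need_hessian=True)
    evals, vecs = np.linalg.eigh(info.hessian)
    if evals[0] >= 0 or (evals[1:] < 0).any():
        raise ValueError("starting point is not a first-order saddle")
    if np.linalg.norm(info.gradient) > 1e-8:
        raise ValueError("starting point is not stationary")
    downhill = vecs[:, 0]

    def descend(direction):
        q = saddle + 1e-4 * direction
        pts = [saddle.copy()]
        energies = [info.energy]
        cur = model_pes.evaluate(q, need_hessian=False)
        for _ in range(max_points):
            pts.append(q.copy())
            energies.append(cur.energy)
            gn = np.linalg.norm(cur.gradient)
            if gn < 1e-8:
                return pts, energies
            q_next = q - step * cur.gradient / gn
            nxt = model_pes.evaluate(q_next, need_hessian=False)
            if nxt.energy >= cur.energy:
                break  # overshot: inside the quadratic basin of the minimum
            q, cur = q_next, nxt
        # normalized-gradient Euler oscillates around the minimum; polish the
        # endpoint down to gradient norm < 1e-8 with a quasi-Newton step
        from scipy.optimize import minimize

        res = minimize(
            lambda p: model_pes.evaluate(p, need_hessian=False).energy,
            q, jac=lambda p: model_pes.evaluate(p, need_hessian=False).gradient,
            method="BFGS", options={"gtol": 1e-10})
        if res.fun <= energies[-1]:
            if np.linalg.norm(res.x - pts[-1]) <= step:
                # final Euler point may have overshot the minimum; snap it
                pts[-1] = res.x
                energies[-1] = float(res.fun)
            else:
                pts.append(res.x)
                energies.append(float(res.fun))
        return pts, energies

    pts_f, e_f = descend(downhill)
    pts_b, e_b = descend(-downhill)
    points = list(reversed(pts_b)) + pts_f[1:]
    energies = list(reversed(e_b)) + e_f[1:]
    return path_from_points(np.array(points), np.array(energies))


# ---------------------------------------------------------------------------
# Pseudo-triatomic molecule with quadratic internal potential


class _InternalQuadraticProvider(Provider):
    """V = 1/2 dq^T K dq over exact internal coordinates (2 bonds + 1 angle).

    Because the internals are exactly invariant under rigid motions, the
    Cartesian Hessian at equilibrium is J^T K J with J the internal-coordinate
    Jacobian, carrying an exact 6-dimensional translation/rotation nullspace.
    Off equilibrium the Hessian is obtained by central differences of the
    analytic gradient.  The provider operates on mass-weighted coordinates.
    """

    def __init__(self, masses_amu: np.ndarray, q_eq: np.ndarray,
                 k_internal: np.ndarray, internal_ref: np.ndarray):
        super().__init__(9, frozenset({"energy", "gradient", "hessian"}))
        self.sqrt_m = np.sqrt(np.asarray(masses_amu, float) * AMU_TO_ME)
        self.k = np.asarray(k_internal, float)
        self.q0 = np.asarray(internal_ref, float)
        self.q_eq = np.asarray(q_eq, float)

    # -- internal coordinates on Cartesian (bohr) positions ------------------

    @staticmethod
    def _internals(x: np.ndarray):
        """(r01, r21, theta) and their Jacobian w.r.t. the 9 Cartesians."""
        a, b, c = x[0], x[1], x[2]  # atoms: terminal, center, terminal
        v1, v2 = a - b, c - b
        r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
        u1, u2 = v1 / r1, v2 / r2
        cth = float(np.clip(u1 @ u2, -1.0, 1.0))
        th = np.arccos(cth)
        sth = np.sqrt(max(1.0 - cth**2, 1e-30))

        jac = np.zeros((3, 9))
        jac[0, 0:3] = u1
        jac[0, 3:6] = -u1
        jac[1, 6:9] = u2
        jac[1, 3:6] = -u2
        # Wilson angle-bend s-vectors
        sa = (cth * u1 - u2) / (r1 * sth)
        sc = (cth * u2 - u1) / (r2 * sth)
        jac[2, 0:3] = sa
        jac[2, 6:9] = sc
        jac[2, 3:6] = -(sa + sc)
        return np.array([r1, r2, th]), jac

    def _cart_energy_grad(self, x_flat: np.ndarray):
        x = x_flat.reshape(3, 3)
        q, jac = self._internals(x)
        dq = q - self.q0
        e = 0.5 * dq @ self.k @ dq
        g = jac.T @ (self.k @ dq)
        return e, g

    def _evaluate(self, point, need_hessian):
        x = (point.reshape(3, 3) / self.sqrt_m[:, None]).ravel()
        e, g_cart = self._cart_energy_grad(x)
        g_mw = (g_cart.reshape(3, 3) / self.sqrt_m[:, None]).ravel()
        h_mw = None
        if need_hessian:
            step = 1e-6
            h = np.empty((9, 9))
            for i in range(9):
                dx = np.zeros(9)
                dx[i] = step
                _, gp = self._cart_energy_grad(x + dx)
                _, gm = self._cart_energy_grad(x - dx)
                h[i] = (gp - gm) / (2 * step)
            h = 0.5 * (h + h.T)
            inv_sm = np.repeat(1.0 / self.sqrt_m, 3)
            h_mw = h * np.outer(inv_sm, inv_sm)
        return PotentialInfo(energy=e, gradient=g_mw, hessian=h_mw)


def pseudo_triatomic() -> tuple[Molecule, Provider]:
    """Bent water-like 3-atom fixture with a quadratic internal potential.

    Returns the equilibrium molecule and a provider in mass-weighted
    coordinates whose equilibrium Hessian has exactly 3 vibrational and 6
    (near-)zero eigenvalues.
    """
    # bent geometry, bond length 1.0 Angstrom, angle ~104.5 degrees
    half = np.deg2rad(104.5 / 2)
    coords = np.array([
        [np.sin(half), np.cos(half), 0.0],
        [0.0, 0.0, 0.0],
        [-np.sin(half), np.cos(half), 0.0],
    ])
    masses = np.array([ISOTOPE_MASSES["H"], ISOTOPE_MASSES["O"],
                       ISOTOPE_MASSES["H"]])
    coords = coords - (masses[:, None] * coords).sum(0) / masses.sum()
    mol = Molecule.from_labels(("H", "O", "H"), coords)
    x_eq = (coords * 1.8897261255)
    q_eq = to_mass_weighted(mol)

    # stiffness in hartree/bohr^2 and hartree/rad^2: stretch, stretch, bend
    k_internal = np.diag([0.45, 0.45, 0.15])
    internal_ref, _ = _InternalQuadraticProvider._internals(x_eq)
    provider = _InternalQuadraticProvider(mol.masses, q_eq, k_internal,
                                          internal_ref)
    return mol, provider
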