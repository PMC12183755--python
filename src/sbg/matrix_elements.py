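"""Closed-form matrix elements between anisotropic Gaussian bases.

For two normalized Gaussians G_1, G_2 with centers Q_1, Q_2 and width
matrices alpha_1, alpha_2, write A = alpha_1 + alpha_2 and
B = alpha_1 A^{-1} alpha_2 (B is symmetric).  The product G_1 G_2 is again a
Gaussian with exponent matrix A centered at the width-weighted midpoint
m = A^{-1}(alpha_1 Q_1 + alpha_2 Q_2), which gives, with d = Q_1 - Q_2:

    <G1|G2>          = e^{zeta_1+zeta_2} sqrt(pi^D / det A) e^{-d^T B d}
    -<G1|d2/dQa dQb|G2> = <G1|G2> (2 B - 4 (B d)(B d)^T)_{ab}

The vibrational kinetic element is 1/2 Tr[(1 - O_tra - O_rot) M] with M the
momentum-moment matrix above; for abstract systems the projectors vanish.
Potential elements use the local harmonic approximation around the pair
midpoint:

    <G1|V|G2> ~= { V(m) + 1/4 Tr[(alpha_1+alpha_2)^{-1} V''(m)] } <G1|G2>

These closed forms are validated against adaptive Gauss-Hermite quadrature
oracles in the test suite before being trusted anywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import GaussianBasis
from .geometry import ProjectionOperators, no_projections
from .pes import PotentialInfo, Provider, SymmetryOperation, symmetry_expand

__all__ = [
    "HamiltonianMatrices",
    "overlap",
    "midpoint",
    "momentum_moments",
    "kinetic_vib",
    "potential_lha",
    "assemble",
]


@dataclass
class HamiltonianMatrices:
    """Overlap, vibrational kinetic and potential matrices for L bases."""

    overlap: np.ndarray
    kinetic_vib: np.ndarray
    potential: np.ndarray
    evaluation_log: list[str] = field(default_factory=list)

    @property
    def n_bases(self) -> int:
        return self.overlap.shape[0]

    @property
    def h_vib(self) -> np.ndarray:
        return self.kinetic_vib + self.potential


def _pair_quantities(g1: GaussianBasis, g2: GaussianBasis):
    """Shared intermediates A, B, d, m for a basis pair."""
    if g1.dim != g2.dim:
        raise ValueError("basis dimensions differ")
    a = g1.width + g2.width
    a_inv = np.linalg.inv(a)
    b = g1.width @ a_inv @ g2.width
    b = 0.5 * (b + b.T)
    d = g1.center - g2.center
    m = a_inv @ (g1.width @ g1.center + g2.width @ g2.center)
    return a, a_inv, b, d, m


def overlap(g1: GaussianBasis, g2: GaussianBasis) -> float:
    """<G1|G2>; equals 1 for identical normalized bases."""
    a, _, b, d, _ = _pair_quantities(g1, g2)
    sign, logdet = np.linalg.slogdet(a / np.pi)
    if sign <= 0:
        raise ValueError("width sum must be positive definite")
    log_s = g1.log_norm + g2.log_norm - 0.5 * logdet - d @ b @ d
    return float(np.exp(log_s))


def midpoint(g1: GaussianBasis, g2: GaussianBasis) -> np.ndarray:
    """Width-weighted midpoint: the peak of the product G1*G2."""
    _, _, _, _, m = _pair_quantities(g1, g2)
    return m


def momentum_moments(g1: GaussianBasis, g2: GaussianBasis) -> np.ndarray:
    """Matrix M with M_ab = -<G1| d^2/(dQ_a dQ_b) |G2>  (= <G1|P_a P_b|G2>, hbar=1)."""
    _, _, b, d, _ = _pair_quantities(g1, g2)
    s = overlap(g1, g2)
    bd = b @ d
    return s * (2.0 * b - 4.0 * np.outer(bd, bd))


def kinetic_vib(g1: GaussianBasis, g2: GaussianBasis,
                proj: ProjectionOperators | None = None) -> float:
    """Vibrational kinetic element 1/2 Tr[(1 - O_tra - O_rot) M]."""
    m = momentum_moments(g1, g2)
    if proj is None:
        return 0.5 * float(np.trace(m))
    o_vib = proj.vibrational_complement
    return 0.5 * float(np.trace(o_vib @ m))


def potential_lha(g1: GaussianBasis, g2: GaussianBasis,
                  info_at_midpoint: PotentialInfo) -> float:
    """Local-harmonic potential element using the *raw* Hessian at the midpoint."""
    if info_at_midpoint.hessian is None:
        from .pes import CapabilityError

        raise CapabilityError("potential_lha requires a Hessian at the midpoint")
    a = g1.width + g2.width
    trace_term = 0.25 * float(np.trace(np.linalg.solve(a, info_at_midpoint.hessian)))
    return (info_at_midpoint.energy + trace_term) * overlap(g1, g2)


# ---------------------------------------------------------------------------
# Hamiltonian assembly with symmetry deduplication of potential evaluations


def _induced_permutation(bases: list[GaussianBasis], op: SymmetryOperation,
                         tol: float = 1e-6) -> list[int]:
    """Index permutation sigma with center[sigma(i)] = M @ center[i]."""
    centers = np.array([b.center for b in bases])
    perm = []
    for i, b in enumerate(bases):
        img = op.apply(b.center)
        dist = np.linalg.norm(centers - img, axis=1)
        j = int(np.argmin(dist))
        if dist[j] > tol:
            raise ValueError(
                f"symmetry operation does not map basis {i} onto the basis set")
        perm.append(j)
    if sorted(perm) != list(range(len(bases))):
        raise ValueError("symmetry operation does not permute the basis set")
    return perm


def pair_orbits(n: int, perm: list[int] | None):
    """Orbits of unordered index pairs (i <= j) under the permutation."""
    pairs = [(i, j) for i in range(n) for j in range(i, n)]
    if perm is None:
        return [[p] for p in pairs]
    seen: set[tuple[int, int]] = set()
    orbits = []
    for p in pairs:
        if p in seen:
            continue
        orbit = []
        q = p
        while q not in seen:
            seen.add(q)
            orbit.append(q)
            q = tuple(sorted((perm[q[0]], perm[q[1]])))
        orbits.append(orbit)
    return orbits


def center_orbits(n: int, perm: list[int] | None):
    """Orbits of single indices under the permutation."""
    if perm is None:
        return [[i] for i in range(n)]
    seen: set[int] = set()
    orbits = []
    for i in range(n):
        if i in seen:
            continue
        orbit = []
        j = i
        while j not in seen:
            seen.add(j)
            orbit.append(j)
            j = perm[j]
        orbits.append(orbit)
    return orbits


def assemble(bases: list[GaussianBasis], source,
             proj: ProjectionOperators | None = None,
             symmetry: SymmetryOperation | None = None) -> HamiltonianMatrices:
    """Assemble S, T_vib and V for a basis set.

    ``source`` is anything with an ``evaluate(point, need_hessian=True)``
    method returning :class:`PotentialInfo` — an analytic or tabulated
    provider, or a GPR-backed source.  Potential information is requested at
    every unordered pair midpoint; when a symmetry operation mapping the
    basis set onto itself is supplied, only one representative per pair
    orbit is evaluated and the images are filled in by transforming that
    result, mirroring how symmetry cuts the number of electronic-structure
    calculations in practice.
    """
    n = len(bases)
    if n == 0:
        raise ValueError("empty basis set")
    dim = bases[0].dim
    if any(b.dim != dim for b in bases):
        raise ValueError("all bases must share one dimension")
    if proj is None:
        proj = no_projections(dim)

    s = np.eye(n)
    t = np.empty((n, n))
    v = np.empty((n, n))
    log: list[str] = []

    for i in range(n):
        for j in range(i, n):
            s[i, j] = s[j, i] = overlap(bases[i], bases[j])
            t[i, j] = t[j, i] = kinetic_vib(bases[i], bases[j], proj)

    perm = None if symmetry is None else _induced_permutation(bases, symmetry)
    infos: dict[tuple[int, int], PotentialInfo] = {}
    for orbit in pair_orbits(n, perm):
        i, j = orbit[0]
        rep_mid = midpoint(bases[i], bases[j])
        rep_info = source.evaluate(rep_mid, need_hessian=True)
        pid = (bases[i].point_id or str(i)) + "|" + (bases[j].point_id or str(j))
        log.append(pid)
        infos[(i, j)] = rep_info
        for (k, l) in orbit[1:]:
            img_info = symmetry_expand(rep_info, symmetry)
            img_mid = midpoint(bases[k], bases[l])
            # the symmetric image is only trusted when it lands on the pair midpoint
            if np.linalg.norm(symmetry.apply(rep_mid) - img_mid) > 1e-6:
                img_info = source.evaluate(img_mid, need_hessian=True)
                log.append((bases[k].point_id or str(k)) + "|"
                           + (bases[l].point_id or str(l)))
            infos[(k, l)] = img_info

    for i in range(n):
        for j in range(i, n):
            v[i, j] = v[j, i] = potential_lha(bases[i], bases[j], infos[(i, j)])

    return HamiltonianMatrices(overlap=s, kinetic_vib=t, potential=v,
                               evaluation_log=log)
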