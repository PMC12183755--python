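"""Molecular structures, mass-weighted coordinates and rigid-body projections.

A molecule with N atoms lives in D = 3N mass-weighted Cartesian coordinates
Q_(A,k) = sqrt(m_A) * x_(A,k) (atomic units).  In these coordinates the
kinetic operator is an isotropic Laplacian, and rigid translations and
rotations span a 6-dimensional (5 for collinear geometries) subspace that
must be projected out of the vibrational kinetic energy.

Abstract (non-molecular) systems of arbitrary dimension D are first class:
they carry no atom structure and no rigid-body subspace, which is exactly
what low-dimensional model potentials and oracle tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import AMU_TO_ME, ANGSTROM_TO_BOHR

__all__ = [
    "Molecule",
    "ProjectionOperators",
    "IrcPath",
    "ISOTOPE_MASSES",
    "to_mass_weighted",
    "from_mass_weighted",
    "align_path",
    "projection_operators",
    "no_projections",
    "read_xyz",
    "write_xyz",
]

# average isotopic masses in amu for the light elements used here
ISOTOPE_MASSES = {
    "H": 1.00782503, "D": 2.01410178, "C": 12.0, "N": 14.0030740,
    "O": 15.9949146, "F": 18.9984032, "S": 31.9720707, "Cl": 34.9688527,
}


@dataclass(frozen=True)
class Molecule:
    """N-atom structure: element labels, masses (amu), coordinates (Angstrom)."""

    labels: tuple[str, ...]
    masses: np.ndarray          # (N,) amu
    coords: np.ndarray          # (N, 3) Angstrom

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not (len(self.labels) == masses.shape[0] == coords.shape[0]):
            raise ValueError("labels, masses and coords must have equal length")
        if np.any(masses <= 0):
            raise ValueError("atomic masses must be positive")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(cls, labels, coords, masses=None) -> "Molecule":
        if masses is None:
            masses = [ISOTOPE_MASSES[lab] for lab in labels]
        return cls(tuple(labels), np.asarray(masses, float), np.asarray(coords, float))


def to_mass_weighted(molecule: Molecule) -> np.ndarray:
    """Map a molecule to the mass-weighted coordinate vector Q (a.u.).

    Component (A, k) is sqrt(m_A) * x_(A,k) with masses in electron masses
    and positions in bohr, giving Q in sqrt(m_e)*bohr.
    """
    m = molecule.masses * AMU_TO_ME
    x = molecule.coords * ANGSTROM_TO_BOHR
    return (np.sqrt(m)[:, None] * x).ravel()


def from_mass_weighted(q: np.ndarray, masses_amu: np.ndarray,
                       labels=None) -> Molecule:
    """Inverse of :func:`to_mass_weighted`."""
    masses_amu = np.asarray(masses_amu, float)
    m = masses_amu * AMU_TO_ME
    x = np.asarray(q, float).reshape(-1, 3) / np.sqrt(m)[:, None]
    if labels is None:
        labels = tuple("X" for _ in masses_amu)
    return Molecule(tuple(labels), masses_amu, x / ANGSTROM_TO_BOHR)


def _mw_com(q: np.ndarray, sqrt_m: np.ndarray) -> np.ndarray:
    """Center of mass of a mass-weighted vector: sum_A sqrt(m_A) Q_A / sum m."""
    qa = q.reshape(-1, 3)
    return (sqrt_m[:, None] * qa).sum(axis=0) / (sqrt_m**2).sum()


def _kabsch(q_ref: np.ndarray, q_mov: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing |q_ref - R q_mov| in mass-weighted space.

    Both vectors must already have zero mass-weighted center.  Mass weighting
    is implicit: the coordinates themselves carry sqrt(m).
    """
    a = q_mov.reshape(-1, 3)
    b = q_ref.reshape(-1, 3)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r


@dataclass
class IrcPath:
    """Ordered, aligned mass-weighted structures along a reaction path.

    ``points`` is an (L, D) array; ``arc`` the cumulative mass-weighted arc
    length (a.u.), ``energies`` per-point potential energies (hartree) and
    ``tangent`` unit tangents by central differences in arc length.
    """

    points: np.ndarray
    arc: np.ndarray
    energies: np.ndarray | None = None
    masses_amu: np.ndarray | None = None
    labels: tuple[str, ...] | None = None
    tangent: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.arc = np.asarray(self.arc, float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("a path needs at least 2 points")
        if np.any(np.diff(self.arc) <= 0):
            raise ValueError("arc length must be strictly increasing")
        grad = np.gradient(self.points, self.arc, axis=0)
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        self.tangent = grad / norms

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def resample(self, n: int) -> "IrcPath":
        """Linear-interpolation resampling to n points uniform in arc length."""
        s = np.linspace(self.arc[0], self.arc[-1], n)
        pts = np.empty((n, self.dim))
        for j in range(self.dim):
            pts[:, j] = np.interp(s, self.arc, self.points[:, j])
        e = None
        if self.energies is not None:
            e = np.interp(s, self.arc, self.energies)
        return IrcPath(pts, s, e, self.masses_amu, self.labels)

    def interpolate(self, s: float) -> np.ndarray:
        """Structure at arc length s by linear interpolation."""
        return np.array([np.interp(s, self.arc, self.points[:, j])
                         for j in range(self.dim)])


def path_from_points(points, energies=None) -> IrcPath:
    """Build an abstract-system path directly from mass-weighted points."""
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return IrcPath(points, arc, None if energies is None else np.asarray(energies, float))


def align_path(structures: list[Molecule], energies=None) -> IrcPath:
    """Align a sequence of structures into a mass-weighted reaction path.

    Each frame is translated to zero mass-weighted center, then sequentially
    rotated onto its predecessor by mass-weighted least-squares superposition,
    so frame-to-frame displacements carry no net linear or angular momentum.
    Arc length is the cumulative Euclidean norm of successive mass-weighted
    displacements.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    n = structures[0].n_atoms
    masses = structures[0].masses
    for s in structures[1:]:
        if s.n_atoms != n or not np.allclose(s.masses, masses):
            raise ValueError("all structures must share atom count and masses")
    sqrt_m = np.sqrt(masses * AMU_TO_ME)

    aligned = []
    for mol in structures:
        q = to_mass_weighted(mol)
        qa = q.reshape(-1, 3) - np.outer(sqrt_m, _mw_com(q, sqrt_m))
        q = qa.ravel()
        if aligned:
            r = _kabsch(aligned[-1], q)
            q = (q.reshape(-1, 3) @ r.T).ravel()
        aligned.append(q)

    pts = np.array(aligned)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    e = None if energies is None else np.asarray(energies, float)
    return IrcPath(pts, arc, e, masses, structures[0].labels)


@dataclass(frozen=True)
class ProjectionOperators:
    """Idempotent projectors onto rigid translation / rotation subspaces."""

    o_tra: np.ndarray
    o_rot: np.ndarray
    reference: np.ndarray

    @property
    def vibrational_complement(self) -> np.ndarray:
        d = self.o_tra.shape[0]
        return np.eye(d) - self.o_tra - self.o_rot


def no_projections(dim: int) -> ProjectionOperators:
    """Trivial projections for abstract (non-molecular) systems."""
    z = np.zeros((dim, dim))
    return ProjectionOperators(z, z.copy(), np.zeros(dim))


def projection_operators(reference: np.ndarray, masses_amu: np.ndarray,
                         com_tol: float = 1e-8) -> ProjectionOperators:
    """Build O_tra and O_rot at a reference geometry.

    Translation vectors t_k have component (A, j) proportional to
    sqrt(m_A) delta_jk; rotation vectors r_k have component (A, j) equal to
    sqrt(m_A) (e_k x x_A)_j with x_A the Cartesian position, i.e. the
    infinitesimal rigid-rotation displacement in mass-weighted coordinates.
    The r_k are Gram-Schmidt orthonormalized against the t_k and each other;
    a zero-norm rotation vector (collinear geometry) is dropped, leaving a
    rank-2 rotational projector.
    """
    q = np.asarray(reference, float)
    masses_amu = np.asarray(masses_amu, float)
    sqrt_m = np.sqrt(masses_amu * AMU_TO_ME)
    n = sqrt_m.size
    if q.size != 3 * n:
        raise ValueError("reference dimension must equal 3 * n_atoms")
    com = _mw_com(q, sqrt_m)
    if np.linalg.norm(com) > com_tol:
        raise ValueError(f"reference has nonzero mass-weighted center {com}")

    d = 3 * n
    tvecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sqrt_m
        t = t.ravel()
        tvecs.append(t / np.linalg.norm(t))

    # Cartesian positions recovered from the mass-weighted reference
    x = q.reshape(-1, 3) / sqrt_m[:, None]
    basis = list(tvecs)
    rvecs = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        r = (sqrt_m[:, None] * np.cross(np.broadcast_to(e, (n, 3)), x)).ravel()
        for b in basis:
            r = r - (b @ r) * b
        nr = np.linalg.norm(r)
        if nr < 1e-10 * max(1.0, np.linalg.norm(q)):
            continue
        r = r / nr
        basis.append(r)
        rvecs.append(r)

    o_tra = sum(np.outer(t, t) for t in tvecs)
    o_rot = (sum(np.outer(r, r) for r in rvecs)
             if rvecs else np.zeros((d, d)))
    return ProjectionOperators(o_tra, o_rot, q.copy())


# ---------------------------------------------------------------------------
# multi-frame XYZ I/O; the comment line may carry "E=<hartree>"

def read_xyz(path) -> tuple[list[Molecule], list[float | None]]:
    frames: list[Molecule] = []
    energies: list[float | None] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].strip())
        comment = lines[i + 1]
        energy = None
        for tok in comment.replace(",", " ").split():
            if tok.upper().startswith("E="):
                energy = float(tok[2:])
        labels, coords = [], []
        for j in range(nat):
            parts = lines[i + 2 + j].split()
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(Molecule.from_labels(labels, np.array(coords)))
        energies.append(energy)
        i += 2 + nat
    return frames, energies


def write_xyz(path, frames: list[Molecule], energies=None) -> None:
    with open(path, "w") as fh:
        for k, mol in enumerate(frames):
            fh.write(f"{mol.n_atoms}\n")
            if energies is not None and energies[k] is not None:
                fh.write(f"E={energies[k]:.12f}\n")
            else:
                fh.write(f"frame {k}\n")
            for lab, xyz in zip(mol.labels, mol.coords):
                fh.write(f"{lab} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
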