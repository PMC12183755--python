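"""Potential-information providers: analytic models, tabulated stores, symmetry.

Every source of potential information implements the same contract: given a
point in mass-weighted coordinates it returns a :class:`PotentialInfo` with
the energy (hartree), optionally the gradient, and optionally the
mass-weighted Cartesian Hessian, whose eigenvalues are squared angular
frequencies in atomic units.  Providers declare capabilities and count their
evaluations, since the number of potential evaluations (in the real
application: quantum-chemistry calculations) is the central cost metric of
the method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PotentialInfo",
    "SymmetryOperation",
    "CapabilityError",
    "Provider",
    "HarmonicProvider",
    "DoubleWellProvider",
    "CallableProvider",
    "PotentialStore",
    "StoreProvider",
    "evaluate",
    "model_double_well",
    "symmetry_expand",
    "finite_difference_hessian",
]

SCHEMA_VERSION = "sbg-pes-1"


class CapabilityError(RuntimeError):
    """A provider was asked for a quantity it cannot produce."""


@dataclass
class PotentialInfo:
    """Local potential information at one point.

    energy in hartree; gradient (optional) in hartree per mass-weighted
    length; hessian (optional) symmetric, in hartree per mass-weighted
    length squared (eigenvalues are omega^2 in a.u.).
    """

    energy: float
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, float)
        if self.hessian is not None:
            h = np.asarray(self.hessian, float)
            scale = max(1.0, np.abs(h).max())
            if np.abs(h - h.T).max() > 1e-10 * scale:
                raise ValueError("hessian must be symmetric")
            self.hessian = 0.5 * (h + h.T)


@dataclass(frozen=True)
class SymmetryOperation:
    """Orthogonal operation in mass-weighted space with finite order."""

    matrix: np.ndarray
    order: int = 2

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if np.abs(m @ m.T - np.eye(m.shape[0])).max() > 1e-12:
            raise ValueError("symmetry matrix must be orthogonal")
        p = np.linalg.matrix_power(m, self.order)
        if np.abs(p - np.eye(m.shape[0])).max() > 1e-10:
            raise ValueError("matrix**order must be the identity")
        object.__setattr__(self, "matrix", m)

    def apply(self, q: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(q, float)


class Provider:
    """Base class for potential-information providers."""

    def __init__(self, dim: int, capabilities: frozenset[str]):
        self.dim = dim
        self.capabilities = frozenset(capabilities)
        self.n_evaluations = 0

    def _evaluate(self, point: np.ndarray, need_hessian: bool) -> PotentialInfo:
        raise NotImplementedError

    def evaluate(self, point: np.ndarray, need_hessian: bool = True) -> PotentialInfo:
        point = np.asarray(point, float)
        if point.size != self.dim:
            raise ValueError(f"point has dimension {point.size}, provider {self.dim}")
        if need_hessian and "hessian" not in self.capabilities:
            raise CapabilityError(
                "provider cannot supply Hessians; wrap with finite_difference_hessian")
        self.n_evaluations += 1
        return self._evaluate(point, need_hessian)


def evaluate(provider: Provider, point, need_hessian: bool = True) -> PotentialInfo:
    """Functional wrapper around ``provider.evaluate``."""
    return provider.evaluate(point, need_hessian)


class CallableProvider(Provider):
    """Energy-only provider built from a plain callable V(Q)."""

    def __init__(self, dim: int, fn):
        super().__init__(dim, frozenset({"energy"}))
        self.fn = fn

    def _evaluate(self, point, need_hessian):
        return PotentialInfo(energy=float(self.fn(point)))


class HarmonicProvider(Provider):
    """V(Q) = e0 + 1/2 (Q-Q0)^T H (Q-Q0) with a constant Hessian H."""

    def __init__(self, hessian: np.ndarray, center=None, e0: float = 0.0):
        h = np.atleast_2d(np.asarray(hessian, float))
        super().__init__(h.shape[0], frozenset({"energy", "gradient", "hessian"}))
        self.h = 0.5 * (h + h.T)
        self.center = np.zeros(self.dim) if center is None else np.asarray(center, float)
        self.e0 = e0

    def _evaluate(self, point, need_hessian):
        d = point - self.center
        return PotentialInfo(
            energy=self.e0 + 0.5 * d @ self.h @ d,
            gradient=self.h @ d,
            hessian=self.h.copy() if need_hessian else None,
        )


class DoubleWellProvider(Provider):
    """Quartic double well along Q1 with harmonic transverse modes.

    V(Q) = V0 (Q1^2 - a^2)^2 / a^4 + sum_k 1/2 omega_k^2 (Q_k + c_k Q1^2)^2

    Two equivalent minima at Q1 = +/- a (with Q_k = -c_k a^2), one saddle at
    the origin with a single negative Hessian eigenvalue -4 V0 / a^2 along Q1
    (plus coupling corrections).  With c_k = 0 the problem is separable and
    its spectrum is the 1D double-well spectrum plus harmonic ladders, which
    makes it the workhorse fixture for oracle comparisons.  The bilinear
    c_k Q1^2 coupling bends the reaction path off the Q1 axis, emulating the
    multi-component structure of a real umbrella-inversion path.
    """

    def __init__(self, v0: float, a: float, omegas=(), couplings=None):
        if v0 <= 0 or a <= 0:
            raise ValueError("barrier height V0 and well separation a must be positive")
        omegas = np.asarray(omegas, float)
        if np.any(omegas <= 0):
            raise ValueError("transverse frequencies must be positive")
        dim = 1 + omegas.size
        super().__init__(dim, frozenset({"energy", "gradient", "hessian"}))
        self.v0, self.a = float(v0), float(a)
        self.omegas = omegas
        self.couplings = (np.zeros(omegas.size) if couplings is None
                          else np.asarray(couplings, float))

    @property
    def minima(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.concatenate([[-self.a], -self.couplings * self.a**2])
        hi = np.concatenate([[+self.a], -self.couplings * self.a**2])
        return lo, hi

    @property
    def saddle(self) -> np.ndarray:
        return np.zeros(self.dim)

    def _evaluate(self, point, need_hessian):
        q1 = point[0]
        qt = point[1:]
        v0, a = self.v0, self.a
        w2 = self.omegas**2
        u = qt + self.couplings * q1**2

        e = v0 * (q1**2 - a**2) ** 2 / a**4 + 0.5 * np.sum(w2 * u**2)

        g = np.empty(self.dim)
        g[0] = 4 * v0 * q1 * (q1**2 - a**2) / a**4 + np.sum(w2 * u * 2 * self.couplings * q1)
        g[1:] = w2 * u

        h = None
        if need_hessian:
            h = np.zeros((self.dim, self.dim))
            h[0, 0] = (4 * v0 * (3 * q1**2 - a**2) / a**4
                       + np.sum(w2 * ((2 * self.couplings * q1) ** 2
                                      + u * 2 * self.couplings)))
            h[0, 1:] = h[1:, 0] = w2 * 2 * self.couplings * q1
            h[1:, 1:] = np.diag(w2)
        return PotentialInfo(energy=e, gradient=g, hessian=h)


def model_double_well(v0: float, a: float, omegas=(), couplings=None) -> DoubleWellProvider:
    """Construct the quartic double-well model provider."""
    return DoubleWellProvider(v0, a, omegas, couplings)


def symmetry_expand(info: PotentialInfo, op: SymmetryOperation) -> PotentialInfo:
    """Potential information at the image point sigma(Q) of a known point.

    Under an orthogonal coordinate operation M the energy is invariant, the
    gradient maps as M g and the Hessian as M H M^T.
    """
    if info.hessian is None:
        raise ValueError("symmetry_expand requires a Hessian")
    m = op.matrix
    if m.shape[0] != info.hessian.shape[0]:
        raise ValueError("dimension mismatch between operation and Hessian")
    return PotentialInfo(
        energy=info.energy,
        gradient=None if info.gradient is None else m @ info.gradient,
        hessian=m @ info.hessian @ m.T,
    )


def finite_difference_hessian(provider: Provider, point, step: float = 1e-3) -> PotentialInfo:
    """Central-difference Hessian from energies, symmetrized.

    O(step^2) accurate; intended as an explicit opt-in fallback for
    energy-only providers, never a silent default (it costs O(D^2)
    evaluations).
    """
    point = np.asarray(point, float)
    d = point.size
    h = np.empty((d, d))
    e0 = provider.evaluate(point, need_hessian=False).energy

    def e_at(dq):
        return provider.evaluate(point + dq, need_hessian=False).energy

    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        h[i, i] = (e_at(ei) + e_at(-ei) - 2 * e0) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            hij = (e_at(ei + ej) - e_at(ei - ej)
                   - e_at(-ei + ej) + e_at(-ei - ej)) / (4 * step**2)
            h[i, j] = h[j, i] = hij
    return PotentialInfo(energy=e0, hessian=0.5 * (h + h.T))


# ---------------------------------------------------------------------------
# Tabulated potential store (HDF5 with JSON fallback, identical schema)


@dataclass
class _StoreRecord:
    coords: np.ndarray
    info: PotentialInfo


class PotentialStore:
    """Tabulated potential information keyed by caller-assigned point IDs.

    IDs are strings chosen deterministically by the basis builder; keying by
    ID rather than by coordinate hash keeps float round-trips out of the
    lookup path.  Serializes to HDF5 (one group per point) or JSON with the
    same schema, version tag ``sbg-pes-1``.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self._records: dict[str, _StoreRecord] = {}
        self.n_evaluations = 0  # provider-compatible counter (unused on read)

    def __contains__(self, point_id: str) -> bool:
        return point_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def ids(self):
        return list(self._records)

    def add(self, point_id: str, coords, info: PotentialInfo) -> None:
        coords = np.asarray(coords, float)
        if coords.size != self.dim:
            raise ValueError("coordinate dimension mismatch")
        self._records[str(point_id)] = _StoreRecord(coords.copy(), info)

    def coords(self, point_id: str) -> np.ndarray:
        return self._records[point_id].coords

    def get(self, point_id: str) -> PotentialInfo:
        return self._records[point_id].info

    def lookup_point(self, point: np.ndarray, tol: float = 1e-8) -> str | None:
        """ID of a stored record whose coordinates match ``point``, if any."""
        point = np.asarray(point, float)
        for pid, rec in self._records.items():
            if np.linalg.norm(rec.coords - point) < tol:
                return pid
        return None

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".json"):
            self._save_json(path)
        else:
            self._save_hdf5(path)

    @classmethod
    def load(cls, path) -> "PotentialStore":
        path = str(path)
        if path.endswith(".json"):
            return cls._load_json(path)
        return cls._load_hdf5(path)

    def _save_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema"] = SCHEMA_VERSION
            f.attrs["dim"] = self.dim
            grp = f.create_group("points")
            for pid, rec in self._records.items():
                g = grp.create_group(pid)
                g.create_dataset("coords", data=rec.coords)
                g.create_dataset("energy", data=rec.info.energy)
                if rec.info.gradient is not None:
                    g.create_dataset("gradient", data=rec.info.gradient)
                if rec.info.hessian is not None:
                    g.create_dataset("hessian", data=rec.info.hessian)

    @classmethod
    def _load_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs["schema"] != SCHEMA_VERSION:
                raise ValueError(f"unknown store schema {f.attrs['schema']!r}")
            store = cls(int(f.attrs["dim"]))
            for pid, g in f["points"].items():
                info = PotentialInfo(
                    energy=float(g["energy"][()]),
                    gradient=g["gradient"][:] if "gradient" in g else None,
                    hessian=g["hessian"][:] if "hessian" in g else None,
                )
                store.add(pid, g["coords"][:], info)
        return store

    def _save_json(self, path):
        out = {"schema": SCHEMA_VERSION, "dim": self.dim, "points": {}}
        for pid, rec in self._records.items():
            entry = {"coords": rec.coords.tolist(), "energy": rec.info.energy}
            if rec.info.gradient is not None:
                entry["gradient"] = rec.info.gradient.tolist()
            if rec.info.hessian is not None:
                entry["hessian"] = rec.info.hessian.tolist()
            out["points"][pid] = entry
        with open(path, "w") as fh:
            json.dump(out, fh)

    @classmethod
    def _load_json(cls, path):
        with open(path) as fh:
            data = json.load(fh)
        if data["schema"] != SCHEMA_VERSION:
            raise ValueError(f"unknown store schema {data['schema']!r}")
        store = cls(int(data["dim"]))
        for pid, entry in data["points"].items():
            info = PotentialInfo(
                energy=entry["energy"],
                gradient=np.array(entry["gradient"]) if "gradient" in entry else None,
                hessian=np.array(entry["hessian"]) if "hessian" in entry else None,
            )
            store.add(pid, np.array(entry["coords"]), info)
        return store


class StoreProvider(Provider):
    """Provider view over a :class:`PotentialStore`: exact-point lookup only."""

    def __init__(self, store: PotentialStore, tol: float = 1e-8):
        super().__init__(store.dim, frozenset({"energy", "hessian"}))
        self.store = store
        self.tol = tol

    def _evaluate(self, point, need_hessian):
        pid = self.store.lookup_point(point, self.tol)
        if pid is None:
            raise CapabilityError("point not present in tabulated store")
        return self.store.get(pid)
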