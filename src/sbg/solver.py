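"""Generalized eigenproblem for the Gaussian expansion and spectrum reports.

The expansion coefficients satisfy S^{-1} H_vib c_m = E_m c_m with a
non-orthogonal, often nearly linearly dependent overlap matrix S.  The
solver uses canonical orthogonalization: eigendecompose S, drop directions
whose eigenvalue falls below s_tol times the largest, solve the ordinary
symmetric eigenproblem in the retained subspace, and back-transform.  The
retained rank and the smallest kept overlap eigenvalue are reported so that
near-degenerate basis sets are visible rather than silent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import GaussianBasis
from .matrix_elements import HamiltonianMatrices, overlap
from .pes import SymmetryOperation
from .units import HARTREE_TO_CM

__all__ = [
    "SpectrumResult",
    "DegenerateBasisError",
    "solve",
    "spectrum_report",
    "evaluate_wavefunction",
]


class DegenerateBasisError(RuntimeError):
    """Every overlap eigenvalue fell below the canonical-orthogonalization cutoff."""


@dataclass
class SpectrumResult:
    """Eigenvalues/eigenvectors of the vibrational problem.

    ``energies`` ascending in hartree; ``coefficients`` has one column per
    state and is S-orthonormal.  ``levels_rel_cm1`` are energies relative to
    the ground state, in cm^-1.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    kept_rank: int
    s_condition: float

    @property
    def zpe(self) -> float:
        return float(self.energies[0])

    @property
    def zpe_cm1(self) -> float:
        return self.zpe * HARTREE_TO_CM

    @property
    def levels_rel_cm1(self) -> np.ndarray:
        return (self.energies - self.energies[0]) * HARTREE_TO_CM


def solve(h: HamiltonianMatrices, s_tol: float = 1e-4) -> SpectrumResult:
    """Canonical-orthogonalization solution of S^{-1} H_vib c = E c."""
    s = h.overlap
    evals, vecs = np.linalg.eigh(s)
    cutoff = s_tol * evals.max()
    keep = evals > cutoff
    if not np.any(keep):
        raise DegenerateBasisError(
            f"all overlap eigenvalues below cutoff {cutoff:.3e}")
    # transformation X with X^T S X = 1 on the retained subspace
    x = vecs[:, keep] / np.sqrt(evals[keep])
    h_ortho = x.T @ h.h_vib @ x
    h_ortho = 0.5 * (h_ortho + h_ortho.T)
    e, c_ortho = scipy.linalg.eigh(h_ortho)
    coeff = x @ c_ortho
    return SpectrumResult(
        energies=e,
        coefficients=coeff,
        kept_rank=int(keep.sum()),
        s_condition=float(evals[keep].min()),
    )


def parity_labels(res: SpectrumResult, bases: list[GaussianBasis],
                  symmetry: SymmetryOperation,
                  s: np.ndarray | None = None) -> list[str]:
    """Parity of each state under a reflection: sign of <chi|sigma|chi>.

    sigma chi is the expansion with permuted coefficients over the mirrored
    bases; its overlap with chi reduces to c^T P^T S c where P is the
    index permutation the operation induces on the basis set.
    """
    from .matrix_elements import _induced_permutation

    perm = _induced_permutation(bases, symmetry)
    if s is None:
        n = len(bases)
        s = np.array([[overlap(bases[i], bases[j]) for j in range(n)]
                      for i in range(n)])
    labels = []
    for m in range(res.coefficients.shape[1]):
        c = res.coefficients[:, m]
        c_mirror = np.empty_like(c)
        for i, j in enumerate(perm):
            c_mirror[j] = c[i]
        labels.append("+" if float(c_mirror @ s @ c) >= 0 else "-")
    return labels


def tunneling_splittings(levels_cm1: np.ndarray,
                         gap_ratio: float = 0.2) -> list[tuple[int, int, float]]:
    """Consecutive near-degenerate pairs labeled as tunneling doublets.

    Levels i, i+1 form a doublet when their gap is below ``gap_ratio`` times
    the gap to the following level.
    """
    out = []
    i = 0
    n = len(levels_cm1)
    while i + 1 < n:
        gap = levels_cm1[i + 1] - levels_cm1[i]
        nxt = levels_cm1[i + 2] - levels_cm1[i + 1] if i + 2 < n else np.inf
        if gap < gap_ratio * nxt:
            out.append((i, i + 1, float(gap)))
            i += 2
        else:
            i += 1
    return out


def spectrum_report(res: SpectrumResult,
                    reference_levels_cm1=None,
                    bases: list[GaussianBasis] | None = None,
                    symmetry: SymmetryOperation | None = None) -> dict:
    """Summary dict: ZPE, relative levels, doublets, optional parity and RMSE.

    ``reference_levels_cm1`` are compared against the lowest excited levels
    (relative to the ground state); the root-mean-square error over that set
    is reported in cm^-1.
    """
    levels = res.levels_rel_cm1
    report = {
        "zpe_hartree": res.zpe,
        "zpe_cm1": res.zpe_cm1,
        "levels_rel_cm1": levels.tolist(),
        "kept_rank": res.kept_rank,
        "s_condition": res.s_condition,
        "splittings_cm1": [
            {"lower": i, "upper": j, "splitting_cm1": v}
            for i, j, v in tunneling_splittings(levels)
        ],
    }
    if bases is not None and symmetry is not None:
        report["parity"] = parity_labels(res, bases, symmetry)
    if reference_levels_cm1 is not None and len(reference_levels_cm1) > 0:
        ref = np.asarray(reference_levels_cm1, float)
        calc = levels[1:1 + ref.size]
        if calc.size != ref.size:
            raise ValueError(
                f"{ref.size} reference levels but only {calc.size} computed")
        report["rmse_cm1"] = float(np.sqrt(np.mean((calc - ref) ** 2)))
    return report


def evaluate_wavefunction(bases: list[GaussianBasis], coeffs,
                          points) -> np.ndarray:
    """chi(Q) = sum_i c_i G_i(Q) at a list of mass-weighted points."""
    coeffs = np.asarray(coeffs, float)
    if coeffs.size != len(bases):
        raise ValueError("one coefficient per basis required")
    points = np.atleast_2d(np.asarray(points, float))
    vals = np.zeros(points.shape[0])
    for c, g in zip(coeffs, bases):
        d = points - g.center
        vals += c * np.exp(-np.einsum("pi,ij,pj->p", d, g.width, d) + g.log_norm)
    return vals


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def write_report_csv(report: dict, path) -> None:
    levels = report["levels_rel_cm1"]
    parity = report.get("parity", [""] * len(levels))
    zpe = report["zpe_hartree"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "E_hartree", "E_rel_cm1", "parity"])
        for i, lv in enumerate(levels):
            w.writerow([i, zpe + lv / HARTREE_TO_CM, lv, parity[i]])
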