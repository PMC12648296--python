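"""Frenkel exciton Hamiltonian with TrESP couplings.

The single-exciton Hamiltonian carries per-pigment site energies E_m on the
diagonal and interpigment couplings V_mn off-diagonal.  Couplings follow the
TrESP scheme: a screened Coulomb sum over atom-centred transition charges,

    V_mn = f * k_e * sum_{I in m, J in n} q_I q_J / |r_mI - r_nJ|

with k_e = 14.39964 eV*Å/e^2 and a constant environmental screening factor
f (default 0.69).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import DEFAULT_SCREENING, EV_TO_CM, KE_EV_ANG
from .structures import ComplexAssembly, PigmentGeometry, TransitionChargeSet, transition_dipole

MIN_INTERATOMIC_ANG = 0.1


@dataclass(frozen=True)
class ExcitonHamiltonian:
    """Symmetric N x N matrix in eV with ordered pigment labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if h.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(h, h.T, atol=1e-12):
            raise ValueError("Hamiltonian must be symmetric to 1e-12")
        if not (np.diag(h) > 0).all():
            raise ValueError("site energies (diagonal) must be positive")
        object.__setattr__(self, "matrix", h)

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.labels) + "\n")
            np.savetxt(fh, self.matrix, fmt="%.10f")

    @classmethod
    def from_text(cls, path: str | Path) -> "ExcitonHamiltonian":
        with open(path) as fh:
            labels = tuple(fh.readline().split())
            matrix = np.loadtxt(fh)
        return cls(labels, np.atleast_2d(matrix))


@dataclass(frozen=True)
class ExcitonStates:
    """Eigen-decomposition of an exciton Hamiltonian.

    ``eigenvalues`` ascend (eV); column k of ``eigenvectors`` is exciton k;
    row k of ``dipoles`` is the exciton transition dipole (e*Å)
    mu_k = sum_m c_mk mu_m.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dipoles: np.ndarray

    @property
    def dipole_strengths(self) -> np.ndarray:
        return np.einsum("ki,ki->k", self.dipoles, self.dipoles)


def tresp_coupling(
    geom_m: PigmentGeometry,
    q_m: TransitionChargeSet,
    geom_n: PigmentGeometry,
    q_n: TransitionChargeSet,
    screening_f: float = DEFAULT_SCREENING,
) -> float:
    """Screened TrESP excitonic coupling between two pigments, in eV."""
    if geom_m.pigment_id == geom_n.pigment_id:
        raise ValueError("coupling requires two distinct pigments")
    r = cdist(geom_m.coords, geom_n.coords)
    if (r < MIN_INTERATOMIC_ANG).any():
        raise ValueError(
            f"overlapping geometries: interatomic distance < {MIN_INTERATOMIC_ANG} Å "
            f"between {geom_m.pigment_id!r} and {geom_n.pigment_id!r}"
        )
    return float(screening_f * KE_EV_ANG * (q_m.charges @ (1.0 / r) @ q_n.charges))


def coupling_matrix(
    assembly: ComplexAssembly, screening_f: float = DEFAULT_SCREENING
) -> np.ndarray:
    """All pairwise TrESP couplings of an assembly (eV, zero diagonal)."""
    n = len(assembly)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = tresp_coupling(
                assembly.pigments[i], assembly.charge_sets[i],
                assembly.pigments[j], assembly.charge_sets[j], screening_f,
            )
    return v


def point_dipole_coupling(
    mu_m: np.ndarray, r_m: np.ndarray, mu_n: np.ndarray, r_n: np.ndarray,
    screening_f: float = DEFAULT_SCREENING,
) -> float:
    """Far-field point-dipole approximation to the coupling (eV).

    Used as an independent cross-check of the TrESP Coulomb sum at large
    centre separations.
    """
    rvec = np.asarray(r_n, float) - np.asarray(r_m, float)
    dist = np.linalg.norm(rvec)
    rhat = rvec / dist
    return float(
        screening_f * KE_EV_ANG
        * (mu_m @ mu_n - 3.0 * (mu_m @ rhat) * (mu_n @ rhat)) / dist**3
    )


def build_hamiltonian(
    site_energies: Mapping[str, float],
    couplings: Mapping[tuple[str, str], float] | np.ndarray | None = None,
    assembly: ComplexAssembly | None = None,
    screening_f: float = DEFAULT_SCREENING,
) -> ExcitonHamiltonian:
    """Assemble the Frenkel Hamiltonian from site energies and couplings.

    ``couplings`` may be a dict keyed by (label_i, label_j) (one-sided or
    symmetric; if both orders are present they must agree to 1e-9 eV), a full
    matrix in label order, or None — in which case an ``assembly`` with
    geometries and charge sets must be given and TrESP couplings are computed.
    """
    labels = tuple(site_energies.keys())
    n = len(labels)
    for lab in labels:
        if site_energies[lab] is None:
            raise ValueError(f"missing site energy for {lab!r}")

    h = np.zeros((n, n))
    np.fill_diagonal(h, [site_energies[lab] for lab in labels])

    if couplings is None:
        if assembly is None:
            raise ValueError("need either explicit couplings or an assembly")
        if assembly.labels != list(labels):
            raise ValueError("assembly order does not match site-energy labels")
        h += coupling_matrix(assembly, screening_f)
    elif isinstance(couplings, np.ndarray):
        v = np.asarray(couplings, float)
        if v.shape != (n, n):
            raise ValueError("coupling matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("asymmetric coupling matrix (disagreement > 1e-9 eV)")
        h += 0.5 * (v + v.T) - np.diag(np.diag(v))
    else:
        idx = {lab: i for i, lab in enumerate(labels)}
        for (a, b), val in couplings.items():
            if a not in idx or b not in idx:
                raise ValueError(f"coupling references unknown pigment {(a, b)}")
            i, j = idx[a], idx[b]
            if i == j:
                continue
            if (b, a) in couplings and abs(couplings[(b, a)] - val) > 1e-9:
                raise ValueError(f"asymmetric couplings for pair {(a, b)} differ > 1e-9 eV")
            h[i, j] = h[j, i] = val
    return ExcitonHamiltonian(labels, h)


def diagonalize(
    ham: ExcitonHamiltonian, site_dipoles: np.ndarray | Sequence[Sequence[float]]
) -> ExcitonStates:
    """Eigenvalues/vectors (ascending) and exciton transition dipoles."""
    mu = np.asarray(site_dipoles, float)
    if mu.shape != (ham.n_sites, 3):
        raise ValueError("site_dipoles must have shape (n_sites, 3)")
    evals, evecs = np.linalg.eigh(ham.matrix)
    return ExcitonStates(evals, evecs, evecs.T @ mu)


def site_dipoles(assembly: ComplexAssembly) -> np.ndarray:
    return np.array(
        [transition_dipole(p, q) for p, q in zip(assembly.pigments, assembly.charge_sets)]
    )


def export_couplings_csv(path: str | Path, ham: ExcitonHamiltonian) -> None:
    """Write off-diagonal couplings as (i, j, V_cm-1) rows."""
    import pandas as pd

    rows = [
        {"i": ham.labels[i], "j": ham.labels[j],
         "V_cm-1": ham.matrix[i, j] * EV_TO_CM}
        for i in range(ham.n_sites) for j in range(i + 1, ham.n_sites)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
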