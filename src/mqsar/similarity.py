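"""Molecular quantum similarity measures (MQSM) and indices.

The similarity between two molecules A and B is the operator-weighted
integral of their electron densities,

    Z_AB = <rho_A | Omega | rho_B>,

with Omega the Dirac delta (overlap similarity: the volume shared by the
two densities) or the Coulomb kernel 1/|r1 - r2| (electrostatic
self-energy-like similarity).  For promolecular Gaussian densities both
integrals have closed forms per shell pair:

  overlap:  N1 N2 (a1 a2 / (pi (a1 + a2)))^(3/2) exp(-mu R^2)
  coulomb:  N1 N2 erf(sqrt(mu) R) / R        (-> 2 N1 N2 sqrt(mu/pi) at R=0)

with mu = a1 a2 / (a1 + a2) and R the inter-center distance.

Derived indices: the Carbo (cosine-like) index Z_IJ / sqrt(Z_II Z_JJ) in
(0, 1]; the generalized distance [k (Z_II + Z_JJ)/2 - x Z_IJ]^(1/2), which
at k = x = 2 is the Euclidean distance between the densities; and the
infinite-order distance max(Z_II, Z_JJ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .density import DensityModel, build_density
from .structures import Molecule

__all__ = [
    "overlap_similarity",
    "coulomb_similarity",
    "carbo_index",
    "generalized_distance",
    "euclidean_distance",
    "infinite_order_distance",
    "SimilarityMatrix",
    "similarity_matrix",
]

_R_SWITCH = 1e-9  # A; below this the Coulomb R->0 limit is used


def _pair_arrays(a: DensityModel, b: DensityModel):
    ca = np.array([s.center for s in a.shells])
    cb = np.array([s.center for s in b.shells])
    aa = np.array([s.exponent for s in a.shells])
    ab = np.array([s.exponent for s in b.shells])
    na = np.array([s.electrons for s in a.shells])
    nb = np.array([s.electrons for s in b.shells])
    R = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    mu = aa[:, None] * ab[None, :] / (aa[:, None] + ab[None, :])
    NN = na[:, None] * nb[None, :]
    return R, mu, NN, aa, ab


def overlap_similarity(a: DensityModel, b: DensityModel) -> float:
    """Overlap MQSM  Z_AB = integral rho_A rho_B dr  (analytic)."""
    if not a.shells or not b.shells:
        raise ValueError("density models must be nonempty")
    R, mu, NN, aa, ab = _pair_arrays(a, b)
    s = aa[:, None] + ab[None, :]
    pref = (aa[:, None] * ab[None, :] / (np.pi * s)) ** 1.5
    return float(np.sum(NN * pref * np.exp(-mu * R**2)))


def coulomb_similarity(a: DensityModel, b: DensityModel) -> float:
    """Coulomb MQSM  Z_AB = integral rho_A(r1) rho_B(r2) / r12  (analytic)."""
    if not a.shells or not b.shells:
        raise ValueError("density models must be nonempty")
    R, mu, NN, _, _ = _pair_arrays(a, b)
    out = np.where(
        R < _R_SWITCH,
        2.0 * NN * np.sqrt(mu / np.pi),
        NN * erf(np.sqrt(mu) * np.maximum(R, _R_SWITCH)) / np.maximum(R, _R_SWITCH),
    )
    return float(np.sum(out))


def carbo_index(z_ii: float, z_jj: float, z_ij: float) -> float:
    """Cosine-like similarity Z_IJ / sqrt(Z_II Z_JJ); 1 iff identical."""
    if z_ii <= 0 or z_jj <= 0:
        raise ValueError("self-similarities must be positive")
    return z_ij / np.sqrt(z_ii * z_jj)


def generalized_distance(
    z_ii: float, z_jj: float, z_ij: float, k: float = 2.0, x: float = 2.0
) -> float:
    """Parameterized distance [k (Z_II + Z_JJ)/2 - x Z_IJ]^(1/2), x in [0, k]."""
    if not 0 <= x <= k:
        raise ValueError("require 0 <= x <= k")
    radicand = k * (z_ii + z_jj) / 2.0 - x * z_ij
    if radicand < -1e-12:
        raise ValueError("negative radicand in generalized distance")
    return float(np.sqrt(max(radicand, 0.0)))


def euclidean_distance(z_ii: float, z_jj: float, z_ij: float) -> float:
    """Euclidean distance between densities: k = x = 2 special case."""
    return generalized_distance(z_ii, z_jj, z_ij, k=2.0, x=2.0)


def infinite_order_distance(z_ii: float, z_jj: float) -> float:
    """Infinite-order distance index max(Z_II, Z_JJ)."""
    if z_ii <= 0 or z_jj <= 0:
        raise ValueError("self-similarities must be positive")
    return float(max(z_ii, z_jj))


_OPERATORS = {"overlap": overlap_similarity, "coulomb": coulomb_similarity}


@dataclass
class SimilarityMatrix:
    """Pairwise Z matrix with derived Carbo and Euclidean index matrices."""

    labels: list[str]
    Z: np.ndarray
    operator: str
    failed_pairs: list[tuple[str, str]]

    @property
    def carbo(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.Z))
        return self.Z / np.outer(d, d)

    @property
    def euclidean(self) -> np.ndarray:
        zd = np.diag(self.Z)
        sq = zd[:, None] + zd[None, :] - 2.0 * self.Z
        return np.sqrt(np.maximum(sq, 0.0))

    def _frame(self, M: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(M, index=self.labels, columns=self.labels)

    def to_csv(self, path, which: str = "Z", decimals: int = 4) -> None:
        """Lower-triangle CSV export (upper triangle blank), 4 decimals."""
        M = {"Z": self.Z, "carbo": self.carbo, "euclidean": self.euclidean}[which]
        n = len(self.labels)
        rows = []
        for i in range(n):
            row = {"": self.labels[i]}
            for j in range(n):
                row[self.labels[j]] = f"{M[i, j]:.{decimals}f}" if j <= i else ""
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def similarity_matrix(
    mols: list[Molecule],
    operator: str = "overlap",
    align: bool = False,
    parameters: dict | None = None,
    tol: float = 0.30,
) -> SimilarityMatrix:
    """Pairwise MQSM matrix over a molecule set.

    With ``align=True`` each pair (I, J), I != J, is rigidly superposed
    (TGSA) before the integral; a pair whose alignment fails is recorded in
    ``failed_pairs`` and its entry left NaN, never silently zeroed.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecules")
    if operator not in _OPERATORS:
        raise ValueError(f"unknown operator {operator!r}")
    zfun = _OPERATORS[operator]
    models = [build_density(m, parameters) for m in mols]
    n = len(mols)
    Z = np.full((n, n), np.nan)
    failed: list[tuple[str, str]] = []
    for i in range(n):
        Z[i, i] = zfun(models[i], models[i])
    if align:
        from .tgsa import AlignmentError, superpose

    for i in range(n):
        for j in range(i + 1, n):
            mi = models[i]
            if align:
                try:
                    ali = superpose(mols[i], mols[j], tol=tol)
                except AlignmentError:
                    failed.append((mols[i].name, mols[j].name))
                    continue
                moved = mols[i].transformed(ali.rotation, ali.translation)
                mi = build_density(moved, parameters)
            Z[i, j] = Z[j, i] = zfun(mi, models[j])
    return SimilarityMatrix([m.name for m in mols], Z, operator, failed)
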