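"""Promolecular Gaussian electron densities.

A molecule's first-order density is approximated as a superposition of
spherical atomic densities, one normalized s-Gaussian per atom carrying that
atom's electron count:

    rho(r) = sum_a  N_a (alpha_a / pi)^(3/2) exp(-alpha_a |r - c_a|^2)

Each shell integrates exactly to N_a electrons, so the promolecular density
conserves the molecular electron count by construction.  Default exponents
are derived from covalent radii as alpha = (c / r_cov)^2 with a single
calibration constant c (default 1.5); similarity *indices* downstream are
ratios of overlap integrals and are insensitive to this choice, which is
why a one-parameter scheme suffices.  Multi-shell per-element tables can be
supplied as JSON (element -> list of (exponent, electrons)) and drop in
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import Molecule, covalent_radius

__all__ = [
    "GaussianShell",
    "DensityModel",
    "default_exponents",
    "load_parameter_file",
    "build_density",
    "evaluate_density",
]

DEFAULT_EXPONENT_SCALE = 1.5  # dimensionless; alpha = (scale / r_cov)^2


@dataclass
class GaussianShell:
    """A normalized s-Gaussian: N_e electrons, exponent alpha (1/A^2)."""

    center: np.ndarray
    exponent: float
    electrons: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.electrons <= 0:
            raise ValueError("electron count must be positive")

    def value(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        r2 = np.sum((pts - self.center) ** 2, axis=-1)
        a = self.exponent
        return self.electrons * (a / np.pi) ** 1.5 * np.exp(-a * r2)


@dataclass
class DensityModel:
    shells: list[GaussianShell]
    molecule: Molecule | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.shells)

    def total_electrons(self) -> float:
        return float(sum(s.electrons for s in self.shells))


def default_exponents(elements, scale: float = DEFAULT_EXPONENT_SCALE) -> dict[str, float]:
    """Per-element Gaussian exponents alpha = (scale / r_cov)^2, 1/A^2."""
    out = {}
    for el in elements:
        r = covalent_radius(el)
        if r <= 0:
            raise ValueError(f"no covalent radius for element {el!r}")
        out[el] = (scale / r) ** 2
    return out


def load_parameter_file(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """JSON parameter file: element -> [[exponent, electrons], ...]."""
    data = json.loads(Path(path).read_text())
    return {el: [(float(a), float(n)) for a, n in shells] for el, shells in data.items()}


def build_density(
    mol: Molecule,
    parameters: dict | None = None,
    exponent_scale: float = DEFAULT_EXPONENT_SCALE,
) -> DensityModel:
    """Promolecular density: one shell per atom, N_e = atomic number.

    ``parameters`` may map element -> exponent (single shell per atom, the
    shell keeps the full electron count) or element -> list of
    (exponent, electrons) multi-shell expansions.
    """
    if parameters is None:
        parameters = default_exponents(set(mol.elements), scale=exponent_scale)
    shells: list[GaussianShell] = []
    for atom in mol.atoms:
        try:
            entry = parameters[atom.element]
        except KeyError:
            raise KeyError(f"no density parameters for element {atom.element!r}") from None
        if isinstance(entry, (int, float)):
            shells.append(GaussianShell(atom.coords, float(entry), float(atom.atomic_number)))
        else:
            for alpha, n_e in entry:
                shells.append(GaussianShell(atom.coords, alpha, n_e))
    return DensityModel(shells, molecule=mol)


def evaluate_density(model: DensityModel, points: np.ndarray) -> np.ndarray | float:
    """Evaluate rho at one point (3-vector) or many (n, 3); never negative."""
    pts = np.asarray(points, float)
    scalar = pts.ndim == 1
    total = np.zeros(1 if scalar else len(pts))
    for shell in model.shells:
        total = total + shell.value(pts)
    return float(total[0]) if scalar else total
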