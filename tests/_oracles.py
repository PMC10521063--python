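"""Independent numerical oracles used by the tests.

These deliberately avoid the analytic shell-pair formulas of
``mqsar.similarity``: integrals are evaluated on a dense Cartesian grid by
the trapezoidal rule (which converges superalgebraically for Gaussian
integrands), and the Coulomb kernel enters through the electrostatic
potential of a single normalized Gaussian charge cloud.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

from mqsar.density import DensityModel


def _axes(models: list[DensityModel], spacing: float, pad_sigmas: float):
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for m in models:
        for s in m.shells:
            pad = pad_sigmas / math.sqrt(s.exponent)
            lo = np.minimum(lo, s.center - pad)
            hi = np.maximum(hi, s.center + pad)
    return [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]


def _rho_on_slab(model: DensityModel, x: float, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    out = np.zeros(Y.shape)
    for s in model.shells:
        dx2 = (x - s.center[0]) ** 2
        r2 = dx2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2
        out += s.electrons * (s.exponent / np.pi) ** 1.5 * np.exp(-s.exponent * r2)
    return out


def _potential_on_slab(model: DensityModel, x: float, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Electrostatic potential of the model's Gaussian charge clouds."""
    out = np.zeros(Y.shape)
    for s in model.shells:
        r = np.sqrt((x - s.center[0]) ** 2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2)
        a = s.exponent
        small = r < 1e-10
        rsafe = np.where(small, 1.0, r)
        v = erf(np.sqrt(a) * rsafe) / rsafe
        v = np.where(small, 2.0 * np.sqrt(a / np.pi), v)
        out += s.electrons * v
    return out


def quadrature_overlap(
    a: DensityModel, b: DensityModel, spacing: float = 0.22, pad_sigmas: float = 8.0
) -> float:
    """Trapezoidal integral of rho_A * rho_B over an enclosing box."""
    xs, ys, zs = _axes([a, b], spacing, pad_sigmas)
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    plane_vals = []
    for x in xs:
        f = _rho_on_slab(a, x, Y, Z) * _rho_on_slab(b, x, Y, Z)
        plane_vals.append(np.trapezoid(np.trapezoid(f, zs, axis=1), ys, axis=0))
    return float(np.trapezoid(np.array(plane_vals), xs))


def quadrature_coulomb(
    a: DensityModel, b: DensityModel, spacing: float = 0.22, pad_sigmas: float = 8.0
) -> float:
    """Trapezoidal integral of rho_A(r) * V_B(r) over an enclosing box."""
    xs, ys, zs = _axes([a, b], spacing, pad_sigmas)
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    plane_vals = []
    for x in xs:
        f = _rho_on_slab(a, x, Y, Z) * _potential_on_slab(b, x, Y, Z)
        plane_vals.append(np.trapezoid(np.trapezoid(f, zs, axis=1), ys, axis=0))
    return float(np.trapezoid(np.array(plane_vals), xs))


def random_density_model(rng: np.random.Generator, n_shells: int | None = None) -> DensityModel:
    """Small random shell model: 2-6 shells, exponents in [0.5, 3] 1/A^2."""
    from mqsar.density import GaussianShell

    if n_shells is None:
        n_shells = int(rng.integers(2, 7))
    shells = [
        GaussianShell(
            center=rng.uniform(-1.5, 1.5, size=3),
            exponent=float(rng.uniform(0.5, 3.0)),
            electrons=float(rng.uniform(1.0, 8.0)),
        )
        for _ in range(n_shells)
    ]
    return DensityModel(shells)
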