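"""CoMFA-style 3D-QSAR: grid fields + PLS regression.

Steric and electrostatic interaction fields are evaluated at the nodes of a
regular lattice enclosing a set of *pre-aligned* ligands, using a probe atom
(sp3 carbon, +1.0 e by default):

    steric(p)        = sum_i 4 eps [ (sigma_i / r_ip)^12 - (sigma_i / r_ip)^6 ]
    electrostatic(p) = sum_i 332.0636 q_i q_probe / (eps(r) r_ip),  eps(r) = r

with sigma_i the probe-atom contact distance from van der Waals radii and
both fields capped at +/-30 kcal/mol, the usual convention that keeps lattice
nodes inside an atom from dominating the regression.

The capped field columns are regressed against pIC50 by partial least
squares (PLS).  Reported statistics follow QSAR practice: training R^2,
leave-one-out cross-validated q^2 = 1 - PRESS / SS_total (q^2 <= 1, may be
negative), and the steric/electrostatic percentage contributions
(sum of |coefficient x column std| per field block, normalized to 100).
Contribution contours partition grid points at the 80th/20th percentiles of
the signed coefficient x std product into favorable/unfavorable sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .structures import Molecule, vdw_radius

__all__ = [
    "FieldGrid",
    "FieldMatrix",
    "QSARModel",
    "compute_fields",
    "fit_pls",
    "loo_q2",
    "contribution_contours",
    "COULOMB_KCAL",
]

COULOMB_KCAL = 332.0636  # kcal*A/(mol*e^2)
FIELD_CAP = 30.0  # kcal/mol
DEFAULT_SPACING = 2.0  # A
DEFAULT_MARGIN = 4.0  # A beyond the ligand bounding box
MIN_COLUMN_STD = 0.05  # near-constant columns dropped before PLS
LJ_EPSILON = 0.1  # kcal/mol, probe-atom well depth
_R_FLOOR = 1e-6  # A, guards 1/r at coincident points (cap applies anyway)


@dataclass
class FieldGrid:
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    probe_element: str = "C"
    probe_charge: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) node coordinates in x-fastest-last (C) order."""
        axes = [self.origin[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.shape) - 1)

    def encloses(self, mol: Molecule) -> bool:
        c = mol.coords
        return bool(np.all(c >= self.origin - self.spacing) and np.all(c <= self.upper + self.spacing))

    @classmethod
    def around(
        cls,
        mols: list[Molecule],
        spacing: float = DEFAULT_SPACING,
        margin: float = DEFAULT_MARGIN,
        **probe,
    ) -> "FieldGrid":
        if not mols:
            raise ValueError("need at least one molecule")
        coords = np.vstack([m.coords for m in mols])
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
        return cls(lo, spacing, shape, **probe)


@dataclass
class FieldMatrix:
    """Rows = ligands, columns = (grid point, field type); values kcal/mol."""

    ligands: list[str]
    X: np.ndarray = field(repr=False)
    field_types: np.ndarray = field(repr=False)  # per column: "steric"|"electrostatic"
    point_index: np.ndarray = field(repr=False)  # per column: grid node index
    grid: FieldGrid | None = None

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def block(self, field_type: str) -> np.ndarray:
        return self.X[:, self.field_types == field_type]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t}_{p}" for t, p in zip(self.field_types, self.point_index)]
        return pd.DataFrame(self.X, index=self.ligands, columns=cols)


def _steric_field(mol: Molecule, pts: np.ndarray, probe_radius: float, cap: float) -> np.ndarray:
    coords = mol.coords
    sigma = np.array([vdw_radius(a.element) for a in mol.atoms]) / 2.0 + probe_radius / 2.0
    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    r = np.maximum(r, _R_FLOOR)
    sr6 = (sigma[None, :] / r) ** 6
    e = np.sum(4.0 * LJ_EPSILON * (sr6**2 - sr6), axis=1)
    return np.clip(e, -cap, cap)


def _electrostatic_field(mol: Molecule, pts: np.ndarray, probe_charge: float, cap: float) -> np.ndarray:
    coords = mol.coords
    q = mol.charges
    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    r = np.maximum(r, _R_FLOOR)
    # distance-dependent dielectric eps = r  =>  E = k q1 q2 / r^2
    e = np.sum(COULOMB_KCAL * q[None, :] * probe_charge / r**2, axis=1)
    return np.clip(e, -cap, cap)


def compute_fields(
    mols: list[Molecule],
    grid: FieldGrid | None = None,
    cap: float = FIELD_CAP,
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> FieldMatrix:
    """Steric + electrostatic probe fields for aligned ligands.

    All molecules must share one reference frame (align upstream) and lie
    inside the grid; partial charges feed the electrostatic block.
    """
    if not mols:
        raise ValueError("need at least one molecule")
    if grid is None:
        grid = FieldGrid.around(mols, spacing=spacing, margin=margin)
    for m in mols:
        if not grid.encloses(m):
            raise ValueError(f"grid does not enclose molecule {m.name!r}")
    pts = grid.points()
    probe_radius = vdw_radius(grid.probe_element)
    rows = []
    for m in mols:
        st = _steric_field(m, pts, probe_radius, cap)
        el = _electrostatic_field(m, pts, grid.probe_charge, cap)
        rows.append(np.concatenate([st, el]))
    X = np.array(rows)
    n = grid.n_points
    field_types = np.array(["steric"] * n + ["electrostatic"] * n)
    point_index = np.concatenate([np.arange(n), np.arange(n)])
    return FieldMatrix([m.name for m in mols], X, field_types, point_index, grid)


@dataclass
class QSARModel:
    n_components: int
    coef: np.ndarray = field(repr=False)  # on retained, centered columns
    kept: np.ndarray = field(repr=False)  # boolean mask over input columns
    x_mean: np.ndarray = field(repr=False)
    block_scale: dict = field(repr=False)
    y_mean: float = 0.0
    r2: float = float("nan")
    q2: float | None = None
    contributions: dict | None = None
    field_types: np.ndarray | None = field(default=None, repr=False)
    point_index: np.ndarray | None = field(default=None, repr=False)
    x_std: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xk = np.asarray(X, float)[:, self.kept]
        scale = np.array([self.block_scale[t] for t in self.field_types[self.kept]])
        Xc = Xk / scale - self.x_mean
        return Xc @ self.coef + self.y_mean


def _prepare(X: np.ndarray, field_types: np.ndarray, block_scale: bool):
    std = X.std(axis=0)
    kept = std >= MIN_COLUMN_STD
    if kept.sum() == 0:
        raise ValueError("all field columns near-constant; nothing to fit")
    scales = {}
    for t in np.unique(field_types):
        blk = kept & (field_types == t)
        if block_scale and blk.any():
            # equalize total variance across field blocks (CoMFA block scaling)
            scales[t] = float(np.sqrt(np.sum(std[blk] ** 2)))
        else:
            scales[t] = 1.0
        if scales[t] == 0:
            scales[t] = 1.0
    scale_vec = np.array([scales[t] for t in field_types[kept]])
    Xk = X[:, kept] / scale_vec
    return Xk, kept, scales


def fit_pls(
    fields: FieldMatrix | np.ndarray,
    y: np.ndarray,
    n_components: int,
    block_scale: bool = True,
    field_types: np.ndarray | None = None,
    compute_q2: bool = False,
) -> QSARModel:
    """Centered (optionally block-scaled) PLS of activities on field columns."""
    if isinstance(fields, FieldMatrix):
        X, field_types = fields.X, fields.field_types
        point_index = fields.point_index
    else:
        X = np.asarray(fields, float)
        if field_types is None:
            field_types = np.array(["steric"] * X.shape[1])
        point_index = np.arange(X.shape[1])
    y = np.asarray(y, float)
    if len(y) != X.shape[0]:
        raise ValueError("activity vector length must equal the number of ligands")
    if np.std(y) == 0:
        raise ValueError("constant activities cannot be fitted")
    Xk, kept, scales = _prepare(X, field_types, block_scale)
    max_comp = min(X.shape[0] - 1, Xk.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xk, y)
    coef = pls.coef_.ravel()
    yhat = pls.predict(Xk).ravel()
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    # field-type contribution split: sum |coef * std| per block -> percent
    std_k = Xk.std(axis=0)
    weight = np.abs(coef) * std_k
    contrib = {}
    for t in np.unique(field_types):
        contrib[t] = float(np.sum(weight[field_types[kept] == t]))
    total = sum(contrib.values()) or 1.0
    contrib = {t: 100.0 * v / total for t, v in contrib.items()}
    model = QSARModel(
        n_components=n_components,
        coef=coef,
        kept=kept,
        x_mean=Xk.mean(axis=0),
        block_scale=scales,
        y_mean=float(y.mean()),
        r2=r2,
        contributions=contrib,
        field_types=field_types,
        point_index=point_index,
        x_std=std_k,
    )
    if compute_q2:
        model.q2 = loo_q2(X, y, n_components, block_scale=block_scale, field_types=field_types)
    return model


def loo_q2(
    fields: FieldMatrix | np.ndarray,
    y: np.ndarray,
    n_components: int,
    block_scale: bool = True,
    field_types: np.ndarray | None = None,
) -> float:
    """Leave-one-out q^2 = 1 - PRESS / SS_total with full per-fold refits."""
    if isinstance(fields, FieldMatrix):
        X, field_types = fields.X, fields.field_types
    else:
        X = np.asarray(fields, float)
        if field_types is None:
            field_types = np.array(["steric"] * X.shape[1])
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xk, kept, scales = _prepare(X[mask], field_types, block_scale)
        ncomp = min(n_components, Xk.shape[0] - 1, Xk.shape[1])
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(Xk, y[mask])
        scale_vec = np.array([scales[t] for t in field_types[kept]])
        xi = X[i, kept] / scale_vec
        pred = float(pls.predict(xi[None, :]).ravel()[0])
        press += (y[i] - pred) ** 2
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def contribution_contours(
    model: QSARModel, grid: FieldGrid | None = None, levels: tuple[float, float] = (80.0, 20.0)
) -> dict:
    """Favorable/unfavorable grid-point sets per field type.

    Per field type, the signed products coefficient x column std are
    partitioned at the upper/lower percentile ``levels``; points at or
    above the upper level form the favorable set, points at or below the
    lower level the unfavorable set.  Coordinates are attached when a grid
    is supplied.
    """
    if model.field_types is None or model.x_std is None:
        raise ValueError("model was not fitted on a FieldMatrix")
    hi, lo = levels
    pts = grid.points() if grid is not None else None
    out = {}
    ft_kept = model.field_types[model.kept]
    pi_kept = model.point_index[model.kept]
    contrib = model.coef * model.x_std
    for t in np.unique(ft_kept):
        sel = ft_kept == t
        vals = contrib[sel]
        idx = pi_kept[sel]
        upper = np.percentile(vals, hi)
        lower = np.percentile(vals, lo)
        fav = idx[vals >= upper]
        unfav = idx[vals <= lower]
        entry = {"favorable": list(map(int, fav)), "unfavorable": list(map(int, unfav))}
        if pts is not None:
            entry["favorable_points"] = pts[fav]
            entry["unfavorable_points"] = pts[unfav]
        out[t] = entry
    return out
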