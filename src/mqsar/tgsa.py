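"""Topo-geometrical superposition (TGSA-style rigid alignment).

Pairs of molecules are aligned on their common heavy-atom substructure using
only topology (bonds, element types) and geometry (interatomic distances):

1. *Duos*: bonded heavy-atom pairs, the elementary comparison unit.
2. *Triads*: each duo extended by a bonded third heavy atom, giving a
   triangle whose sides are interatomic distances.
3. Triads of the two molecules whose element triples agree and whose
   corresponding sides differ by at most ``tol`` are candidate seeds.
4. Each seed triad pair is superposed by least squares (Kabsch); the match
   is greedily extended to all heavy atoms (nearest same-element atom
   within ``tol``), refit, and the seed that maximizes the number of
   superposed atoms (then minimizes RMSD, then smallest atom-id triple)
   wins.  Molecules are treated as rigid bodies; input coordinates are
   never mutated.

The alignment quality score C_IJ uses a Gaussian-kernel cross-correlation
of the superposed heavy-atom point sets,

    C_IJ = d_IJ / sqrt(d_II d_JJ),   d_XY = sum_i sum_j exp(-|x_i - y_j|^2),

which lies in [0, 1] by Cauchy-Schwarz and equals 1 exactly at structural
identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structures import Molecule

__all__ = [
    "Duo",
    "Triad",
    "Alignment",
    "AlignmentError",
    "enumerate_duos",
    "enumerate_triads",
    "match_triads",
    "superpose",
    "alignment_cost",
]

DEFAULT_TOL = 0.30  # A, distance-compatibility tolerance


class AlignmentError(RuntimeError):
    """No common substructure could be superposed."""


@dataclass(frozen=True)
class Duo:
    atom_ids: tuple[int, int]
    elements: tuple[str, str]  # sorted for canonical comparison
    distance: float


@dataclass(frozen=True)
class Triad:
    atom_ids: tuple[int, int, int]
    elements: tuple[str, str, str]
    sides: tuple[float, float, float]  # d(0,1), d(0,2), d(1,2)


@dataclass
class Alignment:
    rotation: np.ndarray
    translation: np.ndarray
    matched_pairs: list[tuple[int, int]]
    rmsd: float
    cost: float


def _heavy_ids(mol: Molecule) -> list[int]:
    return [a.atom_id for a in mol.atoms if not a.is_hydrogen]


def _dist(mol: Molecule, i: int, j: int) -> float:
    return float(np.linalg.norm(mol.atom_by_id(i).coords - mol.atom_by_id(j).coords))


def enumerate_duos(mol: Molecule) -> list[Duo]:
    """One duo per heavy-atom bond; hydrogens are excluded throughout."""
    heavy = set(_heavy_ids(mol))
    duos = []
    for i, j in mol.bonds:
        if i in heavy and j in heavy:
            ei, ej = mol.atom_by_id(i).element, mol.atom_by_id(j).element
            duos.append(Duo((i, j), tuple(sorted((ei, ej))), _dist(mol, i, j)))
    return duos


def enumerate_triads(mol: Molecule) -> list[Triad]:
    """Triads as bonded extensions of duos (caps the combinatorics)."""
    heavy = set(_heavy_ids(mol))
    neighbors: dict[int, set[int]] = {}
    for i, j in mol.bonds:
        if i in heavy and j in heavy:
            neighbors.setdefault(i, set()).add(j)
            neighbors.setdefault(j, set()).add(i)
    seen = set()
    triads = []
    for duo in enumerate_duos(mol):
        i, j = duo.atom_ids
        for k in sorted(neighbors.get(i, set()) | neighbors.get(j, set())):
            if k in (i, j):
                continue
            key = tuple(sorted((i, j, k)))
            if key in seen:
                continue
            seen.add(key)
            a, b, c = key
            triads.append(
                Triad(
                    key,
                    tuple(mol.atom_by_id(x).element for x in key),
                    (_dist(mol, a, b), _dist(mol, a, c), _dist(mol, b, c)),
                )
            )
    triads.sort(key=lambda t: t.atom_ids)
    return triads


def _side(mol: Molecule, ids: tuple[int, int, int]) -> np.ndarray:
    a, b, c = ids
    return np.array([_dist(mol, a, b), _dist(mol, a, c), _dist(mol, b, c)])


def match_triads(
    mol_a: Molecule, mol_b: Molecule, tol: float = DEFAULT_TOL
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Distance-compatible triad pairs.

    Returns ``(ids_A, ids_B)`` tuples where ``ids_B`` is permuted into
    correspondence with ``ids_A`` (same element at each position, all three
    corresponding sides within ``tol``).  Order is deterministic.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tb_by_elems: dict[tuple[str, ...], list[Triad]] = {}
    for tb in enumerate_triads(mol_b):
        tb_by_elems.setdefault(tuple(sorted(tb.elements)), []).append(tb)
    matches = []
    for ta in enumerate_triads(mol_a):
        sa = np.array(ta.sides)
        for tb in tb_by_elems.get(tuple(sorted(ta.elements)), []):
            for perm in itertools.permutations(range(3)):
                ids_b = tuple(tb.atom_ids[p] for p in perm)
                if any(
                    mol_a.atom_by_id(ta.atom_ids[k]).element
                    != mol_b.atom_by_id(ids_b[k]).element
                    for k in range(3)
                ):
                    continue
                if np.all(np.abs(sa - _side(mol_b, ids_b)) <= tol):
                    matches.append((ta.atom_ids, ids_b))
                    break  # one correspondence per (ta, tb) pair suffices
    matches.sort()
    return matches


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform with R P_i + t ~= Q_i, det(R) = +1."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _extend_match(
    mol_a: Molecule, mol_b: Molecule, R: np.ndarray, t: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one map: A heavy atom -> nearest same-element B atom."""
    used_b: set[int] = set()
    pairs = []
    b_heavy = [mol_b.atom_by_id(i) for i in _heavy_ids(mol_b)]
    for ia in _heavy_ids(mol_a):
        aa = mol_a.atom_by_id(ia)
        moved = R @ aa.coords + t
        best, best_d = None, tol
        for ab in b_heavy:
            if ab.atom_id in used_b or ab.element != aa.element:
                continue
            d = float(np.linalg.norm(moved - ab.coords))
            if d <= best_d:
                best, best_d = ab.atom_id, d
        if best is not None:
            used_b.add(best)
            pairs.append((ia, best))
    return pairs


def alignment_cost(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Gaussian-kernel superposition score in [0, 1] (1 = identity)."""
    A = np.atleast_2d(coords_a)
    B = np.atleast_2d(coords_b)

    def d_xy(X, Y):
        r2 = np.sum((X[:, None, :] - Y[None, :, :]) ** 2, axis=-1)
        return float(np.sum(np.exp(-r2)))

    return d_xy(A, B) / np.sqrt(d_xy(A, A) * d_xy(B, B))


def superpose(mol_a: Molecule, mol_b: Molecule, tol: float = DEFAULT_TOL) -> Alignment:
    """Rigid alignment of A onto B via the best matched triad seed."""
    matches = match_triads(mol_a, mol_b, tol=tol)
    if not matches:
        raise AlignmentError(
            f"no distance-compatible triads between {mol_a.name!r} and {mol_b.name!r}"
        )
    best = None  # (-n_matched, rmsd, triad_ids, R, t, pairs)
    for ids_a, ids_b in matches:
        P = np.array([mol_a.atom_by_id(i).coords for i in ids_a])
        Q = np.array([mol_b.atom_by_id(i).coords for i in ids_b])
        R, t = _kabsch(P, Q)
        # extend, refit on all matched pairs, extend once more, final refit
        pairs = _extend_match(mol_a, mol_b, R, t, tol)
        for _ in range(2):
            if len(pairs) >= 3:
                P2 = np.array([mol_a.atom_by_id(i).coords for i, _ in pairs])
                Q2 = np.array([mol_b.atom_by_id(j).coords for _, j in pairs])
                R, t = _kabsch(P2, Q2)
            pairs = _extend_match(mol_a, mol_b, R, t, tol)
        if not pairs:
            continue
        P2 = np.array([mol_a.atom_by_id(i).coords for i, _ in pairs])
        Q2 = np.array([mol_b.atom_by_id(j).coords for _, j in pairs])
        rmsd = float(np.sqrt(np.mean(np.sum((P2 @ R.T + t - Q2) ** 2, axis=-1))))
        key = (-len(pairs), rmsd, ids_a)
        if best is None or key < best[0]:
            best = (key, R, t, pairs, rmsd)
    if best is None:
        raise AlignmentError(
            f"triad seeds found but no atoms matched between {mol_a.name!r} and {mol_b.name!r}"
        )
    _, R, t, pairs, rmsd = best
    heavy_a = np.array([mol_a.atom_by_id(i).coords for i in _heavy_ids(mol_a)])
    heavy_b = np.array([mol_b.atom_by_id(i).coords for i in _heavy_ids(mol_b)])
    cost = alignment_cost(heavy_a @ R.T + t, heavy_b)
    return Alignment(R, t, pairs, rmsd, cost)
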