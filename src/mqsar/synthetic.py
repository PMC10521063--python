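"""Synthetic inputs with known ground truth.

Every generator here is a pure function of (seed, parameters) and emulates
one input class of the analysis:

* **Ligand series** -- a shared rigid macrocycle-like ring scaffold with two
  designated substitution sites, mimicking an ansamycin series whose members
  differ only at two ring positions.  Substituents come from a small library
  of common groups (hydroxy, methoxy, amino, ...) with template geometry and
  partial charges.
* **Pocket** -- pseudo-residues (small polar triatomics) placed on a shell
  around the ligand.  All energies derive from one additive toy Hamiltonian
  (Lennard-Jones 6-12 plus Coulomb over atom pairs), so the supermolecular
  tables E_AM, E_L, E_M are mutually consistent and the true per-residue
  interaction terms are known exactly.
* **Activities** -- pIC50 values planted as a linear function of grid-field
  columns plus Gaussian noise, affinely rescaled into the experimentally
  observed span [5.57, 8.04]; the pre-scaling linear truth is retained for
  parameter-recovery tests.
* **Descriptor tables** -- frontier-orbital energies with gaps in the 4-7 eV
  window typical of closed-shell organics, and atomic populations that
  conserve exactly one electron between the N-1/N/N+1 states.

The defaults (40 ligands, 10 pocket residues, noise sigma 0.1 log units)
are the series size and noise scale the analysis is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comfa import COULOMB_KCAL, FieldMatrix, compute_fields
from .structures import Atom, EnergyTable, Molecule, ResidueSet

__all__ = [
    "SUBSTITUENT_LIBRARY",
    "SyntheticScenario",
    "gen_scaffold",
    "gen_ligand_series",
    "gen_pocket",
    "pocket_energy_tables",
    "toy_pair_energy",
    "toy_intra_energy",
    "gen_activities",
    "gen_descriptor_tables",
    "gen_scenario",
]

# toy Hamiltonian defaults: simple, additive, differentiable
LJ_EPS = 0.1  # kcal/mol
LJ_SIGMA = 3.4  # A
PIC50_RANGE = (5.57, 8.04)  # observed activity span of the modelled series
RING_SIZE = 12
BOND_LENGTH = 1.5  # A, ring C-C
SITE_A, SITE_B = 2, 8  # ring positions carrying the variable substituents

# substituent templates: list of (element, local offset, partial charge);
# local +x is the outward radial direction at the attachment site
SUBSTITUENT_LIBRARY: dict[str, list[tuple[str, tuple[float, float, float], float]]] = {
    "H": [("H", (1.0, 0.0, 0.0), 0.05)],
    "F": [("F", (1.35, 0.0, 0.0), -0.20)],
    "OH": [("O", (1.4, 0.0, 0.0), -0.40), ("H", (2.0, 0.75, 0.0), 0.30)],
    "NH2": [("N", (1.45, 0.0, 0.0), -0.50), ("H", (2.05, 0.7, 0.0), 0.25),
            ("H", (2.05, -0.7, 0.0), 0.25)],
    "OMe": [("O", (1.4, 0.0, 0.0), -0.35), ("C", (2.2, 1.0, 0.0), 0.05),
            ("H", (3.0, 0.8, 0.6), 0.05)],
    "keto": [("O", (1.25, 0.0, 0.0), -0.45)],
    "Me": [("C", (1.5, 0.0, 0.0), -0.10), ("H", (2.1, 0.8, 0.3), 0.05)],
    "OAc": [("O", (1.4, 0.0, 0.0), -0.30), ("C", (2.3, 0.9, 0.0), 0.30),
            ("O", (2.6, 2.0, 0.2), -0.40), ("C", (3.3, 0.1, -0.4), -0.05)],
}


def gen_scaffold(name: str = "scaffold") -> Molecule:
    """Rigid planar ring of RING_SIZE carbons with small alternating charges.

    The ring geometry is fixed (no seed): every series member shares these
    scaffold coordinates exactly, as a rigid macrocycle would.
    """
    r = BOND_LENGTH / (2.0 * np.sin(np.pi / RING_SIZE))
    atoms = []
    for k in range(RING_SIZE):
        th = 2.0 * np.pi * k / RING_SIZE
        atoms.append(
            Atom("C", np.array([r * np.cos(th), r * np.sin(th), 0.0]),
                 partial_charge=0.05 if k % 2 else -0.05, atom_id=k)
        )
    bonds = [(k, (k + 1) % RING_SIZE) for k in range(RING_SIZE)]
    return Molecule(name, atoms, bonds)


def _attach(mol_atoms, mol_bonds, site_id: int, group: list, next_id: int):
    """Place a substituent template at a ring site, oriented radially."""
    site = mol_atoms[site_id]
    radial = site.coords / np.linalg.norm(site.coords)
    # local frame: +x radial, +y tangential (in plane), +z out of plane
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.cross(ez, radial)
    R = np.stack([radial, ey, ez], axis=1)
    prev = site_id
    for element, offset, charge in group:
        coords = site.coords + R @ np.asarray(offset, float)
        mol_atoms.append(Atom(element, coords, partial_charge=charge, atom_id=next_id))
        mol_bonds.append((prev, next_id))
        prev = next_id
        next_id += 1
    return next_id


def gen_ligand_series(
    seed: int,
    n: int,
    substituent_library: dict | None = None,
) -> list[tuple[Molecule, tuple[str, str]]]:
    """``n`` ligands sharing one rigid scaffold, varied at two sites.

    Returns (molecule, (substituent at site A, substituent at site B))
    pairs; substituent choices are drawn per ligand from the library,
    deterministically per seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    lib = substituent_library if substituent_library is not None else SUBSTITUENT_LIBRARY
    if not lib:
        raise ValueError("substituent library is empty")
    rng = np.random.default_rng(seed)
    names = sorted(lib)
    out = []
    for i in range(n):
        sub_a, sub_b = rng.choice(names, size=2)
        scaffold = gen_scaffold()
        atoms = list(scaffold.atoms)
        bonds = list(scaffold.bonds)
        nid = len(atoms)
        nid = _attach(atoms, bonds, SITE_A, lib[sub_a], nid)
        _attach(atoms, bonds, SITE_B, lib[sub_b], nid)
        out.append((Molecule(f"lig{i:03d}", atoms, bonds), (str(sub_a), str(sub_b))))
    return out


# ---------------------------------------------------------------------------
# pocket + toy Hamiltonian
# ---------------------------------------------------------------------------

def _pair_sum(coords_a, q_a, coords_b, q_b) -> float:
    r = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    r = np.maximum(r, 1e-9)
    sr6 = (LJ_SIGMA / r) ** 6
    lj = 4.0 * LJ_EPS * (sr6**2 - sr6)
    coul = COULOMB_KCAL * q_a[:, None] * q_b[None, :] / r
    return float(np.sum(lj + coul))


def toy_pair_energy(mol_a: Molecule, mol_b: Molecule) -> float:
    """Intermolecular energy: LJ + Coulomb over all atom pairs, kcal/mol."""
    return _pair_sum(mol_a.coords, mol_a.charges, mol_b.coords, mol_b.charges)


def toy_intra_energy(mol: Molecule) -> float:
    """Intramolecular energy: the same pair terms over non-bonded atom pairs.

    Bonded (1-2) pairs are excluded -- their separations are far inside the
    Lennard-Jones wall and contribute nothing but a huge constant that
    would dominate the supermolecular differences numerically.
    """
    c, q = mol.coords, mol.charges
    pos = {a.atom_id: k for k, a in enumerate(mol.atoms)}
    bonded = {(min(pos[i], pos[j]), max(pos[i], pos[j])) for i, j in mol.bonds}
    n = len(mol)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            total += _pair_sum(c[i : i + 1], q[i : i + 1], c[j : j + 1], q[j : j + 1])
    return total


_RESIDUE_NAMES = ["Lys", "Asp", "Ser", "Thr", "Gly", "Asn", "Met", "Ile", "Phe", "Glu"]


def gen_pocket(
    seed: int, n_residues: int, contact_range: tuple[float, float] = (3.5, 7.5)
) -> ResidueSet:
    """Pseudo-residues around the (origin-centred) ring scaffold.

    Each residue is a net-neutral polar fragment (amide-like N-H donor head
    backed by a C=O tail) pointing its H at the ring.  The head sits at a
    random distance within ``contact_range`` of the nearest point of the
    scaffold ring circle, giving a mixture of hydrogen-bond-range contacts
    and peripheral residues.
    """
    if n_residues < 1:
        raise ValueError("need n_residues >= 1")
    rng = np.random.default_rng(seed)
    ring_r = BOND_LENGTH / (2.0 * np.sin(np.pi / RING_SIZE))
    residues = []
    for k in range(n_residues):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        phi = np.arctan2(u[1], u[0])
        ring_point = ring_r * np.array([np.cos(phi), np.sin(phi), 0.0])
        d = rng.uniform(*contact_range)
        head = ring_point + d * u
        # donor N-H aimed at the ring, carbonyl C=O behind it; net charge 0
        atoms = [
            Atom("H", head, partial_charge=0.4, atom_id=0),
            Atom("N", head + 1.0 * u, partial_charge=-0.4, atom_id=1),
            Atom("C", head + 2.3 * u, partial_charge=0.3, atom_id=2),
            Atom("O", head + 3.5 * u, partial_charge=-0.3, atom_id=3),
        ]
        name = f"{_RESIDUE_NAMES[k % len(_RESIDUE_NAMES)]}{k + 1}"
        residues.append(Molecule(name, atoms, bonds=[(0, 1), (1, 2), (2, 3)], role="residue"))
    return ResidueSet(residues, source=f"synthetic-pocket-seed{seed}")


def pocket_energy_tables(
    pocket: ResidueSet, ligands: list[Molecule]
) -> tuple[EnergyTable, EnergyTable, EnergyTable, dict]:
    """Mutually consistent (complex, ligand, residue) tables + truth.

    E_AM = E_L + E_M + inter(L, M) by construction, so the recovered
    I.E equals the true pairwise interaction term exactly.
    """
    lig_tab = {m.name: toy_intra_energy(m) for m in ligands}
    res_tab = {r.name: toy_intra_energy(r) for r in pocket.residues}
    cpx_tab = {}
    truth = {}
    for m in ligands:
        for r in pocket.residues:
            inter = toy_pair_energy(m, r)
            truth[(m.name, r.name)] = inter
            cpx_tab[f"{m.name}|{r.name}"] = lig_tab[m.name] + res_tab[r.name] + inter
    return (
        EnergyTable(cpx_tab),
        EnergyTable(lig_tab),
        EnergyTable(res_tab),
        truth,
    )


# ---------------------------------------------------------------------------
# activities and descriptor tables
# ---------------------------------------------------------------------------

def gen_activities(
    X: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    seed: int,
    activity_range: tuple[float, float] = PIC50_RANGE,
) -> tuple[np.ndarray, dict]:
    """Activities y = X beta + N(0, sigma^2), rescaled into pIC50 range.

    The returned truth record carries the pre-scaling linear response, the
    noise draws and the affine map, so recovery tests can work on the
    unscaled signal.
    """
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError("beta length must equal the number of field columns")
    rng = np.random.default_rng(seed)
    signal = X @ beta
    noise = rng.normal(0.0, sigma, size=X.shape[0]) if sigma > 0 else np.zeros(X.shape[0])
    y_lin = signal + noise
    lo, hi = activity_range
    span = y_lin.max() - y_lin.min()
    if span == 0:
        y = np.full_like(y_lin, (lo + hi) / 2.0)
        scale, offset = 0.0, (lo + hi) / 2.0
    else:
        scale = (hi - lo) / span
        offset = lo - scale * y_lin.min()
        y = scale * y_lin + offset
    truth = {
        "beta": beta,
        "signal": signal,
        "noise": noise,
        "y_linear": y_lin,
        "scale": scale,
        "offset": offset,
        "sigma": sigma,
    }
    return y, truth


def gen_descriptor_tables(
    seed: int, names: list[str], n_atoms: int = 6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frontier-orbital and population tables with valid physics built in.

    E_HOMO is drawn in [-7.5, -5.5] eV and the gap in [4, 7] eV; the
    population table distributes exactly +/-1 electron over the atoms
    between charge states (Dirichlet weights), so condensed Fukui
    functions sum to one by construction.
    """
    if not names:
        raise ValueError("names must be nonempty")
    rng = np.random.default_rng(seed)
    orb_rows = []
    pop_rows = []
    for nm in names:
        e_homo = rng.uniform(-7.5, -5.5)
        gap = rng.uniform(4.0, 7.0)
        orb_rows.append({"name": nm, "E_HOMO": e_homo, "E_LUMO": e_homo + gap})
        q_n = rng.uniform(0.5, 8.0, size=n_atoms)
        add = rng.dirichlet(np.ones(n_atoms))
        rem = rng.dirichlet(np.ones(n_atoms))
        for k in range(n_atoms):
            pop_rows.append(
                {
                    "name": nm,
                    "atom_id": k,
                    "q_Nminus1": q_n[k] - rem[k],
                    "q_N": q_n[k],
                    "q_Nplus1": q_n[k] + add[k],
                }
            )
    return pd.DataFrame(orb_rows), pd.DataFrame(pop_rows)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """A complete reproducible study: ligands, pocket, fields, activities."""

    seed: int
    ligands: list[Molecule]
    substituents: list[tuple[str, str]]
    pocket: ResidueSet
    fields: FieldMatrix = field(repr=False)
    beta: np.ndarray = field(repr=False)
    activities: np.ndarray = field(repr=False)
    truth: dict = field(repr=False)
    complex_energies: EnergyTable = field(repr=False)
    ligand_energies: EnergyTable = field(repr=False)
    residue_energies: EnergyTable = field(repr=False)
    interaction_truth: dict = field(repr=False)
    orbitals: pd.DataFrame = field(repr=False)
    populations: pd.DataFrame = field(repr=False)


def gen_scenario(
    seed: int,
    n_ligands: int = 40,
    n_residues: int = 10,
    noise_sigma: float = 0.1,
    n_components_true: int = 3,
    grid_spacing: float = 2.0,
) -> SyntheticScenario:
    """Generate every pipeline input from one seed.

    The planted activity signal is a linear function of the field columns
    whose coefficient vector lies in the span of the top
    ``n_components_true`` principal directions of the (centred) field
    matrix, so the generating model has exactly that latent dimension --
    the quantity a PLS fit at the true component count should recover.
    The linear signal is normalized to unit standard deviation; noise is
    N(0, noise_sigma^2) on that scale.
    """
    rng = np.random.default_rng(seed)
    series = gen_ligand_series(seed, n_ligands)
    ligands = [m for m, _ in series]
    subs = [s for _, s in series]
    fields = compute_fields(ligands, spacing=grid_spacing)
    Xc = fields.X - fields.X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components_true, Vt.shape[0])
    weights = rng.normal(1.0, 0.3, size=k) * rng.choice([-1, 1], k)
    beta = Vt[:k].T @ weights
    sig_std = (fields.X @ beta).std()
    if sig_std > 0:
        beta = beta / sig_std  # unit-variance planted signal
    y, truth = gen_activities(fields.X, beta, noise_sigma, seed + 1)
    pocket = gen_pocket(seed + 2, n_residues)
    cpx, lig_e, res_e, ie_truth = pocket_energy_tables(pocket, ligands)
    orbitals, populations = gen_descriptor_tables(seed + 3, [m.name for m in ligands])
    return SyntheticScenario(
        seed=seed,
        ligands=ligands,
        substituents=subs,
        pocket=pocket,
        fields=fields,
        beta=beta,
        activities=y,
        truth=truth,
        complex_energies=cpx,
        ligand_energies=lig_e,
        residue_energies=res_e,
        interaction_truth=ie_truth,
        orbitals=orbitals,
        populations=populations,
    )
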