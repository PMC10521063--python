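"""Conceptual-DFT reactivity descriptors.

Global descriptors from frontier-orbital energies (eV):

    chemical potential   mu    = (E_LUMO + E_HOMO) / 2
    chemical hardness    eta   = E_LUMO - E_HOMO
    softness             S     = 1 / eta
    electrophilicity     omega = mu^2 / (2 eta)

mu measures the tendency of electrons to escape the system, eta the
resistance to changes in the electronic configuration, and omega the
stabilization energy on saturation with electrons from the environment.

Local descriptors are the condensed Fukui functions from atomic electron
populations q_k of the N-1, N and N+1 electron states:

    f_k(+) = q_k(N+1) - q_k(N)     (site of nucleophilic attack)
    f_k(-) = q_k(N)   - q_k(N-1)   (site of electrophilic attack)

When the population table conserves charge, each condensed function sums
to exactly one electron over the atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "ReactivityProfile",
    "chemical_potential",
    "hardness",
    "softness",
    "electrophilicity",
    "reactivity_profile",
    "reactivity_table",
    "fukui_functions",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal half-up rounding (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_gap(e_homo: float, e_lumo: float) -> None:
    if not e_lumo > e_homo:
        raise ValueError(f"inverted gap: E_LUMO ({e_lumo}) must exceed E_HOMO ({e_homo})")


def chemical_potential(e_homo: float, e_lumo: float) -> float:
    """mu = (E_LUMO + E_HOMO) / 2, eV."""
    _check_gap(e_homo, e_lumo)
    return (e_lumo + e_homo) / 2.0


def hardness(e_homo: float, e_lumo: float) -> float:
    """eta = E_LUMO - E_HOMO, eV (positive for any valid gap)."""
    _check_gap(e_homo, e_lumo)
    return e_lumo - e_homo


def softness(eta: float) -> float:
    """S = 1 / eta, 1/eV."""
    if eta <= 0:
        raise ValueError("hardness must be positive")
    return 1.0 / eta


def electrophilicity(mu: float, eta: float) -> float:
    """omega = mu^2 / (2 eta), eV; invariant under the sign of mu."""
    if eta <= 0:
        raise ValueError("hardness must be positive")
    return mu * mu / (2.0 * eta)


@dataclass
class ReactivityProfile:
    name: str
    mu: float
    eta: float
    S: float
    omega: float


def reactivity_profile(name: str, e_homo: float, e_lumo: float) -> ReactivityProfile:
    mu = chemical_potential(e_homo, e_lumo)
    eta = hardness(e_homo, e_lumo)
    return ReactivityProfile(name, mu, eta, softness(eta), electrophilicity(mu, eta))


def reactivity_table(orbitals: pd.DataFrame, decimals: int | None = 4) -> pd.DataFrame:
    """Descriptor table from a (name, E_HOMO, E_LUMO) frame.

    Columns mirror the standard printed layout: chemical potential,
    hardness (eV), softness (1/eV), electrophilicity (eV).  ``decimals``
    applies half-up rounding for presentation; pass None for full
    precision.
    """
    rows = []
    for rec in orbitals.itertuples(index=False):
        p = reactivity_profile(rec.name, rec.E_HOMO, rec.E_LUMO)
        vals = [p.mu, p.eta, p.S, p.omega]
        if decimals is not None:
            vals = [round_half_up(v, decimals) for v in vals]
        rows.append({"name": p.name, "mu_eV": vals[0], "eta_eV": vals[1],
                     "S_inv_eV": vals[2], "omega_eV": vals[3]})
    return pd.DataFrame(rows)


def fukui_functions(populations: pd.DataFrame) -> pd.DataFrame:
    """Condensed Fukui functions per atom from a population table.

    Expects columns ``atom_id, q_Nminus1, q_N, q_Nplus1`` (atomic electron
    populations, not net charges) for one molecule; returns a frame with
    ``f_plus``/``f_minus`` plus booleans flagging the maximal atom of each
    (the preferred nucleophilic / electrophilic attack site).
    """
    required = ("atom_id", "q_Nminus1", "q_N", "q_Nplus1")
    for col in required:
        if col not in populations.columns:
            raise ValueError(f"population table missing column {col!r}")
    out = populations[["atom_id"]].copy()
    out["f_plus"] = populations["q_Nplus1"].to_numpy() - populations["q_N"].to_numpy()
    out["f_minus"] = populations["q_N"].to_numpy() - populations["q_Nminus1"].to_numpy()
    out["max_f_plus"] = out["f_plus"] == out["f_plus"].max()
    out["max_f_minus"] = out["f_minus"] == out["f_minus"].max()
    return out
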