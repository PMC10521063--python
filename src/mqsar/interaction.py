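"""Per-residue interaction-energy decomposition.

For one ligand (analogue) bound near one residue, the interaction energy is
the supermolecular difference

    I.E = E_AM - E_L - E_M

where E_AM is the energy of the analogue-residue pair, E_L the isolated
ligand energy and E_M the isolated residue energy (all in the same unit,
kcal/mol by default).  Negative values stabilize the complex.

Profiles collect the I.E of one ligand across all active-site residues;
residues are ranked across a ligand series by mean I.E (most negative
first) to flag "critical" residues, the contacts that dominate binding.

Complex energies are looked up in an :class:`~mqsar.structures.EnergyTable`
under the key ``"<ligand>|<residue>"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .structures import EnergyTable

__all__ = [
    "IERecord",
    "InteractionEnergyProfile",
    "CriticalResidueReport",
    "interaction_energy",
    "complex_key",
    "build_profile",
    "rank_critical",
    "series_summary",
    "plot_profile",
]

DEFAULT_TOP_N = 4  # residues flagged critical in the ranking report


def interaction_energy(e_am: float, e_l: float, e_m: float) -> float:
    """I.E = E_AM - E_L - E_M; negative means stabilizing."""
    return e_am - e_l - e_m


def complex_key(ligand: str, residue: str) -> str:
    return f"{ligand}|{residue}"


@dataclass
class IERecord:
    ligand: str
    residue: str
    e_am: float
    e_l: float
    e_m: float

    @property
    def ie(self) -> float:
        return interaction_energy(self.e_am, self.e_l, self.e_m)


@dataclass
class InteractionEnergyProfile:
    ligand: str
    records: list[IERecord]
    series: str = ""

    def __post_init__(self) -> None:
        names = [r.residue for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate residue in profile for {self.ligand!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def residues(self) -> list[str]:
        return [r.residue for r in self.records]

    def ie(self, residue: str) -> float:
        for r in self.records:
            if r.residue == residue:
                return r.ie
        raise KeyError(residue)

    def total(self) -> float:
        return sum(r.ie for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [r.ligand for r in self.records],
                "residue": [r.residue for r in self.records],
                "E_AM": [r.e_am for r in self.records],
                "E_L": [r.e_l for r in self.records],
                "E_M": [r.e_m for r in self.records],
                "IE": [r.ie for r in self.records],
            }
        )


def build_profile(
    complex_energies: EnergyTable,
    ligand_energies: EnergyTable,
    residue_energies: EnergyTable,
    ligand: str,
    residues: list[str],
    series: str = "",
) -> InteractionEnergyProfile:
    """One IERecord per residue; missing rows raise, naming the system."""
    units = {complex_energies.unit, ligand_energies.unit, residue_energies.unit}
    if len(units) != 1:
        raise ValueError(f"mixed energy units: {sorted(units)}")
    if ligand not in ligand_energies:
        raise KeyError(f"missing ligand energy for {ligand!r}")
    e_l = ligand_energies[ligand]
    missing = []
    records = []
    for res in residues:
        key = complex_key(ligand, res)
        if key not in complex_energies:
            missing.append(f"complex {key!r}")
            continue
        if res not in residue_energies:
            missing.append(f"residue {res!r}")
            continue
        records.append(IERecord(ligand, res, complex_energies[key], e_l, residue_energies[res]))
    if missing:
        raise KeyError(
            f"profile for {ligand!r} incomplete; missing energies: " + ", ".join(missing)
        )
    return InteractionEnergyProfile(ligand, records, series=series)


@dataclass
class CriticalResidueReport:
    """Residues ranked by mean I.E across ligands (rank 1 = most favorable)."""

    table: pd.DataFrame = field(repr=False)
    top_n: int = DEFAULT_TOP_N

    def rank(self, residue: str) -> int:
        row = self.table.loc[self.table["residue"] == residue]
        if row.empty:
            raise KeyError(residue)
        return int(row["rank"].iloc[0])

    def critical(self) -> list[str]:
        return list(self.table.loc[self.table["critical"], "residue"])


def rank_critical(
    profiles: list[InteractionEnergyProfile], top_n: int = DEFAULT_TOP_N
) -> CriticalResidueReport:
    """Rank residues by mean I.E over ligands, ascending (most negative first).

    Ties break deterministically by residue name.  The ``top_n`` most
    favorable residues are flagged critical.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append({"residue": r.residue, "IE": r.ie})
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("residue")["IE"]
        .agg(mean_IE="mean", n="count", min_IE="min", max_IE="max")
        .reset_index()
    )
    agg = agg.sort_values(["mean_IE", "residue"], kind="mergesort").reset_index(drop=True)
    agg["rank"] = agg.index + 1
    agg["critical"] = agg["rank"] <= top_n
    return CriticalResidueReport(agg, top_n=top_n)


def series_summary(profiles: list[InteractionEnergyProfile]) -> pd.DataFrame:
    """Per-series aggregation of I.E per residue (count, mean, min, max).

    Profiles without a series tag are grouped under ``"other"``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for p in profiles:
        series = p.series or "other"
        for r in p.records:
            rows.append({"series": series, "residue": r.residue, "IE": r.ie})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["series", "residue"])["IE"]
        .agg(n="count", mean_IE="mean", min_IE="min", max_IE="max")
        .reset_index()
        .sort_values(["series", "residue"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def plot_profile(profile: InteractionEnergyProfile, path) -> None:
    """Bar chart of per-residue I.E for one ligand (kcal/mol)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(profile)), 3.2))
    ies = [r.ie for r in profile.records]
    ax.bar(profile.residues, ies, color=["tab:red" if v < 0 else "tab:blue" for v in ies])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("I.E (kcal/mol)")
    ax.set_title(profile.ligand)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
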