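"""End-to-end orchestration: scenario -> similarity -> descriptors -> I.E -> QSAR.

A :class:`RunConfig` names exactly one input source (a synthetic scenario
seed, or a directory of user structures plus tables) and the stage
parameters: alignment mode (``structure`` = rigid TGSA superposition of the
optimized structures; ``pose``/``pose+rescored`` = coordinates are taken as
already posed, as when poses come from docking or docking plus
semi-empirical rescoring), similarity operators, and the PLS component
counts to report.

:func:`run` executes the stages in order, writes every table as CSV with
decimal points, and stamps the consolidated ``report.json`` with the seed
and a hash of the configuration so reruns are verifiably identical.  Any
stage failure raises with the stage name; artifacts written before the
failure are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cdft, interaction
from .comfa import contribution_contours, fit_pls, loo_q2
from .similarity import similarity_matrix
from .synthetic import gen_scenario

logger = logging.getLogger("mqsar.pipeline")

__all__ = ["RunConfig", "StageError", "run"]

ALIGNMENT_MODES = ("structure", "pose", "pose+rescored")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int = 42
    synthetic: bool = True
    n_ligands: int = 40
    n_residues: int = 10
    noise_sigma: float = 0.1
    input_dir: str | None = None
    alignment_mode: str = "structure"
    operators: tuple[str, ...] = ("overlap", "coulomb")
    pls_components: tuple[int, ...] = (2, 5, 7)
    similarity_subset: int = 8  # pairwise stage restricted to the first k ligands
    output_dir: str = "mqsar_out"

    def validate(self) -> None:
        if self.synthetic == (self.input_dir is not None):
            raise ValueError("exactly one input source: synthetic or input_dir")
        if self.alignment_mode not in ALIGNMENT_MODES:
            raise ValueError(f"alignment_mode must be one of {ALIGNMENT_MODES}")
        if not self.pls_components:
            raise ValueError("pls_components must be nonempty")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("operators", "pls_components"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def log_stage(self, name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        self.stages.append({"stage": name, **info})


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; returns the report (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.digest(), seed=config.seed)

    # --- inputs -----------------------------------------------------------
    with _stage(report, "inputs"):
        if not config.synthetic:
            raise NotImplementedError(
                "user-data runs load structures via mqsar.structures; "
                "wire them into a scenario-like object (synthetic runs only here)"
            )
        sc = gen_scenario(
            config.seed,
            n_ligands=config.n_ligands,
            n_residues=config.n_residues,
            noise_sigma=config.noise_sigma,
        )
        report.log_stage(
            "inputs",
            n_ligands=len(sc.ligands),
            n_residues=len(sc.pocket),
            n_field_columns=int(sc.fields.X.shape[1]),
        )

    # --- similarity matrices ---------------------------------------------
    with _stage(report, "similarity"):
        subset = sc.ligands[: max(2, config.similarity_subset)]
        align = config.alignment_mode == "structure"
        for op in config.operators:
            sm = similarity_matrix(subset, operator=op, align=align)
            for which in ("Z", "carbo", "euclidean"):
                sm.to_csv(out / f"similarity_{op}_{which}.csv", which=which)
            report.log_stage(
                f"similarity:{op}", n_molecules=len(subset), failed_pairs=len(sm.failed_pairs)
            )

    # --- reactivity descriptors ------------------------------------------
    with _stage(report, "cdft"):
        desc = cdft.reactivity_table(sc.orbitals)
        desc.to_csv(out / "descriptors.csv", index=False)
        fukui_frames = []
        for nm, grp in sc.populations.groupby("name", sort=True):
            f = cdft.fukui_functions(grp)
            f.insert(0, "name", nm)
            fukui_frames.append(f)
        pd.concat(fukui_frames, ignore_index=True).to_csv(out / "fukui.csv", index=False)
        report.log_stage("cdft", n_rows=len(desc))

    # --- interaction-energy profiles -------------------------------------
    with _stage(report, "interaction"):
        residues = sc.pocket.names()
        profiles = []
        for m, (sub_a, _) in zip(sc.ligands, sc.substituents):
            profiles.append(
                interaction.build_profile(
                    sc.complex_energies,
                    sc.ligand_energies,
                    sc.residue_energies,
                    m.name,
                    residues,
                    series=f"11-{sub_a}",
                )
            )
        pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
            out / "ie_profiles.csv", index=False
        )
        ranking = interaction.rank_critical(profiles)
        ranking.table.to_csv(out / "critical_residues.csv", index=False)
        interaction.series_summary(profiles).to_csv(out / "series_summary.csv", index=False)
        report.log_stage(
            "interaction", n_profiles=len(profiles), critical=ranking.critical()
        )

    # --- CoMFA / PLS -------------------------------------------------------
    with _stage(report, "comfa"):
        y = sc.activities
        stats_rows = []
        best = None
        for ncomp in config.pls_components:
            model = fit_pls(sc.fields, y, ncomp)
            q2 = loo_q2(sc.fields, y, ncomp)
            stats_rows.append(
                {
                    "n_components": ncomp,
                    "q2": round(q2, 3),
                    "R2": round(model.r2, 3),
                    "steric_pct": round(model.contributions.get("steric", 0.0), 1),
                    "electrostatic_pct": round(
                        model.contributions.get("electrostatic", 0.0), 1
                    ),
                }
            )
            if best is None or q2 > best[0]:
                best = (q2, model)
        stats = pd.DataFrame(stats_rows)
        stats.to_csv(out / "qsar_stats.csv", index=False)
        contours = contribution_contours(best[1], sc.fields.grid)
        serializable = {
            t: {k: v for k, v in entry.items() if not k.endswith("_points")}
            for t, entry in contours.items()
        }
        (out / "contours.json").write_text(json.dumps(serializable, indent=1))
        report.log_stage("comfa", components=list(config.pls_components), best_q2=best[0])

    report.outputs = {
        p.name: p.stat().st_size for p in sorted(out.iterdir()) if p.name != "report.json"
    }
    (out / "report.json").write_text(
        json.dumps(
            {
                "config_hash": report.config_hash,
                "seed": report.seed,
                "stages": report.stages,
                "outputs": report.outputs,
            },
            indent=1,
            default=str,
        )
    )
    return report
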