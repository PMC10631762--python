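"""End-to-end pipeline orchestration.

A single config (YAML/JSON) names the inputs, parameters and requested
stages; :func:`run_pipeline` executes the stages in dependency order, writes
each stage's CSV outputs under the output directory, and records a manifest
(stage, parameters, output file hashes). Deterministic stages reproduce
their hashes on rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biophys as _biophys
from . import contacts as _contacts
from . import infotheory as _info
from . import interaction as _interaction
from .encoding import encode_repertoire
from .repertoire import (
    apply_region_definition,
    filter_productive_unique,
    load_region_definitions,
    parse_family_fasta,
)

log = logging.getLogger("tcrmhc")

STAGE_ORDER = ("encode", "entropy", "mi", "biophys", "potential", "breakdown",
               "contacts", "compare")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    stages: list[str]
    seed: int
    tcr_fasta: Path | None = None
    mhc_fasta: Path | None = None
    tcr_family: str = "TRAV"
    mhc_family: str = "HLA-I"
    region_definitions: Path | None = None
    structure_pdb: Path | None = None
    structure_annotation: Path | None = None
    complex_counts: Path | None = None  # CSV (gene, count): per-complex contacts
    n_subsample: int | None = None
    n_repetitions: int = 1000
    n_permutations: int = 10_000
    vdw_cutoff: float = _contacts.VDW_CUTOFF
    electrostatic_cutoff: float = _contacts.ELECTROSTATIC_CUTOFF
    pad_mode: str = "central"
    hla_groups: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            stages = list(raw["stages"])
            cfg = cls(
                output_dir=Path(raw["output_dir"]),
                stages=stages,
                seed=int(raw["seed"]),
            )
        except KeyError as e:
            raise ConfigError(f"missing required config key: {e}") from e
        for key in ("tcr_fasta", "mhc_fasta", "region_definitions",
                    "structure_pdb", "structure_annotation", "complex_counts"):
            if raw.get(key) is not None:
                setattr(cfg, key, Path(raw[key]))
        for key in ("tcr_family", "mhc_family", "n_subsample", "n_repetitions",
                    "n_permutations", "vdw_cutoff", "electrostatic_cutoff",
                    "pad_mode", "hla_groups"):
            if raw.get(key) is not None:
                setattr(cfg, key, raw[key])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        sequence_stages = {"encode", "entropy", "mi", "biophys", "potential",
                           "breakdown"}
        if sequence_stages & set(self.stages):
            for key in ("tcr_fasta", "region_definitions"):
                path = getattr(self, key)
                if path is None:
                    raise ConfigError(f"stage set {self.stages} requires {key}")
                if not Path(path).exists():
                    raise ConfigError(f"{key}: file not found: {path}")
        if {"mi", "potential", "breakdown"} & set(self.stages):
            if self.mhc_fasta is None or not Path(self.mhc_fasta).exists():
                raise ConfigError("mi/potential/breakdown stages require mhc_fasta")
        if "contacts" in self.stages:
            for key in ("structure_pdb", "structure_annotation"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"contacts stage requires existing {key}")
        if "compare" in self.stages:
            if "potential" not in self.stages:
                raise ConfigError("compare requires the potential stage")
            if self.complex_counts is None or not Path(self.complex_counts).exists():
                raise ConfigError("compare stage requires existing complex_counts")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_family(fasta: Path, family: str, region_defs) -> list:
    records = parse_family_fasta(fasta, family=family)
    if family in region_defs:
        apply_region_definition(records, region_defs[family])
    else:
        raise ConfigError(f"no region definition for family {family!r}")
    return filter_productive_unique(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}
    requested = [s for s in STAGE_ORDER if s in config.stages]

    tcr = mhc = None
    tcr_matrix = mhc_matrix = None
    score_table = None
    contact_records = None

    def need_sequences():
        nonlocal tcr, mhc, tcr_matrix, mhc_matrix
        if tcr is not None:
            return
        region_defs = load_region_definitions(config.region_definitions)
        tcr = _load_family(config.tcr_fasta, config.tcr_family, region_defs)
        tcr_matrix = encode_repertoire(tcr, pad_mode=config.pad_mode)
        if config.mhc_fasta is not None:
            mhc = _load_family(config.mhc_fasta, config.mhc_family, region_defs)
            mhc_matrix = encode_repertoire(mhc, pad_mode=config.pad_mode)

    def record_stage(stage: str, outputs: list[Path], parameters: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "parameters": parameters,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            }
        )

    for stage in requested:
        log.info("stage %s", stage)
        try:
            if stage == "encode":
                need_sequences()
                paths = [out / "tcr_encoded.csv"]
                tcr_matrix.to_csv(paths[0])
                paths.append(Path(str(paths[0]) + ".meta.json"))
                if mhc_matrix is not None:
                    p = out / "mhc_encoded.csv"
                    mhc_matrix.to_csv(p)
                    paths += [p, Path(str(p) + ".meta.json")]
                record_stage(stage, paths, {"pad_mode": config.pad_mode})

            elif stage == "entropy":
                need_sequences()
                paths = []
                for label, matrix in (("tcr", tcr_matrix), ("mhc", mhc_matrix)):
                    if matrix is None:
                        continue
                    prof = _info.subsampled_entropy_profile(
                        matrix,
                        n_subsample=config.n_subsample,
                        n_repetitions=config.n_repetitions,
                        seed=config.seed,
                    )
                    p = out / f"{label}_entropy.csv"
                    prof.to_frame().to_csv(p, index=False)
                    paths.append(p)
                record_stage(stage, paths, {
                    "n_subsample": config.n_subsample,
                    "n_repetitions": config.n_repetitions, "seed": config.seed,
                })

            elif stage == "mi":
                need_sequences()
                mim = _info.mutual_information(
                    tcr_matrix, mhc_matrix, pairing="random",
                    n_repetitions=config.n_repetitions, seed=config.seed,
                )
                p = out / "mutual_information.csv"
                mim.to_frame().to_csv(p, index=False)
                record_stage(stage, [p], {
                    "pairing": "random",
                    "n_repetitions": config.n_repetitions, "seed": config.seed,
                })

            elif stage == "biophys":
                need_sequences()
                paths = []
                for table in (_biophys.charge_table(), _biophys.hydropathy_table()):
                    for label, matrix in (("tcr", tcr_matrix), ("mhc", mhc_matrix)):
                        if matrix is None:
                            continue
                        prof = _biophys.position_property_profile(matrix, table)
                        p = out / f"{label}_{table.name}.csv"
                        prof.to_frame().to_csv(p, index=False)
                        paths.append(p)
                record_stage(stage, paths, {"tables": ["charge", "hydropathy"]})

            elif stage == "potential":
                need_sequences()
                score_table = _interaction.gene_allele_scores(tcr, mhc)
                p = out / "interaction_scores.csv"
                score_table.to_csv(p)
                p2 = out / "interaction_scores_pivot.csv"
                score_table.pivot("CDR1", "helix1").to_csv(p2)
                record_stage(stage, [p, p2], {"validity": "all_weak"})

            elif stage == "breakdown":
                need_sequences()
                rows = []
                for rec in mhc:
                    breakdown = _interaction.per_residue_breakdown(tcr, rec)
                    for helix, values in breakdown.items():
                        for col, v in enumerate(values):
                            rows.append((rec.id, helix, col, v))
                p = out / "per_residue_breakdown.csv"
                pd.DataFrame(
                    rows, columns=["allele", "helix", "column", "mean_score"]
                ).to_csv(p, index=False)
                record_stage(stage, [p], {})

            elif stage == "contacts":
                structure = _contacts.load_structure(str(config.structure_pdb))
                with open(config.structure_annotation) as fh:
                    annotation = _contacts.ComplexAnnotation.from_dict(
                        yaml.safe_load(fh)
                    )
                contact_records = _contacts.find_contacts(
                    structure, annotation,
                    vdw_cutoff=config.vdw_cutoff,
                    electrostatic_cutoff=config.electrostatic_cutoff,
                )
                p = out / "contacts.csv"
                _contacts.records_to_frame(contact_records).to_csv(p, index=False)
                ccm = _contacts.contact_count_matrix(contact_records, "SC-SC")
                p2 = out / "contact_counts_scsc.csv"
                ccm.to_frame(symmetrized=True).to_csv(p2)
                record_stage(stage, [p, p2], {
                    "vdw_cutoff": config.vdw_cutoff,
                    "electrostatic_cutoff": config.electrostatic_cutoff,
                })

            elif stage == "compare":
                if score_table is None:
                    raise StageError("compare requires the potential stage")
                bins = _contacts.assign_potential_bins(score_table.gene_means())
                counts = pd.read_csv(config.complex_counts)
                counts["bin"] = counts["gene"].map(bins.to_dict())
                counts_by_bin = {
                    str(label): counts.loc[counts["bin"] == label, "count"].to_numpy()
                    for label in bins.cat.categories
                }
                comparison = _contacts.group_comparison(
                    counts_by_bin, n_perm=config.n_permutations, seed=config.seed
                )
                p = out / "group_comparison.csv"
                comparison.to_csv(p, index=False)
                record_stage(stage, [p], {
                    "n_permutations": config.n_permutations, "seed": config.seed,
                })
        except (ConfigError, StageError):
            raise
        except Exception as e:  # halt with stage-scoped error, partial manifest
            manifest_path = out / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=1))
            raise StageError(f"stage {stage!r} failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
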