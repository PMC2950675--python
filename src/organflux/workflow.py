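"""Pipeline orchestration: configuration, staged runs, reports.

Ties the stages into two workflows: model building (expression
processing -> evidence-based exchange bounds -> objective assembly ->
GIMME -> reduction) and perturbation analysis (drug-target and
gene-deficiency scans, cryptic-risk-factor calling, sensitivity
sweeps, clinical benchmarking). Each command writes its outputs under
the configured directory; tabular outputs are TSV, reports JSON, and
every report carries the configuration hash so runs are auditable and
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import expression as expr
from .context import (
    EvidenceTable,
    ObjectiveSpec,
    apply_exchange_bounds,
    assemble_objective,
    constrain_by_activity,
    derive_exchange_bounds,
    reduce_model,
    run_gimme,
)
from .perturb import (
    Perturbation,
    SimulationConfig,
    TargetMap,
    find_cryptic_risk_factors,
    scan_drug_targets,
    scan_gene_deletions,
    sensitivity_sweep,
)
from .sbmlio import read_sbml, write_sbml
from .synth import (
    generate_benchmark,
    generate_evidence,
    generate_expression,
    generate_toy_organ,
)
from .validate import BenchmarkTable, crossval_recall, permutation_null, roc_analysis

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "cmd_build",
    "cmd_perturb",
    "cmd_sensitivity",
    "cmd_validate",
    "cmd_crossval",
    "cmd_synth",
]


class ConfigError(ValueError):
    """A configuration problem the user can fix (missing file, bad value)."""


@dataclass
class PipelineConfig:
    """Declarative run configuration; defaults are the pipeline's base values."""

    model_sbml: Optional[str] = None
    expression_rep1: Optional[str] = None
    expression_rep2: Optional[str] = None
    probe_map: Optional[str] = None
    evidence_table: Optional[str] = None
    target_map: Optional[str] = None
    benchmark: Optional[str] = None
    objective: List[dict] = field(default_factory=list)  # {metabolite, direction, weight}
    include_atp_maintenance: bool = False

    sbfc: float = 13.5
    inhibition_fraction: float = 0.0
    disorder_threshold: float = 1.0
    threshold_p: float = 0.05
    lowess_span: float = 0.3
    gimme_required_fraction: float = 0.90
    permutation_trials: int = 100
    crossval_fraction: float = 0.20
    crossval_folds: int = 5
    seed: int = 0
    output_dir: str = "organflux_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require(self, *fields_: str) -> None:
        for name in fields_:
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config field {name!r} is required for this command")
            if name != "objective" and not Path(value).exists():
                raise ConfigError(f"config field {name!r}: file {value} does not exist")

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            sbfc=self.sbfc,
            inhibition_fraction=self.inhibition_fraction,
            disorder_threshold=self.disorder_threshold,
        )

    def objective_spec(self) -> ObjectiveSpec:
        if not self.objective:
            raise ConfigError("config field 'objective' is required for this command")
        return ObjectiveSpec(
            components=[(o["metabolite"], o["direction"]) for o in self.objective],
            weights={o["metabolite"]: o.get("weight", 1.0) for o in self.objective},
            include_atp_maintenance=self.include_atp_maintenance,
            uptake_reactions={
                o["metabolite"]: o["uptake_reaction"]
                for o in self.objective
                if "uptake_reaction" in o
            },
        )


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"config_hash": config.config_hash(), **payload}
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _write_tsv(path: Path, df, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_profile(config: PipelineConfig, model):
    config.require("expression_rep1", "expression_rep2", "probe_map")
    rep1 = expr.read_probe_table(config.expression_rep1)
    rep2 = expr.read_probe_table(config.expression_rep2)
    probe_map = expr.read_probe_map(config.probe_map)
    return expr.build_profile(
        model, rep1, rep2, probe_map, p=config.threshold_p, span=config.lowess_span
    )


def _load_assembly(config: PipelineConfig):
    config.require("model_sbml", "evidence_table")
    base = read_sbml(config.model_sbml)
    evidence = EvidenceTable.from_tsv(config.evidence_table)
    bounds = derive_exchange_bounds(base, evidence, sbfc=config.sbfc)
    constrained = apply_exchange_bounds(base, bounds)
    assembly = assemble_objective(constrained, config.objective_spec())
    return assembly, bounds


def cmd_build(config: PipelineConfig) -> dict:
    """Build the context model: full + reduced SBML, GIMME report, provenance log."""
    out = _outdir(config)
    assembly, bounds = _load_assembly(config)
    profile = _load_profile(config, assembly.model)

    gimme = run_gimme(
        assembly.model,
        profile.reaction_scores,
        profile.threshold,
        objective_reaction=assembly.combined_reaction_id,
        required_fraction=config.gimme_required_fraction,
    )
    full_model = constrain_by_activity(assembly.model, gimme)
    full_model.id = "context_full"
    reduced = reduce_model(full_model, assembly.components)

    write_sbml(full_model, out / "context_full.xml")
    write_sbml(reduced, out / "context_reduced.xml")
    _write_tsv(out / "gimme_report.tsv", gimme.to_table(profile.reaction_scores), config)
    profile.to_tsv(out / "expression_profile.tsv")
    provenance = [
        {"reaction": rid, "lower": b.lower, "upper": b.upper, "rule": b.rule}
        for rid, b in sorted(bounds.items())
    ]
    _write_json(
        out / "build_report.json",
        {
            "threshold": profile.threshold,
            "gimme_inconsistency": gimme.inconsistency_score,
            "gimme_objective_max": gimme.objective_max,
            "required_fraction": gimme.required_fraction,
            "n_reactions_full": len(full_model.reactions),
            "n_reactions_reduced": len(reduced.reactions),
            "incompatible_components": assembly.incompatible,
            "components": [c.id for c in assembly.components],
            "exchange_constraint_log": provenance,
        },
        config,
    )
    return {
        "assembly": assembly,
        "profile": profile,
        "gimme": gimme,
        "full_model": full_model,
        "reduced_model": reduced,
    }


def _reduced_and_components(config: PipelineConfig):
    built = cmd_build(config)
    return built["reduced_model"], built["assembly"].components, built


def cmd_perturb(config: PipelineConfig) -> dict:
    """Gene-deletion and drug-target scans plus cryptic risk factors."""
    out = _outdir(config)
    reduced, components, built = _reduced_and_components(config)
    sim = config.sim_config()
    genes = sorted(reduced.genes())

    untreated = scan_gene_deletions(reduced, genes, components, sim)
    _write_tsv(out / "gene_deletion_untreated.tsv", untreated.to_long(), config)

    result = {"untreated": untreated}
    if config.target_map:
        targets = TargetMap.from_tsv(config.target_map)
        drug = scan_drug_targets(reduced, targets, components, sim)
        treated = scan_gene_deletions(reduced, genes, components, sim, treatment=targets)
        cryptic = find_cryptic_risk_factors(untreated, treated)
        _write_tsv(out / "drug_target_scan.tsv", drug.to_long(), config)
        _write_tsv(out / "gene_deletion_treated.tsv", treated.to_long(), config)
        _write_json(
            out / "cryptic_risk_factors.json",
            {"cryptic_risk_factors": cryptic},
            config,
        )
        result.update({"drug": drug, "treated": treated, "cryptic": cryptic})
    return result


def cmd_sensitivity(config: PipelineConfig, parameter: str = "sbfc", grid=None) -> dict:
    """Parameter sensitivity sweep over sbfc or inhibition fraction."""
    from .perturb import DEFAULT_FRACTION_GRID, DEFAULT_SBFC_GRID

    out = _outdir(config)
    reduced, components, _ = _reduced_and_components(config)
    sim = config.sim_config()
    if grid is None:
        grid = DEFAULT_SBFC_GRID if parameter == "sbfc" else DEFAULT_FRACTION_GRID
        if parameter == "sbfc" and not any(abs(g - sim.sbfc) < 1e-12 for g in grid):
            grid = tuple(sorted(set(grid) | {sim.sbfc}))

    perturbations = []
    if config.target_map:
        targets = TargetMap.from_tsv(config.target_map)
        for tid in targets.target_ids():
            perturbations.append(
                Perturbation(
                    id=tid,
                    reactions=frozenset(targets.reactions_hit(reduced, [tid])),
                )
            )
    else:
        perturbations = [
            Perturbation(id=g, genes=frozenset({g})) for g in sorted(reduced.genes())
        ]

    curves = sensitivity_sweep(reduced, perturbations, components, parameter, grid, sim)
    import pandas as pd

    rows = []
    for c in curves:
        for g, r, n in zip(c.grid, c.ratios, c.nsc):
            rows.append(
                {
                    "perturbation": c.perturbation,
                    "component": c.component,
                    "parameter": c.parameter,
                    "value": g,
                    "ratio": r,
                    "nsc": n,
                }
            )
    _write_tsv(out / f"sensitivity_{parameter}.tsv", pd.DataFrame(rows), config)
    return {"curves": curves}


def cmd_validate(config: PipelineConfig) -> dict:
    """ROC/AROC against the clinical benchmark with a permutation null."""
    out = _outdir(config)
    config.require("benchmark")
    reduced, components, _ = _reduced_and_components(config)
    sim = config.sim_config()
    benchmark = BenchmarkTable.from_tsv(config.benchmark)
    genes = sorted(set(benchmark.entries["gene"]))
    matrix = scan_gene_deletions(reduced, genes, components, sim)
    roc = roc_analysis(matrix, benchmark)
    perm = permutation_null(
        matrix, benchmark, n_trials=config.permutation_trials, seed=config.seed
    )
    _write_json(
        out / "roc_report.json",
        {
            "auc": roc.auc,
            "mean_tpr": roc.mean_tpr,
            "mean_tpr_interior": roc.mean_tpr_interior,
            "thresholds": roc.thresholds,
            "tpr": roc.tpr,
            "fpr": roc.fpr,
            "permutation_mean_auc": perm.mean_auc,
            "permutation_p_value": perm.p_value,
            "permutation_trials": config.permutation_trials,
            "seed": config.seed,
        },
        config,
    )
    return {"roc": roc, "permutation": perm, "matrix": matrix}


def cmd_crossval(config: PipelineConfig) -> dict:
    """Five-fold held-out-expression cross-validation of model building."""
    out = _outdir(config)
    assembly, _ = _load_assembly(config)
    profile = _load_profile(config, assembly.model)
    cv = crossval_recall(
        assembly.model,
        profile.gene_values,
        objective_reaction=assembly.combined_reaction_id,
        required_fraction=config.gimme_required_fraction,
        p_target=config.threshold_p,
        fraction=config.crossval_fraction,
        folds=config.crossval_folds,
    )
    _write_json(
        out / "crossval_report.json",
        {
            "mean_recall": cv.mean_recall,
            "folds": [
                {
                    "fold": f.fold,
                    "recall": f.recall,
                    "p_value": f.p_value,
                    "p_adjusted": f.p_adjusted,
                    "n_held_out": len(f.held_out),
                }
                for f in cv.folds
            ],
        },
        config,
    )
    return {"crossval": cv}


def cmd_synth(config: PipelineConfig) -> dict:
    """Write a complete synthetic fixture set in the pipeline's input formats."""
    out = _outdir(config)
    model, spec, truth = generate_toy_organ(seed=config.seed, sbfc=config.sbfc)
    rep1, rep2, probe_map, _ = generate_expression(
        model, seed=config.seed, expressed_genes=truth.expressed_gene_set
    )
    evidence = generate_evidence(model, truth)
    benchmark = generate_benchmark(truth, seed=config.seed)

    import pandas as pd

    write_sbml(model, out / "toy_model.xml")
    pd.DataFrame(
        {"probeset_id": list(rep1), "intensity": list(rep1.values())}
    ).to_csv(out / "expression_rep1.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"probeset_id": list(rep2), "intensity": list(rep2.values())}
    ).to_csv(out / "expression_rep2.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"probeset_id": list(probe_map), "gene_id": list(probe_map.values())}
    ).to_csv(out / "probe_map.tsv", sep="\t", index=False)
    evidence.to_tsv(out / "evidence.tsv")
    truth.drug_targets.to_tsv(out / "target_map.tsv")
    benchmark.to_tsv(out / "benchmark.tsv")
    _write_json(out / "ground_truth.json", truth.to_dict(), config)
    _write_json(
        out / "synth_config.json",
        {
            "objective": [
                {
                    "metabolite": met,
                    "direction": direction,
                    **(
                        {"uptake_reaction": spec.uptake_reactions[met]}
                        if met in spec.uptake_reactions
                        else {}
                    ),
                }
                for met, direction in spec.components
            ],
        },
        config,
    )
    return {"model": model, "spec": spec, "truth": truth}
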