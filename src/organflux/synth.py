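"""Synthetic organ fixtures with planted ground truth.

Every pipeline stage is testable without external downloads: this
module generates three-compartment toy organ networks (blood ``b``,
cytosol ``c``, urine ``u``) whose phenotypes are known by
construction, plus matching two-replicate probe-intensity tables,
evidence flags, drug-target maps and clinical-style benchmarks.

The planted structure mirrors the motifs the real pipeline must
resolve:

* a secretion product with a single synthesis route — knocking out
  either complex subunit abolishes secretion entirely (total loss);
* a reabsorption function with a direct transporter and an indirect
  catabolic route of different capacities — knockouts yield exact
  fractional ratios;
* an isozyme pair on a shared transport step — either deletion alone
  is silent;
* a secretion with a drug-targeted primary route and a genetically
  encoded backup route — the backup gene is a cryptic risk factor,
  deficient only in combination with the drug;
* decoy pathways whose genes are unexpressed, some flux-capable (GIMME
  should inactivate them) and some dead ends (reduction should drop
  them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .context import EvidenceFlags, EvidenceTable, ObjectiveComponent, ObjectiveSpec
from .fba import maximize_flux
from .gpr import and_node, gene_leaf, or_node
from .model import VMAX, MetabolicModel, Metabolite, Reaction
from .perturb import TargetMap
from .validate import BenchmarkTable

__all__ = [
    "GroundTruth",
    "generate_toy_organ",
    "generate_expression",
    "generate_evidence",
    "generate_benchmark",
]

DEFAULT_SBFC = 13.5


@dataclass
class GroundTruth:
    """What the generator planted, for exact recovery checks.

    Component ids are ``<metabolite>_<direction>`` as produced by
    objective assembly. ``safe_negatives`` are (gene, component) pairs
    guaranteed to keep ratio one, usable as clinical negatives.
    """

    planted_total_loss: List[Tuple[str, str]] = field(default_factory=list)
    planted_partial: List[Tuple[str, str, float]] = field(default_factory=list)
    planted_cryptic: List[Tuple[str, str, str]] = field(default_factory=list)  # gene, target, component
    planted_no_phenotype: List[str] = field(default_factory=list)
    planted_inactive_reactions: List[str] = field(default_factory=list)
    expressed_gene_set: List[str] = field(default_factory=list)
    safe_negatives: List[Tuple[str, str]] = field(default_factory=list)
    components: List[ObjectiveComponent] = field(default_factory=list)
    drug_targets: TargetMap = field(default_factory=TargetMap)

    def to_dict(self) -> dict:
        return {
            "planted_total_loss": self.planted_total_loss,
            "planted_partial": self.planted_partial,
            "planted_cryptic": self.planted_cryptic,
            "planted_no_phenotype": self.planted_no_phenotype,
            "planted_inactive_reactions": self.planted_inactive_reactions,
            "expressed_gene_set": self.expressed_gene_set,
            "safe_negatives": self.safe_negatives,
            "components": [c.id for c in self.components],
        }


def generate_toy_organ(
    seed: int,
    n_pathways: int = 12,
    redundancy_prob: float = 0.3,
    depth: int = 4,
    sbfc: float = DEFAULT_SBFC,
) -> Tuple[MetabolicModel, ObjectiveSpec, GroundTruth]:
    """Deterministic toy organ network with planted phenotypes.

    ``n_pathways`` decoy pathways of ``depth`` reactions each are
    attached to the blood compartment; ``redundancy_prob`` is the
    chance a decoy reaction gets an isozyme pair instead of a single
    gene. The core motifs (see module docstring) are always present.
    Raises after 10 attempts if the drawn parameters ever yield an
    infeasible objective (they do not for sane inputs).
    """
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    for attempt in range(10):
        rng = np.random.default_rng((seed, attempt))
        model, spec, truth = _build_toy(rng, n_pathways, redundancy_prob, depth, sbfc)
        if all(
            (maximize_flux(model, c.boundary_reaction_id).objective_value or 0.0) > 0
            for c in truth.components
        ):
            return model, spec, truth
    raise RuntimeError("could not generate a feasible toy organ in 10 attempts")


def _build_toy(
    rng: np.random.Generator,
    n_pathways: int,
    redundancy_prob: float,
    depth: int,
    sbfc: float,
) -> Tuple[MetabolicModel, ObjectiveSpec, GroundTruth]:
    m = MetabolicModel(id="toy_organ", compartments={"b", "c", "u"})

    def met(mid: str, comp: str) -> None:
        m.add_metabolite(Metabolite(id=mid, compartment=comp))

    truth = GroundTruth()
    core_genes: List[str] = []

    # --- secretion with a unique synthesis route (total-loss plant) -------
    for mid, comp in (("ppre_b", "b"), ("ppre_c", "c"), ("pgi2_c", "c"), ("pgi2_u", "u")):
        met(mid, comp)
    m.add_boundary_reaction("ppre_b", "exchange", -VMAX, sbfc)
    m.add_reaction(
        Reaction(
            "T_ppre",
            {"ppre_b": -1, "ppre_c": 1},
            0,
            VMAX,
            gpr=or_node(gene_leaf("iso1"), gene_leaf("iso2")),
            kind="transport",
            subsystem="core_secretion",
        )
    )
    m.add_reaction(
        Reaction(
            "R_pgi2_synth",
            {"ppre_c": -1, "pgi2_c": 1},
            0,
            VMAX,
            gpr=and_node(gene_leaf("secA"), gene_leaf("secB")),
            subsystem="core_secretion",
        )
    )
    m.add_reaction(
        Reaction(
            "T_pgi2",
            {"pgi2_c": -1, "pgi2_u": 1},
            0,
            VMAX,
            kind="transport",
            subsystem="core_secretion",
        )
    )
    m.add_boundary_reaction("pgi2_u", "exchange", 0.0, sbfc)
    comp_p = "pgi2_u_secretion"
    truth.planted_total_loss += [("secA", comp_p), ("secB", comp_p)]
    truth.planted_no_phenotype += ["iso1", "iso2"]
    core_genes += ["iso1", "iso2", "secA", "secB"]

    # --- reabsorption with direct + indirect routes (partial plants) ------
    cap_dir = int(rng.integers(6, 13))
    cap_ind = int(rng.integers(2, 6))
    total = float(cap_dir + cap_ind)
    for mid, comp in (("glc_b", "b"), ("glc_c", "c"), ("g6p_c", "c")):
        met(mid, comp)
    m.add_boundary_reaction("glc_b", "exchange", -VMAX, sbfc)
    m.add_reaction(
        Reaction(
            "T_glc_direct",
            {"glc_b": -1, "glc_c": 1},
            0,
            cap_dir,
            gpr=gene_leaf("dirT"),
            kind="transport",
            subsystem="core_reabsorption",
        )
    )
    m.add_reaction(
        Reaction(
            "T_glc_indirect",
            {"glc_b": -1, "g6p_c": 1},
            0,
            cap_ind,
            gpr=gene_leaf("indA"),
            kind="transport",
            subsystem="core_reabsorption",
        )
    )
    m.add_reaction(
        Reaction(
            "R_g6p_to_glc",
            {"g6p_c": -1, "glc_c": 1},
            0,
            VMAX,
            gpr=gene_leaf("indB"),
            subsystem="core_reabsorption",
        )
    )
    m.add_boundary_reaction("glc_c", "demand", 0.0, VMAX)
    comp_g = "glc_c_reabsorption"
    truth.planted_partial += [
        ("dirT", comp_g, cap_ind / total),
        ("indA", comp_g, cap_dir / total),
        ("indB", comp_g, cap_dir / total),
    ]
    core_genes += ["dirT", "indA", "indB"]

    # --- drug-targeted primary route with genetic backup (cryptic plant) --
    for mid, comp in (("hpre_b", "b"), ("hpre_c", "c"), ("hip_c", "c"), ("hip_u", "u")):
        met(mid, comp)
    m.add_boundary_reaction("hpre_b", "exchange", -VMAX, sbfc)
    m.add_reaction(
        Reaction(
            "T_hpre",
            {"hpre_b": -1, "hpre_c": 1},
            0,
            VMAX,
            kind="transport",
            subsystem="core_cryptic",
        )
    )
    m.add_reaction(
        Reaction(
            "R_hip_primary",
            {"hpre_c": -1, "hip_c": 1},
            0,
            VMAX,
            gpr=gene_leaf("prim"),
            subsystem="core_cryptic",
        )
    )
    m.add_reaction(
        Reaction(
            "R_hip_backup",
            {"hpre_c": -1, "hip_c": 1},
            0,
            VMAX,
            gpr=gene_leaf("back"),
            subsystem="core_cryptic",
        )
    )
    m.add_reaction(
        Reaction(
            "T_hip",
            {"hip_c": -1, "hip_u": 1},
            0,
            VMAX,
            kind="transport",
            subsystem="core_cryptic",
        )
    )
    m.add_boundary_reaction("hip_u", "exchange", 0.0, sbfc)
    comp_h = "hip_u_secretion"
    truth.drug_targets.add("offtarget1", genes=["prim"])
    truth.planted_cryptic.append(("back", "offtarget1", comp_h))
    core_genes += ["prim", "back"]

    # --- decoy pathways ---------------------------------------------------
    decoy_genes: List[str] = []
    for k in range(n_pathways):
        dead_end = k % 2 == 1  # alternate flux-capable and dead-end decoys
        prev = f"d{k}_0_b"
        met(prev, "b")
        m.add_boundary_reaction(prev, "exchange", -VMAX, sbfc)
        for j in range(depth):
            nxt = f"d{k}_{j + 1}_c"
            met(nxt, "c")
            gene = f"dg{k}_{j}"
            decoy_genes.append(gene)
            if rng.random() < redundancy_prob:
                gene2 = f"dg{k}_{j}x"
                decoy_genes.append(gene2)
                gpr = or_node(gene_leaf(gene), gene_leaf(gene2))
            else:
                gpr = gene_leaf(gene)
            rid = f"R_d{k}_{j}"
            m.add_reaction(
                Reaction(
                    rid,
                    {prev: -1, nxt: 1},
                    0,
                    VMAX,
                    gpr=gpr,
                    subsystem=f"decoy_{k}",
                    kind="transport" if j == 0 else "enzymatic",
                )
            )
            if dead_end:
                truth.planted_inactive_reactions.append(rid)
            prev = nxt
        if not dead_end:
            m.add_boundary_reaction(prev, "demand", 0.0, VMAX)

    spec = ObjectiveSpec(
        components=[
            ("pgi2_u", "secretion"),
            ("glc_c", "reabsorption"),
            ("hip_u", "secretion"),
        ],
        uptake_reactions={"glc_c": "EX_glc_b"},
    )
    truth.components = [
        ObjectiveComponent(
            id=comp_p,
            metabolite_id="pgi2_u",
            direction="secretion",
            boundary_reaction_id="EX_pgi2_u",
        ),
        ObjectiveComponent(
            id=comp_g,
            metabolite_id="glc_c",
            direction="reabsorption",
            boundary_reaction_id="DM_glc_c",
            uptake_reaction_id="EX_glc_b",
        ),
        ObjectiveComponent(
            id=comp_h,
            metabolite_id="hip_u",
            direction="secretion",
            boundary_reaction_id="EX_hip_u",
        ),
    ]
    truth.expressed_gene_set = list(core_genes)
    all_components = [comp_p, comp_g, comp_h]
    for g in truth.planted_no_phenotype + ["prim"] + decoy_genes:
        for cid in all_components:
            truth.safe_negatives.append((g, cid))
    # plants are silent for the components they do not touch
    truth.safe_negatives += [("secA", comp_g), ("secB", comp_h), ("dirT", comp_p)]
    return m, spec, truth


def generate_evidence(model: MetabolicModel, truth: GroundTruth) -> EvidenceTable:
    """Evidence flags consistent with the generated network's bounds.

    Blood-side exchange metabolites are flagged blood+tissue (freely
    exchangeable), urine-side secretion products urine+tissue with the
    secretion-objective override.
    """
    secretion_mets = {
        c.metabolite_id for c in truth.components if c.direction == "secretion"
    }
    flags: Dict[str, EvidenceFlags] = {}
    for rxn in model.exchanges():
        met_id = next(iter(rxn.stoichiometry))
        compartment = model.metabolite(met_id).compartment
        if met_id in secretion_mets or compartment == "u":
            flags[met_id] = EvidenceFlags(
                detected_urine=True,
                detected_tissue=True,
                curated_secretion_objective=met_id in secretion_mets,
            )
        else:
            flags[met_id] = EvidenceFlags(detected_blood=True, detected_tissue=True)
    return EvidenceTable(flags=flags)


def generate_expression(
    model: MetabolicModel,
    seed: int,
    expressed_genes,
    mu_on: float = 1500.0,
    mu_off: float = 400.0,
    sigma: float = 100.0,
    probes_per_gene: int = 3,
    dropout_prob: float = 0.05,
    scale_factor: float = 2.0,
    bias_exponent: float = 0.1,
) -> Tuple[Dict[str, float], Dict[str, float], Dict[str, str], set]:
    """Two-replicate probe tables with a planted on/off expression mixture.

    Genes in ``expressed_genes`` draw probe intensities from
    Normal(mu_on, sigma^2), all other model genes from
    Normal(mu_off, sigma^2); intensities are truncated at zero
    (background-subtracted arrays are nonnegative). Replicate 2 is
    scaled by ``scale_factor`` and distorted by an intensity-dependent
    multiplicative bias ``(x / mu_off)^bias_exponent`` so the lowess
    step has a trend to remove. A ``dropout_prob`` share of genes gets
    no probesets at all, exercising the unpenalized no-data path.

    Returns (replicate 1, replicate 2, probeset-to-gene map, the
    expressed genes that were actually given probesets).
    """
    if mu_on <= mu_off:
        raise ValueError("mu_on must exceed mu_off")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    expressed = set(expressed_genes)
    rep1: Dict[str, float] = {}
    rep2: Dict[str, float] = {}
    probe_map: Dict[str, str] = {}
    measured_on: set = set()
    for gene in sorted(model.genes()):
        if rng.random() < dropout_prob:
            continue
        mu = mu_on if gene in expressed else mu_off
        if gene in expressed:
            measured_on.add(gene)
        for i in range(probes_per_gene):
            probe = f"p_{gene}_{i}"
            probe_map[probe] = gene
            x1 = max(0.0, float(rng.normal(mu, sigma)))
            x2 = max(0.0, float(rng.normal(mu, sigma)))
            bias = (max(x2, 1e-6) / mu_off) ** bias_exponent
            rep1[probe] = x1
            rep2[probe] = scale_factor * x2 * bias
    return rep1, rep2, probe_map, measured_on


def generate_benchmark(
    ground_truth: GroundTruth, n_negatives: int = 6, seed: int = 0
) -> BenchmarkTable:
    """Clinical-style benchmark: planted disorders as positives, safe pairs as negatives."""
    records = []
    for gene, comp in ground_truth.planted_total_loss:
        records.append((gene, comp, "positive"))
    for gene, comp, _ratio in ground_truth.planted_partial:
        records.append((gene, comp, "positive"))
    rng = np.random.default_rng(seed)
    pool = list(ground_truth.safe_negatives)
    if n_negatives > len(pool):
        raise ValueError(f"only {len(pool)} safe negative pairs available")
    idx = rng.choice(len(pool), size=n_negatives, replace=False)
    for i in sorted(idx):
        gene, comp = pool[i]
        records.append((gene, comp, "negative"))
    return BenchmarkTable.from_records(records)
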