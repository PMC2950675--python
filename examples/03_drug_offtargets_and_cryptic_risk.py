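"""Drug off-target inhibition and cryptic genetic risk factors.

The drug-target map links each predicted off-target to the genes (and
hence reactions) it inhibits. Per-target rows show the phenotype of
inhibiting one target; the ALL row inhibits every target at once.
A cryptic risk factor is a gene whose deletion is silent in the
untreated model but produces a disorder ratio under drug treatment.
"""

from organflux import (
    TargetMap,
    find_cryptic_risk_factors,
    generate_toy_organ,
    scan_drug_targets,
    scan_gene_deletions,
)

model, spec, truth = generate_toy_organ(seed=1)
targets: TargetMap = truth.drug_targets

drug = scan_drug_targets(model, targets, truth.components)
print("drug-target scan (rows: targets + ALL):")
print(drug.data.round(3))
print()

genes = sorted(g for g in model.genes() if not g.startswith("dg"))
untreated = scan_gene_deletions(model, genes, truth.components)
treated = scan_gene_deletions(model, genes, truth.components, treatment=targets)
cryptic = find_cryptic_risk_factors(untreated, treated)
for gene, comp in cryptic:
    print(f"cryptic risk factor: {gene} (silent alone, "
          f"treated ratio {treated.ratio(gene, comp):.3f} for {comp})")
print("planted:", [(g, c) for g, _t, c in truth.planted_cryptic])
# the backup-route gene is silent alone because the drug-targeted primary
# route covers the function; with the drug on board the backup is the only
# route left and its deletion abolishes the secretion
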