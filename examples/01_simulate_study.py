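"""Generate a synthetic two-genotype drought study and inspect its truth.

The bundle mirrors the field design the pipeline targets: 2 genotypes x
2 conditions x 6 timepoints (A-F) x 3 replicates, with planted
drought-responsive genes, development-dependent genes, trait-coupled key
metabolites and pathway-linked candidate genes.
"""

from droughtmine import SimulationSpec, generate_dataset

spec = SimulationSpec(n_genes=500, n_metabolites=40, n_key_metabolites=3,
                      n_candidate_genes=6, n_single_genotype_metabolites=4,
                      rng_seed=1)
bundle = generate_dataset(spec)

print(f"expression matrix: {bundle.expression.shape[0]} genes x "
      f"{bundle.expression.shape[1]} samples")
print(f"metabolite table:  {bundle.metabolites.shape[0]} metabolites")
print(f"trait table:       {len(bundle.traits)} plot-level rows")
truth = bundle.truth
print(f"planted: {len(truth.responsive_effects)} drought-responsive genes, "
      f"{len(truth.developmental_effects)} development-dependent genes,")
print(f"         {len(truth.key_metabolites)} key metabolites, "
      f"{len(truth.candidate_genes)} candidate genes")
for gene, info in truth.candidate_genes.items():
    print(f"  candidate {gene} <- metabolite {info['metabolite']} "
          f"({info['trait']}-coupled) via pathway {info['pathway']}")
# Every planted feature is recorded, so downstream stages are testable by
# recovery: the pipeline should rediscover exactly these candidates.
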