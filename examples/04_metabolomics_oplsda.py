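"""GC/MS peak-table statistics: normalization, PCA, OPLS-DA, VIP, DM calls.

Peak intensities are normalized to each sample's total, mean-centered and
unit-variance scaled; OPLS-DA separates drought from well-watered samples
per drought period; metabolites with VIP > 1.0 and univariate p < 0.05 are
differential metabolites (DMs).
"""

import numpy as np

from droughtmine import (
    AnalysisConfig, SimulationSpec, call_differential_metabolites,
    generate_dataset, normalize_sum_intensity, opls_da, pca,
)
from droughtmine.metabolome import autoscale, shared_metabolites

bundle = generate_dataset(SimulationSpec(n_genes=50, n_metabolites=60,
                                         fraction_responsive=0.2,
                                         n_key_metabolites=4, n_candidate_genes=4,
                                         n_single_genotype_metabolites=5, rng_seed=2))
config = AnalysisConfig()
normalized = normalize_sum_intensity(bundle.metabolites)
shared = shared_metabolites(normalized, bundle.metadata)
print(f"{len(shared)}/{len(normalized)} metabolites detected in both genotypes "
      "(only these enter cross-genotype comparisons)")

# PCA of the tolerant genotype's severe-period samples
meta = bundle.metadata
cols = meta[(meta.genotype == "tolerant") & meta.timepoint.isin(["C", "D", "E"])].index
X = normalized.loc[shared, cols].T
scaled, _, _ = autoscale(np.log2(X))
scores, _, ev = pca(scaled, n_components=2)
print(f"PCA explained variance (first two components): "
      f"{ev[0]:.1f}, {ev[1]:.1f} (scaled units)")

period_map = {"A": "I", "B": "I", "C": "II", "D": "II", "E": "II", "F": "III"}
dm_table, models = call_differential_metabolites(
    normalized, meta, "tolerant", period_map, config, restrict_to=shared)
model = models["II"]
print(f"severe-period OPLS-DA: R2X={model.r2x:.2f}, R2Y={model.r2y:.2f}, "
      f"{model.n_orthogonal} orthogonal component(s)")
hits = dm_table[dm_table.is_dm]
print(f"differential metabolites (VIP>1 & p<0.05): {len(hits)} calls")
planted = set(bundle.truth.key_metabolites)
print(f"planted key metabolites among severe-period DMs: "
      f"{sorted(planted & set(hits[hits.period == 'II'].metabolite_id))}")
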