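"""Gene-set enrichment and patient clustering on the differential signature.

Genes are ranked by signal-to-noise between high and low expressers; the
planted module is tested with the weighted Kolmogorov-Smirnov enrichment
score under phenotype permutation.  Patients are then clustered on
1 - Pearson r over the differential genes (complete linkage).
"""

import numpy as np

import survscreen as ss

matrix, clinical, truth = ss.generate_cohort(ss.SyntheticCohortSpec(n_probes=500, seed=7))
groups = ss.assign_subgroups(ss.scale_probe(matrix.probe(truth.biomarker_probe)))

gsea = ss.gsea_permutation_p(
    matrix, groups.low_ids, groups.high_ids, truth.module_probes,
    set_name="planted_module", n_perm=1000, seed=7,
)
print(f"{gsea.set_name}: ES={gsea.es:.3f}, NES={gsea.nes:.2f}, "
      f"permutation p={gsea.p_perm:.4g} ({gsea.n_permutations} permutations)")

# patient clustering needs gene-to-gene heterogeneity in the group signature
# (a signature with one shared fold change is a per-patient constant offset,
# which correlation distance removes), so plant a heterogeneous two-group
# structure the way a real differential signature behaves
import pandas as pd

rng = np.random.default_rng(7)
n_genes, per_group = 40, 20
signature = rng.normal(0, 2, size=n_genes)  # gene-specific effect sizes
a = rng.normal(0, 1, (n_genes, per_group)) + signature[:, None]
b = rng.normal(0, 1, (n_genes, per_group)) - signature[:, None]
planted = ss.ExpressionMatrix(pd.DataFrame(
    np.hstack([a, b]),
    index=[f"G{i}" for i in range(n_genes)],
    columns=[f"S{j}" for j in range(2 * per_group)],
))
dendro, corr = ss.patient_cluster(planted)
labels = dendro.cut(2)
truth_labels = np.array([0] * per_group + [1] * per_group)
pred = np.array([labels[s] for s in planted.sample_ids]) - 1
agreement = max(np.mean(pred == truth_labels), np.mean(pred != truth_labels))
print(f"patient clustering (planted heterogeneous signature): 2-cluster cut "
      f"matches group membership for {agreement:.0%} of patients")
print("-> a positive ES with small p says module genes concentrate at the top of the")
print("   ranking; the cluster cut recovers the groups when the signature varies by gene")
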