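"""Simulate a backcross, attach a phenotype, plant outliers, write a CSV.

The map has 4 chromosomes with 15 markers at 10 cM spacing; four unlinked
QTLs at markers C1M3/C2M6/C3M4/C4M4 contribute half the phenotypic variance.
"""
import numpy as np

import betaqtl as bq

gmap = bq.sim_map(n_chr=4, n_markers=15, spacing_cM=10.0)
cross = bq.sim_cross(gmap, n=300, cross_type="bc", seed=1)
qtls = [
    bq.QTLSpec("1", 20.0, 2.12),
    bq.QTLSpec("2", 50.0, -1.23),
    bq.QTLSpec("3", 30.0, -1.46),
    bq.QTLSpec("4", 30.0, 1.74),
]
cross = bq.sim_phenotype(cross, qtls, heritability=0.5, seed=2)

g = bq.genetic_values(cross, qtls)
h2 = np.var(g, ddof=1) / np.var(cross.phenotype, ddof=1)
print(f"simulated {cross.n} individuals, {cross.map.n_markers} markers")
print(f"realized heritability: {h2:.3f}  (target 0.5)")

# contaminate 5% of phenotypes with ~+8 SD shifts, the robustness stressor
y_cont, idx = bq.contaminate(
    cross.phenotype, bq.ContaminationConfig(rate=0.05, seed=3)
)
flagged = bq.outlier_flags(y_cont)
print(f"contaminated {idx.size} observations; "
      f"{flagged.sum()} flagged by the Q3+3*IQR rule")

bq.write_cross_csv(cross.with_phenotype(y_cont), "contaminated_cross.csv")
print("wrote contaminated_cross.csv (qtl-cross CSV dialect)")
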