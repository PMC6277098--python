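"""Choosing the robustness parameter beta by K-fold cross-validation.

The held-out beta0-divergence criterion picks near-zero beta on clean data
(the robust fit then coincides with classical CIM) and a clearly positive
beta once outliers contaminate the phenotype — beta selection doubles as an
outlier diagnostic.
"""
import numpy as np

import betaqtl as bq
from betaqtl.cv import DEFAULT_BETA_GRID
from betaqtl.studies import cofactor_design, simulate_unlinked

for label, contaminated in (("clean", False), ("5% outliers", True)):
    cross = simulate_unlinked(seed=15, contaminated=contaminated)
    cof = bq.select_cofactors(cross)
    X = cofactor_design(cross, cof)
    res = bq.cv_select_beta(
        cross.phenotype, X, beta_grid=DEFAULT_BETA_GRID, K=10, beta0=0.1, seed=16
    )
    print(f"--- {label} ---")
    for b, s in zip(res.beta_grid, res.scores):
        marker = "  <-- selected" if b == res.beta_opt else ""
        print(f"  beta={b:<6g} heldout score={s:.6f}{marker}")
    print(f"  beta_opt = {res.beta_opt:g}\n")
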