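"""Replicated simulation studies: detection power, effect estimation, beta CV.

Two standard designs are bundled:

* the unlinked design — a backcross of n=300 on 4 chromosomes x 15 markers
  at 10 cM, QTLs at markers C1M3/C2M6/C3M4/C4M4 with effects
  2.12/-1.23/-1.46/1.74 and 50% heritability;
* the linked design — 4 chromosomes x 16 markers at 10 cM carrying 10 QTLs
  (9 clustered on the first three chromosomes), fitted jointly.

Contaminated variants shift 5% of phenotypes by about +8 clean-SD.  Study
replicates derive their seeds as base_seed + replicate_index, so any single
replicate can be re-run in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cv import DEFAULT_BETA_GRID, cv_select_beta
from .data import ContaminationConfig, CrossData, QTLSpec
from .em import fit
from .genetics import design_matrix, interval_qtl_probs, joint_qtl_probs
from .scan import (
    CofactorSet,
    genome_scan,
    marker_codes,
    permutation_threshold,
    select_cofactors,
    threshold_from_null_sample,
)
from .simulate import contaminate, mse, sim_cross, sim_map, sim_phenotype

#: unlinked-QTL design: (chromosome, marker, position cM, additive effect)
UNLINKED_QTLS = (
    ("1", "C1M3", 20.0, 2.12),
    ("2", "C2M6", 50.0, -1.23),
    ("3", "C3M4", 30.0, -1.46),
    ("4", "C4M4", 30.0, 1.74),
)
UNLINKED_GEOMETRY = dict(n_chr=4, n_markers=15, spacing_cM=10.0)
UNLINKED_H2 = 0.5

#: linked-QTL design (10 QTLs, positions at markers of a 4 x 16 @ 10 cM map)
LINKED_QTLS = (
    ("1", "C1M3", 20.0, 0.42),
    ("1", "C1M6", 50.0, 0.75),
    ("1", "C1M12", 110.0, 0.58),
    ("2", "C2M2", 10.0, 1.02),
    ("2", "C2M6", 50.0, -1.23),
    ("2", "C2M9", 80.0, -1.26),
    ("3", "C3M4", 30.0, -0.46),
    ("3", "C3M8", 70.0, 1.61),
    ("3", "C3M14", 130.0, 0.88),
    ("4", "C4M4", 30.0, 0.74),
)
LINKED_GEOMETRY = dict(n_chr=4, n_markers=16, spacing_cM=10.0)
LINKED_H2 = 0.7

DEFAULT_N = 300
CONTAMINATION_RATE = 0.05


def _qtl_specs(design) -> list[QTLSpec]:
    return [QTLSpec(chrom=c, position_cM=p, additive_effect=a) for c, _, p, a in design]


def simulate_unlinked(
    seed: int, n: int = DEFAULT_N, contaminated: bool = False, h2: float = UNLINKED_H2
) -> CrossData:
    """One replicate of the unlinked-QTL backcross design."""
    gmap = sim_map(**UNLINKED_GEOMETRY)
    cross = sim_cross(gmap, n, "bc", seed=seed)
    cross = sim_phenotype(cross, _qtl_specs(UNLINKED_QTLS), h2, seed=seed + 500_000)
    if contaminated:
        cfg = ContaminationConfig(rate=CONTAMINATION_RATE, seed=seed + 900_000)
        y, _ = contaminate(cross.phenotype, cfg)
        cross = cross.with_phenotype(y)
    return cross


def simulate_linked(
    seed: int, n: int = DEFAULT_N, contaminated: bool = False, h2: float = LINKED_H2
) -> CrossData:
    """One replicate of the linked-QTL backcross design."""
    gmap = sim_map(**LINKED_GEOMETRY)
    cross = sim_cross(gmap, n, "bc", seed=seed)
    cross = sim_phenotype(cross, _qtl_specs(LINKED_QTLS), h2, seed=seed + 500_000)
    if contaminated:
        cfg = ContaminationConfig(rate=CONTAMINATION_RATE, seed=seed + 900_000)
        y, _ = contaminate(cross.phenotype, cfg)
        cross = cross.with_phenotype(y)
    return cross


def cofactor_design(cross: CrossData, cofactors: CofactorSet) -> np.ndarray:
    """Intercept + cofactor codes, the scan's null-model matrix."""
    cols = [np.ones((cross.n, 1))]
    cols += [marker_codes(cross, m) for m in cofactors.markers]
    return np.hstack(cols)


def select_beta_for_cross(
    cross: CrossData,
    cofactors: CofactorSet | None = None,
    beta_grid=DEFAULT_BETA_GRID,
    K: int = 10,
    beta0: float = 0.1,
    seed: int | None = None,
) -> float:
    """CV-selected beta with X matching the scan's null model."""
    if cofactors is None:
        cofactors = select_cofactors(cross)
    X = cofactor_design(cross, cofactors)
    return cv_select_beta(
        cross.phenotype, X, beta_grid=beta_grid, K=K, beta0=beta0, seed=seed
    ).beta_opt


@dataclass
class PowerStudyResult:
    """Per-method power/estimate summaries of a replicated power study."""

    methods: tuple[str, ...]
    qtl_markers: tuple[str, ...]
    true_effects: dict[str, float]
    lods: dict[str, np.ndarray]  # method -> (reps, n_qtl)
    effects: dict[str, np.ndarray]
    thresholds: dict[str, float]
    betas: np.ndarray  # per-replicate cv-selected beta (betacim)
    n_reps: int

    def power(self, method: str, marker: str) -> float:
        j = self.qtl_markers.index(marker)
        return float(100.0 * np.mean(self.lods[method][:, j] > self.thresholds[method]))

    def mean_effect(self, method: str, marker: str) -> float:
        j = self.qtl_markers.index(marker)
        return float(np.mean(self.effects[method][:, j]))

    def se_effect(self, method: str, marker: str) -> float:
        j = self.qtl_markers.index(marker)
        return float(np.std(self.effects[method][:, j], ddof=1))

    def summary_table(self):
        import pandas as pd

        rows = []
        for m in self.qtl_markers:
            row = {"marker": m, "effect": self.true_effects[m]}
            for meth in self.methods:
                row[f"{meth}_estimate"] = round(self.mean_effect(meth, m), 3)
                row[f"{meth}_se"] = round(self.se_effect(meth, m), 3)
                row[f"{meth}_power"] = round(self.power(meth, m), 1)
            rows.append(row)
        return pd.DataFrame(rows)


def run_power_study(
    n_reps: int = 100,
    contaminated: bool = False,
    methods=("im", "cim", "betacim"),
    n_perm: int = 100,
    thr_reps: int = 4,
    seed: int = 0,
    n: int = DEFAULT_N,
    step_cM: float = 10.0,
    beta_grid=DEFAULT_BETA_GRID,
) -> PowerStudyResult:
    """Replicated unlinked-design study: LOD and effect at each true QTL.

    Per replicate: simulate, select cofactors (cim/betacim), CV-select beta
    (betacim), scan, and record LOD/effect at the four QTL markers.
    Permutation null samples from the first ``thr_reps`` replicates are
    pooled into one genome-wide threshold per method.
    """
    markers = tuple(m for _, m, _, _ in UNLINKED_QTLS)
    qtl_pos = [(c, p) for c, _, p, _ in UNLINKED_QTLS]
    lods = {meth: np.empty((n_reps, len(markers))) for meth in methods}
    effects = {meth: np.empty((n_reps, len(markers))) for meth in methods}
    null_pool = {meth: [] for meth in methods}
    betas = np.empty(n_reps)

    for rep in range(n_reps):
        rep_seed = seed + rep
        cross = simulate_unlinked(rep_seed, n=n, contaminated=contaminated)
        cof = select_cofactors(cross) if set(methods) - {"im"} else CofactorSet(())
        beta = (
            select_beta_for_cross(
                cross, cof, beta_grid=beta_grid, seed=rep_seed + 700_000
            )
            if "betacim" in methods
            else 0.0
        )
        betas[rep] = beta
        for meth in methods:
            res = genome_scan(
                cross,
                method=meth,
                beta=beta if meth == "betacim" else 0.0,
                cofactors=None if meth == "im" else cof,
                step_cM=step_cM,
            )
            for j, (c, p) in enumerate(qtl_pos):
                lods[meth][rep, j] = res.lod_at(c, p)
                effects[meth][rep, j] = res.effect_at(c, p)
            if rep < thr_reps:
                thr = permutation_threshold(
                    cross,
                    method=meth,
                    beta=beta if meth == "betacim" else 0.0,
                    cofactors=None if meth == "im" else cof,
                    n_perm=n_perm,
                    seed=rep_seed + 800_000,
                    step_cM=step_cM,
                )
                null_pool[meth].append(thr.null_max)

    thresholds = {
        meth: threshold_from_null_sample(np.concatenate(null_pool[meth]), 0.05).value
        for meth in methods
    }
    return PowerStudyResult(
        methods=tuple(methods),
        qtl_markers=markers,
        true_effects={m: a for _, m, _, a in UNLINKED_QTLS},
        lods=lods,
        effects=effects,
        thresholds=thresholds,
        betas=betas,
        n_reps=n_reps,
    )


def joint_effect_estimates(
    cross: CrossData, design=LINKED_QTLS, beta: float = 0.0
) -> np.ndarray:
    """Jointly estimate all QTL effects of a design at their true positions.

    Builds the multi-QTL genetic design matrix and the joint conditional
    class probabilities (row-wise products over intervals) and fits the full
    mixture by maximum beta-likelihood with an intercept-only covariate
    matrix.  Returns the estimated additive effects in design order.
    """
    k = len(design)
    D = design_matrix(cross.cross_type, k)
    parts = [interval_qtl_probs(cross, c, p) for c, _, p, _ in design]
    probs = joint_qtl_probs(parts)
    X = np.ones((cross.n, 1))
    res = fit(cross.phenotype, X, probs, D, beta=beta)
    return res.theta_hat.E.copy()


def run_linked_mse_study(
    n_seeds: int = 10,
    contaminated: bool = False,
    seed: int = 0,
    n: int = DEFAULT_N,
    beta: float | str = "cv",
    beta_grid=DEFAULT_BETA_GRID,
) -> dict:
    """Linked-design MSE of the 10 jointly estimated effects, averaged over seeds.

    ``beta="cv"`` selects beta per replicate by cross-validation under the
    intercept-only null; a float fixes it (0.0 gives the classical fit).
    """
    true = np.array([a for _, _, _, a in LINKED_QTLS])
    mses, betas, est_all = [], [], []
    for i in range(n_seeds):
        rep_seed = seed + i
        cross = simulate_linked(rep_seed, n=n, contaminated=contaminated)
        if beta == "cv":
            b = cv_select_beta(
                cross.phenotype,
                np.ones((cross.n, 1)),
                beta_grid=beta_grid,
                seed=rep_seed + 700_000,
            ).beta_opt
        else:
            b = float(beta)
        est = joint_effect_estimates(cross, LINKED_QTLS, beta=b)
        mses.append(mse(true, est))
        betas.append(b)
        est_all.append(est)
    return {
        "mse_mean": float(np.mean(mses)),
        "mse_per_seed": np.asarray(mses),
        "betas": np.asarray(betas),
        "estimates": np.asarray(est_all),
        "true_effects": true,
    }


def run_beta_selection_study(
    n_reps: int = 100,
    contamination_rates=(0.0,),
    seed: int = 0,
    n: int = DEFAULT_N,
    beta_grid=DEFAULT_BETA_GRID,
    with_cofactors: bool = True,
) -> dict[float, np.ndarray]:
    """CV-selected beta across replicates at each contamination rate.

    Returns {rate: array of selected betas}; medians rise with the
    contamination rate, the diagnostic behaviour the selector exists for.
    """
    out: dict[float, np.ndarray] = {}
    for rate in contamination_rates:
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            rep_seed = seed + rep
            cross = simulate_unlinked(rep_seed, n=n, contaminated=False)
            if rate > 0:
                cfg = ContaminationConfig(rate=rate, seed=rep_seed + 900_000)
                y, _ = contaminate(cross.phenotype, cfg)
                cross = cross.with_phenotype(y)
            cof = select_cofactors(cross) if with_cofactors else CofactorSet(())
            vals[rep] = select_beta_for_cross(
                cross, cof, beta_grid=beta_grid, seed=rep_seed + 700_000
            )
        out[rate] = vals
    return out
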