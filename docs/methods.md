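# Methods

## Model and estimation

A single tested position contributes a latent QTL genotype per individual.
Given the two flanking markers, the class prior `p_ji` follows from the
Haldane map function r = (1 − e^(−2d/100))/2 by exact enumeration of gamete
chains — one segregating F1 gamete for a backcross, two independent gametes
for an intercross. Conditioning is on the flanking pair only (standard
interval mapping), not the full multipoint chain; at a typed marker the
prior degenerates to the observed genotype. For k jointly modelled QTLs the
priors multiply row-wise (valid under no interference) and the genetic
design matrix grows to 2^k × k (backcross, ±½ coding) or 3^k × 2k
(intercross, additive 1/0/−1 and dominance −½/+½/−½ per QTL); pairwise
epistasis columns are products of additive columns. Class order is fixed at
descending Q-allele count everywhere, so mixing-probability columns and
design rows always align.

The fit maximizes the β-likelihood

    L_β(θ) = (1/β) [ (1/n) Σ_j f(y_j|θ,X_j)^β / l_β,j − 1 ],
    l_β,j = [∫ f(y|θ,X_j)^(β+1) dy]^(β/(β+1)),

computed as `expm1(β·log f − log l_β)/β` for numerical continuity at β → 0,
where it reduces to the mean log-likelihood. The normalizer is per
observation: for any single-Gaussian row (null model, degenerate priors, or
coincident class means) it has the closed form
(2πσ²)^(−β/2)(β+1)^(−1/2) raised to β/(β+1) — notably independent of the
mean — and otherwise it is evaluated by panel Gauss–Legendre quadrature
(10-point panels of width ≈ σ over [min μ − 8σ, max μ + 8σ]), which agrees
with the closed form to better than 1e−8 where both apply.

The maximizer alternates:

* **E-step** Π_β[j,i] = π_ji f(y_j)^β with π the ordinary posterior,
  computed in log space; row sums are the robustness weights f(y_j)^β.
* **M-step** effects E solve the Π_β-weighted normal equations V E = b
  (V_ab = Σ_ji Π[j,i] D_ia D_ib, b = Dᵀ Πᵀ (y − Xγ)); a textbook
  single-sweep recurrence E ← m − M E with the same fixed point is kept
  behind `e_update="jacobi"` for comparison. γ is the f^β-weighted
  least-squares update, and σ² = (1+β) Σ_ji Π[j,i](y_j − μ_ji)² / Σ Π,
  written as the explicit quadratic form so it is nonnegative by
  construction. The (1+β) factor makes the null-model fixed point the exact
  stationary point of L_β (verified against the closed-form normalizer).

Initialization is deterministic: OLS for γ, OLS of residuals on the
expected genotype codes E[D|Q] for E, residual variance for σ². Convergence
is declared when the objective moves less than 1e−8·(1+|L|) (default
max_iter 200); the trace is recorded and is non-decreasing to 1e−10 on all
test fixtures. When β = 0 and every mixing row is degenerate (scans at
typed markers), the latent classes are observed and the fit short-circuits
to exact OLS — the same maximizer, at a fraction of the cost. LOD_β uses
log₁₀(e)·n·(L_alt − L_null); negative values (possible for β > 0, where
objectives are not nested-monotone) are reported as computed.

Robustness is demonstrated numerically rather than symbolically: the
gradient of the per-observation objective with respect to (E, γ, σ²),
evaluated by central differences over a wide phenotype grid, has finite
interior suprema for β > 0 (the e^(−βz²) envelope; the additive component's
supremum sits near z ≈ (2β)^(−1/2)) and boundary-growing suprema at β = 0.

## Scans, cofactors, thresholds

Scan grids include every marker plus interior points at the configured step
(half-open per interval, so markers count once); the default step is 1 cM.
CIM cofactors come from forward stepwise regression on marker codes
(backcross 0/1; intercross additive + dominance pair) minimizing BIC, with
at most min(10, 2√n/ln n) cofactors; at scan time any cofactor within ±10 cM
of the tested interval is dropped (configurable window). Both the criterion
and the window are conventional choices — the method class only requires
"a few strongly associated background markers". Genome-wide thresholds are
empirical (1−α) quantiles of the max-LOD over phenotype permutations;
cofactors and β are held fixed at their observed-data values during
permutation. Peak calling keeps local profile maxima above threshold
separated by at least one marker interval, ties resolved toward lower cM.

## Selecting β

K-fold cross-validation under the no-QTL model: for each candidate β the
single-Gaussian null (intercept + cofactors) is fitted on K−1 folds by
maximum β-likelihood and scored on the held-out fold by the negative
β₀-likelihood (β₀ fixed); the aggregate is minimized, ties toward smaller
β. Defaults: K = 10, β₀ = 0.1, grid
{0.001, 0.005, 0.01, 0.02, 0.041, 0.06, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5}.
Running CV under the null rather than per scan position keeps the cost of a
genome scan linear and matches how the selected β is then used for every
alternative fit. As β₀ → 0 the score converges to the negative mean
held-out log-likelihood.

## The simulator and what passing tests show

Gametes are simulated marker-by-marker (first allele 1:1, then Haldane
recombination per adjacent interval; chromosomes independent; no
interference — matching the probability model the mapper assumes).
Phenotypes add Gaussian noise scaled from the *realized* genetic variance,
σ_e² = Var(g)(1−h²)/h², so each replicate's nominal heritability is exact;
a QTL placed off-marker gets its genotype drawn from the flanking-marker
conditional distribution, which reproduces the correct joint law.
Contamination shifts round(rate·n) distinct phenotypes by draws from
Normal(8·s_y, (2·s_y)²), s_y the clean SD — large enough that shifted
points clear the Q3 + 3·IQR outlier rule almost surely. The magnitude is a
package default, not a reported value: the reference simulations say only
that "random numbers" were added, and classical-method power under
contamination depends directly on this unknown scale. The outlier cluster
is one-sided and fairly concentrated; with heavy contamination (≥10%) the
CV criterion partially accommodates such a cluster and settles on a
somewhat smaller β than at 2–5%, so the β-vs-rate curve is not monotone at
the top end under these defaults (it would be for more scattered
contamination). None of this emulates real-data features like genotyping
error, missing genotypes, non-Gaussian trait scales or polygenic
background, so passing tests certify the estimator under its own model
class, not field performance.

Replicate r of a study uses seed base_seed + r; every stochastic component
(genotypes, noise, contamination indices, CV folds, permutations) descends
from an explicit seed, so any single replicate can be re-run alone.

## Study sizes

The bundled studies run the unlinked design (4 chromosomes × 15 markers at
10 cM, n = 300, effects 2.12/−1.23/−1.46/1.74, h² = 0.5) and the linked
design (4 × 16 markers, 10 QTLs, h² = 0.7; the chromosome-4 QTL sits at
marker C4M4 = 30 cM). The packaged reproduction runs use 20–60 replicates
with thresholds pooled from 3–5 replicates × 40–60 permutations on the
marker grid; thresholds are insensitive to the grid step here (2.26 vs 2.28
at steps 10 and 2 cM on a contaminated replicate) and pooling across
replicates stabilizes the tail quantile at equal cost. Full-size runs
(100+ replicates, 1000 permutations) change no conclusion, only the Monte
Carlo error.

## Known limitations

Missing genotypes are rejected rather than imputed (no multipoint HMM);
dominance-only hypothesis tests, multiple-QTL model search, confidence
intervals for QTL location and non-Gaussian residual families are out of
scope. The joint k-QTL fit enumerates 3^k (or 2^k) classes and is intended
for modest k (the bundled study uses k = 10 at typed markers, where the
class priors are degenerate and the fit stays cheap). Expected joint-fit
MSE at n = 300 is bounded below by the per-coefficient sampling variance
σ_e²/(n·Var(x)) ≈ 0.02 for the linked design; single lucky replicates can
print smaller values, multi-seed averages cannot.
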