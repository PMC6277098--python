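# betaqtl — robust QTL interval mapping by minimum β-divergence

`betaqtl` maps quantitative trait loci (QTLs) in experimental crosses
(backcross and F2 intercross) when the phenotype may carry gross outliers.
It implements classical interval mapping (IM) and composite interval mapping
(CIM) together with their robust counterpart, **BetaCIM**, which replaces
the maximum-likelihood fit by a maximum *β-likelihood* (minimum
β-divergence) fit, plus everything needed to study them: a cross simulator,
permutation significance thresholds, and K-fold cross-validated selection of
the robustness parameter β.

## The model

At a tested genome position, each phenotype *y<sub>j</sub>* follows a
Gaussian mixture over the latent QTL genotype classes

&nbsp;&nbsp;&nbsp;&nbsp;*f*(*y<sub>j</sub>* | θ, X<sub>j</sub>) = σ⁻¹ Σ<sub>i</sub> *p<sub>ji</sub>* φ((*y<sub>j</sub>* − μ<sub>ji</sub>)/σ),&nbsp;&nbsp;&nbsp;&nbsp;μ<sub>ji</sub> = X<sub>j</sub>γ + D<sub>i</sub>E,

where *p<sub>ji</sub>* are the conditional QTL-genotype probabilities given
the flanking markers (Haldane map function, no interference), **D** is the
genetic design matrix (additive/dominance codings; 2<sup>k</sup>×k for k
backcross QTLs, 3<sup>k</sup>×2k for F2), **E** the genetic effects, and
X<sub>j</sub>γ covers the intercept plus CIM cofactors. Instead of the mean
log-likelihood, BetaCIM maximizes

&nbsp;&nbsp;&nbsp;&nbsp;L<sub>β</sub>(θ) = (1/β) [ n⁻¹ Σ<sub>j</sub> *f*(*y<sub>j</sub>*)<sup>β</sup> / ℓ<sub>β</sub> − 1 ],&nbsp;&nbsp;&nbsp;&nbsp;ℓ<sub>β</sub> = [∫ *f*<sup>β+1</sup>]<sup>β/(β+1)</sup>,

by an EM-type algorithm whose E-step computes β-weighted posteriors
Π<sub>β</sub>[j,i] = π<sub>ji</sub> *f*(*y<sub>j</sub>*)<sup>β</sup>. Each
observation is downweighted by *f*(*y<sub>j</sub>*)<sup>β</sup>, so
low-density outliers lose influence; the estimating function is bounded for
β > 0 (B-robustness) and everything reduces to classical ML as β → 0.
Evidence for a QTL is LOD<sub>β</sub> = log₁₀(e) · n · (L<sub>β</sub><sup>alt</sup> −
L<sub>β</sub><sup>null</sup>), thresholded by permutation. β itself is
chosen by K-fold cross-validation of a held-out β₀-divergence score — near
0 on clean traits, clearly positive on contaminated ones.

## A worked example

```python
import betaqtl as bq
from betaqtl.studies import simulate_unlinked

cross = simulate_unlinked(seed=8, contaminated=True)   # 5% gross outliers
cof   = bq.select_cofactors(cross)
cim   = bq.genome_scan(cross, method="cim", cofactors=cof, step_cM=10)
rob   = bq.genome_scan(cross, method="betacim", beta=0.1, cofactors=cof, step_cM=10)
print(f"CIM     lod at C1M3: {cim.lod_at('1', 20.0):5.2f}  a_hat {cim.effect_at('1', 20.0):+.2f}")
print(f"BetaCIM lod at C1M3: {rob.lod_at('1', 20.0):5.2f}  a_hat {rob.effect_at('1', 20.0):+.2f}")
```

prints

```
CIM     lod at C1M3:  2.82  a_hat +2.05
BetaCIM lod at C1M3: 11.89  a_hat +2.21
```

The simulated QTL at marker C1M3 has true effect 2.12 and, on clean data,
a CIM LOD near 20. Planting outliers in 5% of the phenotypes collapses the
classical LOD to 2.8 — below a typical permutation threshold of ≈2.5–3 —
while the β-weighted scan keeps the locus unambiguous (LOD<sub>β</sub> ≈ 12)
and its effect estimate on target. The `examples/` scripts walk through
simulation (`01`), scanning and peak calling (`02`), the robustness
comparison (`03`, source of the numbers above) and β selection (`04`);
a thin CLI (`betaqtl sim|scan|cv|perm|reproduce`) wraps the same functions
for shell use.

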