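"""Simulation of genetic maps, experimental crosses and phenotypes.

Gametes are generated marker-by-marker along each chromosome as a Markov
chain: the first marker's allele segregates 1:1, and each subsequent allele
recombines against the previous one with the Haldane probability implied by
the adjacent map spacing (no crossover interference; chromosomes assort
independently).  Phenotypes are genetic values plus Gaussian noise scaled so
the realized heritability matches the requested one, and an optional
contamination step plants gross additive outliers.
"""
from __future__ import annotations

import numpy as np

from .data import (
    BC,
    F2,
    Chromosome,
    ConfigurationError,
    ContaminationConfig,
    CrossData,
    GeneticMap,
    QTLSpec,
)
from .genetics import interval_qtl_probs, recomb_fraction


def sim_map(n_chr: int, n_markers: int, spacing_cM: float) -> GeneticMap:
    """Equally spaced map: ``n_chr`` chromosomes, markers at 0, s, 2s, ... cM.

    Markers are named ``C{i}M{j}`` with 1-based chromosome and marker indices.
    """
    if n_chr < 1 or n_markers < 2 or not spacing_cM > 0:
        raise ConfigurationError(
            f"invalid map geometry: n_chr={n_chr}, n_markers={n_markers}, "
            f"spacing={spacing_cM}"
        )
    chroms = []
    for c in range(1, n_chr + 1):
        chroms.append(
            Chromosome(
                name=str(c),
                markers=tuple(f"C{c}M{m}" for m in range(1, n_markers + 1)),
                positions_cM=np.arange(n_markers, dtype=float) * spacing_cM,
            )
        )
    return GeneticMap(chromosomes=tuple(chroms))


def _sim_gametes(chrom: Chromosome, n: int, rng: np.random.Generator) -> np.ndarray:
    """n gametes along one chromosome; entry 1 = allele from the Q-carrying parent."""
    k = len(chrom.markers)
    r = recomb_fraction(np.diff(chrom.positions_cM))
    g = np.empty((n, k), dtype=np.int8)
    g[:, 0] = rng.random(n) < 0.5
    for i in range(1, k):
        rec = rng.random(n) < r[i - 1]
        g[:, i] = np.where(rec, 1 - g[:, i - 1], g[:, i - 1])
    return g


def sim_cross(
    gmap: GeneticMap, n: int, cross_type: str = BC, seed: int | None = None
) -> CrossData:
    """Simulate marker genotypes for ``n`` individuals (phenotype unset).

    Backcross individuals carry one segregating F1 gamete (codes QQ=1, Qq=0);
    intercross individuals carry two independent F1 gametes (codes = summed
    Q-allele count, QQ=2, Qq=1, qq=0).
    """
    if n < 1:
        raise ConfigurationError(f"need n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in gmap.chromosomes:
        g = _sim_gametes(chrom, n, rng)
        if cross_type == F2:
            g = g + _sim_gametes(chrom, n, rng)
        elif cross_type != BC:
            raise ConfigurationError(f"unknown cross type {cross_type!r}")
        blocks.append(g)
    return CrossData(cross_type=cross_type, genotypes=np.hstack(blocks), map=gmap)


def _qtl_genotypes(
    cross: CrossData, qtl: QTLSpec, rng: np.random.Generator
) -> np.ndarray:
    """Genotype codes at a QTL: observed if it sits on a marker, else drawn
    from the flanking-marker conditional distribution (exact under no
    interference)."""
    chrom = cross.map.chromosome(qtl.chrom)
    at_marker = np.isclose(chrom.positions_cM, qtl.position_cM)
    if at_marker.any():
        marker = chrom.markers[int(np.argmax(at_marker))]
        return cross.marker_genotypes(marker).astype(float)
    probs = interval_qtl_probs(cross, qtl.chrom, qtl.position_cM)
    codes = np.array([lab[0] for lab in probs.class_labels], dtype=float)
    cum = np.cumsum(probs.Q, axis=1)
    u = rng.random(cross.n)
    idx = (u[:, None] > cum).sum(axis=1)
    return codes[idx]


def genetic_values(cross: CrossData, qtls: list[QTLSpec], seed: int | None = None) -> np.ndarray:
    """Summed genetic value per individual over the given QTLs.

    Backcross coding x* in {1 (QQ), 0 (Qq)}; intercross coding
    x* in {1, 0, -1} with dominance deviation z* in {-1/2, +1/2, -1/2}.
    """
    rng = np.random.default_rng(seed)
    g = np.zeros(cross.n)
    for q in qtls:
        q.validate(cross.map)
        codes = _qtl_genotypes(cross, q, rng)
        if cross.cross_type == BC:
            g += q.additive_effect * codes
        else:
            x = codes - 1.0
            z = np.where(codes == 1, 0.5, -0.5)
            g += q.additive_effect * x + q.dominance_effect * z
    return g


def sim_phenotype(
    cross: CrossData,
    qtls: list[QTLSpec],
    heritability: float,
    seed: int | None = None,
) -> CrossData:
    """Attach a phenotype: y = g + e with e ~ Normal(0, sigma_e^2).

    sigma_e^2 = Var(g) * (1 - h^2) / h^2 uses the realized sample variance of
    the genetic values, so each replicate's nominal heritability is exact by
    construction.
    """
    if not (0.0 < heritability < 1.0):
        raise ConfigurationError(f"heritability must be in (0,1), got {heritability}")
    rng = np.random.default_rng(seed)
    g = genetic_values(cross, qtls, seed=rng.integers(2**31))
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ConfigurationError("genetic values are constant; cannot scale noise")
    sigma_e = np.sqrt(var_g * (1.0 - heritability) / heritability)
    y = g + rng.normal(0.0, sigma_e, size=cross.n)
    return cross.with_phenotype(y)


def contaminate(
    y: np.ndarray, cfg: ContaminationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Shift round(rate*n) distinct observations by large additive draws.

    Shifts are Normal(shift_mean*s_y, (shift_sd*s_y)^2) with s_y the clean
    phenotype SD.  Returns (contaminated copy, sorted shifted indices).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    n_out = int(round(cfg.rate * n))
    out = y.copy()
    rng = np.random.default_rng(cfg.seed)
    idx = np.sort(rng.choice(n, size=n_out, replace=False))
    if n_out:
        s = float(np.std(y, ddof=1))
        out[idx] += rng.normal(cfg.shift_mean * s, cfg.shift_sd * s, size=n_out)
    return out, idx


def outlier_flags(y: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Quartile rule: flag observations outside [Q1 - k*IQR, Q3 + k*IQR]."""
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    return (y > q3 + k * iqr) | (y < q1 - k * iqr)


def mse(true_effects: np.ndarray, estimates: np.ndarray) -> float:
    """Mean squared deviation (1/p) * sum (theta_i - theta_hat_i)^2."""
    t = np.asarray(true_effects, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.size == 0:
        raise ValueError(f"shape mismatch or empty: {t.shape} vs {e.shape}")
    return float(np.mean((t - e) ** 2))


def detection_power(lod_at_position: np.ndarray, threshold: float) -> float:
    """Percent of replicates whose LOD at the position exceeds the threshold."""
    lod = np.asarray(lod_at_position, dtype=float)
    if lod.size == 0:
        raise ValueError("empty LOD vector")
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return float(100.0 * np.mean(lod > threshold))
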