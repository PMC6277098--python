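"""Genetic design matrices and conditional QTL-genotype probabilities.

The interval-mapping likelihood treats the unobserved QTL genotype of each
individual as a latent class whose prior, given the two flanking marker
genotypes, follows from the recombination fractions between markers and the
tested position.  With no crossover interference the Haldane map function
applies and flanking-marker conditioning is exact for a single interval.

Genotype-class order is fixed throughout at descending Q-allele count —
(QQ, Qq) for a backcross, (QQ, Qq, qq) for an intercross — and multi-QTL
classes are ordered lexicographically in that per-QTL order, matching the
rows of the multi-QTL genetic design matrix.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, product

import numpy as np

from .data import BC, F2, GENOTYPE_CODES, ConfigurationError, CrossData


def recomb_fraction(d_cM) -> np.ndarray | float:
    """Haldane recombination fraction r = (1 - exp(-2d/100)) / 2 for d in cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"map distance must be >= 0, got {d_cM}")
    r = -0.5 * np.expm1(-2.0 * d / 100.0)
    return float(r) if np.isscalar(d_cM) else r


@dataclass(frozen=True)
class DesignMatrix:
    """Genetic design matrix D mapping genotype classes to genetic parameters.

    Rows are QTL genotype classes (in the package-wide class order), columns
    are genetic parameters (additive/dominance effects and optional epistasis
    products).  ``class_labels`` gives the genotype-code tuple of each row.
    """

    D: np.ndarray
    columns: tuple[str, ...]
    cross_type: str
    k_qtl: int
    class_labels: tuple[tuple[int, ...], ...]

    @property
    def n_classes(self) -> int:
        return self.D.shape[0]

    @property
    def n_params(self) -> int:
        return self.D.shape[1]


# single-QTL additive/dominance codings, class order (QQ, Qq[, qq])
_BC1 = {1: 1.0, 0: 0.0}
_F2_ADD = {2: 1.0, 1: 0.0, 0: -1.0}
_F2_DOM = {2: -0.5, 1: 0.5, 0: -0.5}


def design_matrix(cross_type: str, k_qtl: int = 1, epistasis=None) -> DesignMatrix:
    """Build the genetic design matrix for ``k_qtl`` jointly modelled QTLs.

    Backcross: k=1 gives the two-class column [1, 0]; k>=2 gives the
    2^k x k matrix with entries +1/2 (QQ) and -1/2 (Qq), so each additive
    effect is the contrast between the two genotype classes in both codings.
    Intercross: 3^k x 2k with per-QTL additive (1, 0, -1) and dominance
    (-1/2, 1/2, -1/2) columns, interleaved as (a1, d1, a2, d2, ...).

    ``epistasis`` may be None, "pairwise" (all pairs), or an explicit list of
    0-based QTL index pairs; epistasis columns are elementwise products of
    the corresponding additive main-effect columns.
    """
    if cross_type not in (BC, F2):
        raise ConfigurationError(f"unsupported cross type {cross_type!r}")
    if k_qtl < 1:
        raise ConfigurationError(f"k_qtl must be >= 1, got {k_qtl}")
    codes = GENOTYPE_CODES[cross_type]
    labels = tuple(product(codes, repeat=k_qtl))

    cols: list[np.ndarray] = []
    names: list[str] = []
    add_cols: list[np.ndarray] = []
    for q in range(k_qtl):
        if cross_type == BC:
            if k_qtl == 1:
                a = np.array([_BC1[lab[q]] for lab in labels])
            else:
                a = np.array([0.5 if lab[q] == 1 else -0.5 for lab in labels])
            cols.append(a)
            names.append("a" if k_qtl == 1 else f"a{q + 1}")
            add_cols.append(a)
        else:
            a = np.array([_F2_ADD[lab[q]] for lab in labels])
            d = np.array([_F2_DOM[lab[q]] for lab in labels])
            cols.extend([a, d])
            names.extend(["a", "d"] if k_qtl == 1 else [f"a{q + 1}", f"d{q + 1}"])
            add_cols.append(a)

    if epistasis is not None:
        pairs = (
            list(combinations(range(k_qtl), 2)) if epistasis == "pairwise" else list(epistasis)
        )
        for i, j in pairs:
            if not (0 <= i < k_qtl and 0 <= j < k_qtl and i != j):
                raise ConfigurationError(f"invalid epistasis pair ({i}, {j})")
            cols.append(add_cols[i] * add_cols[j])
            names.append(f"a{i + 1}:a{j + 1}")

    return DesignMatrix(
        D=np.column_stack(cols),
        columns=tuple(names),
        cross_type=cross_type,
        k_qtl=k_qtl,
        class_labels=labels,
    )


@dataclass(frozen=True)
class MixingProbs:
    """Per-individual conditional QTL-genotype probabilities.

    ``Q[j, i]`` = P(QTL genotype class i | flanking marker genotypes of
    individual j); rows lie on the simplex.  Column order matches
    ``class_labels`` and the rows of the matching DesignMatrix.
    """

    Q: np.ndarray
    class_labels: tuple[tuple[int, ...], ...]
    cross_type: str

    @property
    def n(self) -> int:
        return self.Q.shape[0]


def _gamete_chain(r1: float, r2: float) -> np.ndarray:
    """Joint allele distribution of one F1 gamete at (left, qtl, right).

    Entry [aL, aQ, aR] with allele 1 = the Q-carrying parental allele; the
    chain factorises P(aL) t_{r1}(aL,aQ) t_{r2}(aQ,aR) under no interference.
    """
    P = np.empty((2, 2, 2))
    for aL in (0, 1):
        for aQ in (0, 1):
            for aR in (0, 1):
                p = 0.5
                p *= r1 if aL != aQ else 1.0 - r1
                p *= r2 if aQ != aR else 1.0 - r2
                P[aL, aQ, aR] = p
    return P


def _conditional_table_cached(cross_type: str, r1: float, r2: float) -> np.ndarray:
    """Memoized conditional table (scan grids reuse few (r1, r2) pairs)."""
    return _table_cache(cross_type, round(float(r1), 12), round(float(r2), 12))


@lru_cache(maxsize=4096)
def _table_cache(cross_type: str, r1: float, r2: float) -> np.ndarray:
    return _conditional_table(cross_type, r1, r2)


def _conditional_table(cross_type: str, r1: float, r2: float) -> np.ndarray:
    """P(QTL genotype | left, right marker genotypes) lookup table.

    Shape (gL, gR, class) indexed by genotype codes; class axis follows the
    package-wide descending-code order.
    """
    P1 = _gamete_chain(r1, r2)
    if cross_type == BC:
        # one informative F1 gamete; the backcross parent contributes Qq alleles
        joint = P1  # axes already (gL, gQ, gR) with code 1 = QQ
        n_codes = 2
    else:
        # two independent F1 gametes; genotype code = summed allele count
        joint = np.zeros((3, 3, 3))
        for a in product((0, 1), repeat=3):
            for b in product((0, 1), repeat=3):
                joint[a[0] + b[0], a[1] + b[1], a[2] + b[2]] += P1[a] * P1[b]
        n_codes = 3
    # normalise over the QTL axis given (gL, gR)
    codes = GENOTYPE_CODES[cross_type]
    table = np.zeros((n_codes, n_codes, n_codes))
    for gL in range(n_codes):
        for gR in range(n_codes):
            marg = joint[gL, :, gR].sum()
            if marg > 0:
                table[gL, gR, :] = joint[gL, :, gR] / marg
            else:  # impossible flanking pair (only when r1 or r2 is exactly 0)
                table[gL, gR, :] = np.nan
    # reorder class axis from code 0..max to descending-code class order
    order = [c for c in codes]
    return table[:, :, order]


def _locate_interval(chrom, position_cM: float) -> tuple[int, int]:
    """Indices (iL, iR) of the markers flanking ``position_cM``.

    A position at a marker uses that marker as left flank (right flank is the
    next marker, or the previous one for the chromosome-end marker).
    """
    pos = chrom.positions_cM
    if not (pos[0] <= position_cM <= pos[-1]):
        raise ConfigurationError(
            f"position {position_cM} cM off chromosome {chrom.name} "
            f"(span {pos[0]}..{pos[-1]} cM)"
        )
    iR = int(np.searchsorted(pos, position_cM, side="right"))
    if iR == len(pos):  # at the terminal marker: use the last interval, r2 = 0
        return len(pos) - 2, len(pos) - 1
    return iR - 1, iR


def interval_qtl_probs(cross: CrossData, chrom: str, position_cM: float) -> MixingProbs:
    """Conditional QTL-genotype probabilities at one tested position.

    Conditions on the two markers flanking ``position_cM`` on chromosome
    ``chrom`` (standard interval mapping); at a typed marker the rows
    degenerate to unit vectors on the observed genotype.
    """
    c = cross.map.chromosome(chrom)
    iL, iR = _locate_interval(c, position_cM)
    r1 = recomb_fraction(position_cM - c.positions_cM[iL])
    r2 = recomb_fraction(c.positions_cM[iR] - position_cM)
    table = _conditional_table_cached(cross.cross_type, r1, r2)
    gL = cross.marker_genotypes(c.markers[iL])
    gR = cross.marker_genotypes(c.markers[iR])
    Q = table[gL, gR, :]
    if np.isnan(Q).any():
        bad = np.where(np.isnan(Q).any(axis=1))[0]
        raise ConfigurationError(
            f"impossible flanking genotype pair for individuals {bad.tolist()} "
            f"at {chrom}:{position_cM} cM"
        )
    codes = GENOTYPE_CODES[cross.cross_type]
    return MixingProbs(
        Q=Q, class_labels=tuple((c_,) for c_ in codes), cross_type=cross.cross_type
    )


def joint_qtl_probs(parts: list[MixingProbs]) -> MixingProbs:
    """Joint class probabilities for several intervals (row-wise products).

    Valid because, with no interference, the conditional genotype
    distributions of distinct putative QTLs given their own flanking markers
    are independent.  Column order is lexicographic over per-QTL classes,
    matching ``design_matrix`` row order.
    """
    if not parts:
        raise ValueError("need at least one MixingProbs")
    if len({p.n for p in parts}) != 1:
        raise ValueError(f"sample-size mismatch: {[p.n for p in parts]}")
    if len({p.cross_type for p in parts}) != 1:
        raise ValueError("mixed cross types")
    if len(parts) == 1:
        return parts[0]
    Q = parts[0].Q
    labels = [lab for lab in parts[0].class_labels]
    for p in parts[1:]:
        Q = np.einsum("ji,jk->jik", Q, p.Q).reshape(Q.shape[0], -1)
        labels = [l1 + l2 for l1 in labels for l2 in p.class_labels]
    return MixingProbs(Q=Q, class_labels=tuple(labels), cross_type=parts[0].cross_type)
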