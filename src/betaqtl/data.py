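"""Core data containers for experimental-cross QTL mapping.

A cross is described by a genetic map (chromosomes carrying ordered markers
with centimorgan positions), a genotype matrix over those markers, and one
quantitative phenotype per individual.  Two cross types are supported:

* backcross (``bc``): two genotype classes per locus, coded ``QQ=1, Qq=0``;
* intercross (``f2``): three classes, coded ``QQ=2, Qq=1, qq=0``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

BC = "bc"
F2 = "f2"
CROSS_TYPES = (BC, F2)

#: genotype code alphabet per cross type (descending = Q-allele count order)
GENOTYPE_CODES = {BC: (1, 0), F2: (2, 1, 0)}


class ConfigurationError(ValueError):
    """Raised for invalid map geometry, off-map positions or bad settings."""


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: ordered marker names and strictly increasing cM positions."""

    name: str
    markers: tuple[str, ...]
    positions_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_cM, dtype=float)
        object.__setattr__(self, "positions_cM", pos)
        if len(self.markers) != len(pos):
            raise ConfigurationError(
                f"chromosome {self.name}: {len(self.markers)} marker names "
                f"but {len(pos)} positions"
            )
        if len(pos) < 2:
            raise ConfigurationError(
                f"chromosome {self.name}: needs >= 2 markers, got {len(pos)}"
            )
        if not np.all(np.diff(pos) > 0):
            raise ConfigurationError(
                f"chromosome {self.name}: positions must be strictly increasing"
            )

    @property
    def span_cM(self) -> float:
        return float(self.positions_cM[-1] - self.positions_cM[0])


@dataclass(frozen=True)
class GeneticMap:
    """A genetic map: a tuple of chromosomes."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate chromosome names: {names}")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == str(name):
                return c
        raise ConfigurationError(f"no chromosome named {name!r}")

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    def marker_index(self, marker: str) -> int:
        """Column index of a marker in the map-wide genotype matrix."""
        i = 0
        for c in self.chromosomes:
            for m in c.markers:
                if m == marker:
                    return i
                i += 1
        raise ConfigurationError(f"no marker named {marker!r}")

    def marker_location(self, marker: str) -> tuple[str, float]:
        """(chromosome name, cM position) of a marker."""
        for c in self.chromosomes:
            for m, p in zip(c.markers, c.positions_cM):
                if m == marker:
                    return c.name, float(p)
        raise ConfigurationError(f"no marker named {marker!r}")


@dataclass(frozen=True)
class QTLSpec:
    """A simulated QTL: chromosome, cM position and genetic effects.

    ``additive_effect`` is in phenotype units; ``dominance_effect`` applies
    to intercross populations only.
    """

    chrom: str
    position_cM: float
    additive_effect: float
    dominance_effect: float = 0.0

    def validate(self, gmap: GeneticMap) -> None:
        c = gmap.chromosome(self.chrom)
        lo, hi = c.positions_cM[0], c.positions_cM[-1]
        if not (lo <= self.position_cM <= hi):
            raise ConfigurationError(
                f"QTL at {self.position_cM} cM is off chromosome {self.chrom} "
                f"(span {lo}..{hi} cM)"
            )


@dataclass(frozen=True)
class ContaminationConfig:
    """Additive outlier contamination of a phenotype vector.

    A fraction ``rate`` of individuals receive an additive shift drawn from
    Normal(shift_mean*s_y, (shift_sd*s_y)^2) where s_y is the SD of the clean
    phenotype, so the shift scale follows the trait's own scale.
    """

    rate: float
    shift_mean: float = 8.0
    shift_sd: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.rate < 1.0):
            raise ConfigurationError(f"contamination rate must be in [0,1), got {self.rate}")


@dataclass(frozen=True)
class CrossData:
    """Genotypes, phenotype and map for one experimental cross.

    genotypes: (n, M) integer matrix in the cross type's code alphabet.
    phenotype: length-n vector, or None before phenotypes are simulated/loaded.
    """

    cross_type: str
    genotypes: np.ndarray
    map: GeneticMap
    phenotype: np.ndarray | None = None

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ConfigurationError(f"unknown cross type {self.cross_type!r}")
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ConfigurationError("genotypes must be a 2-D matrix")
        if g.shape[0] < 2:
            raise ConfigurationError(f"need n >= 2 individuals, got {g.shape[0]}")
        if g.shape[1] != self.map.n_markers:
            raise ConfigurationError(
                f"genotype matrix has {g.shape[1]} columns but map has "
                f"{self.map.n_markers} markers"
            )
        codes = GENOTYPE_CODES[self.cross_type]
        if not np.isin(g, codes).all():
            bad = sorted(set(np.unique(g)) - set(codes))
            raise ConfigurationError(
                f"genotype codes {bad} invalid for cross type {self.cross_type}"
            )
        object.__setattr__(self, "genotypes", g.astype(np.int8))
        if self.phenotype is not None:
            y = np.asarray(self.phenotype, dtype=float)
            if y.shape != (g.shape[0],):
                raise ConfigurationError(
                    f"phenotype length {y.shape} does not match n={g.shape[0]}"
                )
            if not np.isfinite(y).all():
                raise ConfigurationError("phenotype contains non-finite values")
            object.__setattr__(self, "phenotype", y)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def with_phenotype(self, y: Sequence[float]) -> "CrossData":
        return replace(self, phenotype=np.asarray(y, dtype=float))

    def marker_genotypes(self, marker: str) -> np.ndarray:
        return self.genotypes[:, self.map.marker_index(marker)]
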