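"""YAML scenario configs for simulation runs.

Example::

    map: {n_chr: 4, n_markers: 15, spacing_cM: 10}
    cross_type: bc
    n: 300
    heritability: 0.5
    qtls:
      - {chrom: "1", position_cM: 20, additive_effect: 2.12}
      - {chrom: "2", position_cM: 50, additive_effect: -1.23}
    contamination: {rate: 0.05, shift_mean: 8, shift_sd: 2}
    seed: 1
    replicates: 100
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .data import ConfigurationError, ContaminationConfig, CrossData, QTLSpec
from .simulate import contaminate, sim_cross, sim_map, sim_phenotype


@dataclass(frozen=True)
class Scenario:
    map_geometry: dict
    cross_type: str
    n: int
    heritability: float
    qtls: tuple[QTLSpec, ...]
    contamination: ContaminationConfig | None
    seed: int
    replicates: int

    def simulate(self, replicate: int = 0) -> CrossData:
        """Simulate one replicate; replicate seeds are seed + replicate."""
        rep_seed = self.seed + replicate
        gmap = sim_map(**self.map_geometry)
        cross = sim_cross(gmap, self.n, self.cross_type, seed=rep_seed)
        cross = sim_phenotype(
            cross, list(self.qtls), self.heritability, seed=rep_seed + 500_000
        )
        if self.contamination is not None and self.contamination.rate > 0:
            cfg = ContaminationConfig(
                rate=self.contamination.rate,
                shift_mean=self.contamination.shift_mean,
                shift_sd=self.contamination.shift_sd,
                seed=rep_seed + 900_000,
            )
            y, _ = contaminate(cross.phenotype, cfg)
            cross = cross.with_phenotype(y)
        return cross


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        qtls = tuple(
            QTLSpec(
                chrom=str(q["chrom"]),
                position_cM=float(q["position_cM"]),
                additive_effect=float(q["additive_effect"]),
                dominance_effect=float(q.get("dominance_effect", 0.0)),
            )
            for q in raw["qtls"]
        )
        cont = None
        if raw.get("contamination"):
            c = raw["contamination"]
            cont = ContaminationConfig(
                rate=float(c["rate"]),
                shift_mean=float(c.get("shift_mean", 8.0)),
                shift_sd=float(c.get("shift_sd", 2.0)),
            )
        return Scenario(
            map_geometry={
                "n_chr": int(raw["map"]["n_chr"]),
                "n_markers": int(raw["map"]["n_markers"]),
                "spacing_cM": float(raw["map"]["spacing_cM"]),
            },
            cross_type=str(raw.get("cross_type", "bc")),
            n=int(raw["n"]),
            heritability=float(raw["heritability"]),
            qtls=qtls,
            contamination=cont,
            seed=int(raw.get("seed", 0)),
            replicates=int(raw.get("replicates", 1)),
        )
    except KeyError as e:
        raise ConfigurationError(f"scenario file {path}: missing key {e}") from None
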