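"""Genome scans, cofactor selection and permutation significance thresholds.

Three scan flavours share one engine:

* ``im``  — interval mapping: intercept-only covariates, beta = 0;
* ``cim`` — composite interval mapping: stepwise-selected background markers
  as covariates (excluded near the tested interval), beta = 0;
* ``betacim`` — the robust variant: CIM's model fitted by maximum
  beta-likelihood with beta > 0 (beta -> 0 recovers CIM exactly).

Genome-wide significance thresholds come from permuting the phenotype
against the genotype rows and taking the empirical (1-alpha) quantile of the
genome-wide maximum LOD.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .data import BC, ConfigurationError, CrossData
from .em import fit, fit_null, lod_beta
from .genetics import design_matrix, interval_qtl_probs

log = logging.getLogger(__name__)

METHODS = ("im", "cim", "betacim")


@dataclass(frozen=True)
class CofactorSet:
    """Ordered background markers selected for CIM, with the selection trace."""

    markers: tuple[str, ...]
    trace: tuple[dict, ...] = ()

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class Threshold:
    """Genome-wide LOD threshold from a permutation null sample."""

    alpha: float
    n_permutations: int
    null_max: np.ndarray
    value: float


@dataclass(frozen=True)
class ScanResult:
    """Per-position LOD profile of one genome scan.

    ``table`` columns: chrom, pos_cM, lod, effect (estimated additive effect
    of the tested QTL), method, beta.
    """

    table: pd.DataFrame
    method: str
    beta: float
    cofactors: CofactorSet

    @property
    def max_lod(self) -> float:
        return float(np.nanmax(self.table["lod"].to_numpy()))

    def lod_at(self, chrom: str, pos_cM: float) -> float:
        t = self.table
        sel = (t["chrom"] == str(chrom)) & np.isclose(t["pos_cM"], pos_cM)
        if not sel.any():
            raise KeyError(f"no scan position at {chrom}:{pos_cM} cM")
        return float(t.loc[sel, "lod"].iloc[0])

    def effect_at(self, chrom: str, pos_cM: float) -> float:
        t = self.table
        sel = (t["chrom"] == str(chrom)) & np.isclose(t["pos_cM"], pos_cM)
        if not sel.any():
            raise KeyError(f"no scan position at {chrom}:{pos_cM} cM")
        return float(t.loc[sel, "effect"].iloc[0])

    def peaks(self, threshold: float, gmap=None) -> pd.DataFrame:
        """Local maxima above ``threshold``, separated by at least one marker
        interval; ties broken toward lower cM.  Annotates the nearest marker
        when the scan's map is supplied."""
        rows = []
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_cM"].to_numpy()
            lod = np.nan_to_num(grp["lod"].to_numpy(), nan=-np.inf)
            if gmap is not None:
                min_sep = self._min_marker_interval(gmap, chrom)
            else:
                min_sep = float(np.min(np.diff(np.sort(pos)))) if pos.size > 1 else 0.0
            # candidates: strict local maxima of the profile (ends included)
            is_max = np.ones(lod.size, dtype=bool)
            is_max[1:] &= lod[1:] >= lod[:-1]
            is_max[:-1] &= lod[:-1] >= lod[1:]
            order = np.argsort(-lod, kind="stable")  # stable: lower cM wins ties
            taken: list[int] = []
            for i in order:
                if lod[i] <= threshold:
                    break
                if is_max[i] and all(
                    abs(pos[i] - pos[j]) >= min_sep - 1e-9 for j in taken
                ):
                    taken.append(i)
            for i in sorted(taken, key=lambda i: pos[i]):
                rec = {
                    "chrom": chrom,
                    "pos_cM": pos[i],
                    "lod": lod[i],
                    "effect": grp["effect"].to_numpy()[i],
                }
                if gmap is not None:
                    c = gmap.chromosome(chrom)
                    k = int(np.argmin(np.abs(c.positions_cM - pos[i])))
                    rec["nearest_marker"] = c.markers[k]
                rows.append(rec)
        return pd.DataFrame(rows)

    @staticmethod
    def _min_marker_interval(gmap, chrom) -> float:
        return float(np.min(np.diff(gmap.chromosome(chrom).positions_cM)))


def marker_codes(cross: CrossData, marker: str) -> np.ndarray:
    """Numeric covariate columns for a marker used as a CIM cofactor.

    Backcross: one column in {0, 1}.  Intercross: the additive code
    (1, 0, -1) and the dominance deviation (-1/2, 1/2, -1/2).
    """
    g = cross.marker_genotypes(marker).astype(float)
    if cross.cross_type == BC:
        return g[:, None]
    x = g - 1.0
    z = np.where(g == 1, 0.5, -0.5)
    return np.column_stack([x, z])


def default_max_cofactors(n: int) -> int:
    """2 sqrt(n) / ln(n), capped at 10: few enough to keep df for the scan."""
    return int(min(10, round(2.0 * np.sqrt(n) / np.log(n))))


def select_cofactors(
    cross: CrossData, max_cofactors: int | None = None, criterion: str = "bic"
) -> CofactorSet:
    """Forward stepwise regression of the phenotype on marker codes.

    Adds the marker that most reduces the BIC; stops when no marker improves
    it or ``max_cofactors`` is reached.  Collinear candidates are skipped.
    """
    if criterion != "bic":
        raise ConfigurationError(f"unsupported criterion {criterion!r}")
    if cross.phenotype is None:
        raise ConfigurationError("cross has no phenotype")
    y = cross.phenotype
    n = cross.n
    if max_cofactors is None:
        max_cofactors = default_max_cofactors(n)
    blocks = {m: marker_codes(cross, m) for m in cross.map.marker_names}

    def bic_of(Xc: np.ndarray) -> float:
        coef, res, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
        if rank < Xc.shape[1]:
            return np.inf  # collinear candidate
        rss = float(np.sum((y - Xc @ coef) ** 2))
        return n * np.log(rss / n) + Xc.shape[1] * np.log(n)

    X = np.ones((n, 1))
    current_bic = bic_of(X)
    chosen: list[str] = []
    trace: list[dict] = [{"step": 0, "marker": None, "bic": current_bic}]
    remaining = list(blocks)
    while len(chosen) < max_cofactors:
        best = None
        for m in remaining:
            b = bic_of(np.hstack([X, blocks[m]]))
            if np.isinf(b):
                log.debug("skipping collinear cofactor candidate %s", m)
                continue
            if best is None or b < best[1]:
                best = (m, b)
        if best is None or best[1] >= current_bic:
            break
        m, current_bic = best
        X = np.hstack([X, blocks[m]])
        chosen.append(m)
        remaining.remove(m)
        trace.append({"step": len(chosen), "marker": m, "bic": current_bic})
    return CofactorSet(markers=tuple(chosen), trace=tuple(trace))


def scan_grid(gmap, step_cM: float) -> list[tuple[str, float]]:
    """Scan positions: every marker plus interior grid points at ``step_cM``.

    Positions are half-open per interval (each marker counted once); the
    terminal marker of each chromosome is appended.
    """
    grid: list[tuple[str, float]] = []
    for c in gmap.chromosomes:
        pos = c.positions_cM
        for i in range(len(pos) - 1):
            p = pos[i]
            while p < pos[i + 1] - 1e-9:
                grid.append((c.name, float(p)))
                p += step_cM
        grid.append((c.name, float(pos[-1])))
    return grid


def _excluded(gmap, chrom: str, pos: float, marker: str, window_cM: float) -> bool:
    """Is ``marker`` inside the exclusion window of the interval at pos?"""
    m_chrom, m_pos = gmap.marker_location(marker)
    if m_chrom != chrom:
        return False
    from .genetics import _locate_interval

    c = gmap.chromosome(chrom)
    iL, iR = _locate_interval(c, pos)
    left, right = c.positions_cM[iL], c.positions_cM[iR]
    return left - window_cM <= m_pos <= right + window_cM


def genome_scan(
    cross: CrossData,
    method: str = "cim",
    beta: float = 0.0,
    cofactors: CofactorSet | None = None,
    step_cM: float = 1.0,
    covariates: np.ndarray | None = None,
    window_cM: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    probs_cache: dict | None = None,
) -> ScanResult:
    """Scan the genome for a single QTL at every grid position.

    At each position the model matrix is intercept + covariates + cofactor
    codes (cofactors within ``window_cM`` of the tested interval dropped),
    the latent QTL-class priors come from the flanking markers, and the
    recorded score is LOD_beta of the alternative vs the no-QTL null fitted
    on the same model matrix.  Per-position failures are logged and recorded
    as NaN; the scan continues.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
    if cross.phenotype is None:
        raise ConfigurationError("cross has no phenotype")
    if method == "im":
        cofactors = CofactorSet(markers=())
    elif cofactors is None:
        cofactors = select_cofactors(cross)
    if method in ("im", "cim"):
        beta = 0.0
    if beta < 0:
        raise ConfigurationError(f"beta must be >= 0, got {beta}")

    y = cross.phenotype
    n = cross.n
    gmap = cross.map
    D = design_matrix(cross.cross_type, 1)
    base_cols = [np.ones((n, 1))]
    if covariates is not None:
        base_cols.append(np.atleast_2d(np.asarray(covariates, dtype=float).T).T)
    blocks = {m: marker_codes(cross, m) for m in cofactors.markers}

    null_cache: dict[tuple[str, ...], object] = {}
    records = []
    for chrom, pos in scan_grid(gmap, step_cM):
        included = tuple(
            m for m in cofactors.markers if not _excluded(gmap, chrom, pos, m, window_cM)
        )
        X = np.hstack(base_cols + [blocks[m] for m in included])
        try:
            if probs_cache is not None:
                probs = probs_cache.get((chrom, pos))
                if probs is None:
                    probs = probs_cache[(chrom, pos)] = interval_qtl_probs(cross, chrom, pos)
            else:
                probs = interval_qtl_probs(cross, chrom, pos)
            alt = fit(y, X, probs, D, beta=beta, tol=tol, max_iter=max_iter)
            if included not in null_cache:
                null_cache[included] = fit_null(y, X, beta=beta, tol=tol, max_iter=max_iter)
            nul = null_cache[included]
            records.append(
                {
                    "chrom": chrom,
                    "pos_cM": pos,
                    "lod": lod_beta(alt, nul, n),
                    "effect": float(alt.theta_hat.E[0]),
                    "method": method,
                    "beta": beta,
                }
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            log.warning("scan failed at %s:%s cM: %s", chrom, pos, exc)
            records.append(
                {
                    "chrom": chrom,
                    "pos_cM": pos,
                    "lod": np.nan,
                    "effect": np.nan,
                    "method": method,
                    "beta": beta,
                }
            )
    return ScanResult(
        table=pd.DataFrame(records), method=method, beta=beta, cofactors=cofactors
    )


def permutation_threshold(
    cross: CrossData,
    method: str = "cim",
    beta: float = 0.0,
    cofactors: CofactorSet | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    step_cM: float = 1.0,
    window_cM: float = 10.0,
    **scan_kwargs,
) -> Threshold:
    """Empirical (1-alpha) quantile of the genome-wide max LOD under
    phenotype permutation.

    Cofactors and beta are held fixed at the values chosen on the observed
    data (re-selection per permutation would multiply the cost for little
    change in the null maximum).
    """
    if cross.phenotype is None:
        raise ConfigurationError("cross has no phenotype")
    if method != "im" and cofactors is None:
        cofactors = select_cofactors(cross)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    probs_cache: dict = {}
    for b in range(n_perm):
        y_perm = rng.permutation(cross.phenotype)
        perm_cross = dc_replace(cross, phenotype=y_perm)
        res = genome_scan(
            perm_cross,
            method=method,
            beta=beta,
            cofactors=cofactors,
            step_cM=step_cM,
            window_cM=window_cM,
            probs_cache=probs_cache,
            **scan_kwargs,
        )
        null_max[b] = res.max_lod
        if (b + 1) % 100 == 0:
            log.info("permutation %d/%d", b + 1, n_perm)
    return Threshold(
        alpha=alpha,
        n_permutations=n_perm,
        null_max=null_max,
        value=float(np.quantile(null_max, 1.0 - alpha)),
    )


def threshold_from_null_sample(
    null_max: np.ndarray, alpha: float, n_perm: int | None = None
) -> Threshold:
    """Build a Threshold from an (optionally pooled) null max-LOD sample."""
    null_max = np.asarray(null_max, dtype=float)
    return Threshold(
        alpha=alpha,
        n_permutations=n_perm if n_perm is not None else null_max.size,
        null_max=null_max,
        value=float(np.quantile(null_max, 1.0 - alpha)),
    )
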