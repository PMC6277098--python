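"""Readers and writers for the qtl-cross CSV dialect and result tables.

The cross file layout (one canonical dialect; rotated variants rejected):

    row 1: phenotype name, marker names...
    row 2: (blank),        chromosome ids...
    row 3: (blank),        cM positions...
    rows : phenotype value, genotype codes...

Genotype codes are AA/AB/BB (or the single letters A/H/B), case-insensitive;
AA is the homozygote carrying the Q allele.  Missing genotypes are rejected:
version 1 of the model class has no missing-data handling.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BC, F2, Chromosome, CrossData, GeneticMap


class CrossParseError(ValueError):
    """Parse/validation failure, naming the offending cell."""


_WRITE_CODES = {F2: {2: "AA", 1: "AB", 0: "BB"}, BC: {1: "AA", 0: "AB"}}
_READ_CODES = {"AA": 2, "AB": 1, "BB": 0, "A": 2, "H": 1, "B": 0}


def write_cross_csv(cross: CrossData, path) -> None:
    """Write a cross (with phenotype) in the qtl-cross CSV dialect."""
    if cross.phenotype is None:
        raise ValueError("cross has no phenotype to write")
    codes = _WRITE_CODES[cross.cross_type]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        names = cross.map.marker_names
        w.writerow(["pheno"] + names)
        w.writerow([""] + [c.name for c in cross.map.chromosomes for _ in c.markers])
        w.writerow(
            [""] + [repr(float(p)) for c in cross.map.chromosomes for p in c.positions_cM]
        )
        for j in range(cross.n):
            w.writerow(
                [repr(float(cross.phenotype[j]))]
                + [codes[int(g)] for g in cross.genotypes[j]]
            )


def read_cross_csv(path, cross_type: str | None = None) -> CrossData:
    """Read a qtl-cross CSV file into a CrossData.

    The cross type is inferred from the observed code alphabet (any BB/B
    implies an intercross) unless ``cross_type`` overrides it.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 5:
        raise CrossParseError(f"{path}: need 3 header rows and >= 2 individuals")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    n_cols = len(header)
    if len(chrom_row) != n_cols or len(pos_row) != n_cols:
        raise CrossParseError(f"{path}: header rows have inconsistent lengths")
    if chrom_row[0].strip() or pos_row[0].strip():
        raise CrossParseError(
            f"{path}: rows 2-3, column 1 must be blank (phenotype column)"
        )
    markers = [h.strip() for h in header[1:]]
    chroms_raw = [c.strip() for c in chrom_row[1:]]
    try:
        positions = [float(p) for p in pos_row[1:]]
    except ValueError as e:
        raise CrossParseError(f"{path}: row 3: bad cM position ({e})") from None

    # group consecutive markers by chromosome id
    chrom_list: list[Chromosome] = []
    seen: list[str] = []
    i = 0
    while i < len(markers):
        cid = chroms_raw[i]
        if cid in seen:
            raise CrossParseError(
                f"{path}: chromosome {cid!r} appears in non-consecutive blocks"
            )
        j = i
        while j < len(markers) and chroms_raw[j] == cid:
            j += 1
        pos = np.array(positions[i:j])
        if not np.all(np.diff(pos) > 0):
            raise CrossParseError(
                f"{path}: chromosome {cid!r}: positions not strictly increasing "
                f"(columns {i + 2}..{j + 1})"
            )
        chrom_list.append(
            Chromosome(name=cid, markers=tuple(markers[i:j]), positions_cM=pos)
        )
        seen.append(cid)
        i = j
    gmap = GeneticMap(chromosomes=tuple(chrom_list))

    geno = np.empty((len(rows) - 3, len(markers)), dtype=np.int8)
    pheno = np.empty(len(rows) - 3)
    saw_bb = False
    for r, row in enumerate(rows[3:], start=4):
        if len(row) != n_cols:
            raise CrossParseError(f"{path}: row {r}: expected {n_cols} fields, got {len(row)}")
        try:
            pheno[r - 4] = float(row[0])
        except ValueError:
            raise CrossParseError(
                f"{path}: row {r}, column 1: bad phenotype value {row[0]!r}"
            ) from None
        for c, cell in enumerate(row[1:], start=2):
            code = cell.strip().upper()
            if code == "" or code == "-" or code == "NA":
                raise CrossParseError(
                    f"{path}: row {r}, column {c} ({markers[c - 2]}): missing "
                    "genotype; missing data is not supported"
                )
            if code not in _READ_CODES:
                raise CrossParseError(
                    f"{path}: row {r}, column {c} ({markers[c - 2]}): unknown "
                    f"genotype code {cell!r}"
                )
            geno[r - 4, c - 2] = _READ_CODES[code]
            saw_bb |= code in ("BB", "B")

    if cross_type is None:
        cross_type = F2 if saw_bb else BC
    if cross_type == BC:
        if saw_bb:
            raise CrossParseError(
                f"{path}: BB genotypes present but cross type forced to backcross"
            )
        geno = np.where(geno == 2, 1, 0).astype(np.int8)  # AA -> 1 (QQ), AB -> 0 (Qq)
    return CrossData(
        cross_type=cross_type, genotypes=geno, map=gmap, phenotype=pheno
    )


def write_scan_tsv(result, path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_peaks_tsv(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cv_tsv(cv_result, path) -> None:
    pd.DataFrame(
        {"beta": cv_result.beta_grid, "score": cv_result.scores}
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
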