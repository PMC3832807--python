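"""LINKAGE-style pedigree I/O (pre-makeped layout).

Records are whitespace-delimited lines of
``family-id individual-id father-id mother-id sex affection allele1 allele2``
with affection 2 denoting affected and 0 denoting a missing parent or
genotype.  Allele indices are 1-based on file and converted to the 0-based
contiguous internal convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .ibd import Genotype, IBDPosterior, NuclearFamily
from .likelihood import PairData

__all__ = [
    "read_pedigrees",
    "write_pedigrees",
    "read_pairs_tsv",
    "PedigreeFormatError",
]

log = logging.getLogger("clasp")


class PedigreeFormatError(ValueError):
    """A pedigree line could not be parsed."""


@dataclass
class _Individual:
    fam: str
    iid: str
    father: str
    mother: str
    sex: str
    affection: int
    genotype: Optional[Genotype]


def _parse_line(line: str, lineno: int) -> _Individual:
    fields = line.split()
    if len(fields) != 8:
        raise PedigreeFormatError(
            f"line {lineno}: expected 8 whitespace-delimited fields, got {len(fields)}"
        )
    fam, iid, father, mother, sex, aff, a1, a2 = fields
    try:
        affection = int(aff)
        i1, i2 = int(a1), int(a2)
    except ValueError as exc:
        raise PedigreeFormatError(f"line {lineno}: non-integer field ({exc})") from None
    if (i1 == 0) != (i2 == 0):
        raise PedigreeFormatError(f"line {lineno}: half-missing genotype {i1}/{i2}")
    genotype = None if i1 == 0 else Genotype(i1 - 1, i2 - 1)
    return _Individual(fam, iid, father, mother, sex, affection, genotype)


def read_pedigrees(path: str | Path) -> list[NuclearFamily]:
    """Read nuclear families with two parents and two typed affected sibs.

    Families with more than two affected typed sibs keep the first two (a
    warning is logged); families failing the structure checks are skipped
    with a warning.  Malformed lines raise :class:`PedigreeFormatError`
    with the line number.
    """
    path = Path(path)
    groups: dict[str, list[_Individual]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            ind = _parse_line(line, lineno)
            groups.setdefault(ind.fam, []).append(ind)
    if not groups:
        raise PedigreeFormatError(f"{path}: no pedigree records found")

    families: list[NuclearFamily] = []
    for fam, members in groups.items():
        by_id = {m.iid: m for m in members}
        founders = [m for m in members if m.father == "0" and m.mother == "0"]
        children = [m for m in members if m.father != "0" or m.mother != "0"]
        parent_ids = {(c.father, c.mother) for c in children}
        if len(founders) != 2 or len(parent_ids) != 1:
            log.warning("family %s skipped: not a two-parent nuclear family", fam)
            continue
        father_id, mother_id = parent_ids.pop()
        if father_id not in by_id or mother_id not in by_id:
            log.warning("family %s skipped: parent records missing", fam)
            continue
        sibs = [c for c in children if c.affection == 2 and c.genotype is not None]
        if len(sibs) < 2:
            log.warning("family %s skipped: fewer than 2 typed affected sibs", fam)
            continue
        if len(sibs) > 2:
            log.warning(
                "family %s has %d affected typed sibs; keeping the first two",
                fam, len(sibs),
            )
        families.append(
            NuclearFamily(
                sib1_genotype=sibs[0].genotype,
                sib2_genotype=sibs[1].genotype,
                father_genotype=by_id[father_id].genotype,
                mother_genotype=by_id[mother_id].genotype,
            )
        )
    if not families:
        raise PedigreeFormatError(f"{path}: no usable nuclear families")
    return families


def write_pedigrees(families: Iterable[NuclearFamily], path: str | Path) -> None:
    """Export families in the pre-makeped LINKAGE layout (1-based alleles)."""

    def geno(g: Optional[Genotype]) -> str:
        return "0 0" if g is None else f"{g.allele_a + 1} {g.allele_b + 1}"

    lines = []
    for i, fam in enumerate(families, start=1):
        fid = str(i)
        lines.append(f"{fid} 1 0 0 1 1 {geno(fam.father_genotype)}")
        lines.append(f"{fid} 2 0 0 2 1 {geno(fam.mother_genotype)}")
        lines.append(f"{fid} 3 1 2 1 2 {geno(fam.sib1_genotype)}")
        lines.append(f"{fid} 4 1 2 2 2 {geno(fam.sib2_genotype)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs_tsv(path: str | Path) -> list[PairData]:
    """Read pair data from a TSV of (f0_hat, f1_hat, f2_hat, covariates...).

    A header line is optional (detected by non-numeric first field).  Each
    row becomes one :class:`PairData` with the full-sib prior; columns
    beyond the first three are pair-level covariates on the adjusted scale.
    """
    rows: list[PairData] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                values = [float(x) for x in fields]
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise PedigreeFormatError(f"line {lineno}: non-numeric field")
            if len(values) < 3:
                raise PedigreeFormatError(f"line {lineno}: need at least 3 columns")
            rows.append(
                PairData(IBDPosterior(*values[:3]), covariates=tuple(values[3:]))
            )
    if not rows:
        raise PedigreeFormatError(f"{path}: no pair records found")
    return rows
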