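"""Readers and writers for the text formats the toolkit touches.

Supported formats:

* PLINK-dialect PED/MAP genotype files (6 leading PED columns, ``0`` =
  missing allele);
* array manifest tables (CSV/TSV with header
  ``name,chromosome,position,allele_a,allele_b,flank,tier,mandatory``;
  extra columns tolerated, names matched case-insensitively);
* long-format per-breed frequency tables (``snp,breed,maf,n``);
* pedigree tables (``id,sire,dam,sex,breed``).

Delimiters for the delimited tables default to comma with tab auto-detected.
Positions are 1-based throughout, matching MAP-file convention.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    NOCALL,
    BreedFrequencyTable,
    GenotypeMatrix,
    ParseError,
    SampleMeta,
    SchemaError,
    SnpRecord,
    ValidationError,
    normalize_chromosome,
)

__all__ = [
    "read_map",
    "write_map",
    "read_ped",
    "write_ped",
    "read_manifest",
    "write_manifest",
    "read_frequency_table",
    "write_frequency_table",
    "read_pedigree",
    "write_pedigree",
]

log = logging.getLogger(__name__)

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


# ---------------------------------------------------------------------------
# MAP / PED
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> list[SnpRecord]:
    """Read a PLINK MAP file into SnpRecords, preserving file order.

    Rows carry chromosome, SNP name, genetic position (preserved for
    round-trips but otherwise ignored) and 1-based physical position.
    """
    records: list[SnpRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, name, gpos, ppos = fields
            try:
                position = int(ppos)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer position {ppos!r}"
                ) from None
            try:
                genetic = float(gpos)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric genetic position {gpos!r}"
                ) from None
            if name in seen:
                raise ValidationError(f"{path}: duplicate SNP name {name!r}")
            seen.add(name)
            records.append(
                SnpRecord(name=name, chromosome=chrom, position=position,
                          genetic_pos=genetic)
            )
    return records


def write_map(path: str | Path, snps: Sequence[SnpRecord]) -> None:
    with open(path, "w") as fh:
        for snp in snps:
            fh.write(f"{snp.chromosome}\t{snp.name}\t{snp.genetic_pos:g}\t{snp.position}\n")


def read_ped(path: str | Path, snps: Sequence[SnpRecord]) -> GenotypeMatrix:
    """Read a PLINK PED file against a SNP list into a GenotypeMatrix.

    Allele pairs are mapped to B-allele dosage against each SnpRecord's
    (A, B) allele pair; ``0 0`` maps to NOCALL.  Records whose alleles are
    unknown (for example, straight from a MAP file) have them inferred in
    order of first appearance in the data.
    """
    snps = list(snps)
    n_snps = len(snps)
    alleles: list[list[str]] = [list(s.alleles) if s.alleles else [] for s in snps]
    inferred = [s.alleles is None for s in snps]

    samples: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{path}: line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(fields)}"
                )
            fam, sid, sire, dam, sex_code, _pheno = fields[:6]
            del fam
            samples.append(
                SampleMeta(
                    id=sid,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=_SEX_FROM_PED.get(sex_code, "unknown"),
                )
            )
            row = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    if a1 != a2:
                        raise ValidationError(
                            f"{path}: sample {sid}, SNP {snps[j].name}: "
                            f"half-called genotype {a1}/{a2}"
                        )
                    row[j] = NOCALL
                    continue
                dosage = 0
                for allele in (a1, a2):
                    if allele not in alleles[j]:
                        if inferred[j] and len(alleles[j]) < 2:
                            alleles[j].append(allele)
                        else:
                            raise ValidationError(
                                f"{path}: sample {sid}, SNP {snps[j].name}: "
                                f"allele {allele!r} not in {tuple(alleles[j])}"
                            )
                    dosage += alleles[j].index(allele)
                row[j] = dosage
            rows.append(row)

    out_snps = []
    for snp, pair, was_inferred in zip(snps, alleles, inferred):
        if was_inferred:
            # monomorphic-in-file SNPs get a placeholder B allele
            a = pair[0] if pair else "A"
            b = pair[1] if len(pair) > 1 else ("B" if a != "B" else "A2")
            out_snps.append(snp.with_alleles(a, b))
        else:
            out_snps.append(snp)
    calls = np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)
    return GenotypeMatrix(samples, out_snps, calls)


def write_ped(path: str | Path, g: GenotypeMatrix, family: str = "FAM") -> None:
    """Write a GenotypeMatrix as a PLINK PED file (phenotype column -9)."""
    with open(path, "w") as fh:
        for i, sample in enumerate(g.samples):
            lead = [
                family,
                sample.id,
                sample.sire_id or "0",
                sample.dam_id or "0",
                _SEX_TO_PED[sample.sex],
                "-9",
            ]
            parts = lead
            for j, snp in enumerate(g.snps):
                call = g.calls[i, j]
                if call == NOCALL:
                    parts += ["0", "0"]
                else:
                    a, b = snp.alleles  # type: ignore[misc]
                    parts += [a if call < 2 else b, b if call > 0 else a]
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("name", "chromosome", "position")
_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_manifest(path: str | Path) -> list[SnpRecord]:
    """Read an array manifest table; records are returned sorted by
    (chromosome, position) with chromosome labels normalized.

    The header must name at least ``name``, ``chromosome`` and ``position``
    (case-insensitive); ``allele_a``, ``allele_b``, ``flank``, ``tier`` and
    ``mandatory`` are used when present and extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in _MANIFEST_REQUIRED if c not in cols]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    def col(name: str):
        return df[cols[name]] if name in cols else None

    records: list[SnpRecord] = []
    a_col, b_col = col("allele_a"), col("allele_b")
    for i in range(len(df)):
        a = a_col.iloc[i].strip() if a_col is not None else ""
        b = b_col.iloc[i].strip() if b_col is not None else ""
        tier = col("tier").iloc[i].strip().upper() if "tier" in cols else ""
        flank = col("flank").iloc[i].strip() if "flank" in cols else ""
        mand = col("mandatory").iloc[i].strip().lower() if "mandatory" in cols else ""
        try:
            position = int(float(col("position").iloc[i]))
        except ValueError:
            raise ParseError(
                f"{path}: row {i + 1}: non-integer position "
                f"{col('position').iloc[i]!r}"
            ) from None
        records.append(
            SnpRecord(
                name=col("name").iloc[i].strip(),
                chromosome=col("chromosome").iloc[i],
                position=position,
                alleles=(a, b) if a and b else None,
                flank=flank or None,
                tier=tier or None,
                mandatory=mand in _TRUTHY,
            )
        )
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate SNP names in manifest")
    return sorted(records, key=lambda r: r.sort_key)


def write_manifest(path: str | Path, snps: Sequence[SnpRecord]) -> None:
    rows = [
        {
            "name": s.name,
            "chromosome": s.chromosome,
            "position": s.position,
            "allele_a": s.alleles[0] if s.alleles else "",
            "allele_b": s.alleles[1] if s.alleles else "",
            "flank": s.flank or "",
            "tier": s.tier or "",
            "mandatory": int(s.mandatory),
        }
        for s in snps
    ]
    pd.DataFrame(
        rows,
        columns=[
            "name", "chromosome", "position", "allele_a", "allele_b",
            "flank", "tier", "mandatory",
        ],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------

def read_frequency_table(path: str | Path) -> BreedFrequencyTable:
    """Read a long-format ``snp,breed,maf,n`` table.

    Frequencies above 0.5 are folded to ``1 - maf`` with a logged warning
    (stored frequencies must be minor); values outside [0, 1] are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in ("snp", "breed", "maf") if c not in cols]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    table = BreedFrequencyTable()
    n_folded = 0
    for i in range(len(df)):
        maf = float(df[cols["maf"]].iloc[i])
        if not 0.0 <= maf <= 1.0:
            raise ValidationError(
                f"{path}: row {i + 1}: allele frequency {maf} outside [0, 1]"
            )
        if maf > 0.5:
            maf = 1.0 - maf
            n_folded += 1
        n = int(float(df[cols["n"]].iloc[i])) if "n" in cols and df[cols["n"]].iloc[i] else 0
        table.add(df[cols["snp"]].iloc[i].strip(), df[cols["breed"]].iloc[i].strip(), maf, n)
    if n_folded:
        log.warning("%s: folded %d frequencies > 0.5 to the minor allele", path, n_folded)
    return table


def write_frequency_table(path: str | Path, table: BreedFrequencyTable) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

_SEX_NORMALIZE = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}


def read_pedigree(path: str | Path) -> list[SampleMeta]:
    """Read an ``id,sire,dam,sex,breed`` pedigree table; '0'/'' parents
    become None."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    if "id" not in cols:
        raise SchemaError(f"{path}: missing required column 'id'; found {list(df.columns)}")

    def cell(name: str, i: int) -> str:
        return df[cols[name]].iloc[i].strip() if name in cols else ""

    out: list[SampleMeta] = []
    for i in range(len(df)):
        sire, dam = cell("sire", i), cell("dam", i)
        out.append(
            SampleMeta(
                id=cell("id", i),
                sire_id=sire if sire not in ("", "0") else None,
                dam_id=dam if dam not in ("", "0") else None,
                sex=_SEX_NORMALIZE.get(cell("sex", i).lower(), "unknown"),
                breed=cell("breed", i),
            )
        )
    return out


def write_pedigree(path: str | Path, samples: Sequence[SampleMeta]) -> None:
    rows = [
        {
            "id": s.id,
            "sire": s.sire_id or "0",
            "dam": s.dam_id or "0",
            "sex": s.sex,
            "breed": s.breed,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "breed"]).to_csv(
        path, index=False
    )
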