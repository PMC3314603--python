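"""Y-chromosome and mitochondrial lineage classification.

Haploid genotypes at a fixed ordered locus set are collapsed to a base
string (one letter per locus), matched against a haplotype catalog, and
summarized per breed.  The Y call pattern also infers sex: on a
well-behaved assay, males call at every Y locus and females at none.

Catalogs for the bovine low-density array's 9 Y and 13 mtDNA loci ship with
the package (as published for the array, including lineage annotations);
both are user-replaceable delimited files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import NOCALL, GenotypeMatrix, ValidationError

__all__ = [
    "NOVEL",
    "UNDETERMINED",
    "NONE",
    "HaplotypeCatalog",
    "LineageCall",
    "SexCall",
    "load_catalog",
    "builtin_catalog",
    "extract_haploid_string",
    "classify",
    "infer_sex",
    "classify_samples",
    "breed_haplotype_table",
    "load_published_counts",
]

log = logging.getLogger(__name__)

NOVEL = "NOVEL"
UNDETERMINED = "UNDETERMINED"
NONE = "NONE"
PLACEHOLDER = "."

_INDICINE_Y = {"1"}
_INDICINE_MT = {"7"}


@dataclass(frozen=True)
class HaplotypeCatalog:
    """Named haplotype strings over an ordered haploid locus list."""

    loci: tuple[str, ...]
    haplotypes: dict[str, str]  # name -> base string
    lineages: dict[str, str]  # name -> lineage annotation

    def __post_init__(self) -> None:
        strings = list(self.haplotypes.values())
        for name, h in self.haplotypes.items():
            if len(h) != len(self.loci):
                raise ValidationError(
                    f"haplotype {name}: length {len(h)} != {len(self.loci)} loci"
                )
        if len(set(strings)) != len(strings):
            raise ValidationError("haplotype strings must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.haplotypes)


def load_catalog(path: str | Path) -> HaplotypeCatalog:
    """Read a catalog file: TSV with columns name/haplotype/lineage and a
    ``#loci:`` comment line giving the comma-separated locus names."""
    loci: tuple[str, ...] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#loci:"):
                loci = tuple(t.strip() for t in line[len("#loci:"):].split(","))
                continue
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    header, body = rows[0], rows[1:]
    cols = {c.strip().lower(): i for i, c in enumerate(header)}
    for req in ("name", "haplotype"):
        if req not in cols:
            raise ValidationError(f"{path}: catalog missing column {req!r}")
    haps = {r[cols["name"]]: r[cols["haplotype"]] for r in body}
    lineages = {
        r[cols["name"]]: (r[cols["lineage"]] if "lineage" in cols and len(r) > cols["lineage"] else "")
        for r in body
    }
    if loci is None:
        length = len(next(iter(haps.values())))
        loci = tuple(f"locus_{i + 1}" for i in range(length))
    return HaplotypeCatalog(loci=loci, haplotypes=haps, lineages=lineages)


def builtin_catalog(kind: str) -> HaplotypeCatalog:
    """The bundled Y ('y') or mitochondrial ('mt') haplotype catalog."""
    fname = {"y": "y_haplotypes.tsv", "mt": "mt_haplotypes.tsv"}.get(kind.lower())
    if fname is None:
        raise ValidationError(f"unknown catalog kind {kind!r}")
    ref = resources.files("ldpanel.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_catalog(path)


# ---------------------------------------------------------------------------
# Haploid extraction and classification
# ---------------------------------------------------------------------------

def extract_haploid_string(
    g: GenotypeMatrix, sample_id: str, loci: Sequence[str]
) -> str | None:
    """Collapse a sample's calls at haploid loci to a base string.

    Homozygous calls contribute their base; no-calls a ``.`` placeholder.
    A heterozygous call at a haploid locus is an assay artifact and is also
    treated as a placeholder, with a warning.  Returns None when every
    locus is a placeholder.
    """
    i = g.sample_index(sample_id)
    chars: list[str] = []
    for locus in loci:
        j = g.snp_index(locus)
        call = g.calls[i, j]
        snp = g.snps[j]
        if call == NOCALL:
            chars.append(PLACEHOLDER)
        elif call == 1:
            log.warning(
                "sample %s: heterozygous call at haploid locus %s treated as no-call",
                sample_id, locus,
            )
            chars.append(PLACEHOLDER)
        else:
            if snp.alleles is None:
                raise ValidationError(f"locus {locus} has no allele assignment")
            chars.append(snp.alleles[0] if call == 0 else snp.alleles[1])
    if all(c == PLACEHOLDER for c in chars):
        return None
    return "".join(chars)


def classify(haplotype: str, catalog: HaplotypeCatalog) -> str:
    """Match a base string against a catalog.

    Exact match returns the haplotype name.  With placeholders, the string
    is compatible with a catalog entry when all called positions agree:
    exactly one compatible entry returns that name, zero or several return
    UNDETERMINED.  A fully-called string matching nothing is NOVEL.
    """
    if len(haplotype) != len(catalog.loci):
        raise ValidationError(
            f"haplotype length {len(haplotype)} != catalog locus count "
            f"{len(catalog.loci)}"
        )
    if PLACEHOLDER not in haplotype:
        for name, h in catalog.haplotypes.items():
            if h == haplotype:
                return name
        return NOVEL
    compatible = [
        name
        for name, h in catalog.haplotypes.items()
        if all(c == PLACEHOLDER or c == hc for c, hc in zip(haplotype, h))
    ]
    return compatible[0] if len(compatible) == 1 else UNDETERMINED


@dataclass(frozen=True)
class SexCall:
    sex: str  # {male, female, ambiguous}
    n_called: int
    n_loci: int

    @property
    def call_fraction(self) -> float:
        return self.n_called / self.n_loci if self.n_loci else 0.0


def infer_sex(g: GenotypeMatrix, sample_id: str, y_loci: Sequence[str]) -> SexCall:
    """Infer sex from the Y-locus call pattern.

    All Y loci called -> male; none called -> female; anything in between ->
    ambiguous, with the call fraction reported.
    """
    if not y_loci:
        raise ValidationError("y_loci must be non-empty")
    i = g.sample_index(sample_id)
    calls = [g.calls[i, g.snp_index(l)] for l in y_loci]
    n_called = sum(c != NOCALL for c in calls)
    if n_called == len(y_loci):
        sex = "male"
    elif n_called == 0:
        sex = "female"
    else:
        sex = "ambiguous"
    return SexCall(sex=sex, n_called=n_called, n_loci=len(y_loci))


@dataclass(frozen=True)
class LineageCall:
    """Per-sample lineage classification result."""

    sample_id: str
    y_haplotype: str  # catalog name, NOVEL or NONE
    mt_haplotype: str  # catalog name, NOVEL or UNDETERMINED
    inferred_sex: str  # {male, female, ambiguous}
    subspecies_signal: str  # {taurine, indicine, mixed-evidence, unknown}

    def __post_init__(self) -> None:
        if self.inferred_sex == "female" and self.y_haplotype != NONE:
            raise ValidationError("females must carry y_haplotype NONE")


def _subspecies(y_hap: str, mt_hap: str) -> str:
    evidence = set()
    if y_hap in _INDICINE_Y:
        evidence.add("indicine")
    elif y_hap not in (NONE, NOVEL, UNDETERMINED):
        evidence.add("taurine")
    if mt_hap in _INDICINE_MT:
        evidence.add("indicine")
    elif mt_hap not in (NONE, NOVEL, UNDETERMINED):
        evidence.add("taurine")
    if not evidence:
        return "unknown"
    if len(evidence) == 2:
        return "mixed-evidence"
    return evidence.pop()


def classify_samples(
    g: GenotypeMatrix,
    y_catalog: HaplotypeCatalog | None = None,
    mt_catalog: HaplotypeCatalog | None = None,
) -> list[LineageCall]:
    """Classify every sample's Y and mitochondrial haplotype and sex."""
    y_catalog = y_catalog or builtin_catalog("y")
    mt_catalog = mt_catalog or builtin_catalog("mt")
    out: list[LineageCall] = []
    for sample in g.samples:
        sex = infer_sex(g, sample.id, y_catalog.loci)
        if sex.sex == "female":
            y_hap = NONE
        else:
            s = extract_haploid_string(g, sample.id, y_catalog.loci)
            y_hap = NONE if s is None else classify(s, y_catalog)
        s = extract_haploid_string(g, sample.id, mt_catalog.loci)
        mt_hap = UNDETERMINED if s is None else classify(s, mt_catalog)
        out.append(
            LineageCall(
                sample_id=sample.id,
                y_haplotype=y_hap,
                mt_haplotype=mt_hap,
                inferred_sex=sex.sex,
                subspecies_signal=_subspecies(y_hap, mt_hap),
            )
        )
    return out


def breed_haplotype_table(
    calls: Sequence[LineageCall],
    breeds: Mapping[str, str],
    catalog: HaplotypeCatalog,
    which: str = "y",
) -> pd.DataFrame:
    """Per-breed haplotype count table with an 'All breeds' total row.

    Columns are the catalog haplotype names plus NOVEL and UNDETERMINED;
    samples with no haplotype (NONE, e.g. females for Y) are not counted.
    """
    columns = catalog.names + [NOVEL, UNDETERMINED]
    breed_names = sorted(set(breeds.values()))
    counts = pd.DataFrame(0, index=breed_names + ["All breeds"], columns=columns)
    for call in calls:
        hap = call.y_haplotype if which == "y" else call.mt_haplotype
        if hap == NONE:
            continue
        breed = breeds.get(call.sample_id, "")
        if breed in counts.index and hap in counts.columns:
            counts.loc[breed, hap] += 1
            counts.loc["All breeds", hap] += 1
    return counts


def load_published_counts(kind: str) -> pd.DataFrame:
    """Published per-breed haplotype count tables bundled with the toolkit
    ('y': 4 Y haplotypes; 'mt': 7 mitochondrial haplotypes plus an
    undetermined column), including the printed All-breeds row."""
    fname = {"y": "y_haplotype_counts.csv", "mt": "mt_haplotype_counts.csv"}.get(
        kind.lower()
    )
    if fname is None:
        raise ValidationError(f"unknown counts kind {kind!r}")
    with resources.files("ldpanel.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, index_col="breed")
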