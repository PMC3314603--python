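"""Core domain types shared by every module of the toolkit.

The central objects are :class:`SnpRecord` (one marker of an array manifest),
:class:`SampleMeta` (one animal with pedigree links), :class:`GenotypeMatrix`
(samples x SNPs diploid calls with explicit no-call support) and
:class:`BreedFrequencyTable` (per-SNP, per-breed minor allele frequencies).

Genotypes are stored as B-allele dosage: 0 = AA, 1 = AB, 2 = BB, and
``NOCALL`` (-1) for a missing call.  A no-call is representable at every
pipeline stage and is never silently coerced to a genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NOCALL",
    "CHROMOSOMES",
    "AUTOSOMES",
    "TIERS",
    "PanelError",
    "ValidationError",
    "ParseError",
    "SchemaError",
    "normalize_chromosome",
    "chromosome_sort_key",
    "SnpRecord",
    "SampleMeta",
    "GenotypeMatrix",
    "BreedFrequencyTable",
]

#: Missing-genotype sentinel in dosage arrays.
NOCALL: int = -1

#: Bovine chromosome labels in canonical order: autosomes 1-29, then X, Y, MT.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y", "MT")

#: Marker provenance tiers, highest backward-compatibility priority first.
TIERS: tuple[str, ...] = ("BOVINE3K", "BOVINESNP50", "BOVINEHD")

_CHROM_ALIASES = {"30": "X", "31": "Y", "32": "MT", "33": "MT", "M": "MT", "MITO": "MT"}
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


class PanelError(Exception):
    """Base class for toolkit errors."""


class ValidationError(PanelError):
    """Input violates a documented precondition or invariant."""


class ParseError(PanelError):
    """A text file could not be parsed; the message names the line."""


class SchemaError(PanelError):
    """A delimited table lacks a required column."""


def normalize_chromosome(label: str) -> str:
    """Map a chromosome label onto the canonical set {1..29, X, Y, MT}.

    Accepts PLINK-style numeric sex-chromosome codes (30=X, 31=Y, 32/33=MT),
    a ``chr`` prefix, and lower case.
    """
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper()
    lab = _CHROM_ALIASES.get(lab, lab)
    if lab not in _CHROM_RANK:
        raise ValidationError(f"unknown chromosome label: {label!r}")
    return lab


def chromosome_sort_key(label: str) -> int:
    """Rank of a canonical chromosome label (autosomes ascending, X, Y, MT)."""
    return _CHROM_RANK[normalize_chromosome(label)]


@dataclass(frozen=True)
class SnpRecord:
    """One marker: identity, location, alleles and manifest role flags.

    ``alleles`` is the ordered (A-allele, B-allele) pair; it may be ``None``
    for markers read from a MAP file, in which case the PED reader infers the
    pair from the data.  ``tier`` records which higher-density assay the
    marker originates from; ``mandatory`` flags parentage / breed
    determination / Y / mtDNA content that must be kept on any design.
    """

    name: str
    chromosome: str
    position: int
    alleles: tuple[str, str] | None = None
    flank: str | None = None
    tier: str | None = None
    mandatory: bool = False
    genetic_pos: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position < 1:
            raise ValidationError(
                f"SNP {self.name}: position must be >= 1, got {self.position}"
            )
        if self.alleles is not None:
            a, b = self.alleles
            if a == b:
                raise ValidationError(f"SNP {self.name}: alleles must be distinct")
        if self.tier is not None and self.tier not in TIERS:
            raise ValidationError(f"SNP {self.name}: unknown tier {self.tier!r}")

    def with_alleles(self, a: str, b: str) -> "SnpRecord":
        return replace(self, alleles=(a, b))

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (chromosome_sort_key(self.chromosome), self.position, self.name)


@dataclass(frozen=True)
class SampleMeta:
    """One genotyped animal with its breed, sex and pedigree links."""

    id: str
    breed: str = ""
    sex: str = "unknown"  # {male, female, unknown}
    sire_id: str | None = None
    dam_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"sample {self.id}: invalid sex {self.sex!r}")
        if self.id and self.id in (self.sire_id, self.dam_id):
            raise ValidationError(f"sample {self.id} lists itself as a parent")


class GenotypeMatrix:
    """Diploid calls for an ordered sample list over an ordered SNP list.

    ``calls`` is an int8 array of shape (n_samples, n_snps) holding B-allele
    dosages {0, 1, 2} or :data:`NOCALL`.
    """

    def __init__(
        self,
        samples: Sequence[SampleMeta],
        snps: Sequence[SnpRecord],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(snps)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        bad = ~np.isin(calls, (NOCALL, 0, 1, 2))
        if bad.any():
            raise ValidationError("calls contain values outside {NOCALL, 0, 1, 2}")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in matrix")
        names = [s.name for s in snps]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate SNP names in matrix")
        self.samples = list(samples)
        self.snps = list(snps)
        self.calls = calls
        self._sample_idx = {s.id: i for i, s in enumerate(self.samples)}
        self._snp_idx = {s.name: j for j, s in enumerate(self.snps)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def snp_names(self) -> list[str]:
        return [s.name for s in self.snps]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_idx[sample_id]
        except KeyError:
            raise ValidationError(f"unknown sample id: {sample_id!r}") from None

    def snp_index(self, name: str) -> int:
        try:
            return self._snp_idx[name]
        except KeyError:
            raise ValidationError(f"unknown SNP name: {name!r}") from None

    def get(self, sample_id: str, snp_name: str) -> int:
        return int(self.calls[self.sample_index(sample_id), self.snp_index(snp_name)])

    # -- derived views -------------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.snps, self.calls.copy())

    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        snp_names: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self.sample_index(i) for i in sample_ids], dtype=int)
        )
        cols = (
            np.arange(self.n_snps)
            if snp_names is None
            else np.array([self.snp_index(n) for n in snp_names], dtype=int)
        )
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.snps[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def called_mask(self) -> np.ndarray:
        return self.calls != NOCALL

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


class BreedFrequencyTable:
    """Minor allele frequencies keyed by (SNP name, breed).

    Frequencies are folded: every stored value lies in [0, 0.5].  Missing
    (snp, breed) pairs are permitted and simply absent.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], tuple[float, int]] = {}

    def add(self, snp: str, breed: str, maf: float, n_samples: int = 0) -> None:
        if not 0.0 <= maf <= 0.5:
            raise ValidationError(
                f"({snp}, {breed}): MAF must lie in [0, 0.5], got {maf}"
            )
        if n_samples < 0:
            raise ValidationError(f"({snp}, {breed}): n_samples must be >= 0")
        self._entries[(snp, breed)] = (float(maf), int(n_samples))

    def maf(self, snp: str, breed: str) -> float | None:
        entry = self._entries.get((snp, breed))
        return None if entry is None else entry[0]

    def n_samples(self, snp: str, breed: str) -> int | None:
        entry = self._entries.get((snp, breed))
        return None if entry is None else entry[1]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @property
    def breeds(self) -> list[str]:
        return sorted({b for (_, b) in self._entries})

    @property
    def snps(self) -> list[str]:
        return sorted({s for (s, _) in self._entries})

    def snps_for_breed(self, breed: str) -> list[str]:
        return sorted(s for (s, b) in self._entries if b == breed)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"snp": s, "breed": b, "maf": m, "n": n}
            for (s, b), (m, n) in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["snp", "breed", "maf", "n"])

    @classmethod
    def from_mapping(
        cls, entries: Mapping[tuple[str, str], float | tuple[float, int]]
    ) -> "BreedFrequencyTable":
        table = cls()
        for (snp, breed), value in entries.items():
            if isinstance(value, tuple):
                table.add(snp, breed, value[0], value[1])
            else:
                table.add(snp, breed, value)
        return table
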