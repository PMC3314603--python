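"""Content-validation and frequency statistics.

Covers the statistics used to validate a low-density array on a multi-breed
sample set: per-breed allele frequencies and MAF summaries, polymorphism
rates, call rates, cross-assay concordance, Mendelian duo/trio consistency
and replicate reproducibility.

Percentages are kept unrounded internally; report writers format to two
decimal places.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NOCALL, BreedFrequencyTable, GenotypeMatrix, ValidationError

__all__ = [
    "MafSummary",
    "ConsistencyReport",
    "ConcordanceResult",
    "breed_allele_frequencies",
    "maf_summary",
    "call_rate",
    "concordance",
    "mendelian_duo",
    "mendelian_trio",
    "consistency_report",
    "aggregate_consistency",
    "load_validation_counts",
]

log = logging.getLogger(__name__)

CONSISTENT, INCONSISTENT, UNTESTABLE = "consistent", "inconsistent", "untestable"

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


@dataclass(frozen=True)
class MafSummary:
    """Per-breed MAF summary over a SNP set (mean, median, % polymorphic)."""

    breed: str
    mean_maf: float
    median_maf: float
    pct_polymorphic: float
    n_snps: int
    n_samples: int
    n_missing: int = 0


@dataclass(frozen=True)
class ConsistencyReport:
    """Aggregated outcome of duo / trio / replicate genotype comparisons."""

    comparison_kind: str  # {duo, trio, replicate}
    breed: str
    n_comparisons: int
    n_genotyped: int
    n_inconsistent: int

    def __post_init__(self) -> None:
        if self.n_inconsistent > self.n_genotyped:
            raise ValidationError("inconsistent count exceeds genotyped count")

    @property
    def pct_consistent(self) -> float:
        if self.n_genotyped == 0:
            return float("nan")
        return 100.0 * (self.n_genotyped - self.n_inconsistent) / self.n_genotyped


@dataclass(frozen=True)
class ConcordanceResult:
    pct_concordant: float
    n_compared: int
    n_discordant: int
    discordant: pd.DataFrame


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def breed_allele_frequencies(
    g: GenotypeMatrix, grouping: Mapping[str, str] | None = None
) -> BreedFrequencyTable:
    """Estimate folded MAFs per (SNP, breed) from genotype calls.

    ``maf = min(p, 1 - p)`` with ``p`` the B-allele dosage sum over called
    genotypes divided by twice the called-sample count; no-calls are excluded
    from the denominator.  ``grouping`` maps sample id to breed and defaults
    to each sample's own breed field.  (SNP, breed) cells with no called
    genotype produce no entry.
    """
    if grouping is None:
        grouping = {s.id: s.breed for s in g.samples}
    table = BreedFrequencyTable()
    breeds = sorted(set(grouping.values()))
    names = g.snp_names
    for breed in breeds:
        rows = [i for i, s in enumerate(g.samples) if grouping.get(s.id) == breed]
        if not rows:
            continue
        calls = g.calls[rows, :]
        called = calls != NOCALL
        n_called = called.sum(axis=0)
        dosage = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = dosage / (2.0 * n_called)
        for j, name in enumerate(names):
            if n_called[j] > 0:
                table.add(name, breed, min(p[j], 1.0 - p[j]), int(n_called[j]))
    return table


def maf_summary(
    table: BreedFrequencyTable, breed: str, snps: Sequence[str]
) -> MafSummary:
    """Summarize a breed's MAFs over a SNP list.

    SNPs without an entry for the breed are excluded from the statistics and
    counted in ``n_missing``.  A locus counts as polymorphic when its
    estimated MAF is > 0 in that breed's sample.
    """
    if breed not in table.breeds:
        raise ValidationError(f"breed {breed!r} absent from frequency table")
    mafs = [table.maf(s, breed) for s in snps]
    present = np.array([m for m in mafs if m is not None], dtype=float)
    n_missing = len(snps) - len(present)
    if len(present) == 0:
        raise ValidationError(f"no frequency entries for breed {breed!r} on given SNPs")
    n_samples = max(
        (table.n_samples(s, breed) or 0) for s in snps if (s, breed) in table
    )
    return MafSummary(
        breed=breed,
        mean_maf=float(present.mean()),
        median_maf=float(np.median(present)),
        pct_polymorphic=100.0 * float((present > 0).mean()),
        n_snps=len(present),
        n_samples=n_samples,
        n_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# Call rate and concordance
# ---------------------------------------------------------------------------

def call_rate(g: GenotypeMatrix, axis: str = "overall"):
    """Percent of assay attempts yielding a call, overall or along one axis.

    Returns a float for ``overall`` or a pandas Series indexed by sample id /
    SNP name for ``per_sample`` / ``per_snp``.
    """
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValidationError("call_rate requires a non-empty matrix")
    called = g.called_mask()
    if axis == "overall":
        return 100.0 * float(called.mean())
    if axis == "per_sample":
        return pd.Series(100.0 * called.mean(axis=1), index=g.sample_ids)
    if axis == "per_snp":
        return pd.Series(100.0 * called.mean(axis=0), index=g.snp_names)
    raise ValidationError(f"unknown axis {axis!r}")


def concordance(g1: GenotypeMatrix, g2: GenotypeMatrix) -> ConcordanceResult:
    """Agreement rate of calls across two assays of the same samples.

    The matrices are intersected on shared sample ids and SNP names; a cell
    enters the denominator only where both calls are non-missing.
    """
    shared_samples = [s for s in g1.sample_ids if s in set(g2.sample_ids)]
    shared_snps = [s for s in g1.snp_names if s in set(g2.snp_names)]
    if not shared_samples or not shared_snps:
        raise ValidationError("no shared samples/SNPs between matrices")
    a = g1.subset(shared_samples, shared_snps)
    b = g2.subset(shared_samples, shared_snps)
    both = (a.calls != NOCALL) & (b.calls != NOCALL)
    n_compared = int(both.sum())
    mismatch = both & (a.calls != b.calls)
    n_disc = int(mismatch.sum())
    rows, cols = np.nonzero(mismatch)
    disc = pd.DataFrame(
        {
            "sample": [shared_samples[i] for i in rows],
            "snp": [shared_snps[j] for j in cols],
            "call_1": a.calls[rows, cols],
            "call_2": b.calls[rows, cols],
        }
    )
    pct = 100.0 * (n_compared - n_disc) / n_compared if n_compared else float("nan")
    return ConcordanceResult(pct, n_compared, n_disc, disc)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def mendelian_duo(parent: int, child: int) -> str:
    """Duo check: inconsistent iff parent and child are opposite homozygotes.

    Opposite homozygosity is the only duo-detectable error class; either
    call missing makes the comparison untestable.
    """
    if parent == NOCALL or child == NOCALL:
        return UNTESTABLE
    return INCONSISTENT if abs(parent - child) == 2 else CONSISTENT


def mendelian_trio(sire: int, dam: int, child: int) -> str:
    """Trio check: can the child receive one allele from each parent?

    With one parent missing the check degrades to duo logic on the remaining
    parent; with the child or both parents missing it is untestable.
    """
    if child == NOCALL:
        return UNTESTABLE
    if sire == NOCALL and dam == NOCALL:
        return UNTESTABLE
    if sire == NOCALL:
        return mendelian_duo(dam, child)
    if dam == NOCALL:
        return mendelian_duo(sire, child)
    for a in _ALLELES[sire]:
        for b in _ALLELES[dam]:
            if a + b == child:
                return CONSISTENT
    return INCONSISTENT


_STATUS_CODE = {CONSISTENT: 0, INCONSISTENT: 1, UNTESTABLE: 2}
_DUO_TABLE = np.array(
    [[_STATUS_CODE[mendelian_duo(p, c)] for c in (-1, 0, 1, 2)] for p in (-1, 0, 1, 2)],
    dtype=np.int8,
)
_TRIO_TABLE = np.array(
    [
        [
            [_STATUS_CODE[mendelian_trio(s, d, c)] for c in (-1, 0, 1, 2)]
            for d in (-1, 0, 1, 2)
        ]
        for s in (-1, 0, 1, 2)
    ],
    dtype=np.int8,
)


def _count_codes(codes: np.ndarray) -> tuple[int, int]:
    """(n testable, n inconsistent) from a vector of status codes."""
    return int((codes != 2).sum()), int((codes == 1).sum())


def consistency_report(
    g: GenotypeMatrix,
    replicates: Iterable[tuple[str, str]] = (),
) -> list[ConsistencyReport]:
    """Aggregate Mendelian duo/trio and replicate comparisons over a matrix.

    Pedigree links come from each sample's sire/dam ids; links that do not
    resolve to a genotyped sample are skipped with a warning.  A sample with
    both parents genotyped contributes one trio comparison, with exactly one
    parent a duo comparison.  ``replicates`` lists sample-id pairs declared
    to be the same animal; their comparison counts mismatching called
    genotypes.  Results are reported per (kind, breed) plus an overall row
    per kind.
    """
    idx = {s.id: i for i, s in enumerate(g.samples)}
    per_key: dict[tuple[str, str], list[int]] = {}

    def tally(kind: str, breed: str, n_genotyped: int, n_bad: int) -> None:
        acc = per_key.setdefault((kind, breed), [0, 0, 0])
        acc[0] += 1
        acc[1] += n_genotyped
        acc[2] += n_bad

    for sample in g.samples:
        child = idx[sample.id]
        sire = idx.get(sample.sire_id) if sample.sire_id else None
        dam = idx.get(sample.dam_id) if sample.dam_id else None
        if sample.sire_id and sire is None:
            log.warning("sire %s of %s not genotyped; link skipped", sample.sire_id, sample.id)
        if sample.dam_id and dam is None:
            log.warning("dam %s of %s not genotyped; link skipped", sample.dam_id, sample.id)
        if sire is not None and dam is not None:
            codes = _TRIO_TABLE[
                g.calls[sire] + 1, g.calls[dam] + 1, g.calls[child] + 1
            ]
            tally("trio", sample.breed, *_count_codes(codes))
        elif sire is not None or dam is not None:
            parent = sire if sire is not None else dam
            codes = _DUO_TABLE[g.calls[parent] + 1, g.calls[child] + 1]
            tally("duo", sample.breed, *_count_codes(codes))

    for id_a, id_b in replicates:
        if id_a not in idx or id_b not in idx:
            log.warning("replicate pair (%s, %s) not fully genotyped; skipped", id_a, id_b)
            continue
        a, b = g.calls[idx[id_a]], g.calls[idx[id_b]]
        both = (a != NOCALL) & (b != NOCALL)
        tally(
            "replicate",
            g.samples[idx[id_a]].breed,
            int(both.sum()),
            int((both & (a != b)).sum()),
        )

    reports = [
        ConsistencyReport(kind, breed, *counts)
        for (kind, breed), counts in sorted(per_key.items())
    ]
    reports.extend(aggregate_consistency(reports))
    return reports


def aggregate_consistency(
    rows: Iterable[ConsistencyReport], kinds: Mapping[str, str] | None = None
) -> list[ConsistencyReport]:
    """Sum per-breed comparison rows into overall rows.

    ``kinds`` optionally maps each comparison kind onto an aggregate label
    (e.g. duo and trio both onto "mendelian"); by default each kind
    aggregates to itself.  Overall rows carry breed "Overall".
    """
    acc: dict[str, list[int]] = {}
    for r in rows:
        if r.breed == "Overall":
            continue
        label = (kinds or {}).get(r.comparison_kind, r.comparison_kind)
        a = acc.setdefault(label, [0, 0, 0])
        a[0] += r.n_comparisons
        a[1] += r.n_genotyped
        a[2] += r.n_inconsistent
    return [
        ConsistencyReport(kind, "Overall", *counts) for kind, counts in sorted(acc.items())
    ]


def load_validation_counts() -> pd.DataFrame:
    """Published per-breed validation comparison counts bundled with the
    toolkit (Mendelian duo/trio and replicate comparisons for the 6,844 SNPs
    shared between the low- and high-density bovine assays)."""
    with resources.files("ldpanel.data").joinpath(
        "validation_consistency_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)
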