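"""Spacing/gap statistics and composition summaries for a finished panel.

A gap is the position difference between adjacent markers on the same
chromosome (no +/-1 adjustment); gaps are never computed across chromosome
boundaries.  Pooled statistics by default cover autosomes plus X and exclude
Y and mitochondrial markers, whose coordinates are not comparable to the
nuclear spacing target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BreedFrequencyTable, SnpRecord, chromosome_sort_key
from .stats import MafSummary, maf_summary

__all__ = ["GapStats", "gap_stats", "gap_histogram", "composition_report"]

log = logging.getLogger(__name__)

_DEFAULT_CHROMS = tuple(str(i) for i in range(1, 30)) + ("X",)


@dataclass
class GapStats:
    """Per-chromosome and pooled adjacent-marker spacing statistics."""

    per_chromosome: dict[str, np.ndarray]
    threshold: int
    #: chromosomes with fewer than two markers (spacing undefined)
    degenerate: list[str] = field(default_factory=list)

    @property
    def pooled(self) -> np.ndarray:
        if not self.per_chromosome:
            return np.array([], dtype=int)
        return np.concatenate([self.per_chromosome[c] for c in sorted(
            self.per_chromosome, key=chromosome_sort_key)])

    @property
    def n_gaps(self) -> int:
        return int(self.pooled.size)

    @property
    def median_spacing_mbp(self) -> float:
        """Pooled median spacing in Mbp, rounded to 3 decimals."""
        return round(float(np.median(self.pooled)) / 1e6, 3)

    @property
    def mean_spacing_mbp(self) -> float:
        return float(self.pooled.mean()) / 1e6

    @property
    def n_over_threshold(self) -> int:
        return int((self.pooled > self.threshold).sum())

    @property
    def frac_over_threshold(self) -> float:
        return self.n_over_threshold / self.n_gaps if self.n_gaps else 0.0

    @property
    def largest_gap(self) -> tuple[str, int]:
        """(chromosome, gap size in bp) of the widest interval."""
        best = ("", 0)
        for chrom, gaps in self.per_chromosome.items():
            if gaps.size and int(gaps.max()) > best[1]:
                best = (chrom, int(gaps.max()))
        return best


def gap_stats(
    manifest: Sequence[SnpRecord],
    threshold: int = 1_000_000,
    chromosomes: Sequence[str] | None = None,
) -> GapStats:
    """Adjacent-marker gap statistics over a manifest.

    ``chromosomes`` filters the pooled set (default: autosomes + X).  Input
    that is not sorted by (chromosome, position) is auto-sorted with a
    warning.  Chromosomes with fewer than two markers contribute no gaps and
    are flagged in ``degenerate``.
    """
    wanted = set(chromosomes if chromosomes is not None else _DEFAULT_CHROMS)
    records = [r for r in manifest if r.chromosome in wanted]
    keys = [r.sort_key for r in records]
    if keys != sorted(keys):
        log.warning("manifest not sorted by (chromosome, position); sorting")
        records = sorted(records, key=lambda r: r.sort_key)
    per: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for chrom in sorted({r.chromosome for r in records}, key=chromosome_sort_key):
        pos = np.array([r.position for r in records if r.chromosome == chrom])
        if pos.size < 2:
            degenerate.append(chrom)
            continue
        per[chrom] = np.diff(pos)
    return GapStats(per_chromosome=per, threshold=threshold, degenerate=degenerate)


def gap_histogram(stats: GapStats, bin_mbp: float = 0.1) -> pd.DataFrame:
    """Histogram of pooled gaps in fixed Mbp bins (bin start, count)."""
    gaps = stats.pooled / 1e6
    if gaps.size == 0:
        return pd.DataFrame(columns=["bin_start_mbp", "count"])
    n_bins = int(np.floor(gaps.max() / bin_mbp)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_mbp, bin_mbp)
    counts, _ = np.histogram(gaps, bins=edges)
    return pd.DataFrame(
        {"bin_start_mbp": np.round(edges[:-1], 10), "count": counts}
    )


def composition_report(
    manifest: Sequence[SnpRecord],
    table: BreedFrequencyTable | None = None,
    reasons: Mapping[str, str] | None = None,
) -> dict:
    """Panel composition summary: per-chromosome and per-tier marker counts,
    optional per-breed MAF summaries and selection-reason counts.

    ``reasons`` optionally maps marker name to its selection provenance.
    """
    by_chrom: dict[str, int] = {}
    by_tier: dict[str, int] = {}
    for r in manifest:
        by_chrom[r.chromosome] = by_chrom.get(r.chromosome, 0) + 1
        if r.tier:
            by_tier[r.tier] = by_tier.get(r.tier, 0) + 1
    out: dict = {
        "n_snps": len(manifest),
        "by_chromosome": dict(
            sorted(by_chrom.items(), key=lambda kv: chromosome_sort_key(kv[0]))
        ),
        "by_tier": by_tier,
    }
    if reasons:
        by_reason: dict[str, int] = {}
        for r in manifest:
            reason = reasons.get(r.name)
            if reason:
                by_reason[reason] = by_reason.get(reason, 0) + 1
        out["by_reason"] = by_reason
    if table is not None and len(table):
        names = [r.name for r in manifest]
        summaries: list[MafSummary] = []
        for breed in table.breeds:
            try:
                summaries.append(maf_summary(table, breed, names))
            except Exception:  # breed with no entries on this panel
                continue
        out["maf_by_breed"] = summaries
    return out
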