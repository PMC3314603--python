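"""Window-based, MAF-driven selection of a low-density SNP panel.

The design algorithm tiles each autosome into fixed windows (default
500 kbp), scores every candidate marker on two minor-allele-frequency
criteria — a weighted mean MAF over a breed list and a minimum MAF over a
second breed list — and keeps the top-scoring marker(s) per window, with the
pick count doubled in the first and last window of each chromosome so that
imputation does not degrade near chromosome ends.  A second selection round
rescores the survivors on additional populations.  Post-processing swaps
markers for nearby legacy-chip markers to reach a backward-compatibility
overlap target, injects mandatory content (parentage, breed determination),
fills residual gaps above a threshold, assembles X-chromosome content by
assay tier, and appends fixed Y and mitochondrial marker lists.

Tie-breaking is deterministic throughout: higher combined score first, then
lower position, then lexicographic marker name.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    AUTOSOMES,
    TIERS,
    BreedFrequencyTable,
    SnpRecord,
    ValidationError,
    chromosome_sort_key,
)

__all__ = [
    "Window",
    "WindowGrid",
    "CriterionConfig",
    "SelectionConfig",
    "PanelEntry",
    "PanelDesign",
    "build_window_grid",
    "score_weighted_mean_maf",
    "score_min_maf",
    "combine_criteria",
    "select_in_windows",
    "two_round_select",
    "apply_backward_compatibility",
    "fill_gaps",
    "select_x",
    "design_panel",
]

log = logging.getLogger(__name__)

REASONS = (
    "WINDOW_BEST",
    "TERMINAL_EXTRA",
    "COMPAT_SWAP",
    "MANDATORY",
    "GAP_FILL",
    "X_TIER",
    "Y_FIXED",
    "MT_FIXED",
)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    chromosome: str
    index: int  # 1-based along the chromosome
    start: int  # inclusive, 1-based
    end: int  # inclusive
    terminal: bool


class WindowGrid:
    """Non-overlapping windows tiling [1, length] of each chromosome."""

    def __init__(self, windows: Mapping[str, Sequence[Window]], window_size: int):
        self.window_size = window_size
        self._windows = {c: list(ws) for c, ws in windows.items()}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._windows, key=chromosome_sort_key)

    def windows(self, chromosome: str) -> list[Window]:
        return self._windows[chromosome]

    def window_for(self, chromosome: str, position: int) -> Window:
        if chromosome not in self._windows:
            raise ValidationError(f"chromosome {chromosome!r} absent from window grid")
        idx = (position - 1) // self.window_size
        ws = self._windows[chromosome]
        if idx >= len(ws):
            raise ValidationError(
                f"position {position} beyond chromosome {chromosome} length"
            )
        return ws[idx]

    def __iter__(self):
        for chrom in self.chromosomes:
            yield from self._windows[chrom]


def build_window_grid(
    chrom_lengths: Mapping[str, int], window_size: int = 500_000
) -> WindowGrid:
    """Tile each chromosome into consecutive ``window_size`` windows.

    Window k (1-based) spans [(k-1)*w + 1, min(k*w, L)]; the last window may
    be short.  The first and last window of each chromosome are flagged
    terminal; a single-window chromosome is terminal once.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    grid: dict[str, list[Window]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom}: length must be positive")
        n = -(-length // window_size)  # ceil
        grid[chrom] = [
            Window(
                chromosome=chrom,
                index=k,
                start=(k - 1) * window_size + 1,
                end=min(k * window_size, length),
                terminal=(k == 1 or k == n),
            )
            for k in range(1, n + 1)
        ]
    return WindowGrid(grid, window_size)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CriterionConfig:
    """Breed lists for one selection round's two MAF criteria."""

    mean_breeds: list[str]
    min_breeds: list[str]
    mean_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectionConfig:
    round1: CriterionConfig
    round2: CriterionConfig | None = None
    window_size: int = 500_000
    picks_per_window: int = 1
    terminal_picks: int = 2
    compat_target: int = 2_000
    compat_radius: int = 250_000
    max_gap: int = 1_000_000
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValidationError("window_size must be positive")
        if self.picks_per_window < 1:
            raise ValidationError("picks_per_window must be >= 1")
        if self.terminal_picks < self.picks_per_window:
            raise ValidationError("terminal_picks must be >= picks_per_window")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionConfig":
        def crit(key: str) -> CriterionConfig | None:
            if key not in d or d[key] is None:
                return None
            c = d[key]
            return CriterionConfig(
                mean_breeds=list(c["mean_breeds"]),
                min_breeds=list(c["min_breeds"]),
                mean_weights=dict(c.get("mean_weights") or {}),
            )

        r1 = crit("round1")
        if r1 is None:
            raise ValidationError("config must define round1 criteria")
        kwargs = {
            k: d[k]
            for k in (
                "window_size", "picks_per_window", "terminal_picks",
                "compat_target", "compat_radius", "max_gap",
            )
            if k in d
        }
        lengths = {str(c): int(v) for c, v in (d.get("chrom_lengths") or {}).items()}
        return cls(round1=r1, round2=crit("round2"), chrom_lengths=lengths, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SelectionConfig":
        """The shipped default configuration (breed lists and weights for the
        two selection rounds); chromosome lengths must still be supplied."""
        with resources.files("ldpanel.data").joinpath("default_design.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    """One selected marker with its selection provenance."""

    record: SnpRecord
    reason: str
    window: tuple[str, int] | None = None
    score_a: float | None = None
    score_b: float | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValidationError(f"unknown selection reason {self.reason!r}")


class PanelDesign:
    """An ordered, duplicate-free selected-marker list with provenance."""

    def __init__(self, entries: Sequence[PanelEntry] = ()):
        self._entries: dict[str, PanelEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: PanelEntry, replace: bool = False) -> None:
        name = entry.record.name
        if name in self._entries and not replace:
            raise ValidationError(f"duplicate SNP {name!r} in panel design")
        self._entries[name] = entry

    def remove(self, name: str) -> PanelEntry:
        return self._entries.pop(name)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, name: str) -> PanelEntry:
        return self._entries[name]

    @property
    def entries(self) -> list[PanelEntry]:
        return sorted(self._entries.values(), key=lambda e: e.record.sort_key)

    @property
    def snps(self) -> list[SnpRecord]:
        return [e.record for e in self.entries]

    @property
    def names(self) -> set[str]:
        return set(self._entries)

    def entries_on(self, chromosome: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.record.chromosome == chromosome]

    def merged_with(self, other: "PanelDesign") -> "PanelDesign":
        out = PanelDesign(self.entries)
        for e in other.entries:
            if e.record.name not in out:
                out.add(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            r = e.record
            rows.append(
                {
                    "name": r.name,
                    "chromosome": r.chromosome,
                    "position": r.position,
                    "allele_a": r.alleles[0] if r.alleles else "",
                    "allele_b": r.alleles[1] if r.alleles else "",
                    "tier": r.tier or "",
                    "mandatory": int(r.mandatory),
                    "window": e.window[1] if e.window else "",
                    "score_a": e.score_a if e.score_a is not None else "",
                    "score_b": e.score_b if e.score_b is not None else "",
                    "score": e.score if e.score is not None else "",
                    "reason": e.reason,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        by_reason: dict[str, int] = {}
        by_chrom: dict[str, int] = {}
        for e in self.entries:
            by_reason[e.reason] = by_reason.get(e.reason, 0) + 1
            c = e.record.chromosome
            by_chrom[c] = by_chrom.get(c, 0) + 1
        return {"n_snps": len(self), "by_reason": by_reason, "by_chromosome": by_chrom}


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_weighted_mean_maf(
    table: BreedFrequencyTable,
    breeds: Sequence[str],
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Weighted mean MAF per SNP over the listed breeds.

    Breeds without an entry for a SNP are excluded from that SNP's mean
    (both numerator and weight sum); SNPs with no entry in any listed breed
    receive no score.
    """
    if not breeds:
        raise ValidationError("breed list must be non-empty")
    weights = dict(weights or {})
    for b, w in weights.items():
        if w <= 0:
            raise ValidationError(f"weight for breed {b!r} must be positive")
    breed_set = set(breeds)
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for (snp, breed), (maf, _n) in table.items():
        if breed in breed_set:
            w = weights.get(breed, 1.0)
            num[snp] = num.get(snp, 0.0) + w * maf
            den[snp] = den.get(snp, 0.0) + w
    return {snp: num[snp] / den[snp] for snp in num}


def score_min_maf(
    table: BreedFrequencyTable, breeds: Sequence[str]
) -> dict[str, float]:
    """Minimum MAF per SNP across the listed breeds (breeds with entries)."""
    if not breeds:
        raise ValidationError("breed list must be non-empty")
    breed_set = set(breeds)
    out: dict[str, float] = {}
    for (snp, breed), (maf, _n) in table.items():
        if breed in breed_set:
            cur = out.get(snp)
            out[snp] = maf if cur is None else min(cur, maf)
    return out


def combine_criteria(
    score_a: Mapping[str, float], score_b: Mapping[str, float]
) -> dict[str, float]:
    """Mean of the two criterion scores; SNPs missing either are excluded."""
    return {s: (a + score_b[s]) / 2.0 for s, a in score_a.items() if s in score_b}


def criterion_scores(
    table: BreedFrequencyTable, criterion: CriterionConfig
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """(criterion-A, criterion-B, combined) score maps for one round."""
    a = score_weighted_mean_maf(table, criterion.mean_breeds, criterion.mean_weights)
    b = score_min_maf(table, criterion.min_breeds)
    return a, b, combine_criteria(a, b)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _ranked(entries: list[tuple[float, SnpRecord]]) -> list[tuple[float, SnpRecord]]:
    return sorted(entries, key=lambda t: (-t[0], t[1].position, t[1].name))


def select_in_windows(
    candidates: Sequence[SnpRecord],
    scores: Mapping[str, float],
    grid: WindowGrid,
    cfg: SelectionConfig,
    score_a: Mapping[str, float] | None = None,
    score_b: Mapping[str, float] | None = None,
    reason: str = "WINDOW_BEST",
    extra_reason: str = "TERMINAL_EXTRA",
) -> PanelDesign:
    """Keep the top-scoring candidates per window.

    Interior windows keep ``picks_per_window`` markers, terminal windows
    ``terminal_picks``; windows with fewer scored candidates keep all of
    them.  Candidates without a score are excluded.  In terminal windows the
    picks beyond ``picks_per_window`` are flagged with ``extra_reason``.
    """
    per_window: dict[tuple[str, int], list[tuple[float, SnpRecord]]] = {}
    for rec in candidates:
        if rec.name not in scores:
            continue
        win = grid.window_for(rec.chromosome, rec.position)
        per_window.setdefault((rec.chromosome, win.index), []).append(
            (scores[rec.name], rec)
        )

    design = PanelDesign()
    for (chrom, idx) in sorted(per_window, key=lambda k: (chromosome_sort_key(k[0]), k[1])):
        win = grid.windows(chrom)[idx - 1]
        k = cfg.terminal_picks if win.terminal else cfg.picks_per_window
        for rank, (score, rec) in enumerate(_ranked(per_window[(chrom, idx)])[:k]):
            design.add(
                PanelEntry(
                    record=rec,
                    reason=reason if rank < cfg.picks_per_window else extra_reason,
                    window=(chrom, idx),
                    score_a=score_a.get(rec.name) if score_a else None,
                    score_b=score_b.get(rec.name) if score_b else None,
                    score=score,
                )
            )
    return design


def two_round_select(
    candidates: Sequence[SnpRecord],
    table: BreedFrequencyTable,
    grid: WindowGrid,
    cfg: SelectionConfig,
) -> PanelDesign:
    """Two-round window-wise selection.

    Round 1 scores and selects from the full candidate list; its output
    becomes the exclusive candidate pool for round 2, which applies its own
    breed lists with the same window and terminal pick counts.
    """
    a1, b1, c1 = criterion_scores(table, cfg.round1)
    sel1 = select_in_windows(candidates, c1, grid, cfg, score_a=a1, score_b=b1)
    if cfg.round2 is None:
        return sel1
    a2, b2, c2 = criterion_scores(table, cfg.round2)
    return select_in_windows(sel1.snps, c2, grid, cfg, score_a=a2, score_b=b2)


def apply_backward_compatibility(
    sel: PanelDesign,
    compat: Sequence[SnpRecord],
    max_shift: int,
    target: int,
) -> PanelDesign:
    """Swap selected markers for nearby legacy-chip markers until the overlap
    with the legacy set reaches ``target`` (best effort).

    At each step the selected non-legacy marker whose nearest unused legacy
    marker (same chromosome, distance <= ``max_shift``) is closest is
    replaced by that legacy marker, keeping the original window accounting.
    Stops when the target is met or no eligible swap remains.
    """
    out = PanelDesign(sel.entries)
    compat_names = {r.name for r in compat}
    used = {n for n in out.names if n in compat_names}
    overlap = len(used)

    # unused legacy markers per chromosome, position-sorted
    by_chrom: dict[str, list[SnpRecord]] = {}
    for r in sorted(compat, key=lambda r: r.sort_key):
        if r.name not in out:
            by_chrom.setdefault(r.chromosome, []).append(r)

    def nearest(rec: SnpRecord) -> tuple[int, SnpRecord] | None:
        pool = by_chrom.get(rec.chromosome)
        if not pool:
            return None
        positions = [p.position for p in pool]
        i = bisect_left(positions, rec.position)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pool):
                d = abs(pool[j].position - rec.position)
                if d <= max_shift and (best is None or (d, pool[j].name) < (best[0], best[1].name)):
                    best = (d, pool[j])
        return best

    while overlap < target:
        swap = None  # (distance, entry, legacy record)
        for entry in out.entries:
            if entry.record.name in compat_names or entry.reason not in (
                "WINDOW_BEST", "TERMINAL_EXTRA",
            ):
                continue
            cand = nearest(entry.record)
            if cand and (
                swap is None
                or (cand[0], entry.record.name) < (swap[0], swap[1].record.name)
            ):
                swap = (cand[0], entry, cand[1])
        if swap is None:
            log.info("compat target %d not reached; overlap %d", target, overlap)
            break
        _d, entry, legacy = swap
        out.remove(entry.record.name)
        out.add(PanelEntry(record=legacy, reason="COMPAT_SWAP", window=entry.window))
        by_chrom[legacy.chromosome].remove(legacy)
        overlap += 1
    return out


def fill_gaps(
    sel: PanelDesign,
    pool: Sequence[SnpRecord],
    max_gap: int,
    scores: Mapping[str, float] | None = None,
) -> PanelDesign:
    """Add pool markers into same-chromosome gaps wider than ``max_gap``.

    For each adjacent selected pair farther apart than ``max_gap``, the pool
    marker closest to the gap midpoint is added (ties: higher score, lower
    position, name), iterating until no fillable gap remains.  Unfillable
    gaps are logged and left.
    """
    out = PanelDesign(sel.entries)
    scores = scores or {}
    available = sorted(
        (r for r in pool if r.name not in out), key=lambda r: r.sort_key
    )
    changed = True
    while changed:
        changed = False
        by_chrom: dict[str, list[SnpRecord]] = {}
        for r in available:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for chrom in sorted({e.record.chromosome for e in out.entries}, key=chromosome_sort_key):
            recs = [e.record for e in out.entries_on(chrom)]
            for left, right in zip(recs, recs[1:]):
                if right.position - left.position <= max_gap:
                    continue
                inside = [
                    r
                    for r in by_chrom.get(chrom, ())
                    if left.position < r.position < right.position
                ]
                if not inside:
                    log.info(
                        "gap %s:%d-%d (%d bp) has no candidate to fill",
                        chrom, left.position, right.position,
                        right.position - left.position,
                    )
                    continue
                mid = (left.position + right.position) / 2.0
                best = min(
                    inside,
                    key=lambda r: (
                        abs(r.position - mid),
                        -scores.get(r.name, 0.0),
                        r.position,
                        r.name,
                    ),
                )
                out.add(
                    PanelEntry(
                        record=best,
                        reason="GAP_FILL",
                        score=scores.get(best.name),
                    )
                )
                available.remove(best)
                changed = True
                break  # re-scan this chromosome with the new marker in place
    return out


def select_x(
    tiers: Sequence[Sequence[SnpRecord]],
    table: BreedFrequencyTable,
    grid: WindowGrid,
    cfg: SelectionConfig,
    criterion: CriterionConfig | None = None,
) -> PanelDesign:
    """Assemble X-chromosome content from prioritized assay tiers.

    ``tiers`` lists candidate sets in priority order (legacy low-density
    content first, then medium-density, then high-density).  Each window is
    filled from the highest-priority tier that has a scored candidate in it;
    lower tiers are used only for windows left empty.  Residual gaps are
    then filled from the lowest-priority tier.
    """
    criterion = criterion or cfg.round1
    a, b, combined = criterion_scores(table, criterion)
    design = PanelDesign()
    filled: set[tuple[str, int]] = set()
    for tier_cands in tiers:
        fragment = select_in_windows(
            tier_cands, combined, grid, cfg,
            score_a=a, score_b=b, reason="X_TIER", extra_reason="X_TIER",
        )
        for e in fragment.entries:
            if e.window not in filled and e.record.name not in design:
                design.add(e)
        filled |= {e.window for e in design.entries if e.window}
    if tiers:
        design = fill_gaps(design, tiers[-1], cfg.max_gap, scores=combined)
    return design


def design_panel(
    cfg: SelectionConfig,
    candidates: Sequence[SnpRecord],
    table: BreedFrequencyTable,
    compat: Sequence[SnpRecord] = (),
    mandatory: Sequence[SnpRecord] = (),
    y_fixed: Sequence[SnpRecord] = (),
    mt_fixed: Sequence[SnpRecord] = (),
) -> PanelDesign:
    """Run the full design pipeline and return the finished panel.

    Autosomal candidates go through two-round window selection, legacy-chip
    compatibility swapping, mandatory-marker injection and gap filling; X
    candidates are assembled by assay tier; the fixed Y and mitochondrial
    marker lists are appended.  The result is sorted by (chromosome,
    position) and duplicate-free.
    """
    grid = build_window_grid(cfg.chrom_lengths, cfg.window_size)
    autosomal = [r for r in candidates if r.chromosome in AUTOSOMES]
    x_cands = [r for r in candidates if r.chromosome == "X"]
    other = [r for r in candidates if r.chromosome not in AUTOSOMES + ("X",)]
    if other:
        raise ValidationError(
            "Y/MT markers must be passed via y_fixed/mt_fixed, not candidates: "
            + ", ".join(r.name for r in other[:5])
        )

    sel = two_round_select(autosomal, table, grid, cfg)
    if compat and cfg.compat_target > 0:
        sel = apply_backward_compatibility(
            sel, compat, cfg.compat_radius, cfg.compat_target
        )
    for rec in sorted(mandatory, key=lambda r: r.sort_key):
        if rec.name not in sel:
            sel.add(PanelEntry(record=rec, reason="MANDATORY"))
    final_crit = cfg.round2 or cfg.round1
    _a, _b, combined = criterion_scores(table, final_crit)
    pool = [r for r in autosomal if r.name not in sel]
    sel = fill_gaps(sel, pool, cfg.max_gap, scores=combined)

    if x_cands and "X" in cfg.chrom_lengths:
        tier_rank = {t: i for i, t in enumerate(TIERS)}
        tiers: list[list[SnpRecord]] = [[] for _ in TIERS]
        for r in sorted(x_cands, key=lambda r: r.sort_key):
            tiers[tier_rank.get(r.tier or "BOVINEHD", len(TIERS) - 1)].append(r)
        sel = sel.merged_with(select_x(tiers, table, grid, cfg))

    for rec, reason in [(r, "Y_FIXED") for r in y_fixed] + [
        (r, "MT_FIXED") for r in mt_fixed
    ]:
        if rec.name not in sel:
            sel.add(PanelEntry(record=rec, reason=reason))
    return sel
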