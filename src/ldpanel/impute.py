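"""In-silico imputation-accuracy evaluation for a candidate panel.

The evaluation protocol mirrors how low-density arrays are validated in
practice: take a population genotyped at high density, keep part of it as a
reference, reduce the target animals' genotypes in silico to the panel under
test, impute the masked genotypes back, and score the proportion of correct
genotypes — both over the imputed (off-panel) markers only and over all
markers, stratified by whether each target's sire and dam were genotyped.

The built-in imputer is a deliberately simple windowed haplotype-library
method: a greedy within-window phasing pass over the reference builds a
library of haplotype vectors, and each target is assigned the library pair
that best matches its observed panel calls (optionally restricted to a
genotyped parent's haplotypes).  It is an evaluation harness, not a
production imputer; accuracy is counted per genotype (a heterozygous
imputation of a homozygous truth genotype is one error), matching standard
practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NOCALL, GenotypeMatrix, ValidationError

__all__ = [
    "MaskSpec",
    "LibraryWindow",
    "HaplotypeLibrary",
    "AccuracyResult",
    "ImputationReport",
    "mask_to_panel",
    "build_library",
    "impute",
    "accuracy",
    "run_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskSpec:
    """Which samples are reduced to which panel for an experiment."""

    panel_snps: frozenset[str]
    target_ids: frozenset[str]
    reference_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.target_ids & self.reference_ids:
            raise ValidationError("target and reference sample sets must be disjoint")

    @classmethod
    def create(
        cls,
        panel_snps: Iterable[str],
        target_ids: Iterable[str],
        reference_ids: Iterable[str],
    ) -> "MaskSpec":
        return cls(frozenset(panel_snps), frozenset(target_ids), frozenset(reference_ids))


def mask_to_panel(g: GenotypeMatrix, spec: MaskSpec) -> GenotypeMatrix:
    """Reduce target samples' genotypes to the panel: off-panel calls become
    NOCALL; reference samples are returned unchanged."""
    snp_names = set(g.snp_names)
    unknown = spec.panel_snps - snp_names
    if unknown:
        raise ValidationError(f"panel SNPs absent from matrix: {sorted(unknown)[:5]}")
    sample_ids = set(g.sample_ids)
    unknown_ids = (spec.target_ids | spec.reference_ids) - sample_ids
    if unknown_ids:
        raise ValidationError(f"unknown sample ids in spec: {sorted(unknown_ids)[:5]}")
    out = g.copy()
    off_panel = np.array([s.name not in spec.panel_snps for s in g.snps])
    for i, sample in enumerate(g.samples):
        if sample.id in spec.target_ids:
            out.calls[i, off_panel] = NOCALL
    return out


# ---------------------------------------------------------------------------
# Haplotype library
# ---------------------------------------------------------------------------

@dataclass
class LibraryWindow:
    """Haplotypes observed in one genomic window of the reference."""

    snp_indices: np.ndarray  # columns of the library SNP list
    haplotypes: np.ndarray  # n_haps x window_len, alleles {0, 1}
    counts: np.ndarray  # usage count per haplotype
    sample_haps: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_haps(self) -> int:
        return int(self.haplotypes.shape[0])


@dataclass
class HaplotypeLibrary:
    snp_names: list[str]
    windows: list[LibraryWindow]
    window_snps: int
    overlap: int


def _window_slices(n_snps: int, window_snps: int, overlap: int) -> list[np.ndarray]:
    step = window_snps - overlap
    if step <= 0:
        raise ValidationError("overlap must be smaller than window_snps")
    slices, start = [], 0
    while start < n_snps:
        end = min(start + window_snps, n_snps)
        slices.append(np.arange(start, end))
        if end == n_snps:
            break
        start += step
    return slices


def build_library(
    reference: GenotypeMatrix,
    window_snps: int = 100,
    overlap: int = 25,
    max_haps: int = 100,
    conflict_threshold: int = 2,
    seed: int | None = None,
) -> HaplotypeLibrary:
    """Greedy within-window phasing of the reference into a haplotype library.

    Within each window, samples are processed from most to least homozygous
    (stable order), so the early, well-determined genotypes seed the library
    with low-ambiguity haplotypes before highly heterozygous samples are
    phased against them.  Each genotype vector is assigned the existing
    haplotype pair with the fewest conflicts; when the best conflict count
    exceeds ``conflict_threshold`` (and the window is below ``max_haps``) a
    new haplotype is created from the genotype, with unresolved sites
    (no-calls, and the phase-ambiguous heterozygous sites of a freshly
    created haplotype) filled from the window's consensus allele.  The pass
    is fully deterministic; ``seed`` is accepted for interface uniformity
    with the stochastic operations.
    """
    del seed  # the greedy pass has no random choices
    if window_snps < 2:
        raise ValidationError("window_snps must be >= 2")
    if reference.n_samples == 0:
        raise ValidationError("reference must be non-empty")

    # windows never straddle chromosomes
    windows: list[LibraryWindow] = []
    chrom_bounds: list[tuple[int, int]] = []
    start = 0
    for j in range(1, reference.n_snps + 1):
        if j == reference.n_snps or reference.snps[j].chromosome != reference.snps[start].chromosome:
            chrom_bounds.append((start, j))
            start = j

    for lo, hi in chrom_bounds:
        for rel in _window_slices(hi - lo, window_snps, overlap):
            cols = rel + lo
            calls = reference.calls[:, cols]
            called = calls != NOCALL
            with np.errstate(invalid="ignore"):
                freq = np.where(called, calls, 0).sum(0) / np.maximum(
                    2.0 * called.sum(0), 1.0
                )
            consensus = (freq >= 0.5).astype(np.int8)
            L = cols.size
            haps = np.empty((0, L), dtype=np.int8)
            counts: list[int] = []
            assignment: dict[str, tuple[int, int]] = {}

            order = np.argsort((calls == 1).sum(axis=1), kind="stable")
            for i in order:
                sample = reference.samples[i]
                g = calls[i]
                has = g != NOCALL
                hom0, hom2, het = g == 0, g == 2, g == 1

                def new_hap_from_genotype() -> np.ndarray:
                    h = consensus.copy()
                    h[hom0] = 0
                    h[hom2] = 1
                    h[het] = consensus[het]
                    return h

                # first haplotype: fewest homozygous-site conflicts
                if haps.shape[0]:
                    conf = haps[:, hom0].sum(1) + (1 - haps[:, hom2]).sum(1)
                    i1 = int(conf.argmin())
                    if conf[i1] > conflict_threshold and haps.shape[0] < max_haps:
                        haps = np.vstack([haps, new_hap_from_genotype()])
                        counts.append(0)
                        i1 = haps.shape[0] - 1
                else:
                    haps = np.vstack([haps, new_hap_from_genotype()])
                    counts.append(0)
                    i1 = 0
                h1 = haps[i1]

                # second haplotype: complement of h1 given the genotype
                h2t = np.full(L, -1, dtype=np.int8)
                h2t[hom0] = 0
                h2t[hom2] = 1
                h2t[het] = 1 - h1[het]
                defined = h2t >= 0
                if haps.shape[0]:
                    mism = (haps[:, defined] != h2t[defined]).sum(1)
                    i2 = int(mism.argmin())
                else:  # pragma: no cover - haps always non-empty here
                    i2, mism = 0, np.array([conflict_threshold + 1])
                if mism[i2] > conflict_threshold and haps.shape[0] < max_haps:
                    h2 = consensus.copy()
                    h2[defined] = h2t[defined]
                    haps = np.vstack([haps, h2])
                    counts.append(0)
                    i2 = haps.shape[0] - 1
                counts[i1] += 1
                counts[i2] += 1
                assignment[sample.id] = (i1, i2)

            windows.append(
                LibraryWindow(
                    snp_indices=cols,
                    haplotypes=haps,
                    counts=np.array(counts),
                    sample_haps=assignment,
                )
            )
    return HaplotypeLibrary(
        snp_names=reference.snp_names,
        windows=windows,
        window_snps=window_snps,
        overlap=overlap,
    )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _pair_agreement(haps: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Agreement count of every haplotype pair (i, j) with observed calls.

    For a called site with dosage 0 the pair agrees iff both alleles are 0;
    dosage 2 iff both are 1; dosage 1 iff exactly one is 1.  Implemented as
    three rank-reduced matrix products over the called site classes.
    """
    H = haps.shape[0]
    a = np.zeros((H, H), dtype=np.int32)
    h = haps.astype(np.int32)
    for dosage in (0, 1, 2):
        sites = obs == dosage
        if not sites.any():
            continue
        m = h[:, sites]
        if dosage == 0:
            a += (1 - m) @ (1 - m).T
        elif dosage == 2:
            a += m @ m.T
        else:
            a += m @ (1 - m).T + (1 - m) @ m.T
    return a


def impute(
    target: GenotypeMatrix,
    lib: HaplotypeLibrary,
    pedigree: Mapping[str, tuple[str | None, str | None]] | None = None,
) -> GenotypeMatrix:
    """Fill every no-call covered by the library from the best haplotype pair.

    Per window, the haplotype pair maximizing agreement with the sample's
    observed calls is chosen; with ``pedigree`` links (sample id ->
    (sire id, dam id); defaults to the matrix's own metadata), the first
    haplotype is restricted to a genotyped parent's library haplotypes when
    that parent is in the reference.  The restriction is evidence-gated:
    when the best parent-restricted pair agrees with the observed calls less
    well than the best unrestricted pair (the parent evidence is
    contradicted, e.g. by recombination within the window), the unrestricted
    pair is used, so pedigree information breaks ties but never overrides
    the observed genotypes.  Observed calls are never altered.
    """
    name_to_col = {n: j for j, n in enumerate(lib.snp_names)}
    missing = [n for n in target.snp_names if n not in name_to_col]
    if missing:
        raise ValidationError(
            f"target SNPs absent from library: {missing[:5]}"
        )
    if pedigree is None:
        pedigree = {
            s.id: (s.sire_id, s.dam_id) for s in target.samples
        }
    # map library window columns onto target columns
    target_col = {n: j for j, n in enumerate(target.snp_names)}
    out = target.copy()
    for window in lib.windows:
        names = [lib.snp_names[c] for c in window.snp_indices]
        cols = np.array([target_col[n] for n in names if n in target_col])
        keep = np.array([n in target_col for n in names])
        if cols.size == 0:
            continue
        haps = window.haplotypes[:, keep]
        if haps.shape[0] == 0:
            log.warning("empty library window; SNPs left as no-calls")
            continue
        pair_dosage = (haps[:, None, :] + haps[None, :, :]).astype(np.int8)
        for i, sample in enumerate(target.samples):
            obs = target.calls[i, cols]
            agree = _pair_agreement(haps, obs)
            best_any = int(agree.max())
            sire_id, dam_id = pedigree.get(sample.id, (None, None))
            row_ok = _parent_rows(window, sire_id, haps.shape[0])
            col_ok = _parent_rows(window, dam_id, haps.shape[0])
            masked = np.where(row_ok[:, None] & col_ok[None, :], agree, -1)
            if int(masked.max()) < best_any:
                masked = agree  # parent evidence contradicted; fall back
            flat = int(masked.argmax())
            bi, bj = divmod(flat, haps.shape[0])
            fill = out.calls[i, cols] == NOCALL
            out.calls[i, cols[fill]] = pair_dosage[bi, bj, fill]
    return out


def _parent_rows(window: LibraryWindow, parent_id: str | None, n: int) -> np.ndarray:
    ok = np.zeros(n, dtype=bool)
    if parent_id is not None and parent_id in window.sample_haps:
        for h in window.sample_haps[parent_id]:
            ok[h] = True
        return ok
    ok[:] = True
    return ok


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracyResult:
    """Genotype-correctness rates for one animal set.

    ``pct_imputed_correct`` covers off-panel truth-called genotypes only;
    ``pct_all_correct`` covers all truth-called genotypes, with panel
    genotypes counted as observed.
    """

    pct_imputed_correct: float
    pct_all_correct: float
    n_imputed_compared: int
    n_all_compared: int


def accuracy(
    imputed: GenotypeMatrix,
    truth: GenotypeMatrix,
    panel: Iterable[str],
) -> AccuracyResult:
    """Score imputed against truth genotypes; truth no-calls are excluded
    from both denominators.  A genotype is correct iff the dosages match
    exactly (a heterozygote imputed for a homozygote is an error)."""
    counts = _per_sample_counts(imputed, truth, panel)
    off_total = int(counts["n_off_total"].sum())
    all_total = int(counts["n_all_total"].sum())
    return AccuracyResult(
        pct_imputed_correct=(
            100.0 * counts["n_off_correct"].sum() / off_total if off_total else float("nan")
        ),
        pct_all_correct=(
            100.0 * counts["n_all_correct"].sum() / all_total if all_total else float("nan")
        ),
        n_imputed_compared=off_total,
        n_all_compared=all_total,
    )


def _per_sample_counts(
    imputed: GenotypeMatrix, truth: GenotypeMatrix, panel: Iterable[str]
) -> pd.DataFrame:
    if imputed.snp_names != truth.snp_names or imputed.sample_ids != truth.sample_ids:
        raise ValidationError("imputed and truth matrices must align")
    panel = set(panel)
    on_panel = np.array([s.name in panel for s in truth.snps])
    truth_called = truth.calls != NOCALL
    correct = truth_called & (imputed.calls == truth.calls)
    off = ~on_panel
    return pd.DataFrame(
        {
            "sample": truth.sample_ids,
            "n_off_correct": correct[:, off].sum(1),
            "n_off_total": truth_called[:, off].sum(1),
            "n_all_correct": correct.sum(1),
            "n_all_total": truth_called.sum(1),
        }
    )


@dataclass
class ImputationReport:
    """Per-stratum accuracy table for one masked-and-imputed experiment."""

    strata: pd.DataFrame  # sire_status, dam_status, n_animals, accuracies
    overall: AccuracyResult
    n_reference: int
    n_target: int
    panel_size: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.strata.copy()
        total = pd.DataFrame(
            [
                {
                    "sire_status": "All",
                    "dam_status": "",
                    "n_animals": self.n_target,
                    "pct_imputed_correct": self.overall.pct_imputed_correct,
                    "pct_all_correct": self.overall.pct_all_correct,
                }
            ]
        )
        return pd.concat([df, total], ignore_index=True)


def _parent_status(
    parent_id: str | None, reference: frozenset[str], targets: frozenset[str]
) -> str:
    if parent_id is None:
        return "none"
    if parent_id in reference:
        return "HD"
    if parent_id in targets:
        return "LD"
    return "none"


def run_experiment(
    g: GenotypeMatrix,
    panel: Iterable[str],
    split: float | tuple[Iterable[str], Iterable[str]],
    seed: int = 0,
    window_snps: int = 100,
    overlap: int = 25,
    max_haps: int = 100,
    conflict_threshold: int = 2,
    use_pedigree: bool = True,
) -> ImputationReport:
    """Mask, impute and score one experiment on a high-density matrix.

    ``split`` is either the target fraction (targets drawn without
    replacement with the given seed) or an explicit (reference ids, target
    ids) pair.  Rows of the report stratify targets by sire and dam
    genotyping status: 'HD' (parent in the reference), 'LD' (parent itself a
    panel-genotyped target) or 'none'.  Strata with no animals are omitted.
    """
    panel = list(panel)
    if isinstance(split, float):
        if not 0.0 < split < 1.0:
            raise ValidationError("split fraction must be in (0, 1)")
        rng = np.random.default_rng(seed)
        ids = np.array(g.sample_ids)
        n_target = max(1, int(round(split * len(ids))))
        targets = frozenset(rng.choice(ids, size=n_target, replace=False).tolist())
        reference = frozenset(ids) - targets
    else:
        reference, targets = frozenset(split[0]), frozenset(split[1])
    if not reference or not targets:
        raise ValidationError("split must leave both sets non-empty")

    spec = MaskSpec.create(panel, targets, reference)
    masked = mask_to_panel(g, spec)
    ref_matrix = g.subset(sample_ids=[i for i in g.sample_ids if i in reference])
    target_matrix = masked.subset(
        sample_ids=[i for i in g.sample_ids if i in targets]
    )
    lib = build_library(
        ref_matrix,
        window_snps=window_snps,
        overlap=overlap,
        max_haps=max_haps,
        conflict_threshold=conflict_threshold,
    )
    pedigree = (
        {s.id: (s.sire_id, s.dam_id) for s in target_matrix.samples}
        if use_pedigree
        else {s.id: (None, None) for s in target_matrix.samples}
    )
    imputed = impute(target_matrix, lib, pedigree=pedigree)
    truth = g.subset(sample_ids=target_matrix.sample_ids)

    counts = _per_sample_counts(imputed, truth, panel)
    counts["sire_status"] = [
        _parent_status(s.sire_id, reference, targets) for s in target_matrix.samples
    ]
    counts["dam_status"] = [
        _parent_status(s.dam_id, reference, targets) for s in target_matrix.samples
    ]
    rows = []
    for (ss, ds), grp in counts.groupby(["sire_status", "dam_status"], sort=True):
        off_total, all_total = grp["n_off_total"].sum(), grp["n_all_total"].sum()
        rows.append(
            {
                "sire_status": ss,
                "dam_status": ds,
                "n_animals": len(grp),
                "pct_imputed_correct": (
                    100.0 * grp["n_off_correct"].sum() / off_total if off_total else float("nan")
                ),
                "pct_all_correct": (
                    100.0 * grp["n_all_correct"].sum() / all_total if all_total else float("nan")
                ),
            }
        )
    overall = accuracy(imputed, truth, panel)
    return ImputationReport(
        strata=pd.DataFrame(rows),
        overall=overall,
        n_reference=len(reference),
        n_target=len(targets),
        panel_size=len(set(panel)),
        seed=seed,
    )
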