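"""Allele frequencies, call rates, concordance and Mendelian checks."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from ldpanel.core import NOCALL, GenotypeMatrix, ValidationError
from ldpanel.simulate import SimConfig, simulate_frequencies
from ldpanel.stats import (
    CONSISTENT,
    INCONSISTENT,
    UNTESTABLE,
    aggregate_consistency,
    breed_allele_frequencies,
    call_rate,
    concordance,
    consistency_report,
    load_validation_counts,
    maf_summary,
    mendelian_duo,
    mendelian_trio,
    ConsistencyReport,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "column, expected_maf, expected_n",
    [
        ([[0], [1], [2]], 0.5, 3),  # AA, AB, BB
        ([[0], [0], [1]], 1.0 / 6.0, 3),  # one B allele of six
        ([[0], [NOCALL]], 0.0, 1),  # no-call excluded from denominator
    ],
)
def test_breed_allele_frequencies(column, expected_maf, expected_n):
    g = make_matrix(column)
    table = breed_allele_frequencies(g, {s.id: "B1" for s in g.samples})
    assert table.maf("snp0", "B1") == pytest.approx(expected_maf)
    assert table.n_samples("snp0", "B1") == expected_n


def test_nocall_never_changes_numerator():
    g1 = make_matrix([[0], [1]])
    g2 = make_matrix([[0], [1], [NOCALL]])
    grouping = lambda g: {s.id: "B" for s in g.samples}
    t1 = breed_allele_frequencies(g1, grouping(g1))
    t2 = breed_allele_frequencies(g2, grouping(g2))
    assert t1.maf("snp0", "B") == t2.maf("snp0", "B")


def test_maf_summary_examples():
    from ldpanel.core import BreedFrequencyTable

    t = BreedFrequencyTable.from_mapping(
        {("a", "B"): (0.1, 10), ("b", "B"): (0.3, 10), ("c", "B"): (0.5, 10)}
    )
    s = maf_summary(t, "B", ["a", "b", "c"])
    assert s.mean_maf == pytest.approx(0.3)
    assert s.median_maf == pytest.approx(0.3)
    assert s.pct_polymorphic == 100.0

    t2 = BreedFrequencyTable.from_mapping({("a", "B"): 0.0, ("b", "B"): 0.4})
    assert maf_summary(t2, "B", ["a", "b"]).pct_polymorphic == pytest.approx(50.0)
    with pytest.raises(ValidationError):
        maf_summary(t2, "Unknown", ["a"])


def test_maf_summary_recovers_simulated_spectrum():
    """Estimated mean MAF from 500 genotyped samples tracks the simulated
    per-breed truth within 0.01 at panel scale (6,909 loci)."""
    cfg = SimConfig(n_chromosomes=1, n_snps_per_chrom=6909, seed=42)
    freqs = simulate_frequencies(cfg)
    rng = np.random.default_rng(43)
    p = freqs.per_breed["BreedA"]
    calls = rng.binomial(2, p, size=(500, len(p))).astype(np.int8)
    g = make_matrix(calls, snps=freqs.records)
    est = breed_allele_frequencies(g, {s.id: "BreedA" for s in g.samples})
    summary = maf_summary(est, "BreedA", g.snp_names)
    truth_mean = float(np.minimum(p, 1 - p).mean())
    assert abs(summary.mean_maf - truth_mean) < 0.01
    # the default spectrum targets an ancestral mean MAF of 0.33
    anc = freqs.ancestral
    assert abs(float(np.minimum(anc, 1 - anc).mean()) - 0.33) < 0.01


# ---------------------------------------------------------------------------
# Call rate and concordance
# ---------------------------------------------------------------------------

def test_call_rate_axes():
    calls = np.ones((1, 10), dtype=np.int8)
    calls[0, 0] = NOCALL
    g = make_matrix(calls)
    assert call_rate(g, "per_sample").iloc[0] == pytest.approx(90.0)
    assert call_rate(g, "overall") == pytest.approx(90.0)
    assert call_rate(make_matrix(np.ones((2, 5)))) == 100.0


def test_call_rate_panel_scale_rounding():
    calls = np.zeros((1, 6909), dtype=np.int8)
    calls[0, :5] = NOCALL
    g = make_matrix(calls)
    assert round(call_rate(g, "overall"), 2) == 99.93


def test_call_rate_empty_matrix_rejected():
    g = make_matrix(np.empty((0, 0), dtype=np.int8), snps=[], samples=[])
    with pytest.raises(ValidationError):
        call_rate(g)


def test_concordance_rules():
    a = make_matrix([[0, 1, 2, 0, 1, 2, 0, 1, 2, 0]])
    b_calls = [[0, 1, 2, 0, 1, 2, 0, 1, 2, 2]]  # one mismatch
    b = make_matrix(b_calls)
    r = concordance(a, b)
    assert r.pct_concordant == pytest.approx(90.0)
    assert r.n_discordant == 1 and r.n_compared == 10
    # identity and symmetry
    assert concordance(a, a).pct_concordant == 100.0
    assert concordance(b, a).pct_concordant == r.pct_concordant
    # a no-call on either side removes the cell from the denominator
    c = make_matrix([[NOCALL, 1, 2, 0, 1, 2, 0, 1, 2, 2]])
    assert concordance(a, c).n_compared == 9


def test_concordance_disjoint_matrices_rejected():
    a = make_matrix([[0]])
    b = GenotypeMatrix([replace(a.samples[0], id="other")], a.snps, a.calls)
    with pytest.raises(ValidationError):
        concordance(a, b)


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "parent, child, expected",
    [(0, 2, INCONSISTENT), (2, 0, INCONSISTENT), (0, 1, CONSISTENT),
     (1, 1, CONSISTENT), (NOCALL, 2, UNTESTABLE), (0, NOCALL, UNTESTABLE)],
)
def test_mendelian_duo(parent, child, expected):
    assert mendelian_duo(parent, child) == expected


def _transmission_oracle(sire, dam, child):
    """Independent enumeration of gamete transmissions over allele pairs."""
    genotype_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    if child == NOCALL or (sire == NOCALL and dam == NOCALL):
        return UNTESTABLE
    if sire == NOCALL or dam == NOCALL:
        parent = dam if sire == NOCALL else sire
        pa, ca = genotype_alleles[parent], genotype_alleles[child]
        return CONSISTENT if set(pa) & set(ca) else INCONSISTENT
    for a in genotype_alleles[sire]:
        for b in genotype_alleles[dam]:
            if tuple(sorted((a, b))) == genotype_alleles[child]:
                return CONSISTENT
    return INCONSISTENT


def test_mendelian_trio_matches_exhaustive_oracle():
    states = (NOCALL, 0, 1, 2)
    for s, d, c in itertools.product(states, repeat=3):
        assert mendelian_trio(s, d, c) == _transmission_oracle(s, d, c), (s, d, c)


def test_trio_specific_cases():
    assert mendelian_trio(0, 0, 1) == INCONSISTENT  # no B allele available
    for child in (0, 1, 2):
        assert mendelian_trio(1, 1, child) == CONSISTENT


# ---------------------------------------------------------------------------
# Consistency report
# ---------------------------------------------------------------------------

def test_error_free_pedigree_has_no_inconsistencies(small_pop):
    reports = consistency_report(small_pop.truth)
    assert sum(r.n_inconsistent for r in reports) == 0
    assert any(r.comparison_kind == "trio" for r in reports)


def test_injected_duo_errors_are_counted_exactly(small_pop):
    g = small_pop.truth
    # keep only the sire link so children contribute duo comparisons
    samples = [replace(s, dam_id=None) for s in g.samples]
    g = GenotypeMatrix(samples, g.snps, g.calls.copy())
    idx = {s.id: i for i, s in enumerate(g.samples)}
    injected = 0
    parents = {s.sire_id for s in g.samples if s.sire_id}
    for s in g.samples:
        # only terminal samples: an error in a mid-pedigree animal would also
        # show up in comparisons with its own offspring
        if injected == 10 or not s.sire_id or s.id in parents:
            continue
        i, pi = idx[s.id], idx[s.sire_id]
        hom = np.nonzero((g.calls[pi] == 0) & (g.calls[i] != 2))[0]
        g.calls[i, hom[injected]] = 2  # opposite homozygote vs the sire
        injected += 1
    assert injected == 10
    reports = consistency_report(g)
    duo_total = sum(
        r.n_inconsistent for r in reports
        if r.comparison_kind == "duo" and r.breed != "Overall"
    )
    assert duo_total == 10


def test_replicate_comparison_counts_mismatches():
    g = make_matrix([[0, 1, 2, NOCALL], [0, 2, 2, 1]])
    reports = consistency_report(g, replicates=[("s0", "s1")])
    rep = next(r for r in reports if r.comparison_kind == "replicate" and r.breed != "Overall")
    assert rep.n_genotyped == 3  # no-call cell excluded
    assert rep.n_inconsistent == 1


def test_trio_free_pedigree_has_empty_trio_section():
    g = make_matrix([[0, 1], [1, 2]])
    assert consistency_report(g) == []


def test_published_counts_reaggregate_to_printed_overalls():
    """Re-summing the bundled per-breed validation rows reproduces the
    printed overall Mendelian consistency and reproducibility rates."""
    df = load_validation_counts()
    rows = [
        ConsistencyReport(r.comparison, r.breed, r.n_comparisons,
                          r.n_genotyped, r.n_inconsistent)
        for r in df.itertuples()
    ]
    overall = {
        r.comparison_kind: r
        for r in aggregate_consistency(
            rows, kinds={"duo": "mendelian", "trio": "mendelian"}
        )
    }
    mend = overall["mendelian"]
    assert (mend.n_comparisons, mend.n_genotyped, mend.n_inconsistent) == (
        32, 217719, 118,
    )
    assert round(mend.pct_consistent, 2) == 99.95
    rep = overall["replicate"]
    assert (rep.n_comparisons, rep.n_genotyped, rep.n_inconsistent) == (10, 47760, 6)
    assert round(rep.pct_consistent, 2) == 99.99
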