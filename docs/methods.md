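# Methods

This note documents the models and procedures implemented in `ldpanel`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Panel design

The design algorithm selects markers for a reduced-density array whose
purpose is imputation to a higher-density assay.

**Window grid.** Each chromosome of length `L` is tiled into consecutive
windows of `window_size` bp (default 500,000); window `k` spans
`[(k-1)·w+1, min(k·w, L)]`, the last window may be short, and the first and
last window of each chromosome are flagged *terminal*. A single-window
chromosome is terminal once. Positions are 1-based throughout, following
MAP-file convention.

**Scoring.** Two criteria per selection round, both computed from a
per-SNP × per-breed folded MAF table:

- criterion A — weighted mean MAF over a breed list:
  `score_A = Σ w_b·MAF_b / Σ w_b`, breeds without an entry excluded from
  both sums;
- criterion B — minimum MAF over a (possibly different) breed list:
  `score_B = min_b MAF_b`. The minimum guards against monomorphism in any
  target breed: a marker useless in one breed is penalized no matter how
  informative elsewhere.

The combined score is `(A + B)/2`; markers missing either criterion are
excluded. The shipped default configuration gives round 1 a twelve-breed
European list with Holstein double-weighted for criterion A and six major
dairy breeds for criterion B, and round 2 a five-breed list spanning
North America/Oceania (including one indicine breed) for A and three breeds
for B. All lists and weights are user-editable YAML.

**Selection.** Interior windows keep the `picks_per_window` (default 1)
top-scoring markers, terminal windows `terminal_picks` (default 2) — the
density doubling at chromosome ends compensates for the missing flanking
information that otherwise degrades end-of-chromosome imputation. Round 1's
output is the exclusive candidate pool for round 2, which applies its own
breed lists with the same pick counts. Tie-breaking everywhere is
deterministic: higher combined score, then lower position, then
lexicographic name; the design is therefore invariant to candidate input
order (property-tested).

**Post-processing.**

- *Backward compatibility*: while the overlap with a legacy marker set is
  below `compat_target` (default 2,000), the selected non-legacy marker
  whose nearest unused same-chromosome legacy marker lies within
  `compat_radius` is replaced by that marker, preserving the window
  accounting. The radius default is 250 kbp — half a window; the swap is
  meant to substitute a near-equivalent anchor, so half a window is the
  natural "nearby" scale. Best-effort: stops when no eligible swap remains.
- *Mandatory content*: parentage/breed-determination markers not already
  selected are injected verbatim (deduplicated by name; an already-selected
  marker keeps its original provenance).
- *Gap filling*: for each adjacent same-chromosome pair farther apart than
  `max_gap` (default 1 Mbp, i.e. a floor of ~2 SNPs/Mbp), the pool marker
  closest to the gap midpoint is added, iterating until no fillable gap
  remains; unfillable gaps are logged and left.
- *X chromosome*: candidates are grouped by assay tier (legacy low-density
  first, then medium-density, then high-density) and each window is filled
  from the highest-priority tier with a scored candidate — tier priority
  beats score, because reusing already-validated legacy assays trumps a
  marginal MAF gain — with gap filling from the lowest tier afterwards.
- *Y and mtDNA*: fixed marker lists appended as-is; they serve sex
  determination and lineage classification, not imputation, so they bypass
  scoring.

Per-window occupancy of the final design is reported, not asserted: gap
filling, swaps and mandatory injection legitimately perturb the one-per-
window pattern.

## Validation statistics

- **Call rate**: called entries / total entries, per sample, per SNP or
  overall, in percent.
- **Concordance**: two matrices are intersected on shared sample ids and
  marker names; a cell enters the denominator only when both calls are
  non-missing. Symmetric; self-concordance is 100%.
- **Mendelian duo**: inconsistent iff parent and child are opposite
  homozygotes — the only duo-detectable error class; anything involving a
  no-call is untestable.
- **Mendelian trio**: consistent iff the child's genotype can be assembled
  from one allele of each parent; with one parent missing the check
  degrades to duo logic on the other; with the child or both parents
  missing it is untestable. The implementation is rule-based and is tested
  against an independent exhaustive enumeration of gamete transmissions
  over all 64 call combinations.
- **Replicates**: two samples declared the same animal; the comparison
  counts mismatching calls where both are called.
- Half-called genotypes do not exist in the data model: anything not fully
  called is a no-call, at every pipeline stage.
- Percentages are held unrounded internally and formatted to two decimals
  in reports. "Polymorphic" means estimated MAF > 0 in that breed's sample.

The package bundles the published per-breed validation comparison tables
for the bovine low-density array (Mendelian duo/trio and replicate counts
on the 6,844 markers shared with the high-density assay, and the per-breed
Y/mtDNA haplotype counts). These ship as printed, including internal
inconsistencies of the source tables (e.g. a replicate row whose
marker count does not match the chip size); the toolkit re-aggregates rows
rather than reconciling them.

## Lineage classification

A haploid genotype string is extracted per sample over an ordered locus
list: homozygous calls contribute their base, no-calls a `.` placeholder,
and heterozygous calls at haploid loci — clustering artifacts — are demoted
to placeholders with a warning rather than raised as errors. Classification
against a catalog: exact match → haplotype name; with placeholders, exactly
one compatible catalog entry → that name, zero or several → undetermined; a
fully-called non-matching string → novel. Sex is inferred from the Y call
pattern (all loci called → male, none → female, otherwise ambiguous with
the call fraction reported); females carry no Y haplotype by construction.
The subspecies signal combines the lineage annotations of the Y and mtDNA
assignments: indicine-annotated evidence on either side plus
taurine-annotated evidence on the other yields "mixed-evidence".

## Imputation evaluation

The harness measures how well a panel supports imputation, not how good any
particular production imputer is. The built-in imputer is deliberately
simple and interchangeable in spirit:

- **Library**: overlapping windows of `window_snps` markers (default 100)
  with `overlap` (default 25), never straddling chromosomes. Within each
  window, reference samples are phased greedily from most to least
  homozygous (stable order): the first haplotype is the existing library
  entry with the fewest homozygous-site conflicts, the second the best
  match to the genotype's complement given the first; when the best
  conflict/mismatch count exceeds `conflict_threshold` (default 2) and the
  window holds fewer than `max_haps` (default 100) haplotypes, a new
  haplotype is created, with no-calls and phase-ambiguous sites filled from
  the window consensus. The homozygosity ordering matters: it seeds the
  library with low-ambiguity haplotypes before highly heterozygous samples
  are phased against them, and raised library fidelity substantially in
  development experiments. The pass is fully deterministic.
- **Imputation**: per window, the haplotype pair maximizing agreement with
  the sample's observed panel calls is chosen (computed exactly via three
  rank-reduced matrix products over the dosage-0/1/2 site classes) and
  fills the no-calls; observed calls are never altered (property-tested).
  With pedigree links, the first haplotype is restricted to a genotyped
  parent's library haplotypes — but the restriction is *evidence-gated*:
  if the best parent-restricted pair agrees with the observed calls less
  well than the best unrestricted pair (parent evidence contradicted, e.g.
  by within-window recombination or a poorly phased parent), the
  unrestricted pair is used. Pedigree information therefore breaks ties
  without ever overriding observed genotypes; an unconditional restriction
  measurably hurt accuracy in development and inverted the expected
  parent-stratum ordering.
- **Accuracy**: counted per genotype — an imputed heterozygote against a
  homozygous truth call is one error. Two rates are reported: over imputed
  (off-panel) truth-called genotypes only, and over all truth-called
  genotypes with panel genotypes counted as observed-correct. Truth
  no-calls are excluded from both denominators. Reports stratify targets by
  sire/dam status — in the reference (high density), among the targets
  (panel density), or ungenotyped — and omit empty strata.

## Synthetic populations

The generator emulates the inputs a panel designer works from; it is not a
demographic simulation.

- **Frequencies**: ancestral B-allele frequencies drawn from a target MAF
  spectrum (default uniform on [0.16, 0.5], mean 0.33, reflecting the
  high-MAF content selection of imputation arrays) with random minor-allele
  orientation; per-breed frequencies from the Balding–Nichols model,
  `p_b ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, default F = 0.05 (typical of
  related taurine breeds); F = 0 reproduces the ancestral values exactly.
  Folding after divergence slightly shrinks the per-breed mean MAF relative
  to the ancestral mean (drift past 0.5 reflects back), a model property
  the tests assert rather than hide.
- **Founder haplotypes**: a Gaussian-copula AR(1) allele process — alleles
  are a latent AR(1) normal thresholded at each site's frequency quantile —
  so per-site frequencies are exact in expectation while adjacent-site
  correlation is tunable. The `ld_correlation` parameter targets the
  allele-level adjacent correlation at a median split; the latent
  autocorrelation is `sin(π·c/2)` (inverting the arcsine dichotomization
  formula). Default 0.9, giving adjacent r² well above 0.5, as in dense
  livestock panels. The process restarts at chromosome boundaries.
- **Pedigree**: founders draw two haplotypes from a breed-specific pool of
  `n_founder_haplotypes` (default 40 — a small effective founder pool is
  what makes livestock imputation from sparse panels feasible); each
  non-founder receives one recombinant gamete per parent with Poisson
  crossover counts (Haldane model, no interference; default 1 Morgan per
  chromosome) and uniform crossover positions. Offspring sexes alternate
  so every generation can reproduce. Before artifact injection every trio
  is Mendelian-consistent by construction.
- **Artifacts**: each call is independently dropped to no-call
  (default rate 7×10⁻⁴, matching a ~99.93% call rate typical of validated
  arrays) and each surviving call perturbed to a uniformly chosen different
  genotype (default 5×10⁻⁴, the order of observed Mendelian-inconsistency
  rates).

Everything is a deterministic function of (config, seed).

**What the synthetic tests show — and do not.** The generator produces
realistic MAF spectra, strong local LD, real pedigree structure and
calibrated artifact rates, so it exercises every code path end to end and
supports quantitative claims about the *protocol* (masking, scoring,
stratification, monotonicity in reference size and panel density). It does
not reproduce real bovine haplotype structure, long-range LD decay,
ascertainment bias, or assay-specific error modes; absolute accuracy values
on synthetic data therefore say nothing precise about accuracy on real
cattle, and the published per-breed accuracies are not reproducible at desk
scale with public data.

## Standard evaluation configuration

The bundled evaluation population (used by the acceptance script and the
property tests) is 2 chromosomes × 1,500 SNPs over 100 Mbp each, one breed,
150 founders and two generations of 450 offspring (1,050 animals), error-
free truth genotypes; experiments mask 50 targets to a 20%-density panel
against 500 (or 1,000) reference animals. The sizes keep a full simulate–
design–impute cycle in a few seconds while leaving every stratum of the
parent-status table populated. Under this configuration imputed-genotype
accuracy is ≈95–96%, the both-parents-in-reference stratum scores at or
above the no-genotyped-parent stratum, and doubling the reference raises
mean accuracy by ≈1 percentage point over five seeds.

## Known limitations

- The greedy haplotype library is windowed and count-capped; very diverse
  references (many rare haplotypes) will saturate `max_haps` and degrade.
- The compatibility swap is greedy per-distance, not globally optimal.
- Duo checks detect only opposite-homozygote conflicts, so duo-based error
  rates underestimate the true genotype error rate by construction.
- Chromosome lengths are a required configuration input; the toolkit ships
  no genome assembly.
- The statistics of the released commercial array manifest (total marker
  count, X/mtDNA composition, spacing distribution) can only be recomputed
  from the vendor's per-SNP supplementary file, which is not
  redistributable with this package; the corresponding acceptance test
  documents the expected values and runs when that file is supplied.
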