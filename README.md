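# ldpanel

Design and evaluation toolkit for **low-density SNP genotyping panels
optimized for imputation**, modeled on the methodology behind reduced-density
bovine arrays used for low-cost genomic selection.

Genomic selection needs genome-wide genotypes, but high-density arrays are
too expensive to run on every animal. The practical alternative is a small
panel (a few thousand SNPs) chosen so that the missing markers can be
*imputed* from a reference population genotyped at high density. `ldpanel`
implements the full design-and-validation cycle for such panels:

- **Panel design** (`ldpanel.design`): tile each autosome into fixed windows
  (default 500 kbp) and keep the top-scoring marker per window, doubling the
  pick count in the first and last window of every chromosome (imputation
  degrades near chromosome ends without extra anchors). Candidates are
  scored on two minor-allele-frequency criteria — a weighted mean MAF over
  one breed list, `Σ w_b·MAF_b / Σ w_b`, and a minimum MAF over a second
  list, `min_b MAF_b` — combined as their mean; a second selection round
  rescores the survivors on additional populations. Post-processing swaps
  markers for nearby legacy-chip markers (backward compatibility), injects
  mandatory parentage/lineage content, fills gaps above 1 Mbp, assembles
  X-chromosome content by assay tier, and appends fixed Y and mtDNA marker
  lists.
- **Panel QC** (`ldpanel.qc`): adjacent-marker spacing and gap statistics,
  gap histograms, per-chromosome/tier composition.
- **Validation statistics** (`ldpanel.stats`): per-breed allele frequencies
  and MAF summaries, call rates, cross-assay concordance, Mendelian duo/trio
  consistency (a duo conflict is an opposite-homozygote pair; a trio is
  consistent iff the child can receive one allele from each parent), and
  replicate reproducibility.
- **Lineage classification** (`ldpanel.lineage`): collapse haploid Y and
  mtDNA genotypes to base strings, classify them against bundled haplotype
  catalogs (4 Y haplotypes over 9 loci, 7 mtDNA haplotypes over 13 loci,
  with taurine/indicine lineage annotations), infer sex from the Y call
  pattern, and build per-breed count tables.
- **Imputation evaluation** (`ldpanel.impute`): reduce target animals'
  genotypes in silico to a panel, impute them back with a built-in windowed
  haplotype-library imputer, and score the proportion of correct genotypes —
  over imputed markers only and over all markers — stratified by sire/dam
  genotyping status.
- **Synthetic populations** (`ldpanel.simulate`): multi-breed
  Balding–Nichols allele frequencies, founder haplotypes with tunable LD,
  pedigree gene dropping with Haldane recombination, and genotyping
  artifacts, all deterministic functions of a seed.

## Worked example

```sh
$ ldpanel simulate --config sim.yaml --out-prefix pop --seed 42
wrote 200 samples x 800 SNPs to pop.[ped,map,pedigree.csv,freqs.csv]

$ ldpanel design run --config design.yaml --freqs pop.freqs.csv \
      --candidates candidates.csv --out panel.csv
selected 84 SNPs; by reason: {'TERMINAL_EXTRA': 4, 'WINDOW_BEST': 80}

$ ldpanel qc gaps --manifest panel.csv
SNPs: 84
median spacing: 0.491 Mbp
gaps > 1000000 bp: 0 (0.0%)
largest gap: 930490 bp on chromosome 1

$ ldpanel impute eval --ped pop.ped --map pop.map --panel panel.csv \
      --target-frac 0.2 --seed 3
sire_status dam_status  n_animals  pct_imputed_correct  pct_all_correct
         HD         HD         17                82.93            84.72
         HD         LD          7                81.35            83.31
         LD         HD          7                82.83            84.63
       none       none          9                84.46            86.09
        All                    40                82.98            84.77
```

Here `sim.yaml` describes a toy population (2 chromosomes of 20 Mbp, 400
SNPs each, 40 founders, two generations of 80 offspring) and `design.yaml` a
single-round, single-breed selection over 500-kbp windows. The design picks
one SNP per interior window and two per terminal window (hence the four
`TERMINAL_EXTRA` entries), and the QC confirms no gap exceeds 1 Mbp. The
imputation report masks 40 animals down to the 84-SNP panel, rebuilds their
800-SNP genotypes from a haplotype library phased out of the remaining 160
animals, and prints the percentage of genotypes recovered correctly per
parent stratum — modest here because the toy reference is tiny; at the
package's standard evaluation scale (3,000 SNPs, 500 reference animals, 20%
panel density) accuracy is above 95% (see below).

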