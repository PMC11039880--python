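# Methods

`cerna-weaver` implements an integrative lncRNA–miRNA–mRNA analysis for
two-factor microarray experiments: differential expression, positional
classification of lncRNA loci, proximity-based cis pairing, assembly of
direction-concordant ceRNA ("sponge") triplets from interaction tables, and
hypergeometric gene-set over-representation. This note documents the models,
the defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Experimental design and comparisons

The design is a 2×2 factorial: Oct4 knockdown (`siNT` control vs `siOct4`)
crossed with oxidized-phospholipid treatment (`DMSO` vehicle vs `POVPC`), with
`n` replicates per cell (default 3). Three canonical contrasts are analyzed,
each a test condition over a control condition:

1. `siNT-POVPC vs siNT-DMSO` — treatment effect in wild-type cells;
2. `siOct4-DMSO vs siNT-DMSO` — knockdown effect;
3. `siOct4-POVPC vs siOct4-DMSO` — treatment effect under knockdown.

## Differential expression

**Quantile normalization.** Each column is mapped onto the reference
distribution formed by the row means of the column-sorted matrix. Ties within
a column receive the mean of the reference values they span. Consequence
worth stating: on tie-free data every normalized column has the identical
sorted value vector (tested exactly); when a column contains ties, the
tie-averaging necessarily perturbs that multiset — this matches the common
`limma`-style behaviour and is deliberate.

**Fold change** is the ratio of group means on the normalized linear scale,
test over control; downregulation is FC < 1. A guard of 1e-12 protects
against all-zero group means (unreachable for log-normal intensities). The
un-normalized test-group mean is carried along as `raw_intensity` for the
expressed-lncRNA filter.

**Test statistic.** Welch's two-sample t on `log2(intensity + pseudocount)`
(pseudocount 1.0, configurable) with the Welch–Satterthwaite df and two-sided
p. The original study's array software does not name its test; Welch on log
intensities is the standard substitute and is exposed, not hidden. Degenerate
conventions: zero variance in both groups with equal means gives `t = 0,
p = 1`; with unequal means, `p = 0` (flagged by the infinite t) — this makes
the noiseless limit well defined. Benjamini–Hochberg adjustment is computed
for every record; the status call uses raw p by default (`use_adjusted_p`
flips it), matching how array studies of this kind report significance.

**Status.** `up` when FC ≥ 1.5 and p ≤ 0.05; `down` when FC ≤ 1/1.5 (the
symmetric bar) and p ≤ 0.05; `ns` otherwise. Thresholds are inclusive.
Records are emitted in feature-id order, so output is deterministic and
invariant to input row permutation.

**Clustering.** Heatmap-style hierarchical clustering uses average linkage on
1 − Pearson distance (zero-variance rows get distance 1 to everything by
convention). Rows are pre-sorted by id before linkage so that equal-distance
merges resolve toward the lexicographically smallest member; the merge
sequence is checked against a brute-force O(n³) agglomeration in the tests.

## lncRNA positional subclasses

Each lncRNA is assigned exactly one subclass relative to protein-coding
genes, by fixed precedence (first match wins):

1. `sense_overlapping` — exonic overlap with a same-strand gene;
2. `intronic_sense` — contained in a same-strand gene, no exon overlap;
3. `natural_antisense` — exonic overlap with an opposite-strand gene;
4. `intronic_antisense` — contained in an opposite-strand gene, no exon overlap;
5. `bidirectional` — no gene overlap, TSS within 1 kb of a gene TSS in
   divergent (head-to-head) orientation;
6. `intergenic` — otherwise.

The field's subclass names are standard but no canonical precedence exists;
sense-before-antisense and exonic-before-intronic is this package's
documented convention. The 1 kb divergent-promoter window is the common
convention for bidirectional promoters. Classification is total and invariant
to gene-list order.

## cis lncRNA–mRNA pairing

A cis pair is a lncRNA and a protein-coding gene on the same chromosome whose
span-to-span gap (bases strictly between the intervals; 0 when they overlap)
is below the window, default 300 kb, with both members significantly
differentially expressed in the same comparison. Span gap is the simplest
reading of genomic proximity; a TSS-to-TSS mode is available by flag. Strand
is ignored for distance and recorded as orientation (upstream / downstream /
overlapping relative to the gene's strand). The implementation is
interval-indexed and is property-tested against a brute-force all-pairs scan.

## Sponge (ceRNA) triplet assembly

A triplet (lncRNA L, miRNA m, mRNA G) is emitted, per comparison, when:

- L passes the sponge-candidate filter: status in the module direction, raw
  signal intensity > 100 fluorescence units (highly expressed on the array),
  and catalogued in a GENCODE/Ensembl-style reference (flag-controlled);
- a **validated** lncRNA–miRNA binding edge (L, m) exists and passes the
  binding-site filter (below);
- m is called in the opposing direction;
- a miRNA–mRNA target row links m to G with admissible evidence (validated
  only, or validated-or-predicted — the default, mirroring how target
  databases are used in practice);
- G is differentially expressed in the module direction.

The up module is (L up, m down, G up); the down module is the mirror image,
and the two are exact mirrors under fold-change inversion (tested).

**miRNA direction mode.** Microarray miRNA fold changes are compressed, so a
reproducibly shifted sponge partner may miss the 1.5× bar. The default
`significance_only` mode therefore calls miRNA direction from the sign of the
fold change at p ≤ 0.05; `full_threshold` defers to the magnitude-filtered DE
status. The default is required to treat weakly-shifted but significant
miRNAs (e.g. FC 0.89 at p = 0.014) as direction-informative.

**Binding-site filter scope.** The sponge hypothesis requires more than one
binding site (≥ 2, the strict reading of "more than one"). By default the
requirement qualifies the *lncRNA*: a candidate whose strongest miRNA edge
has ≥ 2 sites keeps all of its validated miRNA edges, including weaker ones —
a sponge that is engaged by a miRNA family is reported with all its partners.
A strict per-edge mode (`binding_site_scope="edge"`) drops every individual
edge below the threshold. The packaged published modules are only reproduced
under the lncRNA-level reading (one of the listed partner miRNAs has a single
site yet is counted by the source study).

**Counting.** One triplet is emitted per miRNA→mRNA input row (per connecting
miRNA for family-attributed rows); row multiplicity is preserved, so a gene
listed twice under one miRNA counts twice in `n_mrna_associations`, with
`n_mrna_distinct` as the collapsed count and a `dedup_associations` flag to
collapse repeated (miRNA, mRNA) listings entirely. Module summaries are
unions over the comparisons analyzed. Interaction rows naming unmeasured
features are skipped with a warning and counted.

## Gene-set over-representation

For a DE list of size `n` from a measured background of size `N`, a set with
`K` measured members and `k` DE members is scored with the right tail
P(X ≥ k), X ~ Hypergeometric(N, K, n) — the right-tailed Fisher exact test.
The background defaults to the measured universe of the molecule class
(a knowledge-base background is not reproducible; the measured universe is,
and is flag-overridable by passing any id list). The tail is summed with
exact integer combinatorics for N ≤ 1000 (bit-exact small cases, verified
against full fixed-margin enumeration) and with the log-space hypergeometric
survival function above. BH adjustment is applied across all sets tested in
one run; results are ordered by (p, set id).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
complete ground truth:

- **Intensities** are log-normal: `2^(baseline + effect·indicator + ε)`,
  `ε ~ N(0, noise_log2_sd)`, with per-feature baselines
  `N(baseline_log2_mean = 8, sd = 1.5)` (raw units ~256 typical). Defaults
  follow the conditions the package is validated under: 3 replicates, planted
  effect 1.5 log2 units, noise 0.25 log2 units.
- **Planted DE** assigns each affected feature to exactly one comparison and
  direction (`de_fraction` per direction per comparison, features disjoint
  across comparisons). Effects are placed on design cells so the three
  contrasts stay orthogonal: treatment effects go to the respective POVPC
  cell only, and the knockdown effect to *both* siOct4 cells so it cancels
  out of the third contrast.
- **Sponge triplets** are drawn from the planted DE sets, direction-concordant
  by construction, with binding sites uniform in {2..8}; decoy triplets are
  identical except for a single binding site, so they must be rejected by the
  binding-site filter in either scope. Sponge lncRNA baselines are floored so
  their raw intensity clears the > 100 filter. Background edges involve only
  non-DE miRNAs and therefore can never complete a triplet — with zero noise,
  recovery of exactly the planted triplets is an invariant, not a tendency.
- **Genome geometry** allocates each gene a 200 kb territory (3 exons, 6–10 kb
  introns) and attaches lncRNAs to host genes so that each planted subclass
  is realized unambiguously; subclass counts use exact largest-remainder
  apportionment, so recovered proportions equal the planted mix exactly. The
  default mix (72% intergenic, 12% natural antisense, 9% intronic antisense,
  remainder spread over the other classes) follows the proportions reported
  for arrays of this kind. A configurable fraction of intergenic lncRNAs is
  placed ≥ 300 kb from every gene; the rest sit inside gene-territory margins
  and generate cis pairs. Ground-truth cis pairs are derived from the
  constructed geometry by exact brute force.
- **Gene sets** are uniform draws except one set seeded with planted DE genes
  (default 60% of its 25 members), used to validate enrichment ranking.

What it does **not** emulate: probe-level effects, cross-sample technical
bias (columns are generated on a common scale — recovery is therefore scored
without renormalization, and quantile normalization's defining property is
validated separately on its own contract), correlated co-expression beyond
the planted effects, heavy-tailed noise, and sequence-determined binding.
Passing recovery tests therefore demonstrates correctness of the inference
chain under the stated noise model, not robustness to array artifacts.

One root seed drives per-component child seeds (`numpy` `SeedSequence`
spawning), so outputs are byte-identical across runs of the same config.

## Problem sizes used in validation

The packaged validation suite and the acceptance script use: 500 random
instances of ≤ 20 features/class for the triplet-assembly oracle check; 200
random annotations for the cis-pairing oracle check; full fixed-margin
enumeration for all backgrounds N ≤ 30 for the Fisher tail; 20 seeds of a
150/300/60-feature experiment for noisy recovery (effect 1.5, noise 0.25,
n = 3); 20 seeds of a 100/200/50-feature null experiment for p-value
calibration; and a 120/400/60-feature noiseless experiment for exact
structure recovery. These sizes give stable aggregate rates while keeping the
suite fast.

## Known limitations

- The analysis is correlational: direction-concordant triplets are candidate
  sponge interactions, not causal claims.
- Genome-wide counts from the original microarray study (total DE features,
  135 cis pairs, subclass percentages) require its deposited raw data and
  probe annotation and are out of scope; the packaged tables cover the
  curated sponge modules only.
- Printed fold changes and p-values in the packaged tables come with fixture
  placeholders where the source tables print nothing (mRNA effect sizes, raw
  lncRNA intensities); these are conventions, not data, and are documented in
  `cerna_weaver.fixtures`.
- The Welch test at n = 3 is slightly conservative (null p ≤ 0.05 fraction
  ≈ 0.034 in calibration runs), which trades a little power for false-positive
  control — appropriate for the screening role it plays here.
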