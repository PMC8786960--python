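# Methods

This note documents the statistical procedures, their assumptions, the
tunable parameters, and the design decisions taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Strain sharing from SNP haplotypes

Each species' input is a multiple alignment of the dominant-strain SNP
haplotypes, one aligned sequence per sample (the interchange form assumed
for StrainPhlAn-style haplotypes). For every sample pair:

- Columns where either sequence carries a gap (`-`) or an ambiguous base
  (`N`) are excluded. Pairs with fewer than `min_overlap = 100` comparable
  sites are skipped with a warning rather than erroring — haplotype
  alignments from low-coverage samples are legitimately gappy.
- The observed mismatch fraction p is corrected for multiple substitutions
  with the Jukes–Cantor model, d = −(3/4)·ln(1 − 4p/3), defined for
  p < 0.75. Saturated pairs are skipped with a warning.
- Within each species, every pair's d is divided by the **median of all
  pairwise distances of that species** — within-family and unrelated pairs
  pooled. Normalization puts species with very different within-species
  diversity on one scale: 0 means identical haplotypes, 1 the species'
  median dissimilarity. Species whose median distance is 0 (all strains
  identical, no resolution) are excluded with a warning.

A **shared strain** is a within-family mother–infant pair with normalized
distance ≤ `threshold` (default 0.2, inclusive — the boundary convention is
exposed as a flag). Only mother–infant pairs within a family are eligible;
all other similarities appear in the distance table but are never called.
At most one event is kept per (species, family). No direction of transfer
is inferred: a shared strain may be mother-to-infant, infant-to-mother, or
a common external source.

Per-species strain phylogenies are built by neighbor joining on the
Jukes–Cantor distance matrix (scikit-bio's implementation; negative branch
lengths clamped to zero) and written as newick.

## Relative expression and shift calling

RNA and DNA gene-family abundances are both *relative* (copies-per-million)
quantifications, so a transcriptionally hyperactive species makes every
other species' RNA look depleted relative to its DNA. For each (species,
sample) stratum the pipeline therefore computes each gene family's RNA/DNA
ratio and divides it by the stratum's **median** ratio. This *relative
expression* is invariant to rescaling all RNA (or DNA) values of a stratum
by a constant — the property the tests assert directly.

Conventions, chosen where the definition leaves room:

- Genes with zero DNA are excluded from the stratum (the ratio is
  undefined); no pseudocount by default, though a pseudocount argument
  exists for sensitivity analysis.
- Genes with positive DNA and zero RNA get ratio 0 and **do** enter the
  median: "not transcribed" is a real observation.
- A stratum needs ≥ `min_genes = 10` gene families with positive DNA and a
  positive median ratio; otherwise it is excluded with a warning. A shared
  strain is analyzed only when mother and infant strata both qualify
  ("transcriptome signal in both").

For each qualifying strain, gene families with positive DNA in **both**
subjects are compared: fold = infant / mother relative expression
(+∞ when the mother's is 0). A gene family is **activated** when infant
relative expression > 2 and fold > 2, **deactivated** when infant relative
expression < ½ and fold < ½; all four inequalities strict; the two calls
are mutually exclusive by construction. Families with more than one infant
sample are rejected with an instruction to select samples explicitly — no
implicit averaging.

Counting: the *gene-family universe* is the per-strain set of comparable
gene families summed over strains, so a gene family carried by three shared
strains contributes three units — the convention under which per-strain
totals add up. Event percentages divide event counts by this universe.
*Unique* counts deduplicate gene families within a species across families.
The per-species **replication rate** is, among unique gene families
activated in at least one infant, the fraction activated in two or more
infants; it is undefined (NA) for species with fewer than two family pairs.

Annotation: a gene family is treated as unannotated when its id matches a
configurable pattern (default: ids ending `_unknown`), is in a configured
id set, or an explicit two-column TSV says so. Per strain, the percentage
of annotated genes among all comparable genes and among (de)activated genes
are paired and compared across strains with a Wilcoxon signed-rank test —
exact for n ≤ 25 without ties, normal approximation with continuity
correction otherwise; all-zero differences give p = 1.

## Community statistics

Shannon diversity uses natural logarithms (nats), the vegan-ecosystem
default. Bray–Curtis is computed by scipy's pairwise machinery and checked
against the closed form in the tests. PERMANOVA decomposes the sum of
squared distances into among- and within-group parts; R² = SS_among /
SS_total; the p-value is the permutation estimate
(1 + #{F_perm ≥ F_obs}) / (1 + n_permutations) with ties counted as ≥
(conservative), default 999 seeded permutations. The diversity comparison
is an equal-variance two-sample t-test. Groups of fewer than two samples
and degenerate (constant-distance) matrices are rejected.

## Pathway differential abundance

Pathways observed (value > 0) in at least `min_samples = 2` samples are
tested one at a time on y = log₁₀(abundance + pseudocount), with the
pseudocount set to half the table's smallest nonzero value. The model is a
linear mixed model with role (mother/infant) as fixed effect and a random
intercept per family — the only plausible grouping with one sample per
subject. The Wald statistic for the role effect is referred to a t
distribution with containment degrees of freedom (n_obs − n_families − 1),
not the normal: with ~10 families the normal reference is visibly
anticonservative, and the containment df makes the per-test level
approximately nominal (the null-calibration test measures this). Singular
or degenerate fits fall back to an ordinary linear model with a logged
downgrade; constant pathways are skipped. q-values are Benjamini–Hochberg,
computed within molecule type over the filtered set; DNA and RNA are tested
separately and reported side by side. Significance is q < 0.05.

## Synthetic cohort generator

The generator emulates the analyzed study design — n families, one mother
and one infant stool sample each — with planted ground truth. Defaults
(10 families, 20 species, 500 gene families per species) give a cohort a
strain-level mother–infant study of this kind would consider realistic
while keeping a full pipeline run under a minute on one CPU.

- **Taxonomy.** Mothers draw species profiles from Dirichlet(α = 1),
  infants from Dirichlet(α = 0.3): infants get lower-evenness, lower-
  diversity communities, qualitatively matching infant guts. Both α are
  configurable.
- **Haplotypes.** Ancestor sequences are i.i.d. uniform over {A,C,G,T},
  1,000 columns by default. Each (family, species) is transmitted with
  probability 0.3. Transmitted pairs descend from a common family strain
  with divergence 10⁻⁴ substituted sites between mother and infant;
  everyone else diverges independently from the species ancestor at 10⁻²
  per lineage — a 100× separation, mirroring the bimodal within-family vs
  background distance structure seen in real strain-tracking data. Sites
  substitute independently, always to a different base; divergence must be
  < 0.75 (the Jukes–Cantor domain). Optional gap injection exercises the
  gap-exclusion path.
- **Gene families.** DNA CPM allocates each sample's million copies across
  species by the taxonomic profile, then across a species' gene families by
  lognormal weights. RNA = DNA × lognormal(0, σ) noise on the RNA/DNA ratio
  (σ = 0.1 default) — multiplicative noise on the ratio because the ratio
  is the analyzed statistic. On transmitted strains, a planted 5% of gene
  families is activated (infant RNA × 8) and a disjoint 5% deactivated
  (÷ 8) before the RNA column is renormalized to CPM; the renormalization
  is absorbed by the median normalization downstream. An activation fold of
  8 with σ = 0.1 is comfortably but not trivially above the calling
  threshold of 2; folds ≤ 2 are rejected as unrecoverable. Half the gene
  family ids carry an `_unknown` suffix (unannotated), matching roughly
  half of infant-gut genes lacking functional annotation.
- **Pathways.** 60 pathways with per-pathway lognormal baselines; 10% are
  planted differential with a 4-fold role effect (alternating direction);
  5% sparsity exercises the prevalence filter. The same planted set drives
  the DNA and RNA tables with independent noise.
- All randomness flows from a single integer seed; a fixed seed yields
  byte-identical output files. The pipeline fans one global seed out to
  per-stage child seeds by a fixed affine derivation so stages can be rerun
  in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing depth and read-level noise, gene
presence/absence differences between strains of a species (every gene
family is present in every stratum), within-subject temporal variability
(one time point per subject, as in the emulated design), phylogenetically
structured substitution processes, correlated gene modules and operons, and
compositional coupling between the planted pathway effects and the
gene-family tables. Recovery of planted truth demonstrates the pipeline's
correctness, not field performance.

## Numerical and degenerate-input choices

- Taxonomic profiles are accepted on either the 0–1 or the 0–100
  convention and rescaled; rows must sum to one within 10⁻⁶ afterwards.
- Per-sample CPM totals may not exceed 10⁶ (an unclassified remainder is
  allowed); negative values anywhere are format errors naming the offending
  row and column.
- Normalized-distance threshold comparisons are inclusive (≤); shift
  threshold comparisons are strict (>) at all four boundaries.
- The sharing caller resolves multiple qualifying pairs per (species,
  family) by keeping the smallest distance; summaries sort by event count
  then species name, making all outputs deterministic.
- Wilcoxon p-values with every paired difference zero are reported as 1.

## Known limitations

The per-event shift calls are descriptive thresholds, not hypothesis
tests — with one sample per subject there is no within-subject null
distribution for gene-level inference, so no per-gene p-values are
offered. The mixed-model df correction is the containment approximation,
not Satterthwaite. Breastfeeding status is carried through all outputs but
no stratified inference is attempted. NMDS/PCoA ordination and figure
rendering are out of scope; outputs are plain TSV/JSON.
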