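# Methods

This note records the models, conventions, numerical choices and
limitations behind `svpopdiff`, in the spirit of the methods documentation
of established population-genetics packages. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All internal coordinates are 0-based half-open `[start, end)`. VCF input
(1-based POS, inclusive INFO/END) converts at the I/O boundary; BED is read
natively. Deletion length is `end − start` (symbolic-allele convention).
Genotypes are diploid alternate-allele dosages {0, 1, 2} with −1 for
missing, held in a samples × sites int16 matrix sorted by (chrom, start).

Interval algebra: reciprocal overlap of two intervals is
`min(overlap/len(a), overlap/len(b))` (0 across chromosomes); interval
merging treats bookended (touching) intervals as one region — the
conservative cluster definition, declared rather than silent, because the
"merge the overlapped regions" step of DEL-DC construction is otherwise
under-specified.

## Consensus sets

* **Support rule.** Per sample and SV type, calls from distinct eligible
  callers (deletions: DELLY, Breakdancer, Pindel, CNVnator, Lumpy;
  inversions: all but CNVnator; duplications: Pindel and DELLY) are
  single-linkage clustered at reciprocal overlap ≥ 0.5; a cluster survives
  with ≥ 2 distinct callers. Size bounds 50 bp – 10 Mb apply first.
* **Representative breakpoints** are per-coordinate medians of cluster
  members — robust to one outlier caller. Single-linkage chains can leave
  two cluster medians closer than the merge threshold even when no member
  pair was; the cross-sample clustering therefore iterates on the
  representatives until output sites of one type are pairwise separated
  (RO < 0.5). On non-chained data this changes nothing.
* **Genotyped set.** A genotyped site is kept when it matches a merged site
  of the same type at reciprocal overlap ≥ 0.9; each merged site absorbs at
  most one genotyped site (best overlap, ties to the leftmost). The type
  constraint is an explicit choice; common practice varies on
  whether the match is type-constrained.
* **Precise set.** Sites < 60 kb, flagged `precise` — a stand-in for
  assembly-refined breakpoints, which are only attainable for short SVs.
  The hotspot scan uses this set by default (configurable).
* **Population QC.** Remove sites with missing rate > 0.05; sites
  homozygous alternate in every non-missing sample ("fixed", reference-
  artifact candidates); and, when a LQLC mask track is supplied with fixed-
  site dropping disabled, fixed sites intersecting the mask. A per-genotype
  GQ floor is honoured only when the input carries GQ; otherwise the rule
  is a logged no-op (no defensible default exists).

## Mechanism classification and hotspots

The classifier is a simplified, rule-based stand-in for breakpoint-sequence
pipelines, and is labelled as such. Priority:

1. **VNTR** — both breakpoints inside one annotated tandem-repeat interval;
2. **TEI** — one TE interval covers ≥ 85% of the deleted span (the pig
   hallmark is the ~300 bp SINE, which is why deletion length distributions
   peak there);
3. **NAHR** — supplied flank homology ≥ 50 bp (sequence-level homology
   search is out of scope in v1; homology comes from annotation or input);
4. **NHR** — fall-through; `NA` without TE/VNTR tracks.

Thresholds (0.85, 50 bp) are configuration keys: the rules, not the
numbers, are the contract.

**Runs test.** The Wald–Wolfowitz statistic needs a binary sequence; the
genome-ordered inter-deletion start spacings are dichotomized at their
median (below-median → 1). Regions of elevated deletion density produce
long same-symbol runs and a strongly negative Z; the encoding is a design
choice of this package and is declared here because no single standard
exists for applying a runs test to genomic positions.
Note the median split is informative for density *variation* along the
genome — uniformly tight, equally-sized clusters with rare large gaps can
still look random under this encoding.

**Hotspots.** Non-overlapping 1 Mb windows; a site belongs to the window
containing its start (half-open, boundary goes right). The threshold is the
nearest-rank 95th percentile of per-window counts (value at sorted index
⌈0.95·n⌉), and windows with count ≥ threshold are flagged — by construction
n − ⌈0.95n⌉ + 1 windows plus ties, so the flagged fraction carries a small
positive discreteness offset above 5%. Dominance: a mechanism forming
> 50% of a hotspot's SVs labels it, else `mixed`. Enrichment uses the
two-sided Fisher exact test on mechanism × in/out-of-hotspot counts; the
cross-hotspot comparison is a one-way ANOVA over per-hotspot mechanism
fractions (the stated test name with a declared layout).

## Population statistics

* **Missing data:** excluded pairwise for frequency, heterozygosity, LD and
  F_ST; mean-imputed only for PCA.
* **F_ST** is the Weir & Cockerham (1984) two-population variance-components
  estimator: per-site components a (among populations), b (among
  individuals), c (within individuals) from group sizes, allele frequencies
  and observed heterozygosities; per-site estimate a/(a+b+c), multi-site and
  windowed estimates as the ratio of sums Σa/Σ(a+b+c). Raw values are kept
  (slightly negative is legitimate for an unbiased estimator — a finite
  sample of two identical groups sits just below zero); a clipped column
  serves reporting.
* **Permutation null.** Group labels are shuffled over the pooled samples
  with group sizes fixed; p = (n_exceed + 1)/(n_perm + 1) with n_exceed the
  count of permuted statistics ≥ observed. With 10,000 permutations and
  zero exceedances p = 1/10,001 exactly. Observed and permuted replicates
  always use the same site set; the RNG is seed-controlled and the seed is
  recorded in every report.
* **Tajima's D** treats each diploid as two chromosomes (n = 2 × samples for
  the normalizing constants) and computes per-site pairwise diversity from
  that site's non-missing allele counts, π_site = 2k(m−k)/(m(m−1)); S counts
  polymorphic sites; D = (π − S/a₁)/√(e₁S + e₂S(S−1)); undefined (NaN) when
  S = 0. Windows slide over variant indices (20 deletions, step 10) or over
  a 1 Mb bp grid. The trailing-partial rule is the only reading consistent
  with both of its defining examples: a trailing window is kept only when it
  holds ≥ 10 variants *and* extends past the last full window's coverage
  (so 20 variants give one window and 40 give exactly three).
* **LD** is the squared Pearson correlation of dosage vectors over
  pairwise-complete samples (composite LD) — phase-free and deterministic;
  EM-based haplotype r² on unphased data differs slightly. Decay profiles
  average all same-chromosome pairs within 1 Mb per distance bin; a
  reporting-only r² ≥ 0.2 filter applies to the pair dump, never to the
  binned means.
* **PCA** centres dosages by 2p, scales by √(2p(1−p)), drops monomorphic
  sites, and eigendecomposes the sample covariance; coordinates are
  eigenvectors scaled by √eigenvalue. Components with eigenvalue ~0 are
  numerical null space.
* **Allele sharing.** An alternate allele is "present" in a group when its
  group frequency exceeds 0; sites classify as specific-to-one-group,
  shared-by-some, shared-by-all, or absent. The per-genome specific-site
  rate divides a group's specific-site count by its sample count — the
  normalization is a declared convention (alternatives, such as dividing by
  total cohort size, exist) and is flagged as such.

## Differentiation and DEL-DC

* **Top loci:** threshold = nearest-rank 95th percentile of per-site F_ST;
  a locus passes with F_ST ≥ threshold and permutation p < 0.001 (with
  1,999+ permutations the attainable minimum p is below that alpha).
* **Anchoring:** a passing deletion anchors a passing SNP on the same
  chromosome within 1 Mb when r² is strictly > 0.9. The ±1 Mb window
  matches the LD computation's own windowing.
* **DEL-DC:** seeds are every passing deletion's interval plus the span
  from each anchored deletion to each of its anchored SNPs; seeds merge
  into disjoint clusters (bookended merge). SNP-only seeds are excluded by
  definition — clusters are deletion-anchored.
* **Low-LD deletions:** passing deletions whose maximum r² with any SNP
  within 1 Mb is < 0.6 (vacuously included when no SNP is in range) carry
  differentiation signal no SNP tags.
* **Gene association:** a locus links to a gene by transcript overlap or by
  ≤ 200 kb distance to a strand-aware TSS (both inclusive); TSS grouping
  partitions deletions as INTRON (precedence) / C50 (TSS distance ≤ 50 kb)
  / D50. The precedence is declared; with it, the three groups always sum
  to the passing-deletion count.
* **D statistic:** with σ²_T the population variance of the pooled
  breed-vs-wild F_ST values and σ²_A, σ²_B the within-group variances,
  D = [σ²_T − (σ²_A/n_A + σ²_B/n_B)/(n_A + n_B)] / σ²_T.
  The source equation's typesetting is ambiguous; this parse is the only
  one consistent with the prose definition of every symbol and with D ≤ 1.
  D = 1 when both within-group variances vanish; it decreases
  monotonically in either; NaN when σ²_T = 0. Significance uses the same
  permutation contract (pooled values shuffled between groups).
* **χ² (LD × differentiation):** Pearson df-1 without continuity
  correction on the 2×2 table from two declared dichotomizations: "high
  LD" = max nearby r² > 0.9, "more differentiated" = upper half of the
  passing loci's F_ST. Both cuts are configuration keys.

## The simulated world

Defaults state the emulated cohort once: 66 diploids in three groups
(20 NCPG + 18 SCPG + 28 TWPG — northern and southern Chinese domestic pigs
and the Tibetan-plus-wild group), a three-chromosome 24 Mb genome standing
in for the 2.5 Gb pig assembly, ~570 SV sites (500 DEL / 40 INV / 25 DUP,
roughly 1/100 of a genome-wide merged set) and 2,000 SNPs, 1% missingness.

* **Structure:** Balding–Nichols — ancestral p ~ U(0.05, 0.95), group
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at F = 0.1, dosages
  Binomial(2, p_group). The closed-form target F makes estimator-recovery
  tests possible; a coalescent backend is a non-goal.
* **LD** is induced by comonotone block coupling (one latent uniform per
  100 kb block per sample, used with probability 0.8 per site), not by
  recombination maps: only the r²-threshold machinery needs exercising.
* **Implanted systems:** 20 deletions get group frequencies 0.9 vs 0.1
  (delta 0.8, expected site F_ST ≈ 0.6) — the magnitude of strongly
  differentiated domestication loci, which sit well above a top-5%
  selection threshold of ~0.4 on an F = 0.1 background; each gets a
  companion SNP within 50 kb copying its dosages with 2% flip noise — the
  high-LD anchor structure.
* **Callers:** per-caller sensitivity / false calls per Mb / breakpoint
  jitter s.d. reflect the tools' characters (split-read callers precise,
  read-depth callers coarse): delly (0.90/0.2/3), breakdancer
  (0.85/0.3/25), pindel (0.90/0.2/2), cnvnator (0.70/0.5/50), lumpy
  (0.88/0.2/10). True SV sites of one type are placed with pairwise
  RO < 0.5 (rejection sampling) because the truth emulates a merged call
  set, which is separated at the merge criterion by construction.
* **Annotations:** TE lengths mix an 80% Normal(300, 35) SINE-like peak
  with a log-uniform tail; VNTRs 100–2,000 bp; gene models with 2–8 exons,
  random strand, strand-aware TSS; LQLC mask ~15% of the genome. Tracks
  are sorted, internally non-overlapping and bounded.

What a green test does *not* establish: the generator has no sequence
content, no realistic recombination or demography, no caller biases beyond
the three profile parameters, and mutual independence of annotation tracks
— so green tests certify the statistical machinery and its rules, not
concordance with any real cohort's headline numbers, which derive from 66
high-depth genomes and are out of desk-scale reach.

## Determinism and numerics

Every stochastic routine takes a seed and uses an isolated
`numpy.random.Generator`; identical (inputs, config, seed) give
byte-identical summaries. Quantiles are nearest-rank throughout (no
interpolation), fractions over empty denominators are NaN rather than
errors where a statistic is merely undefined, and dual-implementation
oracle tests pin the F_ST components and Tajima's D to 1e-10.
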