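# Methods

## The inference problem

A hybridogenetic complex contains sexual species and hemi-clonal hybrid
lineages. Each lineage carries one haploid genome clonally (identical in
every individual and every generation, absent mutation) and combines it
with a fresh gamete from a sexual host species each generation; the host
is a genetic parent but never a genetic grandparent of the offspring.
When the sexual ancestor of the clonal genome is missing, its genome is a
"ghost" observable only inside the lineages. The package answers three
questions from co-dominant genotypes (SNPs or allozymes):

1. which individuals are hybridogens (and of which parent pair);
2. how taxa relate (heterozygosity, fixed differences, distances, PCoA);
3. whether a putatively pure population of the ghost species is a true
   remnant or a "resurrection" cross between two ghost-carrying lineages.

The resurrection test rests on an allele-sharing identity, not on a
likelihood model: offspring of a cross between lineages 1 and 2 carry
clonal haplotype 1 plus clonal haplotype 2, so they share at least one
allele with each lineage at every genotyped locus. A single absolute
fixed difference against a founder (beyond the error tolerance τ)
falsifies descent from that founder pair. The verdict rule is:
both counts ≤ τ → `resurrection-consistent`; any count > τ →
`pure-remnant`; no comparable loci → `inconclusive`.

## Statistics and their conventions

- **Allele profiles.** All pairwise statistics are computed from
  per-taxon, per-locus allele frequencies over non-missing calls. Calls
  are unordered pairs; phase is never used.
- **Fixed differences.** With tolerance `tloc`, a locus (compared when
  both taxa have ≥ `min_n` genotyped individuals; default `min_n = 1`)
  is a fixed difference iff no allele exceeds frequency `tloc` in both
  taxa. At `tloc = 0` this is exact disjointness of the observed sets.
  Loci with data in only one taxon are excluded from that pair's
  comparison and from `n_loci_compared`; the count is reported next to
  `n_loci_compared` so stricter `min_n` choices can be explored.
- **H_O** is the unweighted mean over loci of the per-locus heterozygote
  fraction; loci with zero calls in the taxon are excluded, and a taxon
  with no data yields an explicit NaN, never a silent 0.
- **Euclidean distance** is the unscaled root-sum-of-squares of
  reference-allele frequency differences over shared-data loci (with
  thousands of loci its magnitude is tens; a `normalize` option divides
  by the square root of the locus count).
- **Nei's (1972) D** averages the homozygosity/identity terms across
  loci *before* the logarithm (the standard-distance convention, not
  per-locus log averaging). Disjoint profiles give +∞, flagged as such.
- **Diagnostic panels** are the tloc-qualified fixed-difference loci of
  a pair of sexual reference taxa. A panel locus's A-side/B-side allele
  sets keep only alleles with frequency > `tloc` in that parent;
  otherwise a rare shared allele (typically genotyping error) would put
  the same allele on both sides and let homozygotes masquerade as
  diagnostic heterozygotes.
- **Hybridogen score.** `f_het` is the fraction of non-missing panel
  loci where an individual carries one A-side and one B-side allele.
  Classification threshold θ defaults to 0.9 — "mostly fixed"
  heterozygosity, leaving room for genotyping error and borderline
  panel loci — with at least `min_loci = 10` usable panel loci required
  for a confident call (an allozyme-scale panel of ~13 loci should
  still qualify).
- **Classification** scores every individual against every pair of
  sexual references; the best pair wins if its `f_het ≥ θ`, otherwise
  the individual goes to the sexual reference sharing the largest
  fraction of its alleles. Resurrection-cross offspring are homozygous
  combinations of two ghost haplotypes and correctly classify as
  sexual, not hybridogen.
- **Resurrection tolerance τ** defaults to 0: the sharing argument is
  absolute. τ > 0 is offered because genotyping error in small samples
  can manufacture spurious fixed differences.

## Ordination

Individual distances are Euclidean on per-locus allele dosage (count of
the reference allele, 0/1/2; loci with more than two alleles expand to
one dosage column per allele). Missing data is handled by
pairwise-complete rescaling: squared differences are averaged over
mutually non-missing features and multiplied by the total feature count.
This preserves expected distances when missingness is random within a
taxon — important when one taxon (the remnant, with restriction-site
divergence) loses a quarter of its loci — at the cost of a distance
matrix that is not exactly Euclidean-embeddable; the PCoA therefore
drops small negative-eigenvalue axes with a warning recording their
magnitude. PCoA itself is Gower double-centering of −D²/2 followed by a
symmetric eigendecomposition; axis shares are percentages of the
positive-eigenvalue total. Intermediacy uses taxon centroids in the
first k = 2 axes (the axes one inspects on a scatterplot): projection
fraction t (0.5 = exact midpoint) and scaled midpoint displacement
D_mid. Coordinates are defined up to rotation/reflection; tests compare
configurations through Procrustes alignment, and an independent PCoA
(scikit-bio) serves as a cross-check oracle.

## Filtering

The locus filter chain runs in the fixed order reproducibility →
call rate → secondaries → monomorphics, each step inclusive (≥) in its
threshold: reproducibility ≥ 0.99, call rate ≥ 0.95 (i.e. remove loci
with *more than* 5% missing calls), one uniformly random SNP retained
per sequenced tag under a recorded seed, then loci monomorphic over
non-missing calls removed (monomorphism commonly *arises* after
individuals or populations are dropped, so the step is also exposed for
use after any subset). Only loci are ever filtered, never individuals.
The `FilterReport` reconciles exactly: `loci_out = loci_in −
loci_removed` at every step, and step outputs chain.

## The simulator

The generator emulates the statistical structure the analysis assumes,
with known truth per individual (class, origin, clonal haplotype ID,
maternal clade):

- **Species frequencies.** Ancestral frequencies ~ Uniform(0.05, 0.95);
  each species drifts by a Balding–Nichols step: Beta(p(1−F)/F,
  (1−p)(1−F)/F). The default divergence is **F = 0.8**: the taxa are
  distinct species whose markers are largely fixed within species, so
  within-species H_O lands near 0.07 while hybridogens (heterozygous
  wherever their two genomes disagree) land near 0.37 — the
  qualitative contrast (unisexual H_O far above sexual H_O, hundreds of
  fixed differences between sexual species at 4,000 loci) that real
  reduced-representation data from such complexes shows. Per species
  pair, a configurable block of loci is *forced* diagnostic
  (frequencies 1 vs 0; default 40 per pair).
- **Populations.** Sexual samples are Hardy–Weinberg (two independent
  gametes). A hybridogen lineage draws its clonal haplotype once at
  founding (optionally several founding clones) and pairs it with a
  fresh host gamete per individual; extra generations change nothing
  but the host gametes, so the clonal genome is bit-identical across
  generations. A resurrection cross combines the two founders' clonal
  haplotypes, making all offspring genetically identical. A remnant
  population drifts from the ghost frequencies by a further
  Balding–Nichols step (default F_drift = 0.05) and is then sampled
  under Hardy–Weinberg.
- **Degradation.** Per-taxon locus dropout (probability δ a locus is
  missing for the whole taxon — restriction-site mutation), then
  per-call missingness ε, then symmetric one-allele flips at the
  genotyping error rate. Defaults: ε = 0.015 and δ = 0.30 for the
  remnant taxon, so ordinary taxa sit near 1.5% missingness and the
  remnant near 31% (expectation δ + (1−δ)ε = 0.3105); error rate
  0.001.
- **Default scenario.** Three species (A, B, ghost X), 4,000 loci, two
  sampled sexual species (n = 20 each), a drifted remnant of X
  (n = 20), and the three lineages A×B*, A×X*, B×X* (n = 20 each;
  maternal clade = host species unless overridden).

What the simulator deliberately does **not** reproduce: linkage and
recombination maps, mutation within lineages (clonal transmission is
exact), ascertainment bias of marker discovery, gynogenesis, and
sequence-level mtDNA (the maternal clade is a categorical label).
Passing tests therefore demonstrate the *logic* of the inference —
inheritance rules, statistics, verdict calibration under drift,
missingness and genotyping error — not robustness to linked markers or
non-random missingness.

## Numerical choices and degenerate inputs

- Integer allele codes are per-locus, first-seen order; original
  symbols are kept for reporting. Unordered-pair storage makes 0/1 and
  1/0 identical; half-missing VCF calls (./0) are treated as missing.
- Frequency denominators of zero (no data) produce flagged all-zero
  profile rows, never NaN propagation; empty taxa raise.
- PCoA drops eigenvalues below 1e−10·λ₁ and warns when negative
  eigenvalues exceed that tolerance; coincident parent centroids make
  the intermediacy axis undefined and raise.
- Secondaries thinning iterates tags in sorted order with a single
  recorded global seed, so the retained set is a pure function of
  (dataset, seed).
- The remnant drift step clips frequencies to (1e−9, 1−1e−9) before the
  Beta draw (the Beta parameters degenerate at 0/1) and restores exact
  fixation afterwards, so forced diagnostic loci stay fixed.

## Validation scale

The test suite validates each statistic against naive brute-force
recomputation (1,000 random ≤ 10 × 50 datasets), the zero-fixed-
difference law for lineages vs hosts (100 full-scale scenarios),
verdict calibration (200 replicates each at L = 4,000, remnant n = 7,
F_drift = 0.05), six-taxon classification recovery (5 replicates at
n = 20, L = 4,000, accuracy ≥ 98%), and F1 intermediacy (100 replicates
at L = 1,000, n = 30 per taxon; t ∈ [0.45, 0.55] in ≥ 95%). The
exhaustive resurrection identity is checked over all 3^L founder
genotype configurations for L ≤ 6. Where the published filtered
genotype tables of a real complex are placed under
`data/supplementary/`, an additional test recomputes the published
pairwise summary (H_O to ±0.005, fixed-difference counts exactly)
directly from them.

## Known limitations

- `min_n = 1` admits single-individual locus comparisons; with very
  small samples the fixed-difference count is an underestimate of true
  divergence yet can also contain error-driven false positives — hence
  the exposed τ and `tloc`.
- Classification assumes the sexual references are correctly designated
  and non-overlapping; it does not detect backcrosses or later-
  generation hybrids (no admixture model).
- The Euclidean distance uses one reference allele per locus and is
  intended for biallelic data; for multi-allelic allozymes Nei's D is
  the appropriate pairwise distance.
- The intermediacy statistic is descriptive geometry on centroids, not
  a significance test.
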