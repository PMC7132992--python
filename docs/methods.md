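# Methods

## The imputation problem

A breeding nucleus population is recorded in a sorted pedigree (parents
before progeny). Most animals are genotyped with a low-density (LD) or
high-density (HD) marker array; a small fraction (~2%) is sequenced,
mostly at 1-2x, with a few key ancestors at 15-30x. The goal is a
posterior expected alt-allele dosage for *every* pedigree member at
*every* sequence variant, using pedigree transmission and linkage — not
population linkage disequilibrium.

## Genotype and inheritance model

Genotypes are carried as probability 4-vectors over ordered genotypes
(aa, aA, Aa, AA), first symbol paternal. Inheritance at a locus is a
segregation state s in {pp, pm, mp, mm}: whether the paternal gamete
copied the sire's paternal (p) or maternal (m) haplotype, and likewise
for the maternal gamete within the dam. Conditional on s, transmission is
deterministic copying; uncertainty in s enters as a mixture over the four
kernels.

Evidence enters through a penetrance vector per individual and locus:
sequencing reads contribute a binomial likelihood with alt-read
probability (e, 1/2, 1/2, 1-e) per ordered genotype (e = per-read error,
default 1e-3), and an observed array genotype contributes 1-eps to the
matching ordered states and eps/2 elsewhere (eps default 1e-4).

## Peeling as message passing

The pedigree is factorized into nuclear-family factors (sire, dam, all
their joint children). Each individual's posterior is proportional to

    anterior x penetrance x prod(posterior terms over families as parent)

where the anterior is the message from its parents' family and the
posterior terms are messages from each family in which it is a parent.
The engine runs synchronous sweeps: a parents-first pass updating
child-bound messages, then a progeny-first pass updating parent-bound
messages, iterated until the largest posterior change falls below the
tolerance (default 1e-4, at most 20 iterations; 1e-12/100 for oracle
comparisons). On loop-free pedigrees this is exact sum-product: the unit
tests verify equality with exhaustive enumeration over all 4^n ordered
genotype configurations to 1e-6. Inbreeding loops make it iterative
(loopy) peeling; on a realistic partially-observed looped fixture the
deviation from enumeration is <1e-3, but adversarial penetrance
configurations on looped pedigrees can deviate by ~1e-2 — an accepted
approximation. An optional damping factor (default off) is available for
oscillating loops.

Single-parent records are completed with a virtual, data-free founder
co-parent. Probabilities are floored at 1e-30 before normalization; an
all-zero product is thereby repaired rather than raised.

## Two-step hybrid peeling

1. **Multi-locus step** on the HD panel loci only, using all array data as
   observed (LD individuals contribute their LD loci directly, without
   pre-imputation to HD) plus panel-site reads. Genotype sweeps alternate
   with a forward-backward pass per individual along each chromosome over
   the four segregation states; transitions between adjacent loci
   factorize into independent paternal/maternal switches with probability
   r from Haldane's map function r = (1 - exp(-2d))/2. Founders keep the
   uniform segregation distribution.
2. **Interpolation**: each segregation indicator's marginal is bridged
   from the flanking panel loci through the two-state Markov chain with
   the Haldane recombination fraction for the intervening distance; the
   two flank forecasts are combined as independent sources. Beyond
   terminal panel loci the single-flank forecast decays toward uniform.
   A variant on the panel receives the panel posterior unchanged.
3. **Single-locus step** at every variant (processed in batches), with the
   interpolated segregation mixture in the transmission kernel and a
   founder prior at the per-variant allele frequency estimated as
   (sum of alt evidence)/(sum of evidence) from array genotypes and
   alt-read fractions, clipped away from fixation by 1/(2N).

Dosage = P(aA) + P(Aa) + 2 P(AA). Relabelling ref/alt everywhere maps
dosages to 2-d up to the convergence tolerance; the penetrance and
frequency-estimation arithmetic is written to make that mapping exact in
floating point up to iteration-count effects.

A gauge caveat: for a child of a *founder*, which founder haplotype a
gamete copied is unidentifiable in principle (swapping a founder's two
haplotypes together with all its progeny's indicators leaves the
likelihood unchanged), so segregation recovery is only assessed on
individuals whose parents are both non-founders.

## Synthetic populations

The generator emulates the statistical structure the analyses assume:

- **Pedigree**: discrete generations; per generation 5% of males and 50%
  of females are selected (at random — no trait is modelled) and litters
  of Poisson(6) size, truncated at 1, are produced until the generation
  quota is filled. Defaults: 40 founders, 10 generations, 2000
  individuals — an effective population size of roughly 20, matching an
  intensely selected nucleus line; at a desk-scale census the deep,
  narrow shape is what preserves realistic haplotype sharing.
- **Genomes**: 2 chromosomes x 100 cM with 5000 evenly spaced variants
  each. Founder alt-allele frequencies are Beta(0.3, 0.3) truncated to
  [1/(4N), 1-1/(4N)] (many rare variants); founder haplotypes are drawn
  site-independently (Hardy-Weinberg, **no ancestral LD**). Gametes
  recombine by a no-interference crossover process consistent with the
  Haldane map.
- **Panels**: HD = 200/chromosome (2 markers/cM), LD = 40/chromosome,
  nested, snapped to nearby sites with MAF >= 0.05 where possible. The
  densities preserve the per-cM informativeness that segregation
  estimation needs; scaling the commercial panel-to-variant count ratio
  down instead would give an LD array 30x sparser per cM than any real
  array.
- **Genotyping statuses**: generations 0-1 are 50% ungenotyped / 50% HD
  (marker arrays adopted mid-pedigree); later generations 2% none / 68%
  LD / 30% HD. Arrays are observed without error.
- **Reads**: per-site sequenceability s_v ~ Gamma(shape 4, mean 1) once
  per variant; read totals Poisson(c_i s_v); each read reports a
  uniformly chosen haplotype's allele, flipped with probability 1e-3.

What the generator does *not* capture: ancestral linkage disequilibrium
(founder haplotypes share no segments), array genotyping error,
overlapping generations, sex chromosomes, and structural variation.
Passing tests therefore demonstrate the pedigree-and-linkage machinery,
not performance on populations whose founders share haplotypes — on real
data, read pooling across distantly related carriers of a shared
ancestral haplotype adds information this model cannot express, and the
desk-scale median accuracy (~0.88-0.89) sits below what full-scale
populations with shared founder haplotypes can attain partly for that
reason.

## Sequencing-budget allocation

A fixed budget (default: cost of sequencing 2% of the population at 2x)
is split 30/15/25/30 across four tiers drawing from one global pool:
top sires (most genotyped progeny) at 2x; top dams at 1x; "focal" key
ancestors — greedy picks maximizing not-yet-covered pedigree descendants
— at 30x for the first pick and 15x after, their unsequenced parents at
5x; and 1x top-ups for individuals whose parents and grandparents carry
under 10x of cumulative assigned coverage, most deficient first. The
focal tier may draw ahead of its nominal share so that one deep key
ancestor is funded whenever the global budget allows; unspent capacity
rolls forward. The descendant-count greedy stands in for
haplotype-representation scoring: it preserves the strategy's shape (few
deep key ancestors plus a broad 1x spread) without phased haplotypes.

## Accuracy auditing

- **Individual-wise accuracy**: Pearson correlation between true
  genotypes and imputed dosages across variants after subtracting twice
  the population allele frequency from both ("MAF-corrected"), which
  stops rare variants from inflating the statistic. Zero-variance cases
  are counted and excluded, not zeroed. Variant-wise accuracy is the
  plain correlation across individuals at one site; a quantile-matched
  table maps corrected to raw values for comparability.
- **Leave-one-out**: each high-coverage validation individual's reads are
  removed, the population re-imputed, and its dosages correlated against
  either the recorded truth or the full-data imputation, on a seeded
  random subset of variants (default 2000; a full re-run per individual,
  restricted to that subset, keeps this affordable).
- **Factor analysis**: regression trees (greedy binary partitioning, a
  split kept only if it raises overall model R^2 by >= 0.005, minimum
  leaf 20) on 23 individual-level factors (population size, own status,
  12 genotyped-relative counts, 8 sequencing variables, connectedness =
  sum of numerator-relationship coefficients) and 6 variant-level factors
  (MAF, position, panel distance, site depth and carrier counts).
  Consecutive splits on one variable are reported merged. A stratified
  tenfold cross-validation scores prediction of individuals below the
  0.95 accuracy threshold (sensitivity, specificity, and sensitivity by
  observed-accuracy band); a joint OLS screens all factors. At desk scale
  the individual tree's first split is the individual's *own* genotyping
  status rather than grandparent genotyping: a desk population cannot
  supply the dense relative networks that, in very large pedigrees, keep
  even ungenotyped individuals accurate and push ancestor genotyping to
  the top of the hierarchy. Grandparent and progeny genotyping counts
  appear at the next level.
- **Error injection**: worst-case scenarios per high-coverage target —
  sequence reads replaced by another high-coverage individual's (donor
  keeps its data), array record replaced by an HD individual's, a
  high-coverage donor's progeny re-assigned to the target, and a
  removal control. Impact is the MAF-corrected dosage correlation between
  clean-data and corrupted-data runs, per relative class; without the
  correction, the correlation between any two members of a closed Ne~20
  population is ~0.8 from the shared frequency profile alone, masking
  every effect. The perturbation fixture (400 individuals, one
  chromosome, budget fraction 0.06 plus five 15x validation parents)
  keeps a single validation individual's coverage share marginal, as in a
  full-scale validation design; under a strict 2% desk budget the removal
  control would measure budget starvation rather than error propagation.

## Quality control

Parent-progeny pairs sharing >= 50 comparable loci are flagged when their
opposing-homozygote percentage exceeds 2% (array error rates are far
below that). Rule 1 removes all data of an individual conflicting with
every available parent and progeny; rule 2 cuts a link whose conflict is
confined to one pair on both sides; rule 3 replaces a parent by a
data-free dummy (ids DUM<N>, prepended as founders) when a full-sib
litter conflicts with that parent only, preserving the full-sib
relationship. Rules apply in order 1-2-3 and conflicts are recomputed
once. A separate filter drops variants whose mean depth across sequenced
individuals exceeds 3x the overall mean (repetitive-region proxy).

## Numerical and design choices

- Probability floors 1e-30; message and posterior vectors renormalized at
  every update; all randomness through `numpy.random.default_rng` seeded
  from the run configuration.
- Multi-locus outer loop stops when the segregation change drops below
  max(tol, 1e-3); the single-locus stage runs per chromosome in batches
  of 600 variants to bound memory.
- Budget-plan ties break by earlier pedigree position, then id; greedy
  focal ties by descendant count then earlier position.
- Relationship sums materialize the numerator relationship matrix in
  float32 (an n^2 cost, comfortable to ~10k individuals) rather than a
  matrix-free recursion.
- The accuracy-structure analyses evaluate a seeded 2000-variant random
  subset of the 10,000 simulated variants; the problem sizes throughout
  (population 2000, two chromosomes, panel sizes above) are the package's
  default desk-scale study design.

## Known limitations

Loopy peeling is approximate on inbred pedigrees (bounded in tests only
for realistic fixtures); founders carry no LD, bounding attainable
imputation accuracy below the real-data setting; array genotypes are
simulated error-free, so QC fixtures inject rather than sample errors;
segregation for children of founders is unidentifiable (gauge freedom)
and excluded from recovery metrics; the CLI's evaluate/factors/perturb
subcommands re-run the in-memory study rather than consuming intermediate
files.
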