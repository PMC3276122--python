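# Methods

`qtnmap` operationalizes a fine-mapping strategy for quantitative trait
loci (QTL) in half-sib livestock designs: combine daughter-design QTL
segregation statuses of a small panel of patriarch sires with dense SNP
genotypes to find markers *concordant* with the QTL, delimit the candidate
interval by the haplotype shared identically by all chromosomes carrying
the favorable marker allele, resolve the gene variants segregating in the
interval from allele-specific amplicon sequencing, and test variant copy
number for association with breeding values. This note records the models,
the defaults and why, the numerical choices, and what the synthetic data
do and do not establish.

## Concordance model

A biallelic marker is fully concordant with a QTL across a sire panel when

1. every QTL-homozygous sire is marker-homozygous,
2. every QTL-heterozygous sire is marker-heterozygous, and
3. all doubly heterozygous sires carry the same marker allele in coupling
   with the favorable QTL allele (same linkage phase).

`classify_snp` counts the state matches (1, 2) and, when phase assignments
are supplied, the size `k` of the majority phase group among the doubly
heterozygous sires. Classifications: `FULL` (all three conditions),
`PHASE_PARTIAL` (states fully matched, phase not unanimous or not
supplied), `STATE_PARTIAL` (exactly one of the two state conditions holds
panel-wide), `NONE` (neither holds), `SKIPPED_MISSING` (any missing
genotype; such markers are never ranked — only fully genotyped comparisons
are reported). A family counts as concordant when its sire satisfies its
own condition: state match for QTL-homozygotes, state match plus majority
phase for QTL-heterozygotes.

**Null probability.** Under marker–QTL independence with marker allele
frequency `p` (`q = 1 − p`), and sires independent, a QTL-homozygous sire
is marker-homozygous with probability `p² + q²`, and a QTL-heterozygous
sire is marker-heterozygous *with a designated linkage phase* with
probability `pq` (half of `2pq`). The probability of the exact observed
configuration — all homozygotes matched, all heterozygotes matched,
exactly `k` of them on the designated phase — is

    P = (p² + q²)^n_hom · C(n_het, k) · (pq)^n_het

and `configuration_probability` generalizes this to partial matches. With
`p = 0.5`, `n_hom = n_het = 5`, `k = 4`:
`P = 0.5⁵ · 5 · 0.25⁵ = 1.52588 × 10⁻⁴`, and over `m = 704` independently
tested markers the expected count at this concordance level is
`mP ≈ 0.107` — the multiple-testing argument that a single such marker is
unlikely to arise by chance.

Two semantic choices deserve note. First, `p` is used as the **marker**
allele frequency throughout; fixing `p = 0.5` treats the marker as
maximally polymorphic, which is the conservative choice (it maximizes
`pq`). By default the scan estimates `p` per marker from the panel's
chromosomes; `--null-p 0.5` (or `null_p=0.5`) fixes it. Second, the
closed form prices a **designated** phase (`C(n,k)(pq)^n`), whereas the
classifier's `k` is the **modal**-group size, since observed data carry no
a-priori phase label. The designated-phase form matches how such a
configuration is conventionally priced (the direction is fixed by the
population-level association); the Monte-Carlo calibration test counts
designated-phase outcomes on both sides of the comparison, so it is
internally consistent. With an exact phase tie the majority is undefined;
`k = ⌈n/2⌉` is used and the result is flagged (`phase_tie`).

Ranking in `scan_concordance` is deterministic: classification first
(`FULL` best), then ascending chance probability, then position.

## Shared-haplotype detection

Chromosomes carrying a young, favorable allele are expected to share an
identical-by-descent segment around it. `find_shared_region` collects
every chromosome (haplotype, not individual — a homozygote contributes
two) carrying the anchor allele and extends greedily in both directions,
admitting the adjacent SNP while **all** carriers agree on a single
non-missing allele; the first disagreement (or the window edge) stops
extension on that side. Boundaries are reported at SNP positions,
inclusive; the span is the distance between the outermost shared SNPs,
with no extrapolation into the flanking intervals. By default a missing
allele on any carrier stops extension (conservative, since unanimity can
no longer be verified); `missing_tolerant=True` lets missing calls
abstain. Shared alleles may be common in the population, so
`region_exclusivity` counts the non-carrier chromosomes matching the
consensus at every region SNP except the anchor itself — a large count
warns that the region tags a common haplotype rather than an exclusive
lineage.

`phase_conflict_check` compares two independent phasings (e.g. an
unrelated-individuals phaser versus a pedigree-based one) per individual
*up to swap* of the haplotype pair — within-individual haplotype order is
arbitrary everywhere in the package — choosing the pairing that minimizes
disagreements and reporting each still-disagreeing SNP.

## Variant deconvolution

An allele-specific primer splits a duplicated locus into two template
pools; direct sequencing of a pool shows, per polymorphic site, one base
(homogeneous) or two (a double peak where two co-amplified variants
differ). Each pool therefore mixes at most two variant sequences — more
than two components is out of scope and reported as unresolved rather
than guessed. Given one known component, the second is determined exactly:
the complementary base at double-peak sites, the shared base elsewhere.
`collect_variants` harvests pure (all-singleton) profiles as seeds in
input order, deconvolves mixed profiles against every consistent known
sequence (a seed is consistent when its base lies in the call set at every
site), feeds newly inferred sequences back as seeds until a fixed point,
and deduplicates by base string. Labels follow first appearance
(`V1, V2, …`); a label map can pin canonical names. Deconvolution is an
involution (deconvolving against the inferred component returns the
known), every inferred base is conserved from the call set, and site-wise
remixing of the two components reproduces the observed call sets — all
enforced as tests.

## qPCR copy number and association

With amplification efficiency `E` (2.0 = perfect doubling), template
amount is proportional to `E^−Ct`. Per sample,

    RQ = E_t^(−mean Ct_target) / E_r^(−mean Ct_reference)

computed in log space for numerical safety, normalizes the target against
a non-CNV autosomal reference gene; all RQs are rescaled so the largest
sample equals `scale_max` (default 2.0, i.e. two copies per diploid genome
for the top sample — the published scaling convention). Replicates are
summarized by the arithmetic mean Ct (the replicate-combination rule is
not dictated by the data; a geometric-mean-of-RQ alternative is available
and coincides with the default for balanced replicates). The NRQ standard
error comes from the first-order delta method:
`se(NRQ) = NRQ · sqrt((ln E_t)²·var(mean Ct_t) + (ln E_r)²·var(mean Ct_r))`,
with `var(mean) = s²/r` (zero for a single replicate). Efficiencies
default to 2.0 unless standard curves supply estimates via
`E% = 100·(10^(−1/slope) − 1)`; note that printed slope/efficiency pairs
in older reports are not always mutually consistent under this standard
formula, so curves — not printed percentages — are authoritative here.
The LOD-to-NTC gap bounds nonspecific product at `100·2^(−ΔCt)` percent
(6.25% at 4 cycles), assuming perfect doubling.

Association is ordinary least squares of breeding values on copy number
and/or genotype dosage (0/1/2 copies of the favorable allele), singly or
jointly, with plain two-sided t-tests; no pedigree/relatedness correction
is applied (matching the simple regression the design calls for), no
interaction term, and perfectly collinear or constant predictors raise a
singularity error naming the predictors. t-statistics are invariant to
predictor standardization (tested).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular chromosome:

- **Founders with LD**: a handful of ancestral haplotypes (default 4) are
  copied in blocks (per-step switch probability `spacing / ld_block_length`,
  defaults 50 kb / 250 kb) with per-site mutation (default 0.01), giving
  decaying LD and genuine shared ancestral segments. Ancestor source and
  mutation flags are retained in `SimulationTruth`, so tests can verify
  identity-by-descent premises from ground truth rather than from the
  detectors under test.
- **Sires**: pairs of founder haplotypes; QTL status is defined as QTN
  heterozygosity (`HET` iff the two QTN alleles differ), and the default
  10-sire panel is rejection-sampled to the 5 het / 5 hom split of the
  study design (a feasibility error after 10,000 attempts, rather than a
  silent relaxation).
- **Phases**: for doubly heterozygous sires, the marker allele on the
  haplotype carrying the favorable QTN allele, taken from truth.
- **Breeding values**: `bv = effect · favorable dosage + N(0, polygenic_sd)`
  with defaults 0.57 trait units and unit polygenic standard deviation.
- **qPCR**: `Ct = base_ct − log_E(copies) + N(0, ct_noise_sd)` per
  replicate (defaults: base 25 cycles, `E = 2`, 0.1-cycle noise,
  duplicates); zero copies produce Ct at a residual floor
  (`base_ct + 8` cycles), emulating the trace signal an absent variant
  still yields; the reference probe sees a constant two copies.

Everything is driven by one integer seed through `numpy.random.default_rng`;
identical configurations are byte-identical on disk.

What passing tests on these data show — and do not. The simulator produces
exact HWE sampling of founder chromosomes, symmetric Gaussian noise, and
block LD with a single global block-length scale. It has no pedigree
structure among sires, no genotyping error, no allele-frequency spectrum
matched to a real chip, and no daughter-level phenotypes (statuses come
from truth, not from segregation analysis — inferring them is explicitly
out of scope). Parameter-recovery results therefore validate the
estimators' correctness and calibration under the stated model, not their
robustness to relatedness or genotyping artifacts in real panels.
Population-scale association quantities (significance at n = 900,
realized R² values) depend on real genotype/EBV data and are deliberately
not simulated; the package covers them only through the recovery
properties (effect recovered within 3 SE in ≥95% of replicates at
n = 900; NRQ rank-recovers true copies in ≥95% of replicates).

## Problem sizes and numerical choices

The test suite's stochastic checks use 2,000 simulated 704-marker panels
for the Monte-Carlo concordance calibration, 200 replicates of n = 900 for
effect recovery, 500 replicates for qPCR rank recovery, and 60 replicates
for the shared-region containment property — sizes chosen so Monte-Carlo
standard errors are small relative to the 3-SE acceptance bands while the
whole suite stays desk-scale. Exact-arithmetic checks (enumeration oracle
vs closed form) are held to 10⁻¹². Probabilities are computed with
`math.comb` and plain floats; the configuration probability allows the
degenerate boundary `p ∈ {0, 1}` internally (monomorphic markers in a
scan) while the public single-configuration entry point rejects it, as a
frequency outside (0, 1) there is always a caller error.

## Known limitations

- Concordance assumes sire genotypes independent under the null; related
  patriarchs violate this and make the chance probability anti-conservative.
- The shared-region detector is exact unanimity — a single genotyping
  error on one carrier truncates the region; there is no mosaic/error
  tolerance beyond the missing-data flag.
- Deconvolution trusts the two-component assumption of allele-specific
  splitting; three co-amplified variants in one pool are reported
  unresolved, never resolved heuristically.
- OLS association ignores relatedness and heteroscedasticity; p-values on
  half-sib panels should be read as descriptive.
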