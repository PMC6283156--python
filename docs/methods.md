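# Methods

`riailmap` implements the quantitative-genetics pipeline used to dissect
multi-trait responses of a two-parent recombinant inbred advanced intercross
line (RIAIL) panel phenotyped on a large-particle sorter: trait processing,
dimensionality reduction, linkage mapping, heritability decomposition,
hotspot detection, and the introgression-line validation calculus.  This note
records the models, the defaults and why they are what they are, and the
places where a design choice had to be made.

## The synthetic panel

The generator emulates the marginal genetics of a RIAIL panel rather than its
pedigree.  Each strain's chromosome is a two-state Markov chain over the
marker grid with switch probability per interval given by the inverse Haldane
map function, r = (1 − e^(−2d/100))/2, applied to the interval's *expanded*
genetic length d.  Advanced-intercross map expansion is folded into the map
itself: the default map has six chromosomes whose lengths are multiples of
26 cM summing to 1,690 cM (so 26-cM binning tiles the genome in exactly 65
bins), with markers every 5 cM (346 markers).  The marker density is a
desk-scale choice — real panels of this kind are genotyped at thousands of
markers, but every statistic here depends on genotype correlations, which a
5-cM grid already resolves; the spacing parameter is exposed and the builder
guarantees the realized spacing never exceeds the request.  No residual
heterozygosity, genotyping error or segregation distortion is simulated, so
tests passing on this panel say nothing about robustness to those artifacts.

Alleles are coded parent A = −1, parent B = +1.  Under this symmetric coding
with allele frequency 1/2, two unlinked markers and their product are
mutually orthogonal, which makes planted additive and product-term
(epistatic) variance fractions directly interpretable and lets a pure
interaction hide completely from marginal scans — the property the
two-dimensional scan exists to break.

Phenotypes are built as a latent trait z = Σ√f_k·g_k + Σ√f_ij·g_i·g_j + e,
with e filling the variance to 1, then projected onto correlated observed
traits: trait t = λ_t·z + √(1−λ_t²)·ε_t, so each loading λ_t is the trait's
correlation with the latent trait.  The default 24 loadings fall linearly
from 0.95 to 0.30, mimicking the empirical structure of sorter summary
statistics (size quantiles highly inter-correlated; dispersion and brood
traits loosely coupled).  The sorter-record generator emits per-animal TOF
(length) and EXT (optical density) draws per well, with per-assay batch
shifts so the assay regression has real work to do.

## Sorter traits

Each well reduces to 24 traits: {mean, median, q10, q25, q75, q90} of TOF,
EXT and norm.EXT (= EXT/TOF per animal), plus var.TOF, var.EXT, cv.TOF,
cv.EXT, brood size n, and norm.n = n / animals sorted.  Quantiles use linear
interpolation (R type-7).  Single-animal wells get variance 0 by convention;
empty wells get n = 0 and missing distribution traits; non-positive TOF
records are invalid sorter events and are dropped.

Processing order is: (1) residuals of a one-way fixed-effect fit on assay
label (exactly each value minus its assay mean), (2) outlier removal, (3)
regression against the control condition.  The outlier rule drops values
beyond mean ± 2 SD — with mean and SD computed once on the input, not
iteratively — *unless* at least 5% of strains fall outside, in which case the
trait is treated as genuinely dispersed and everything is kept.  Control
regression returns residuals of the toxin-condition value on the same trait
in control; a zero-variance control degenerates to centering and is flagged.

## Trait reduction

Per condition, traits are scaled to mean 0, SD 1 and decomposed by SVD
(equivalently, eigendecomposition of the trait correlation matrix); the
number of retained components is the smallest k whose cumulative variance
fraction reaches 90%.  PC signs are fixed by making each component's
largest-magnitude loading positive — eigenvector signs are arbitrary and
determinism matters downstream.  Trait clustering uses distance
1 − |Pearson correlation| with complete linkage, cut into k groups matching
the retained PC count; |r| rather than r because a trait and its negation
carry the same information for a validation assay.  For a given PC, the
validation roster is the most-correlated trait plus its whole cluster.

## Linkage mapping

The association statistic is the marker-regression LOD,
LOD = −n·ln(1−r²)/(2·ln 10), algebraically (n/2)·log10(SST/SSE) of the
single-marker linear model; n is the per-marker complete-case count.  The
phenotype is standardized first, which provably changes nothing (the
statistic depends only on correlations) but matches the processing contract.
Monomorphic markers get LOD 0; r² is capped at 1 − 1e−12 so a perfectly
linked marker yields a large finite LOD.

Genome-wide 5% significance comes from 1,000 strain-label permutations.  One
permutation per replicate is applied jointly to all trait columns, preserving
the correlation structure among phenotypes; the threshold is the 95th
percentile of replicate maxima of the LOD curve, per trait.  A per-trait
independent permutation variant exists for sensitivity checks only.

The forward search iterates: scan the phenotype residualized on the accepted
cofactor markers; if the maximum LOD clears a permutation threshold
recomputed on those residuals, accept the peak (leftmost marker on ties) as
a new cofactor; stop otherwise or at a safety cap of 10 QTL.  Recomputing
the threshold each round is the default (a flag reuses the first threshold).
Confidence intervals extend contiguously from the peak over markers within
1.5 LOD of it, stopping at the first marker below and never leaving the
chromosome.  Variance explained per QTL is the squared correlation between
the peak-marker genotype and the original (unresidualized) trait.

The two-dimensional scan thins markers to a uniform cM grid (default 5 cM;
coarser grids trade resolution for speed) and, for each pair, compares the
full model {g_i, g_j, g_i·g_j} and the additive model {g_i, g_j} against the
null; LOD_interaction is their difference, i.e. the LOD of the product term
given both marginals.  Significance uses permutation maxima of
LOD_interaction.  The implementation precomputes per-pair Gram inverses so
each permutation costs only cross-products; the full model nests the
additive one, so LOD_full ≥ LOD_additive is enforced exactly.

## Heritability

Broad-sense: H² = (σ_R² − σ_P²)/σ_R², with σ_R² the phenotypic variance
among panel strains and σ_P² the variance among parental values.  The
default pools all parental replicate values of both parents — the literal
reading — which conflates the between-parent genetic difference with noise;
`broad_sense_h2_pooled_within` centers each parent first and is the variant
to use when the parents differ strongly.  Raw (unclamped) values are always
reported beside the [0, 1]-clamped estimate.

Variance components: y = μ + a + i + e with cov(a) = σ²_A·A,
cov(i) = σ²_I·(A∘A), cov(e) = σ²_E·I, where A is the genotype-correlation
relatedness matrix and A∘A its Hadamard square (PSD by the Schur product
theorem; the pairwise additive×additive epistasis kernel).  Estimation is
restricted maximum likelihood by quasi-Newton optimization of log-variances
(so negative components cannot occur; boundary estimates appear as
vanishingly small variances), from several starting points.  The
two-component fit additionally warm-starts from the one-component optimum
with a vanishing interaction variance, which guarantees the nested model's
likelihood is never lost to a local optimum.  At panel sizes of a few
hundred strains each likelihood evaluation is a dense Cholesky and the whole
fit takes about a second; no low-rank machinery is warranted.

## Hotspots

The genetic map is re-estimated from the panel itself: interval
cM = 100 × (fraction of strains switching between adjacent markers),
cumulative per chromosome, with no map-function correction — the panel's
switch fractions already embody the accumulated intercross recombination.
The genome is tiled per chromosome with half-open [start, end) bins of 26 cM
(terminal partial bins kept and flagged; bins never span chromosomes).  QTL
peaks are assigned to bins; λ = total QTL / total bins is computed exactly
and never rounded before taking the quantile; the hotspot rule is strict
count > q, where q is the smallest integer with Poisson CDF(q; λ) ≥ 0.99.
At the study scale of 82 QTL over 65 bins, λ = 1.2615 and q = 4.  Peak-in-bin
assignment drives hotspot detection; confidence-interval overlap (half-open
interval intersection) drives membership listings — two deliberately
separate semantics.

## Validation categorization

Strain comparisons use Tukey's honest significant difference on a one-way
ANOVA (phenotype ~ strain), significance at p < 0.05, with strains having a
single replicate excluded; a degenerate assay where every value is identical
yields p = 1 throughout.  Replicate counts come from the noncentral-t power
function of the two-sided two-sample t-test (smallest n per group reaching
80% power at α = 0.05, minimum 2), capped at 100 replicates — the practical
assay ceiling — with a flag when the cap binds.

The six-category NIL tree is evaluated in fixed order: (1) parents not
significantly different → *no parental difference*; (2) both introgression
lines recapitulate → *recapitulation*; (3) neither differs from its
background parent → *no QTL effect*; (4) both transgressive →
*bidirectional*; (5) exactly one transgressive while the other recapitulates
or is quiet → *unidirectional*; (6) *miscellaneous*.  Operational
definitions: a line *recapitulates* when it differs significantly from its
background parent, its median is shifted toward its introgression parent,
and it is *not* transgressive; it is *transgressive* when it differs
significantly from both parents and its median lies strictly outside the
closed interval of the parental medians.  Excluding transgressive lines from
recapitulation is a deliberate sharpening: a line beyond both parents is
evidence of additional loci, not of the planted one alone, and without the
exclusion the bidirectional branch would be unreachable.  The tree is total
and single-valued over the whole configuration space of significance
booleans and median orderings, and invariant under relabeling the parents
(with introgression labels swapped) — both property-tested.

The seven-category combined tree compares the NIL call with the
chromosome-substitution (CSS) call for the same trait: interaction only in
the CSS → *interchromosomal external*; the same interaction in both (same
uni/bi directionality and the same transgressive side — differing sides fall
to miscellaneous) → *interchromosomal internal*; interaction only in the
NIL → *intrachromosomal*; agreement on recapitulation or no-effect passes
through; parents non-significant in either assay, or opposite parental
direction across assays, voids the comparison.  Synergistic/antagonistic
direction tags are emitted but never used for category assignment — the
boundary case of a near-zero parental difference makes them ill-defined.

## Problem sizes and numerical choices

Simulation-backed checks run at the study's panel size (296 strains) with
1,000 permutations and 100 simulation seeds for forward-search and REML
recovery; the GWER calibration uses 500 null traits on a 10-cM marker grid,
and the pair-scan recovery uses a 20-cM grid with 30–40 seeds.  These sizes
give binomial standard errors comfortably inside the asserted bands while
keeping a full run to a few minutes on one core.  Degenerate inputs are
handled explicitly rather than by exception where a convention exists
(variance 0 for single observations, LOD 0 for monomorphic markers, centering
for zero-variance controls); everything else rejects loudly with a named
error.  All randomness flows through numpy Generators seeded from a single
SeedSequence, so identical seeds give bit-identical outputs, including the
full pipeline's TSV artifacts.

## Known limitations

The generator's Markov chain reproduces marginal two-point linkage but not
the exact breakpoint-count distribution of a finite-generation intercross;
inferences about interference are out of reach.  The REML additive kernel is
weakly identified against the residual when the panel is small and markers
few (A close to I), so single-trait component estimates are noisy even when
their 100-seed means are accurate.  Broad-sense heritability inherits the
literal parental-variance definition's bias when parents differ genetically.
The categorization trees consume medians and Tukey p-values only; replicate
structure within assays (plates within days) is assumed to have been removed
upstream by the assay regression.
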