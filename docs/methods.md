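# Methods

`recombreed` simulates a doubled-haploid (DH) genomic-selection (GS)
breeding programme in which the frequency and genomic distribution of
meiotic recombination can be manipulated, and measures how those
manipulations propagate into genetic variance, genetic gain, prediction
accuracy, and linkage statistics. This note documents the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Founder populations

**Synthetic founders.** `generate_founders` emulates a diverse panel of
fully inbred wheat accessions: by default 26 lines over 21 chromosomes
averaging 1.22 Morgans, with a requested number of biallelic SNPs per
chromosome, the major allele coded 1 and no monomorphic loci. Haplotypes
come from a per-founder latent Gaussian AR(1) field thresholded at a
per-locus cut giving minor-allele frequencies in (0.1, 0.5). The AR
coefficient controls how strongly neighbouring loci share allelic state
across founders, i.e. the balance of coupling vs repulsion phase. It is
tuned by bisection (at most 50 panel draws) until the realized fraction of
adjacent locus pairs whose minor alleles are negatively correlated across
founders matches a target (default 0.33, the baseline coupling excess of
the wheat panel this emulates: fewer than a third of adjacent random-QTL
pairs are in repulsion). The tuning is empirical rather than analytic
because only realized phase fractions are specified, not a generative
model.

The synthetic panel reproduces the *statistical* structure the analysis
needs — inbreeding, local linkage phase, a pericentromeric
low-recombination window, annotation enrichment, subgenome differences —
but not coalescent-grade population history: there is no deep population
structure, no allele-frequency spectrum skew beyond the uniform draw, no
outlier lines, and no missing data. Results on synthetic founders
therefore demonstrate the machinery and the direction of treatment
effects, not the magnitudes a particular real panel would give.

**Annotations.** `annotate_deleterious` flags loci as putatively
deleterious ("high impact" or "nonsynonymous coding", mutually exclusive
classes). The whole flag budget is first allocated between the 0.2-M
centromere-spanning window and the rest of the chromosome so that the
per-Morgan flag density inside the window exceeds the outside density by a
requested enrichment (default 3x), then split between classes
proportionally. Chromosomes labelled as the D subgenome (the last third,
by the wheat convention) receive 0.3x the flag counts, so the
deleterious-variant QTL capacity there is proportionally smaller (about
60 vs 200 at full scale). When the window holds too few SNPs the realized
enrichment saturates below the request; the defaults stay close to it.

**Biparental derivation.** `derive_biparental` selects the pair of
founders maximizing allele-sharing distance (brute force over all pairs),
keeps only loci polymorphic between them, and recodes the first parent's
allele as 1. The full-panel minor-allele designation is carried through
(`FounderSet.minor_code`) so linkage-phase statistics remain comparable;
in a biparental panel both alleles sit at frequency 0.5 and "minor" is
otherwise undefined.

**Real data.** `read_founders` accepts delimited text (loci as rows; id,
chromosome, position, then founder calls in {0,1,NA} or {A,B,NA}) and
applies, in order: drop loci with more than 60% missing calls or an
unknown chromosome; drop monomorphic loci; recode the major allele as 1;
fill remaining missing calls with the major allele. The fill is a
deliberate simplification of the stochastic imputation used on the
original data and is reported through the optional logger. Principal-
component outlier removal of founders is available behind a flag
(threshold on first-PC score, default 3 SD) and off by default.

## Meiosis

Crossovers are a stationary gamma renewal process on the four-strand
bundle with shape 2.63 and chiasma intensity 2 per Morgan, thinned by 1/2
per gamete — the standard process-level approximation to the Kosambi map
function. The two-point Kosambi relation r = tanh(2d)/2 is itself only a
map function with no exact multilocus process; the gamma model reproduces
it to within simulation error at distances up to ~0.5 M (verified in the
tests at 0.1 M: r = 0.0987 ± 0.01) while giving an expected crossover
count per gamete equal to map length in Morgans on any map, which is the
central lever of the map-scaling design. Stationarity is achieved by
starting the renewal 4 Morgans before the chromosome. No obligate
crossover is enforced (a pure renewal process can produce zero-crossover
gametes). Chromosomes assort independently.

**Map treatments.** `scale_map` implements three treatments: `WT`
(identity; scale forced to 1), `Chromosome` (every inter-locus distance
multiplied by the scale factor), and `Pericentromere` (only distance
inside the wildtype 0.2-M window multiplied; intervals straddling the
window boundary are split at the boundary and scaled piecewise, making
total-length arithmetic exact: a 1.22-M chromosome becomes 1.22 + 19x0.2
= 5.02 M under 20x pericentromere scaling and 24.4 M under 20x chromosome
scaling). Because expected crossovers equal map length, a 24.4-M
chromosome yields ~24 crossovers per gamete. Reports exist of 20x-scaled
breeding simulations realizing only 14–15 crossovers; this implementation
follows the literal map-size rule and makes no attempt to match such
saturated counts.

## Trait model

All effects are purely additive: g = Σ aᵢ·doseᵢ with dose the count of
the allele coded 1. Effect magnitudes are |N(0,1)| draws; the magnitude
pipeline is shared across sign scenarios so that only linkage phase
differs. Five sign scenarios set the coupling/repulsion conditions:
(1) all positive; (2) positive with probability 2/3; (3) 1/2; (5) 1/3
(genome-wide Bernoulli draws — the choice between genome-wide and
per-chromosome stratification is open in the source description; genome-
wide is implemented); (4) strict alternation of signs along map order,
continuing across chromosome boundaries, first sign drawn once per
replicate — exactly half positive for even QTL counts.

Effects are rescaled so the reference population has additive variance
exactly 1 (division by √varA; idempotent and scale-invariant). This is
done twice: on the founder panel at setup and on the training population
at the end of burn-in. The phenotype error variance is frozen at
standardization time as σ²ₑ = (1−H²)/H² (varA = 1) and held constant
through GS, so realized heritability drifts downward as variance erodes
— matching the behaviour of the stochastic simulator this design mirrors.
Heritability is H² ∈ {0.2, 0.8} by default.

The marker panel (`sample_snpchip`) draws up to a fixed number of SNPs
per 1-cM bin (default 10 per bin ≈ 1200 markers on a 1.22-M chromosome);
co-located picks are separated by a 0.00001-M jitter at map construction.
QTL are drawn per chromosome from non-marker loci, either uniformly (R)
or from the deleterious-variant candidate pool (DV). The DV pool is
re-drawn each replicate as exactly round(0.9 x n_high) high-impact plus
round(0.25 x n_nonsynonymous) nonsynonymous loci (round half-up, so pool
sizes are reproducible). Marker/QTL disjointness is enforced at
assignment.

## Genomic prediction

`fit_rrblup` solves the ridge system u = (Z'Z + λI)⁻¹Z'(y − ȳ) with Z
the column-centred predictor doses and λ = σ²ₑ/σ²ₘ estimated by REML
each refit (the model is refit from scratch every cycle). The REML
profile in λ needs only the eigenvalues of the centred Gram matrix; the
implementation eigendecomposes whichever of ZZ' (n-side) or Z'Z (m-side)
is smaller and handles the zero-eigenvalue bulk in closed form, so both
genome-wide panels (m ≈ thousands) and causal-variant panels (m = QTL
count) are cheap. If the one-dimensional optimisation fails, λ falls
back to m(1−h²)/h². A single grand-mean intercept is the only fixed
effect. Candidates are centred by the training-population column means
(no leakage). Monomorphic predictors carry zero effect by construction;
no frequency filtering is applied.

The predictor set distinguishes the two relationship-matrix conditions:
`GW` uses the marker panel (subject to marker–QTL linkage
disequilibrium, which decays as maps grow), `CV` uses the causal variants
themselves (the perfect-LD benchmark).

## Breeding scheme

Burn-in: 10 cycles (full-founder mode) of 400 random crosses among the
current parents — the very first among the founders — each cross giving
one F1 and one DH; phenotypic selection advances the top 80 DHs (20%);
in the final cycle all 400 DHs become the training population (TP).
Biparental mode burns in for a single unselected cycle. Parent pairs are
drawn uniformly with replacement across crosses, selfing excluded.

GS cycles: the TP is also the cycle-0 candidate population. Each cycle
fits RRBLUP on the TP, predicts the 400 DH candidates, advances the
top 20 (5%) as parents, phenotypes the top 160 (40%) into the TP, and
drops the 80 lowest-EBV TP members (EBVs re-predicted for the whole TP
under the current model, since TP pruning follows the model update). The
TP therefore grows by a net 80 per cycle: 400, 480, …, 1200 at cycle 10.
The source description of the drop rule is internally inconsistent
("bottom 20% of the updated TP" vs a stated cycle-10 TP of 1200; the
literal 20% rule converges to 640); the 1200 endpoint is treated as
authoritative and the literal rule kept behind `SimConfig.tp_rule =
"literal20"`. The 160 phenotyped DHs include the 20 selected parents
(overlapping truncations). All truncation selections break ties by
position order, for determinism. The map treatment is applied once, at
GS start.

Each replicate emits 11 records (cycle 0 = post-burn-in baseline plus 10
GS cycles) with: additive variance of the 400 candidates' true genetic
values (population variance, divisor n — a population parameter, not an
estimate); genic variance Σ2pᵢqᵢaᵢ² (the Hardy–Weinberg/linkage-
equilibrium expectation, applied as-is to inbred populations to mirror
the convention of the simulator this follows — a fully inbred population
at linkage equilibrium therefore shows varA = 2 x genic); the Bulmer
ratio varA/(2·genicVar), 1 at linkage equilibrium and below 1 under
repulsion-generated negative LD; genetic gain (mean genetic value minus
the cycle-1 mean, so gain(1) = 0); prediction accuracy (Pearson
correlation of EBV with true genetic values; undefined correlations are
reported missing, not zero); QTL fixation fractions by |effect| tercile
(remainders assigned to the lower terciles, so 200 QTL split 67/67/66;
fixations are also split by whether the fixed allele is favorable); and
mean favorable-allele frequency change per tercile (negative values
expose hitchhiking of unfavorable alleles). Allele frequencies are
computed from genotype doses over individuals.

## Factorial experiment and statistics

The canonical design crosses founder mode {full, biparental} x QTL per
chromosome {2, 200} x H² {0.2, 0.8} x scale {2, 20} x map type {WT,
Pericentromere, Chromosome} x QTL type {R, DV} x scenario {1..5; 3–4 in
biparental} x predictor {GW, CV}: 672 cells, of which the 96
biparental x DV cells are not evaluable (a biparental panel loses most
annotated polymorphic sites) and are logged and skipped by the runner.
Replicate seeds derive deterministically from the base seed and the cell,
so results are identical regardless of scheduling; completed cells are
skipped on resume.

`variance_decomposition` fits response ~ (all main effects)² + replicate
block by ordinary least squares and reports each term's share of total
sum of squares (Type-II, which under the balanced design is the
orthogonal decomposition and coincides with treating replicate as a
random intercept). Rank-deficient designs raise an error listing aliased
terms. `marginal_means` averages cell means with equal weight over the
balanced grid of the other factors, with optional conditioning subsets.
Post-hoc Tukey-corrected pairwise contrasts are out of scope; level means
can be compared with the `percent_difference` helper, which is not a
multiple-testing-corrected procedure.

## Reduced desk scale

The pre-configured studies in `recombreed.studies` run at a reduced
scale chosen once for desk verification: 26 founders, 5 chromosomes of
~1.22 M with 600 SNPs each, ~240 markers per chromosome, 40 QTL per
chromosome standing in for the polygenic (200) architecture, scenario 4,
H² = 0.8, 20 replicates. At this scale a replicate runs in seconds and
the directional treatment effects are measurable: 20x maps retain more
candidate variance than WT through the GS cycles, genome-wide prediction
accuracy is lower under 20x maps, oligogenic (2-QTL) architectures fix
sooner — often completely during burn-in, which the study records as
terminal fixation rather than discarding the replicate — and the
repulsion scenario shows a stronger Bulmer effect than the coupling
scenario. Because the genome is ~4x shorter than full scale, diversity
exhausts faster: by cycle 10 both map treatments approach fixation and
the WT arm's variance distribution becomes strongly skewed — mostly zero,
with occasional stalled replicates that retain variance without gain.
At that terminal point the replicate *mean* of WT variance can exceed the
20x mean even though the median and the large majority of paired
replicates favor 20x, as every earlier cycle does; cycle-10 variance
means at this scale are therefore not a reliable readout of the
treatment effect, while mid-cycle variances, gains, accuracies and
fixation rates are. Full-scale magnitudes (e.g. marginal-
mean percent differences between map types) require the real founder
panel and the complete 100-replicate factorial, for which the
`run_grid`/CLI harness is provided but not executed here.

## Numerical choices

- Population variance uses divisor n throughout.
- Standardization raises an error when varA ≤ 1e−12 (fixed up to noise).
- REML searches log₁₀λ in [−8, 8] with a bounded scalar optimiser.
- Co-located map positions are jittered by 0.00001 M; map I/O accepts
  Morgans or centiMorgans and stores Morgans.
- Gamma-renewal burn-in of 4 M before the chromosome start; crossover
  buffers are extended on the rare draws that fail to cover the map.
- Ties in truncation selection break by position (stable argsort).
- Seeds everywhere are integers below 2³¹; every stochastic routine
  takes a `numpy.random.Generator` or an explicit seed.
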