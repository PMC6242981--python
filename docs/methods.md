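# Methods

This package re-implements, as a tested pipeline over synthetic data, the
population-genetic computations behind a study of a Mendelian bill-size
polymorphism in the black-bellied seedcracker (*Pyrenestes ostrinus*): the
age of the dominant "large-bill" haplotype is estimated by rejection ABC
over structured-coalescent simulations conditioned on forward-simulated
allele-frequency trajectories under heterozygote advantage, and the
surrounding candidate-region analyses (Δ-based region bounding,
gene-length-weighted private-allele enrichment, shared-polymorphism density
scanning, haplotype/phenotype association) are provided as reusable
operations.

## The balanced-polymorphism model

A diallelic autosomal locus controls bill size; the derived allele is
dominant for the large-billed phenotype and is maintained as a balanced
polymorphism. We model balancing selection as overdominance with
heterozygote fitness 1, ancestral-homozygote fitness `1 - s2`, and
derived-homozygote fitness `1 - s1`. The model is parameterized by

- `S = 4 Ne s2`, the scaled heterozygous selection coefficient (the
  heterozygote's advantage over the ancestral homozygote), uniform prior
  50–1000;
- `f_eq`, the deterministic equilibrium frequency of the derived allele,
  uniform prior 0.2–0.8. Given `(S, f_eq)` the second penalty is implied:
  `s1 = s2 (1 - f_eq)/f_eq`, so `s2/(s1 + s2) = f_eq`;
- `T_age`, the allele age in coalescent units of `4 Ne` generations,
  uniform prior 0–5.

This reading of "scaled heterozygous selection coefficient" (4N-scaled, the
het-vs-ancestral-homozygote contrast, with the second homozygote pinned by
`f_eq`) makes `(S, f_eq)` a complete, orthogonal parameterization in the
style of msms's 4N-scaled selection arguments; the alternative 2N scaling
would simply relabel the prior.

### Trajectories

Trajectories run forward from a single copy `round(T_age * 4 * N_sim)`
generations before the present: each generation applies the deterministic
selection update `p' = p (p w_DD + q w_Dd) / w-bar` followed by binomial
resampling of `2 N_sim` allele copies. Paths that hit loss or fixation are
rejected and restarted (the count is recorded; a configurable budget,
default 5000, turns a loss-dominated corner of the prior into an explicit
error). Returned paths therefore segregate at every generation. Trajectories
are not conditioned on any particular present-day frequency — only on
segregation — since the sample's class configuration is conditioned on in
the coalescent stage instead.

`N_sim` (default 5000) is a rescaled simulation size: selection (`s2 =
S/(4 N_sim)`) and mutation (`mu_sim = theta/(4 N_sim)`) are scaled through
it, so summary statistics are invariant to the choice up to Monte-Carlo
error; the test suite checks this invariance at `N_sim` 2000 vs 8000.

### Structured coalescent conditional on a trajectory

Backward in time on the trajectory's own generation grid, the sampled
lineages are partitioned into the derived and ancestral allelic classes.
With `k` lineages in a class whose frequency is `x(t)`, each pair coalesces
in generation `t` with probability `1/(2 N_sim x(t))` (ancestral class:
`1 - x(t)`); there is no migration between classes while the allele
segregates, reflecting the locus's suppressed recombination. At the origin
generation the derived class holds a single copy, so all remaining derived
lineages merge there and the survivor joins the ancestral class; older than
the origin a standard single-class discrete coalescent runs to the root.

Event times are sampled exactly on the discrete grid: the next coalescence
is the first generation at which the accumulated hazard
`sum_t C(k,2) * (-log(1 - p_t))` crosses an Exp(1) draw — distributionally
identical to per-generation Bernoulli trials with success probability
`1 - (1 - p_t)^C(k,2)` but located by binary search on precomputed
cumulative hazards instead of a per-generation sweep. One pair merges per
event; near the origin the per-generation hazard is effectively infinite
(probabilities are clamped at `1 - 1e-12` for the log), so the forced
behaviour emerges naturally and the origin merge is additionally explicit.

Mutations follow the infinite-sites model: each branch receives
Poisson(branch length in generations × `theta L / (4 N_sim)`) mutations at
fresh uniform positions in `[1, L]`; mutations above the root are ignored.
The Kingman limit of the whole machinery (no derived lineages) is tested
against closed forms (`E[T2] = 2N`, `E[pi] = theta_locus`,
`E[S] = theta_locus * a_n`, the neutral site-frequency spectrum) and, as an
integration oracle, against msprime at identical parameters.

### Summary statistics and the ABC step

The three statistics are per-bp nucleotide diversity within the ancestral
class, within the derived class, and the average between-class divergence
(`d_xy`). The empirical sample configuration is 20 ancestral and 10 derived
haplotypes (the homozygous small- and large-billed birds) over the ~286 kb
non-recombining interval at `theta = 0.001/bp`.

Rejection ABC draws parameters from the priors, simulates one sample per
draw, and retains the `n_accept` draws (default 200, after 200,000 draws at
study scale; 20,000 at desk scale) with the smallest Euclidean distance to
the observed statistics. The raw (unstandardized) Euclidean distance is the
default; a variant dividing each statistic by its reference-table standard
deviation is provided (`normalized_euclidean`), standard ABC practice that
matters when `d_xy`'s scale dominates the two diversities. Posterior modes
are the argmax of a Gaussian KDE (Silverman bandwidth, fixed for
reproducibility) on a 512-point grid over the prior support; a degenerate
accepted sample returns its common value with a warning. Failed simulations
are dropped rather than resampled (the acceptance count is unchanged),
keeping the reference table i.i.d. from the prior restricted to feasible
parameters; more than 10% failures aborts.

Scaling to natural units uses the plug-in Watterson estimate of theta
(computed on the observed ancestral class; the package exposes the choice),
an unscaled mutation rate `mu = 2.2e-9` per bp per generation and a
5-year generation time: `Ne = theta/(4 mu)` (0.001/bp gives 113,636,
reported as 114,000), `generations = T_age * 4 * Ne`,
`years = generations * g`.

### Desk-scale recovery check

The acceptance-level check runs the full ABC at truth
`(S = 500, f_eq = 0.5, T_age = 2.0)` on a 30 kb locus with the locus-wide
mutation input preserved (`theta = 286/30000` per bp, matching
`0.001 x 285,969`), 20,000 simulations, 200 accepted, `N_sim = 5000`,
repeated over ten seeds. The pseudo-observed statistics are the Monte-Carlo
expectation over 100 replicates at the true parameters: a single
non-recombining locus yields one genealogy, and the genealogical noise in
one draw of `pi_anc` alone (coefficient of variation near 0.5) would make
any point-recovery check a test of luck rather than of the inference
machinery. The posterior-mode tolerance (±0.10 on `f_eq`, ±0.75 on
`T_age`, met in ≥8/10 repetitions, with posterior variance below prior
variance throughout) then genuinely measures calibration of the simulator,
distance and density estimation. The width of a single-locus posterior —
visible in the accepted-sample spread — is the honest statement of
real-data precision.

## Candidate-region analyses

**Δ scan and region bounding.** Δ is the absolute difference in
reference-allele frequency between two pools; sites pass at Δ ≥ 0.9 after
depth filtering (per-pool total depth in [10, 40]; minor-allele count ≥ 2
summed over the two pools compared — a per-pool minor count would discard
every fixed difference, i.e. exactly the Δ = 1 sites of interest). Passing
sites are clustered with a 100 kb gap rule (the clustering rule is not
dictated by the outcome it emulates, so it is exposed in the API); the
cluster with most sites (ties to the smaller span) gives the region, whose
span is `end - start` — the convention forced by the printed arithmetic
(55,371,638 - 55,070,008 = 301,630; 55,470,638 - 54,971,008 = 499,630;
55,386,717 - 55,067,422 = 319,295 ≈ 319.3 Kb).

**Inversion screen.** Polymorphisms shared by both allelic classes are
located, and their density is computed with a rectangular kernel of
half-width 1.5 kb on a 100 bp grid ("bandwidth" is read as half-width, the
R `density` convention the original analysis used; the full-width reading
is a parameter away). Depleted runs — density below 0.25× the flank median
for ≥ 10 kb, where the flanks are the outer 15% of the scanned extent on
each side — are reported as candidate suppressed-recombination intervals.
The extent is expected to include flanking sequence precisely so the flanks
calibrate the freely recombining background. Only the variant-level scan is
implemented; read-pair orientation screening is out of scope.

**Private-allele enrichment.** Sites fixed in the focal (mega) pool for an
allele absent from the other pools are assigned to genes (BED half-open
intervals; a 1-based position `p` is in-gene when `start < p <= end`). The
null redistributes the `M` in-gene alleles across genes with probability
proportional to gene length, 10,000 replicates; `p` is the fraction of
replicates strictly exceeding the observed count, exactly as printed (a
conservative `(1 + #{>=})/(1 + B)` variant is available). Under this null
each gene's count is marginally Binomial(M, length share), which the tests
exploit as an exact oracle. Only in-gene alleles are redistributed;
intergenic alleles are counted but excluded from the null. Redistributing
alleles length-proportionally is the reading of "draws with replacement of
genes, weighted by total length" that actually yields a per-gene null count
distribution; resampling whole genes would not.

**Haplotype statistics.** Observed heterozygosity uses 200-SNP windows with
a 100-SNP step over the SNP index (trailing partial window kept and
flagged). Mismatch fractions divide by the number of assayed SNP sites
(the "% mismatches" convention on SNP panels), while per-bp diversities
divide by the locus length. The haplotype-dosage association regresses the
quantitative trait (lower mandible width, LMW, in mm) on derived-haplotype
copy number (0/1/2) by OLS, reporting beta, its standard error, Wald
`T = beta/SE`, `R^2`, and the two-sided p from the t distribution on n-2
degrees of freedom.

## The synthetic-data generator

The generator produces truth-known datasets with the structure the
analyses assume; passing tests demonstrate that each analysis recovers what
was planted under that structure, not that real data meet the structure.

- **Haplotype panel**: two founder haplotypes differing at
  `ceil(divergence * L)` sites (divergence 1.0 emulates the fully divergent
  A/I haplotypes); members are founder copies with independent per-site
  flips at rate `intra_diversity` (0.045 gives ~9% within-class
  mismatches); recombinants are single-breakpoint mosaics with the
  breakpoint recorded (multiple breakpoints are out of scope — few events
  were observed). An option places the two classes' flips on disjoint site
  halves (rate doubled to preserve mismatch levels), emulating
  infinite-sites private variation so that a non-recombining interior
  shares no polymorphisms between classes; the freely recombining flanks
  use the default shared-site mode with divergence 0.
- **Cohort**: small birds carry two ancestral-class haplotypes; large birds
  at least one derived-class haplotype, alternating heterozygous and
  homozygous so both genotypes occur; mega birds are homozygous derived
  (their real architecture is more complex; for these analyses only the
  homozygous-derived property is used). LMW is Normal(morph mean, sd) with
  morph means 12.8/16.4/19.6 mm; the within-morph sd is not reported
  empirically and defaults to 0.5 mm as a plausible within-class spread
  relative to the ~3.5 mm between-morph gaps. Heterozygous large birds get
  a −0.5 mm offset, emulating the observed incomplete dominance.
- **Pool table**: background sites draw a shared per-site frequency
  (uniform 0.05–0.95, or fixed) plus binomial sequencing noise at the
  pool's read depth (uniform in [10, 40]); candidate-interval sites have
  exact `|freq_small - freq_large| = delta_in_region` with the first and
  last site pinned to the interval boundaries, so exact recovery is
  well-defined; optional private sites are clean fixed differences for the
  focal pool.
- **Gene annotation**: non-overlapping intervals with uniform lengths,
  placed by randomly spreading the free space.

Coordinates follow the field's conventions throughout: VCF/TSV positions
1-based, BED half-open with 0-based starts, spans `end - start`. One
integer seed drives everything; each operation derives a child stream from
(seed, operation name), so outputs are byte-reproducible and insertion of
new operations does not disturb existing streams.

What the generator does not emulate: linkage maps and recombination within
the locus interior, read-level error, missing genotypes, population
structure beyond one random-mating deme, sex chromosomes, and selective
sweeps. Analyses whose empirical values depend on genome-scale real data
(window counts, F_ST medians, sweep calls) are correspondingly out of
scope; their in-package counterparts are checked by construction-based
oracles instead.

## Numerical and performance notes

- The Wright-Fisher generation loop is JIT-compiled (numba). Binomial
  variates come from Hörmann's BTRS transformed-rejection sampler (exact;
  validated against scipy's binomial pmf by chi-square in the suite) over a
  xoshiro256++ stream seeded via splitmix64; the BTRS setup logs/lgammas
  are deferred to the rare non-squeeze branch. This makes the ~10^9
  generation steps of a desk-scale ABC run tractable on one core.
- Cumulative coalescence hazards are accumulated in the same kernel;
  `-log(1-p)` uses a 3-term series below 0.01 (absolute error < 3e-11).
- Problem sizes: reference tables default to 20,000 simulations at desk
  scale (the study-scale 200,000 is a parameter); the Kingman oracle uses
  2,000 replicates; the analysis scripts default to 5,000 ABC simulations.
- Ties in rejection sampling break by draw index (stable argsort);
  KDE bandwidth is Silverman's rule; degenerate inputs (zero dosage
  variance, empty groups, zero-length extents, infeasible gene packing,
  non-overdominant fitnesses, too-strong selection for the chosen `N_sim`)
  raise explicit errors.

## Known limitations

- Simultaneous multi-mergers within one generation are approximated by
  sequential binary merges at the same generation (a small-`N_sim`
  discreteness artifact that vanishes under rescaling).
- The trajectory's quasi-stationary fluctuations are simulated, but the
  coalescent uses the single realized path; parameter uncertainty from
  trajectory-to-trajectory variation is therefore part of the ABC noise,
  as intended, not marginalized analytically.
- `watterson_theta` assumes complete data; the empirical pipeline's
  missingness filtering happens upstream.
- The enrichment p-values are reported raw, per gene, as in the original
  analysis; no multiple-testing correction is applied.
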