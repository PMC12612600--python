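# Methods

## The model

Observations are measurements on ramets (grafted copies) of clones planted
on row/column grids at one or two sites. The univariate model is

    y = X beta + Z u + e

with fixed effects for the overall mean, site, and population-within-site
(populations are the seed-stand origins of the clones; levels observed only
once are merged into a catch-all level to keep X estimable, and redundant
columns are dropped by pivoted QR). The clonal effects u are nested within
site with covariance

    G = Sigma_a (x) K,

where Sigma_a is the SxS matrix of per-site genetic variances and the
cross-site covariance, and K is the Yang et al. genomic relationship matrix
computed from filtered SNP dosages (missing dosages imputed to 2p per SNP;
near-fixed SNPs excluded by a frequency guard of 0.005; a jitter of at most
the deficit to 1e-6 .. 1e-4 is added to the diagonal only when K is not
positive definite, and the flag is recorded). Because ramets of a clone are
genetically identical, the "genetic variance" here is the total genotypic
variance, hence broad-sense heritability.

Residuals are independent across sites; within a site they follow the
separable spatial structure standard in field-trial analysis,

    R_s = sigma_xi^2 AR1(rho_col) (x) AR1(rho_row) + sigma_eta^2 I,

evaluated at the occupied grid cells (empty cells — mortality, roads — enter
only through the grid distances of the occupied cells). The nugget is never
dropped; the spatial variance may collapse to zero.

The bivariate model stacks two responses (two traits, or one trait measured
in two years) with G = Sigma_a (x) K over (trait, clone) effects and
R = Sigma_e (x) I across co-observed ramets; ramets observed for only one
response contribute an independent residual with that trait's variance, so
partially overlapping designs are handled without imputation.

## REML evaluation and optimization

The restricted log-likelihood

    l_R = -1/2 [ (n - p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

is evaluated exactly through the mixed-model-equations identity
log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C| and
y'Py = y'R^-1 y - b'C^-1 b, where C is the MME coefficient matrix. This
keeps every factorization at the size of the effect vector (a few hundred)
instead of the data vector, and gives BLUPs of the clonal effects for free
from the same solve. Per-site residual blocks are factorized densely each
evaluation (sites have at most a few hundred ramets); the bivariate
Sigma_e (x) I inverse is analytic. The test suite verifies the evaluation
against a naive dense from-definition implementation to 1e-8 on randomized
instances.

Free parameters are optimized on a transformed scale — log variances,
correlations and AR1 coefficients through tanh — with a bounded
quasi-Newton method (L-BFGS-B), the response standardized to unit variance
internally for conditioning. We chose a generic bounded optimizer over
classical average-information update iterations because it is robust near
boundaries at these problem sizes and the two approaches maximize the same
criterion; the average-information matrix

    AI_ij = 1/2 (Py)' dV/dtheta_i P dV/dtheta_j (Py)

is still computed at the optimum (derivatives of V by central differences on
the small structured factors) and its inverse is the parameter covariance
used for all standard errors. Starting values come from an OLS pre-fit:
half the residual variance each to the spatial and nugget components, half
the clone-mean variance to the genetic variance, AR1 rho at 0.1.

Parameters within 0.5 (transformed scale) of a bound are treated as pinned:
the remaining parameters are re-polished with the pinned ones fixed, the
boundary flag is set, and no SE is reported for any estimate involving a
pinned parameter (correlations pinned at |r| = 1 are reported as +/-1 with
SE = NA).

## Inference

Variance components are tested by likelihood-ratio tests against the model
with the component fixed at zero. A single variance tested on the boundary
uses the 1/2 chi2_0 + 1/2 chi2_1 mixture; a covariance fixed at zero (an
interior point) uses chi2_1. The empirical size of the boundary-mixture test
under the null is checked by simulation in the test suite (500 replicates;
size within [0.03, 0.08] at nominal 0.05). When the full fit itself
converges at a boundary the chi-square reference is invalid and no p-value
is reported.

Broad-sense heritability is H^2 = sigma_g^2 / sigma_p^2 with
sigma_p^2 = sigma_g^2 + sigma_xi^2 + sigma_eta^2 by default — the spatially
structured residual is environment and belongs in the phenotypic variance; a
switch exposes the nugget-only alternative. The pooled two-site H^2 is the
ramet-count-weighted mean of the per-site H^2 from the joint fit (the joint
fit shares the genetic covariance, which is what shrinks the pooled SE);
a constrained common-variance model would be the alternative reading.
SEs of H^2 and of genetic correlations are delta-method transforms of the
inverse AI matrix.

Type B correlation: r_B = cov_a(S1,S2) / sqrt(var_a(S1) var_a(S2)) from the
two-site fit. Type A and year-to-year correlations come from the bivariate
fit (year-to-year is the same machinery with "trait" = year). Per-wavelength
scans fit one model per band independently and report per-band significance
without multiple-testing correction by default (a Bonferroni option exists);
failed bands are recorded with the failure reason rather than dropped.

## The synthetic generator

The generator draws from exactly the process the models assume: clonal
values from Sigma_a (x) K with K the realized Yang GRM of simulated array
SNPs, spatial fields drawn exactly via the Kronecker Cholesky square root of
the AR1 matrices on the full grid and then subset to occupied cells, an
independent nugget, and fixed site/population effects. Genotypes use
Beta(1.5, 1.5) allele frequencies mapped onto (0.02, 0.5) (array-ascertained
SNPs are intermediate-frequency and polymorphic), two populations perturbed
by a Balding-Nichols model at Fst = 0.02, and optional half-sib clone pairs
(shared parental haplotype) for the weak relatedness found among plus trees
from neighboring stands — off by default. Spectral phenotypes draw clone x
band genetic values from K (x) C with C a squared-exponential cross-band
correlation (bandwidth in nm; infinite bandwidth = one shared signal), plus
an independent per-band nugget.

Default conditions mirror the orchards the models were built for: a
Nepomuk-like site (31 clones, 200 ramets, 15x15 grid), a Plasy-like site
(29 clones, 148 ramets, 13x13), 24 clones shared between sites, 5,000 SNPs,
unit total phenotypic variance split as sigma_xi^2 = 0.20 with
rho_row = rho_col = 0.4 and the nugget absorbing the remainder after the
genetic fraction. The 0.4/0.20 spatial settings are a moderate field-trial
autocorrelation chosen once; recovery results are not sensitive to them at
these scales.

What the generator does **not** emulate: linkage disequilibrium and any
sequence-level structure, pedigree beyond optional half-sib pairs,
radiative-transfer realism in spectra (band means are an arbitrary smooth
profile; only the covariance structure matters for the genetic analyses),
measurement-protocol artifacts (detector splices, illumination drift), and
non-Gaussian trait distributions. Passing recovery tests therefore shows
the estimators are correct under the assumed model at field scale — not that
the model is adequate for any particular real orchard.

## Validation scales and numerical choices

Parameter-recovery checks use 30 replicates per scenario at the field
dimensions above (~20 s to ~3 min per scenario on one CPU); the LRT
calibration uses 500 replicates of a 100-ramet / 25-clone nugget-only
design, since the mixture reference does not depend on the residual
structure. Replicate seeds derive from one master seed through spawned
`numpy` SeedSequence streams, so every result is reproducible from a single
integer.

Numerical details worth knowing: optimizer bounds are log-variance in
[-15, 6] on the standardized scale and |atanh r| <= 7; convergence uses the
optimizer's function-value tolerance (1e-12 standardized); monomorphic SNPs
get HWE p = 1 by convention; an all-missing SNP has undefined frequency
(flagged, never silently zero); clonal rankings break BLUP ties by clone
identifier; the canopy pair-averaging convention (band i <- mean(i, i+1),
last band kept) is the one consistent with 269 - 13 - 36 = 220 analysis
bands; needle reflectance is sample/white-reference radiance; pigment
absorbances are blank-corrected by the 750 nm reading before the Wellburn
DMF equations.

## Known limitations

* One or two sites (and two traits/years) — the Kronecker structures are
  2x2 at most; factor-analytic multi-environment models are out of scope.
* No dominance/epistatic relationship matrices and no pedigree A matrix.
* Per-band scans refit each band independently; no smoothing or borrowing
  of strength across wavelengths.
* The AI matrix is computed densely at the optimum; fine up to a few
  thousand observations, not intended for much larger trials.
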