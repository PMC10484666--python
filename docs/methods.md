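# Methods

## Competition equilibrium

The core model treats one protein pool competing for two RNA species,
each a single independent 1:1 site (the KH34 di-domain's two sub-sites
are not modelled separately). Free protein is the unique root of the
monotone mass balance

    g(P) = P + Σᵢ [L]t,i · P/(K_D,i + P) − [P]t

on [0, [P]t]; g is strictly increasing (g′ ≥ 1), g(0) = −[P]t and
g([P]t) ≥ 0, so existence and uniqueness are structural, not numerical.
`free_protein_cubic` expands g into the cubic, takes the real root
inside the physical bracket via `numpy.roots`, and polishes it with
Newton steps on g until |g| < 1e−12·max(1, [P]t); the polish removes
the ill-conditioning of widely separated K_Ds. `free_protein_oracle`
is a deliberately naive bisection on the same bracket and is kept
independent of the cubic route so the two can cross-check each other
(they agree to better than 1e−8 relative over randomized systems).

Degenerate inputs return exact limits rather than errors: zero protein
gives zero free protein, zero RNA gives free = total, and a species
with zero total has bound fraction defined as 0.

Units are nanomolar internally; the CLI converts pM/nM/µM/mM/M on
input. Grids must be strictly increasing; both a free-protein axis
(fractions evaluated directly, RNA totals irrelevant) and a
total-protein axis (free protein solved per grid point, so RNA can
deplete the pool) are supported.

### The discrimination window

At fixed free protein the methylated/unmethylated bound-fraction ratio
is (K_D^RNA + P)/(K_D^meRNA + P): it starts at the K_D ratio (5.65 for
20.9/3.7 nM), passes 2.98 at 5 nM and 1.60 at 25 nM, and decays to 1.
This is the quantitative content of "discrimination needs a poised
protein concentration".

### RNA-concentration independence, quantified

On a free-protein axis the bound fraction is independent of RNA total
by construction. On a total-protein axis the statement needs
qualification, and the package asserts exactly what the model gives:
RNA totals well below K_D (0.04 vs 0.4 nM at K_D 3.7 nM) produce curves
within 0.02 of each other everywhere above 1 nM protein, but a 4 nM RNA
total depletes a low-nanomolar protein pool appreciably — the 0.04-vs-4
nM difference peaks at 0.128 near 3 nM total protein and only falls
below 0.05 once total protein exceeds the largest RNA total by roughly
threefold (≥ 13 nM). "Virtually identical" is therefore an accurate
description either on the free-protein axis or at protein
concentrations comfortably above the RNA pool, and the tests encode
both regimes explicitly.

## Biosensor kinetics

Ideal 1:1 Langmuir kinetics without mass-transport limitation or
baseline drift (traces are assumed reference-subtracted): association
R(t) = Req·(1 − e^(−k_obs t)) with k_obs = k_on·C + k_off and
Req = Rmax·C/(C + K_D); dissociation R(t) = R0·e^(−k_off t).

Fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`)
with data-driven starting values: plateau from the last response,
k_obs from the reciprocal of the time at half-plateau. Traces shorter
than 5 points, flat traces and rising "dissociation" traces raise
fitting errors carrying diagnostics. k_on is the OLS slope of k_obs vs
concentration (≥ 3 points); the intercept is a secondary k_off
estimate, but the reported k_off always comes from the single-curve
dissociation fit, and K_D = k_off/k_on. Replicate k_obs values at one
concentration are averaged after fitting each trace individually.

Fold changes between conditions a and b are lifetime_fold =
k_off,a/k_off,b, affinity_fold = K_D,a/K_D,b and kon_fold =
k_on,a/k_on,b, chosen so lifetime_fold = affinity_fold × kon_fold is an
algebraic identity (K_D = k_off/k_on makes any other orientation of the
k_on ratio inconsistent).

Simulation defaults emulate the study conditions: a 5–320 nM doubling
series, triplicates, additive Gaussian noise at 1% of Rmax, 600 s
association and 3600 s dissociation windows sampled at 1 s. The
scenario truth uses equal k_on (1e−4 nM⁻¹s⁻¹ = 1e5 M⁻¹s⁻¹, a typical
protein–RNA association rate) and an 8-fold k_off contrast
(2e−3 vs 2.5e−4 s⁻¹), giving K_Ds of 20 and 2.5 nM that bracket the
measured Zipcode affinities. These magnitudes are realism defaults,
not measured values.

## Chemical-shift perturbations

CSP = √(ΔδH² + (0.15·ΔδN)²) per residue present and unflagged in both
tables; overlapped residues are excluded, missing residues dropped
pairwise, never imputed. The top-n summary (default n = 11,
configurable) reports a weighted mean ± weighted SD with ties broken by
residue id; weighting is uniform by default (reducing to the plain mean
and population SD) with a magnitude-weighted option, since no single
convention is universal. Condition comparison is the homoscedastic
(pooled-variance) two-sample t-test, hand-implemented and
oracle-checked against `scipy.stats.ttest_ind(equal_var=True)`.
Annotation: `**` for p ≤ 0.005, `*` for 0.005 < p ≤ 0.05, `ns`
otherwise — the double-star band is anchored at the smaller p, the only
self-consistent ordering of the two thresholds.

Titrations are emulated in the fast-exchange limit: one
population-averaged peak per residue moving linearly with the bound
protein fraction, which comes from the exact ligand-depletion
quadratic f = ((P+L+K_D) − √((P+L+K_D)² − 4PL))/(2P) (limit L/(L+K_D)
returned at P = 0). Defaults: 80 µM protein, RNA at 0.5/1/2/4/8
equivalents. Intermediate-exchange line broadening is out of scope, so
simulated titrations always show clean trackable peaks — real
weak-to-intermediate systems may not.

## Genomic summaries

BED 0-based half-open coordinates throughout; single-nucleotide
cross-links are width-1 intervals; the BED score column carries
cross-link counts. Replicate merging sums counts at identical
(chrom, start, end, strand). Intersection uses an interval tree per
chromosome (and strand, in the default strand-aware mode; an `ignore`
mode is provided since the original comparison's strand handling is
unknown); a peak overlaps if it shares ≥ 1 base with ≥ 1 site. Region
summaries divide counts by region length and normalise densities to
percentages summing to 100.

## Synthetic data: what it does and does not show

One top-level seed is split into fixed per-generator substreams
(`numpy` SeedSequence spawn keys), so identical seeds give identical
datasets and adding a generator never perturbs the others. Every
generator emits a truth manifest sufficient for automated recovery
scoring.

- The BLI generator produces exactly the model the fitter assumes
  (plus Gaussian noise), so recovery tests validate the estimation
  pipeline, not robustness to drift, mass transport or heterogeneous
  ligand — real sensorgrams violate 1:1 kinetics in ways these tests
  cannot detect.
- The peak-table generator (180 residues numbered from 387, matching a
  KH34-sized di-domain; 10% perturbed; 0.005 ppm noise, ~10:1
  effect-to-noise) plants clean localized perturbations; it does not
  emulate peak overlap, exchange broadening or assignment errors.
- The genome fixture plants an exact overlap count (default 7 of 20
  peaks) with ≥ 1 nt guard gaps and co-stranded planted pairs, so the
  truth holds under both strand modes; it is a bookkeeping fixture, not
  a realistic transcriptome.

## Numerical and design notes

- Newton polish tolerance 1e−12·max(1,[P]t); bisection oracle default
  relative tolerance 1e−12; all physical quantities clipped to their
  ranges only to absorb round-off, never to mask model violations.
- `curve_fit` bounded below at zero; non-physical fit results (k ≤ 0)
  are errors, not silently clamped.
- Zero pooled variance in the t-test returns t = 0, p = 1 for equal
  means and ±∞, p = 0 otherwise.
- Magnitude weighting with all-zero values degenerates to uniform.
- Provenance JSON (config echo, version, seed, timestamp) is written
  next to outputs; timestamps never enter data files, so re-runs are
  byte-identical.

## Known limitations

Cooperative/multi-site binding, kinetic competition, K_D fitting from
competition or CSP data, global multi-curve kinetic fits, exchange-
regime modelling, peak picking, read alignment and peak calling are all
out of scope. The package quantifies a published equilibrium argument
and provides the scaffolding to test it — it does not re-measure any
experimental quantity.
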