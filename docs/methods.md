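# Methods

`vesicleshift` implements the statistical pipeline used to define the
protein content of transport vesicles captured by mitochondrially
re-anchored golgin tethers in LOPIT-DC spatial proteomics. A golgin
normally resident at the Golgi is fused to a mitochondrial anchor; the
vesicles it tethers accumulate on mitochondria, so the fractionation
profiles of their cargo proteins shift partway toward the mitochondrial
profile. The pipeline detects those shifts and calls cargo proteins from
protein-level quantitation alone.

## Data model

A LOPIT-DC experiment yields, per condition, a matrix of reporter-ion
abundances over proteins × (replicate, fraction): ~10 differential
centrifugation fractions, 3 replicates. Each (protein, replicate) block is
sum-normalised to a composition on the simplex — the profile's shape, not
its total intensity, encodes localisation. Rows with missing cells are
dropped at read time. Proteins with a contaminant-database frequency ≥ 0.1
are removed unless they are curated organelle markers, along with a small
editable accession blocklist (keratins, serum albumin, trypsin).

Compositions are rank-deficient (each block sums to one), so model fitting
happens in additive log-ratio (ALR) coordinates where useful: for a D-part
composition x, alr(x) = (log x_1/x_D, …, log x_{D−1}/x_D). Zeros are
replaced by half the smallest non-zero part of the block (then
re-normalised) before the transform; the inverse transform reconstructs
zero-free compositions to 1e-9.

## Organelle assignment and pre-filter (TAGM-MAP)

Each organelle class k is a Gaussian N(μ_k, Σ_k) over the per-replicate ALR
profiles concatenated across replicates (dimension R·(D−1)); a single fixed
multivariate-T component (df κ = 4, location = data mean, scale = half the
data covariance) absorbs outliers. Conjugate priors follow the standard
TAGM defaults: Dirichlet(1) on mixing weights; normal-inverse-Wishart on
each (μ_k, Σ_k) with μ0 = data mean, λ0 = 0.01, ν0 = D + 2,
S0 = diag(data variances)/K^(2/D); Beta(2, 10) on the outlier weight ε.
Parameters are fitted by EM to the joint posterior mode. Marker proteins
have fixed class membership (only their outlier indicator is latent);
unknowns carry joint responsibilities over (class, outlier). The
log-posterior is non-decreasing over iterations up to a small ridge
(1e-6·trace/D) added to each covariance update; a decrease beyond numerical
tolerance raises an error rather than being silently accepted.

TAGM is fitted in ALR rather than raw compositional coordinates because the
exact sum constraint makes the concatenated data covariance singular, which
gives the fixed T component unbounded density on the constraint manifold;
the log-ratio representation removes the degeneracy while keeping replicate
concatenation. Initialisation is deterministic, from the conjugate
posterior mode of each class's markers — this keeps initial class
covariances at within-class scale even when markers are fewer than
dimensions.

The pre-filter runs on the control condition only: proteins whose MAP class
is mitochondrial or nuclear are discarded before differential testing
(movement *toward* those compartments is the signal of interest; residents
would contribute ratio noise). Discard classes default to any label
containing "mito", "nucle" or "chromatin" (case-insensitive) and are
configurable. No minimum posterior-probability cutoff is applied before
discarding. Markers of non-discarded classes are always retained under
their curated label.

A supervised alternative (`classify_supervised`) trains an RBF SVM on
marker profiles and assigns unknowns only when the class decision score
clears a per-class threshold estimated on held-out markers (stratified
cross-validation) so the estimated false discovery proportion is ≤ 0.05 by
default. When the estimated FDP never exceeds the target down to the lowest
held-out score, no cutoff is imposed.

## Two-sample test (GP Bayes factor)

Per protein, the ALR profiles of both conditions are compared under two
models: M0, one shared Gaussian process over the ALR component index
generating all observations; M1, an independent GP per condition. The
kernel is squared-exponential, k(x, x′) = σ_f²·exp(−(x−x′)²/(2ℓ²)), plus
i.i.d. noise σ_n²; replicates are repeated observations at the same
coordinates; all observations are centred by the pooled per-protein mean so
the zero-mean GP needs no mean function (this also makes the statistic
invariant to common additive shifts). Hyperparameters carry Gamma(1, 1)
hyperpriors (configurable) and are optimised per model by type-II MAP:
a fixed 3×3×3 grid of starts in log space (scaled to the data variance and
coordinate span) followed by Nelder-Mead; ties and failures fall back to
the best grid point, so the procedure is deterministic. The reported
statistic is the natural-log Bayes factor
log BF = [log ML(control) + log ML(treatment)] − log ML(pooled),
with the marginal likelihoods evaluated at the optimised hyperparameters.
A jitter of 1e-8·σ_f² on the Gram diagonal guards the Cholesky
factorisation.

Full marginalisation of the hyperparameters is not attempted; type-II MAP
with fixed multi-start makes the statistic cheap, deterministic, and — as
the null simulations show — conservative at the decision threshold (null
log BF essentially never approaches 14).

## MitoRatio

For each protein in each condition, the squared Mahalanobis distance
d² = (x − m)ᵀ S⁻¹ (x − m) to the mitochondrial marker centroid is computed
on the concatenated R·D compositional profile, and the statistic is
log2 MitoRatio = log2 d²_control − log2 d²_treatment (floored at 1e-8
before the logs so the ratio stays finite; written as a difference of logs
so condition swap negates it exactly). Positive values mean the protein sat
nearer the mitochondrial profile in the treatment.

m and S are estimated separately within each condition from that
condition's mitochondrial markers, so an organelle-wide profile change of
the mitochondria themselves (swelling under vesicle capture) is absorbed.
The estimator is Minimum Covariance Determinant (support ⌈(n+p+1)/2⌉,
consistency-corrected) when markers comfortably outnumber dimensions and
the sample scatter is well-conditioned; otherwise the sample covariance is
shrunk analytically toward its diagonal (Ledoit-Wolf-style intensity
estimated from the data) with a final ridge if the condition number still
exceeds 1e8. Sum-constrained compositional profiles always take the
shrinkage branch — their scatter is exactly rank-deficient, and the
deviations being tested lie in the constraint subspace, so the shrunken
inverse is well-behaved there.

The ratio uses squared distances, the direct reading of the procedure
(d² is computed, then "the ratio of the distances"); using unsquared
distances would halve every log2 value, and the convention is exposed in
the API for that reason.

A known property, quantified during development: because S is estimated
independently per condition from finitely many markers, every protein in a
run shares a multiplicative estimation-noise factor of order √(p/n) in its
d² values. With ~25 markers and p = 30 this makes a single run's *mean*
log2 MitoRatio wander by ±0.2-0.4 around zero under the null, even though
the expectation is exactly zero by control/treatment exchangeability. The
statistic is therefore calibrated jointly with the Bayes factor (which is
unaffected), not used alone: under the dual thresholds the null hit rate
in simulation is ~0 and relocated proteins at α ≥ 0.5 sit far above both
cut-offs (mean log2 MitoRatio ≈ 6). The unbiasedness property test
averages over a seed ensemble with covariance-swapped antithetic pairs,
which cancels the shared factor exactly.

## Hit calling and calibration

A protein is a hit when log-e BF ≥ 14.0 AND log2 MitoRatio ≥ 0.40 — the
calibrated default thresholds. Bait accessions (the re-anchored golgin
itself) are flagged and reported separately from the hit count.
`calibrate_thresholds` re-derives thresholds from known positives and
negatives: it returns the largest threshold pair on the observed score grid
covering every positive and no negative, or, when no such pair exists, the
pair maximising positives-minus-negatives covered (ties toward stricter)
with an infeasibility flag. No multiple-testing correction is applied; the
design uses fixed empirical thresholds validated against known cargo, and
the package follows that design rather than substituting an FDR procedure.

## Synthetic data generator

The generator emulates a two-condition LOPIT-DC comparison with known
ground truth. Organelle templates are smooth bumps over the fraction axis
(organelles enrich in a few adjacent centrifugation fractions) plus seeded
ALR jitter, redrawn until all pairwise Aitchison distances reach a
separation floor (default 3.0). Defaults: 8 classes (including
mitochondria and nucleus), D = 10 fractions, R = 3 replicates, 2000
proteins, 25 markers per class, replicate noise sd 0.25 in ALR space
(logistic-normal, chosen as a modest replicate-to-replicate variation
consistent with well-separated organelle clusters on a PCA projection),
5% outliers, 2.5% relocated proteins with displacement α ~ U(0.5, 1).

Relocated proteins' treatment templates are (1−α)·source + α·mito in ALR
space — partial displacement, mixing in the same coordinates the noise
model and downstream tests use. Relocation sources exclude mitochondria-
and nucleus-like classes: vesicle cargo originates from the
secretory/endosomal system, and residents of the pre-filtered compartments
cannot meaningfully move toward them. Outliers are multivariate-T (df 4)
in ALR space around the template-cloud centre, drawn once per protein and
shared across conditions (chronic mislocalisation, not relocation), so
they stress the mixture model without breaking the two-sample null.
Markers are never outliers nor relocated, so marker-based fitting is clean.

What the generator does not emulate — and hence what passing tests do not
establish about real data: peptide-level identification noise, missing
values, TMT isotope interference, protein-specific random effects that
correlate replicates, multi-localised proteins, and marker annotation
errors. The logistic-normal noise matches the model assumptions by
construction; real profile noise is heavier-tailed and structured.

## Problem sizes and numerical choices

Simulation-based checks run at 2000 proteins × 10 fractions × 3 replicates
× 2 conditions (the scale of one real comparison); oracle checks use 100
random instances each. Numerical details chosen once: GP Gram jitter
1e-8·σ_f²; covariance ridge 1e-6·trace/D per TAGM update; EM stops on
relative log-posterior change < 1e-8 (max 200 iterations); MitoRatio floor
1e-8; Nelder-Mead capped at 300 function evaluations per GP fit; MCD seeded
for deterministic subset search; PCA component signs fixed so the
largest-magnitude loading is positive.

## Limitations

* The Bayes factor uses optimised (not marginalised) hyperparameters; its
  absolute scale depends mildly on the Gamma hyperpriors, and the 14.0
  threshold was calibrated against known cargo, not derived from theory.
* Single-run mean MitoRatio carries the shared covariance-estimation noise
  described above; per-protein ratios should be interpreted jointly with
  the Bayes factor.
* TAGM-MAP reports posterior responsibilities only; no posterior sampling
  of parameter uncertainty (the MCMC variant is out of scope).
* The pre-filter takes the MAP class without a probability cutoff;
  low-confidence mitochondrial calls are discarded like confident ones.
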