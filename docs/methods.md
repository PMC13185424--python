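# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Freelist preparation

Raw mentions are matched to a taxon catalog after Unicode NFKC
normalization, trimming, and case folding — hand-transcribed interview data
differ in exactly these ways, and nothing fancier (no fuzzy spelling
correction) is attempted; an unresolvable label is surfaced as an error (or
a validation finding), never silently dropped.  When two mentions in one
list resolve to the same taxon (vernacular synonyms), the earliest mention
is kept, because freelist rank encodes accessibility from memory.

The higher-order insertion rule adds a catalog parent taxon (e.g. the genus
people call "crows") immediately before its first-listed member species
whenever at least one member is listed but the parent itself is not.  Two
deliberate restrictions:

* **One level only.**  The inserted taxon is the catalog's declared parent —
  the name people actually use for the group — not the full chain of ranks
  above it.  Inserted items therefore never trigger further insertions.
* **Deterministic order.**  If a list contains members of several missing
  parents, insertions happen in order of each parent's first-member
  position; the operation is idempotent and never reorders listed items.

List lengths are computed on the prepared lists, so an inserted taxon counts
toward length (the "credit rule"): naming a member species is worth the
species credit plus the group credit.

## Salience and the cultural domain

Smith's S for a taxon is the mean over **all** informants asked the question
— including those who listed nothing — of (n − r + 1)/n for listers and 0
otherwise.  This yields two exact identities used as oracles in the tests:
S never exceeds the taxon's relative frequency, and the sum of S over all
taxa equals the mean of (n_i + 1)/2 over non-empty lists.  Mean ranks use
post-insertion ranks: salience is a property of the prepared lists, and the
inserted group name genuinely occupies a recall slot.

Domain membership applies the threshold to the exact fraction
(`rel_freq >= threshold`, no pre-rounding), 0.05 by default and 0.20 for
"general knowledge".  With overlap exclusion on, any member that is an
ancestor (walking the catalog parent chain) of another member is removed, so
the same knowledge is not counted at two taxonomic levels.  The long-format
freelist CSV cannot represent an empty list, so the dataset reader restores
an empty freelist for every (participant, domain) pair absent from the file
— otherwise every per-participant denominator would silently shrink.

## Age-group randomization test

The test statistic is the difference in group means of the per-participant
contributions c_i, older minus younger.  The exchangeable unit is the
participant with their whole freelist; the null distribution permutes group
labels over participants with c_i held fixed.  The two-sided Monte-Carlo
p-value uses the add-one estimator (1 + #{|d*| ≥ |d|})/(n_perm + 1), which
is strictly positive and valid at any n_perm; 10,000 permutations is the
default.  For ≤ ~20 participants the assignment space can be enumerated
exhaustively (`exact=True`), which the tests use as the oracle.  The age
split is classes 1–3 (18–45 y) versus 4–6 (46+ y); because ages are
recorded in classes, the boundary is unambiguous.  p-values are reported
raw, per taxon; an optional Holm/Bonferroni column is available but off by
default, since the per-taxon tests are descriptive flags rather than a
family-wise decision.

## List-length models

Lengths are overdispersed counts; the model is NB2 (variance μ + αμ²) with
log link, fitted by joint maximum likelihood over coefficients and α
(statsmodels' discrete NB likelihood, started from the Poisson fit).  AIC
counts the regression coefficients plus the dispersion parameter.

Smooth terms are **unpenalized fixed-df** regression terms with df = 2, the
analogue of a 3-knot fixed-basis spline: with so few distinct predictor
values (ordinal class codes 1–6) a penalized smoother adds machinery without
changing the fit.  The basis is a QR-orthogonalized polynomial in the
predictor, centered against the intercept, deterministic given (x, df), and
exactly nesting the linear term at df = 1.

Effect types per predictor — (I) linear, (II) smooth, (III) linear × gender
(with gender main effect), (IV) gender + separate smooth per gender level —
are chosen by lowest AIC on univariate fits; exact AIC ties (measure zero in
practice) go to the simpler type.  The joint model combines each predictor's
chosen type with a single gender main effect, then backward elimination
repeatedly drops the least significant term (largest likelihood-ratio χ²
p-value above 0.05, dispersion re-estimated in every refit) while never
removing a main effect that a remaining interaction requires.  One term is
dropped per iteration, for determinism.  Deviance explained is
100·(1 − residual/null deviance), both deviances evaluated at the model's
fitted dispersion; rows with missing values in *used* variables are dropped
casewise, so n can differ between models (income is the only field allowed
to be missing).

Age, education, and income enter as their ordinal class codes (1..6).  The
coding is a convention, not a claim that classes are equidistant; class
midpoints would change coefficient scales but not selection or signs.

## Binomial mixed model for indicator frequency

Per (indicator taxon, age class) the count of listers out of the class size
is modelled as Binomial with logit link, fixed effects = intercept + df-2
age smooth, and a Gaussian random intercept per taxon capturing how well
known each taxon is overall.  The marginal likelihood integrates the random
effect by adaptive Gauss–Hermite quadrature (Laplace-centered, 15 nodes;
one-dimensional Newton for each group mode) and is maximized over (β, log σ)
with BFGS.  The age effect is reported as L = 2(ll_full − ll_null) against
the model without the smooth, on 2 df.  A test cross-checks β, σ, and L
against `lme4::glmer` (nAGQ = 15): agreement is ~1e-3.  Under a true σ = 0
the ML estimate sits on the boundary in about half of replicates and is
small otherwise, which is the behaviour the tests assert (σ² < 0.05), not
σ ≡ 0.

## Synthetic survey generator

The generator emulates the study conditions the analyses assume: 463
participants (seniors and women overrepresented: 25% in the oldest class,
60.7% female), two question domains, and per domain

* a taxon pool of species plus higher-order (genus-level) entries, a share
  of species carrying a catalog parent (45% plants, 55% birds);
* Zipf popularity weights over a shuffled pool ordering (exponent 1.4 for
  plants over 300 species, 1.6 for birds over 200), giving the heavy tail of
  once-listed taxa that freelist surveys show;
* NB list lengths with log μ = β₀ + β_age·(age − 3.5) + β_age2·(age − 3.5)²
  + β_edu·(edu − 3) + β_gender·[male], dispersion θ = 3, defaults tuned once
  so harmonized mean lengths land near 6 (plants) and 10 (birds) with maxima
  in the observed 0–35 range;
* items drawn without replacement by Plackett–Luce sequential sampling
  (Gumbel top-k), so salient taxa tend to come to mind first and Smith's S
  is meaningful; indicator-taxon weights are multiplied by
  exp(γ·(age − 3.5)) (γ = 0.15 by default, 0 under the null), emulating
  higher indicator salience among older participants;
* a few species with an alternate vernacular label, ~1.3% missing income,
  and list lengths truncated (not rejected) at the pool size.

Known limitations: a single Zipf law cannot simultaneously reproduce a
cumulative richness as low as real bird lists (~116 taxa) and their 25%
singleton share — the generator prioritizes mean lengths, domain sizes, and
a realistic singleton share, yielding somewhat richer cumulative lists.  The
insertion rule fires more often than in real data (synthetic participants
rarely volunteer genus-level names that real informants use freely), labels
are systematic codes rather than vernacular names, and list lengths and item
choices are independent across participants — there is no interviewer or
town effect.  Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed data-generating process, not
fidelity of any particular ecological claim.

## Problem sizes and numerical choices

The test suite works at deliberately modest sizes chosen for statistical
sufficiency: ~110 random fixtures for the Smith's-S oracle; 8 small samples
(6–10 participants) for exhaustive-vs-Monte-Carlo agreement at 10,000
permutations; 500 null datasets of 80 participants (999 permutations each)
for type-I calibration at α = 0.05; 100 replicates of n = 2000 for NB
coefficient coverage and 21 for effect-type selection consistency.  Ties in
the permutation statistic are counted as "at least as extreme" with a 1e-12
float tolerance, which keeps the test valid (conservative) under ties.
NB fits fall back from BFGS to Newton to Nelder–Mead and raise a fit error
with context if none converges; α estimates pinned at the boundary are
truncated at 0 (Poisson).
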