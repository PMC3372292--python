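# Methods

## The problem

High-throughput protein-production pipelines express thousands of
constructs in *E. coli* and score each one for expression level (E) and
solubility (S) on 0–5 integer scales read off stained SDS-PAGE gels; S is
never recorded when nothing expressed (E = 0).  A construct is *usable* —
worth scaling up for purification — when E·S > 11 (equivalently ≥ 12 on
integers).  This package implements the statistical machinery for asking
which primary-sequence properties drive these outcomes, and for turning the
answer into a predictor (pES, the probability of expressed and soluble
protein) that scores new sequences from composition alone.

## Sequence parameters

Per construct the feature layer computes 72 core parameters: the 20
fractional amino-acid contents (`a` … `y`), their predicted-buried
(`ab` … `yb`) and predicted-exposed (`ae` … `ye`) splits, and 12 compound
parameters — GRAVY (mean Kyte–Doolittle hydropathy), mean side-chain
conformational entropy over all (`sce`) and over exposed (`esce`) residues,
six electrostatic variables (counts and chain-length-normalized fractions
of total, net, and |net| charge from R, K, D, E), the disorder fraction
(`diso`), chain length, and the isoelectric point.  When an in-frame CDS is
supplied, the R/I/L/P fractions are additionally split into rare-codon and
common-codon components (default rare set: Arg AGA/AGG/CGA/CGG, Ile ATA,
Leu CTA, Pro CCC — configurable, and recorded in run provenance).

Denominator conventions matter and are fixed as follows: every fraction,
including the buried/exposed splits and `diso`, divides by total chain
length, so the algebraic closures Σx = 1, x = xb + xe and
rare + common = total hold exactly; the two entropy means divide by the
number of residues averaged (`esce` by the exposed count).  Nonstandard
residue codes count toward chain length but enter no numerator and no
scale mean, with a per-record warning.

The isoelectric point is the root of the Henderson–Hasselbalch net-charge
curve (side chains D, E, C, Y, H, K, R plus free termini,
Bjellqvist/ExPASy-style pKa constants, overridable) found by bisection on
[0, 14]; the curve is strictly decreasing in pH so the root is unique, and
iteration stops below 1e-4 pH units.  The side-chain entropy scale is a
Monte-Carlo-derived conformational entropy table (Creamer family,
cal·mol⁻¹·K⁻¹); like the hydropathy scale it is injected through
`ScaleConfig`, and no result in this package depends on its specific
values beyond sign and ordering.

Burial and disorder are *inputs*: the package deliberately does not
re-implement the neural predictors that produce them in production
settings.  For testing, a deterministic baseline annotator labels the ~45%
of residues with the highest window-smoothed hydropathy as buried and
residues in high-disorder-propensity windows (TOP-IDP-style propensities,
window 15) as disordered.  It is a stand-in with the right statistical
texture, not a surface-accessibility method.

## Regression models

Outcomes are modeled with the two logistic families:

* binary (usability): Pr(Y=1) = e^θ / (1 + e^θ), θ = β₀ + xᵀβ;
* proportional-odds ordinal (E and S): P(Y ≤ j) = e^(t_j − θ) / (1 + e^(t_j − θ)),
  θ = xᵀβ, with strictly increasing thresholds t₁ < … < t_{J−1} and no
  separate intercept.

Under this sign convention larger θ pushes mass toward higher scores, so a
positive slope reads "more of this feature, better outcome".  At J = 2 the
ordinal model reduces exactly to the binary one with t₁ = −β₀ (asserted in
the tests).

Fitting is Newton–Raphson on the exact log-likelihood with analytic
gradient and analytic Hessian (the Hessian is cross-checked against finite
differences in the test suite), step-halving that insists on a likelihood
increase and monotone thresholds, and a BFGS fallback in a reparameterized
space (first threshold + log-increments) that cannot produce crossing
thresholds.  Convergence requires a gradient infinity-norm below 1e-8
(200 iterations max).  Standard errors come from the observed information
matrix; Wald Z tests use log-space survival functions so extreme p-values
stay exact, and likelihood-ratio χ² tests switch to the upper-tail
asymptotic expansion where `logsf` underflows.

Degenerate inputs are diagnosed, not silently tolerated: constant or
collinear predictors raise an error naming the offending columns, and
complete separation raises rather than returning a divergent fit.
Separation is flagged when a *standardized* slope (slope × predictor SD)
exceeds 50 during iteration or when the likelihood saturates at
convergence.  The standardized scale is deliberate: fraction-valued
sequence parameters occupy ranges of ~0.0–0.3, so their legitimate
raw-scale slopes run into the tens to hundreds and a raw cutoff would
reject valid fits, while truly separated fits can reach a vanishing
gradient before any raw slope reaches 50.

## The analysis chain

1. **Clone aggregation.**  Replicate (E, S) scores per construct are
   collapsed by one of: componentwise maxima (the primary convention —
   pipeline failures lower scores, so the maximum estimates the
   construct's potential), blind averaging, the replicate with maximal
   E·S (ties to the first clone in input order), or a consistency cull
   that drops any construct whose replicates disagree.  Averaged
   non-integer scores are rounded half-up before ordinal fitting, since a
   cumulative-logit model needs discrete levels.
2. **Screening.**  Each parameter is regressed alone against the outcome
   (ordinal for E and S, binary for usability); S screens use only
   constructs with E > 0.  Reported per parameter: slope, Wald p, signed
   −log₁₀(p) (sign of the slope attached), and the predictive value
   slope × SD — a scale-free effect size.  Constant columns are excluded
   with a warning.
3. **Culling.**  The buried/exposed split of an amino acid replaces its
   total fraction only when both split members are significant with
   opposite-signed slopes; for each whole-vs-fractional charge pair the
   smaller-p member is kept (ties prefer the length-normalized version).
   Everything not significant at the Bonferroni threshold α/n (0.05/72 ≈
   0.00069 for the default parameter set; recomputed from the actual
   number screened) is dropped.
4. **Stepwise + AIC.**  Forward/reverse stepwise selection over the culled
   pool: add the candidate with the smallest Wald p if p < 0.049, then
   remove the worst in-model variable if p ≥ 0.05; ties break
   lexicographically, candidates whose addition makes the design
   rank-deficient are skipped, and revisiting a previously seen variable
   set terminates the search (cycle guard).  The result is pruned by
   repeatedly removing any variable whose removal strictly lowers the
   AIC (= 2k − 2ℓ), until a full pass removes nothing.
5. **Prediction.**  Surviving coefficients are serialized as a
   `CoefficientSet`; pES = 1/(1+e^(−θ)) for binary sets, and ordinal sets
   yield full probability distributions over the 0–5 levels.  Calibration
   curves bin constructs at equal θ intervals (width 0.1, anchored at 0,
   both configurable) and compare observed usable fractions — with
   central 95% Bayesian binomial intervals under a Jeffreys Beta(½, ½)
   prior (uniform prior available); the stated "Bayesian counting
   statistics" interval is ambiguous, and Jeffreys is the standard
   counting-statistics choice.  Cutoff trade-off tables report, per pES
   cutoff, the fraction of the pool kept and the percentage increase in
   usable rate among kept targets over the whole pool.

Two auxiliary screens probe mechanism: paired rare/common codon
regressions fit the rare- and common-codon fractions of R, I, L, P jointly
(two predictors per amino acid) so each slope is adjusted for the other
usage class, and permissive/enhancing screens run binary regressions on
the extreme-score boundaries (score 0 vs > 0; score 5 vs < 5) to locate
whether a parameter gates any outcome at all or pushes good outcomes to
the top.

## The synthetic cohort generator

No public dataset accompanies the analysis this package operationalizes,
so validation runs on synthetic cohorts whose *structure* mirrors the
real screen:

* sequences drawn from E. coli-like residue frequencies with a per-construct
  Dirichlet perturbation (concentration 100 — between-construct composition
  SDs of ~0.01–0.03 per residue, a realistic proteome spread); lengths
  lognormal (median ≈ 200) clipped to [50, 600];
* E drawn from the same proportional-odds family the analysis fits, with
  latent θ a configured linear combination of the construct's *realized*
  feature values — this makes parameter recovery a well-posed question,
  and is the central modeling choice to keep in mind: passing recovery
  tests certifies the estimation machinery, not the realism of logistic
  outcome noise.  A latent-normal mode provides a deliberately
  misspecified variant for robustness checks;
* S from a second proportional-odds model whose latent scale adds
  0.6·(E − 3), inducing the strong positive E–S coupling characteristic of
  expression screens; S is set missing when E = 0;
* default thresholds place ~60–70% of scores at the extremes (0 or 5),
  the bimodality real screens show, and leave ~35–40% of constructs
  usable;
* two clones per construct, with 25% of constructs made discrepant by
  lowering one clone's E or S by one unit (scores are only ever perturbed
  downward, matching the premise that errors lower scores; the discrepant
  constructs are drawn from those with something to lower, so the
  realized fraction matches the 25% target up to rounding);
* a 4:1 analysis/test split by per-construct Bernoulli(0.8) draw — a
  random assignment, not an exact partition.

The generator does not emulate phylogenetic composition structure, real
disorder/burial predictors, tag sequences, or any nonlinearity in the
outcome process; conclusions about real screens require the real
annotations and data.

## Validation studies and their design

* **Oracle equivalence.**  On every ≤15-observation single-predictor
  fixture, fitted log-likelihoods match an independent refining
  grid-search oracle (direct threshold/slope parameterization, final
  resolution < 1e-4) to 1e-6.
* **Frequentist calibration.**  200 cohorts of n = 5000 drawn from the
  ordinal model give slope biases ≪ 5% and pooled 95% Wald-CI coverage
  inside [93%, 97%]; 2000 null replicates at n = 1000 give a Wald type-I
  error of 5% ± 1.5 points.
* **End-to-end recovery.**  Fifty cohorts of 7733 constructs carry
  planted effects fracnumcharge +8, gravy −0.8, Arg fraction −20 (raw
  feature scale; marginal |Z| ≈ 8–25, chosen a priori to sit clearly
  above the Bonferroni bar without the overwhelming significances a real
  cohort of this size produces).  Because fracnumcharge = d + e + k + r
  *exactly*, the planted model is identified only up to a basis of the
  charge-fraction family; the study therefore scores recovery as: gravy
  selected, selected charge variables spanning the planted coefficient
  vector, and no more than two selections outside the charge family plus
  gravy.  Measured: 90% recovery over the 50 frozen seeds, never more
  than two nulls.  The acceptance script also reports the strict
  no-extras rate for transparency.
* **Calibration curves.**  On perfectly calibrated data, ≥ 95% of θ-bin
  Jeffreys intervals cover the bin-mean predicted probability across 100
  seeds.
* **Closure invariants.**  Fraction, split, and codon-split closures and
  the zero-charge property of the pI hold across 1000 random sequences.

Problem sizes throughout (cohorts of 5000–7733, 50–2000 replicates) were
chosen to keep each study's Monte-Carlo error well below the margin it is
judged against while completing in minutes on one core.

## Known limitations

* The generator shares its outcome family with the estimator; the
  latent-normal mode exists precisely because that symmetry flatters
  recovery statistics.
* Proportional odds is assumed, never tested (no Brant-style diagnostics).
* Standard errors use observed information; no robust or clustered
  variants.
* The shipped pKa table uses single N-/C-terminal constants rather than
  residue-specific termini, so computed pI values can differ from other
  tools by ~0.1 pH unit; the table is overridable.
* No pretrained coefficient sets ship with the package — predictors are
  whatever `build_model` produces on the user's (or simulated) data, and
  test-set recalibration of θ is out of scope.
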