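# Methods

This note documents the statistical machinery in `haisac`, the assumptions
behind the synthetic-cohort generator, the numerical choices that matter,
and what the tests do and do not establish about real clinical data.

## The instrument and its scoring model

The HAI-SAC awards up to 60 points: an objective subscore (HAI-SAC-3, 40
points) from three memory subtests — confrontational naming of objects,
colors and details (CNOCD, 16), memory for photo locations (ML, 12) and
recall of object functions (RFO, 12) — plus an informant subscore
(HAI-SAC-I, 20 points) from two questions, reported cognitive decline (CD)
and functional interference of that decline (FD). Negative informant
reports score 8 and 12 points respectively, so higher totals always mean
better cognition.

Scoring choices worth spelling out:

* **ML cap.** Two points per correctly placed photo would allow 14 points
  with the perfect-response bonus; the instrument's maximum is 12. The rule
  implemented caps the per-photo base at 10 and grants the 2-point bonus
  only for a perfect six-of-six arrangement. Algebraically the score equals
  `2 × count` over the whole 0–6 range; the cap-and-bonus reading preserves
  the stated per-photo rule and the printed maximum simultaneously.
* **FD presupposes CD.** When an informant reports no cognitive decline
  there is no decline to interfere with daily life, so FD defaults to "no
  interference" (12 points) in that case. The generator treats the two as
  distinct correlated latents instead, because the validation battery needs
  FD's marginal distribution.
* **NPI sum of boxes** is `Σ frequency × severity` over the 12 symptom
  domains (maximum 144). The caregiver-distress rating, although collected
  alongside, is not part of this summary score.
* CASI composites (`0.5·(short + long delayed recall) + 0.6·recognition`;
  `0.5·(reading + writing) + 0.3·naming + commands`) are kept as exact
  decimals; no rounding happens anywhere inside scoring.

## Synthetic cohorts

No subject-level data ship with the package. The generator emulates the
three-group validation cohort (CU n=133, MCI n=231, DAT n=397) at two
fidelity levels; the packaged YAML (`haisac/data/reference_cohort.yaml`)
carries the published per-group means and SDs of every scale.

**Scale level.** Each variable is a group-conditional normal. `untruncated`
mode keeps the exact normal draw — the right setting for ROC calibration,
because the published AUCs agree with the binormal values implied by the
published moments to within ±0.01. `bounded` mode clips to the instrument
ranges and snaps to the score grids (CD ∈ {0,8}, FD ∈ {0,12}, ML to even
points, CDR-SB to half points, integers elsewhere); the two-point informant
items are drawn as `maximum × Bernoulli(mean/maximum)` through the latent
normal so their means match the published values exactly. Variables are
independent within group by default; `within_group_correlation` mixes a
single shared per-subject latent into every standardized variable (sign
flipped for age, CDR-SB and NPI-SB, where larger is worse), the minimal
one-parameter copula able to mimic the strong observed between-test
correlations.

**Item level.** Per subject, two correlated standard-normal factors — a
semantic-memory/contextual-binding factor (SMCB) and an informant factor
(INF) — generate standardized items via `λᵀf + √ψ ε` with the published
pattern loadings (CNOCD 0.95, RFO 0.96, ML 0.55 on SMCB; CD 0.97, FD 0.45
on INF with a 0.48 cross-loading). Objective items are rescaled to the
group's item moments and rounded onto the raw response grids; binary
informant responses come from thresholding their latent at the group's
Bernoulli probability (a probit/threshold model). The inter-factor
correlation is not published; 0.30 was fixed once as a typical moderate
oblique correlation between cognitive and informant-report factors. CD's
probability is `mean/8`; FD's is derived as `(HAI-SAC-I mean − CD mean)/12`
because the published FD row duplicates the IADL row and cannot describe a
12-point binary item.

**What the generator does not emulate.** Real response processes (floor and
practice effects, education-dependent performance, informant bias),
within-group covariance beyond the one-parameter copula, missing data, and
longitudinal change. Two measurable consequences: pooled item correlations
come out somewhat stronger than in the real battery (Cronbach's α ≈ 0.80 on
default cohorts versus the published 0.63; the published α and Bartlett
statistic are themselves not mutually consistent with the published
near-singular loadings), and passing tests demonstrate correctness of the
machinery under the stated model, not clinical performance of the
instrument.

## Reliability and factor analysis

Cronbach's α uses sample variances (n−1) throughout. KMO contrasts raw with
anti-image partial correlations from the inverse correlation matrix.
Bartlett's sphericity is `−(n−1−(2p+5)/6)·ln det R` on `p(p−1)/2` df.

Extraction is iterated principal-axis factoring: SMC-initialized
communalities, eigendecomposition of the reduced matrix, communalities
rebuilt from the leading factors. Convergence is declared when the largest
communality change drops below 1e-3 (cap 1000 iterations) — the loose
convention of the standard packages, adopted deliberately: batteries with a
weakly determined factor (here, a two-item informant factor) exhibit an
unbounded, slow Heywood drift under exact iteration, so tight tolerances
are unattainable on sampled matrices, while exact low-rank constructions
still converge to 1e-10 when requested. Heywood cases are flagged, never
clipped.

Rotation is classical promax (power 4): Kaiser-normalized varimax start,
element-wise `|λ|³·λ` target, least-squares transformation with column
normalization; pattern matrix and factor correlation follow the R
`stats::promax` convention (verified against it to ~2e-4). Factor count
defaults to the Kaiser criterion on the unreduced correlation matrix — the
SMC-reduced variant cannot select the weak informant factor even on the
exact generating model — and is overridable, which matters in practice: on
the default discretized cohort, binary attenuation of CD's correlations
pulls the second eigenvalue to ≈0.89, so selecting two factors is the same
scree/variance judgment the original analysis made. Factors are ordered by
variance explained (squared structure loadings over item count) and signed
so each factor's strongest item loads positively. Factor scores are
loading-weighted sums of raw item scores, the screening-report convention,
not regression scores.

A caution established during development and enforced in the tests only as
far as mathematics allows: the published informant-factor loadings
(CD 0.97 / FD 0.45) sit at a near-singular stationary point that
SMC-started principal-axis iteration does not reach even in population —
both this implementation and an independent implementation converge to a
solution with CD communality ≈0.5. The objective block is recovered within
±0.03 at n=5000; informant loadings are determined only up to this
indeterminacy, so recovery tests assert the structure (which items define
which factor), not the printed informant values.

## Discrimination

Cases are the impaired, lower-scoring arm; a subject is screen-positive
when the score is at or below the cutoff. AUC is the Mann-Whitney
probability `P(case < control) + ½P(tie)`; confidence intervals and the
paired AUC comparison use DeLong's placement-value estimator, with the
difference tested as χ²(1) = z². The optimal cutoff maximizes Youden's
J = sensitivity + specificity − 1; ties prefer the lowest cutoff (highest
specificity, the conservative referral rule); cutoffs are rendered as the
conventional "a/b" pair bracketing the midpoint between the last positive
and first negative achievable score. The analytic companion
`binormal_auc = Φ(|Δμ|/√(σ₁²+σ₂²))` ties the simulator to the ROC layer:
Monte-Carlo AUCs on untruncated cohorts converge to it. Sensitivities,
specificities and cutoffs are reported but never asserted against published
values — they depend on distribution shape, which group moments do not
determine.

## Group statistics

One-way ANOVA is available from raw data and from per-group (n, mean, SD)
summaries; the two agree to 1e-9 on any raw sample with exactly those
moments, which is how the published F statistics are reproduced from the
summary table (printed SDs treated as sample SDs, the convention that
reproduces them). Pairwise contrasts are pooled-variance t-tests flagged at
the Bonferroni-corrected α = 0.017. Chi-square independence uses no
continuity correction. Correlation strengths are banded at |r| ≥ 0.4
(moderate) and ≥ 0.7 (strong). Steiger's Z compares two dependent
correlations sharing one variable, with the covariance term evaluated at
the back-transformed average correlation; it is validated against a
subject-level permutation oracle.

## Problem sizes and reproducibility

Acceptance-style reproductions average 200 seeded replicate cohorts of 761
subjects (a few seconds); parameter-recovery checks use n=5000; law-of-
large-numbers checks use up to 10⁵ subjects per group. Every stochastic
path is driven by `numpy.random.default_rng` seeds; library calls without a
seed draw one from OS entropy and record it in the output's metadata so the
draw stays auditable. Identical (config, seed) pairs give bit-identical
cohorts and byte-identical validation reports.

## Known limitations

* The generator's independence-within-group default makes the paired
  DeLong comparisons in the validation report conservative relative to real
  batteries, where tests correlate strongly within subject; set
  `within_group_correlation` to exercise the correlated case.
* Bounded-mode scale cohorts draw each component independently, so
  component scores need not sum to the drawn totals; item-level cohorts are
  the consistent path for exercising the scoring engine.
* EFA on 5 items with one two-item factor is intrinsically fragile; results
  near the Heywood boundary should be read through the flags the package
  reports rather than suppressed.
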