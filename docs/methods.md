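# Methods

## Choice model

Each questionnaire item presents two hypothetical treatments A and B,
described by five attributes: chance of OHSS (0/5/10%), number of
daily injections (0/4/20), number of treatments needed to reach a 30%
chance of pregnancy (1–4), chance of cycle cancellation (0/5/10/15%)
and out-of-pocket cost (€0–3000).  Under the random-utility model a
respondent attaches utility U = V + ε to each alternative, with
V = x′β the linear systematic part over coded attribute values and ε
i.i.d. standard Gumbel.  The Gumbel scale is fixed to 1 — the standard
logit identification, since only β/scale is estimable — so the
probability of choosing A in a set is

    P(A) = logistic(V_A − V_B).

With two unlabeled alternatives the conditional logit is exactly a
binary logit on the difference design x_A − x_B; estimation is
Newton–Raphson on the analytic gradient and Hessian (step halving;
convergence at gradient max-norm < 1e-8, at most 200 iterations), with
the covariance taken as the inverse observed information at the
optimum.  Separation is flagged (not silently accepted) when any
coefficient exceeds 50 in magnitude.  A respondent-position constant
for alternative A is supported but off by default: the alternatives
are unlabeled, and simulations accordingly generate choices without
one.

Coding follows the convention that makes coefficients directly
interpretable: OHSS and cancellation per percentage point, pregnancy
per extra treatment, cost per €1000, and injections as dummies against
the 0-injection reference because the injection effect on preference
is non-linear.  `select_coding` automates the usual linearity check
for a multi-level quantitative attribute: both codings are fitted and
continuous coding is kept when its AIC is no worse (the per-level
categorical coefficients are reported alongside so the linearity can
be inspected directly).

McFadden's pseudo R² uses the equal-probability null (ℓ₀ = −n log 2).
With unlabeled paired alternatives, a constant-only model cannot do
better than p = 1/2, making this the natural null; published pseudo R²
values computed under other conventions are therefore not directly
comparable.

## Instrument construction

The full factorial has 3·3·4·4·4 = 576 scenarios.  A fractional design
of the requested size is selected by a greedy member/non-member swap
search minimising an orthogonality penalty: the sum over attributes of
normalised level-count imbalance plus the sum over attribute pairs of
deviation of joint level counts from independence.  The penalty is
zero exactly for a balanced orthogonal array (the full factorial
scores zero), the search is seeded and deterministic, and the result
never scores worse than its random starting subset.  This is a
reproducible, testable stand-in for catalogue-based orthogonal
designs; it does not optimise D-efficiency.

Scenarios are paired uniformly at random into binary sets; pairings
containing a set with identical alternatives are redrawn, because a
choice between identical treatments carries no information.  The
default instrument asks 16 questions: 14 estimation sets from a
28-scenario fraction plus 2 appended dominance sets (32 distinct
scenarios in total).  A dominance set pits the all-favourable-levels
scenario against one drawn from strictly unfavourable levels on every
attribute, so the answer is predictable for any monotone preference;
choosing the dominated option excludes the respondent.  An alternative
construction (`dominance_from_pool=True`) draws the dominance pairs
from within a 32-scenario fraction instead; both conventions produce
16 questions and the choice between them does not affect estimation,
which never uses dominance sets.

The sample-size helper implements the common rule of thumb of 20
respondents per attribute (five attributes → 100).

## Synthetic respondents

The generator's defaults are the study conditions of the motivating
cohort: 120 invited, a 95/120 response rate, 3/95 incomplete
questionnaires, covariate marginals matching the cohort profile (age
discrete-uniform 21–39; a previous cancelled cycle in 37.4%; pregnant
while answering in 12.1%; education, income and current-treatment
shares as reported), and a two-class preference mixture with shares
0.46/0.54 whose class coefficient vectors are the published reference
values.  Careless respondents (default rate 1.5%, chosen so that
about one respondent per cohort fails a dominance test, since a
uniformly random answerer fails at least one of two dominance sets
with probability 3/4) answer every set uniformly at random — one
mechanism explains dominance failures without special-casing dominance
sets.  Covariates are drawn independently: no covariance structure is
reported for the cohort, so none is imposed.  Class membership can
alternatively be linked to covariates through a multinomial-logit
membership link, used to test the membership regressions.

For exact reproduction of the screening cascade (120 → 95 returned →
92 complete → 91 rational) the `exact_counts` fixture rounds the
nonresponse and incompleteness counts deterministically, lets every
attentive respondent pass the dominance tests, and forces a configured
number of respondents (default fixture: one) to pick the dominated
alternative.  Without that fixture the cascade holds in expectation
only.

What the generator does **not** emulate: ordering or learning effects
across the 16 questions, panel correlation beyond class membership
(no random-parameters/mixed logit), item-level missingness patterns
other than respondent-level incompleteness, and any dependence between
covariates and choices except through the optional membership link.
Passing recovery tests therefore show that the estimators are correct
for this data-generating process, not that real questionnaire data
meet its assumptions.

## Latent-class analysis

Preference heterogeneity is a finite mixture: respondent i belongs to
unobserved class k with prior share π_k and answers all of her sets
with that class's β_k, giving

    ℓ = Σ_i log Σ_k π_k Π_t P(choice_it | β_k).

EM alternates posteriors τ_ik ∝ π_k Π_t P_it(β_k) with share updates
π = mean(τ) and τ-weighted logit fits per class.  The M-step runs
warm-started Newton with step halving, which never decreases the
weighted objective, so the procedure is a generalized EM and the
observed log-likelihood is non-decreasing at every iteration (asserted
in tests).  Defaults: 20 seeded random starts (Dirichlet posteriors),
stop at Δℓ < 1e-7, at most 500 iterations; a start whose smallest
share falls below 1/n is discarded as degenerate.  Classes are sorted
by descending share so "class 1" is always the largest.

Model selection reports consistent AIC, −2ℓ + k(ln n + 1), and
sample-size-adjusted BIC, −2ℓ + k ln((n+2)/24), choosing K by cAIC
with ties broken toward the smaller K.  n is the number of
respondents: they, not the choice rows, are the exchangeable units of
the panel mixture.

Standard errors come from the observed information of the full mixture
log-likelihood in (class betas, share log-odds): the analytic mixture
score is differentiated by central finite differences (step
1e-5·(1+|θ|)).  Unlike the naive per-class weighted information, this
accounts for membership uncertainty; share standard errors follow by
the delta method.

Respondents are hard-assigned to their highest-posterior class (ties
to the lower index).  Membership is then related to covariates by
univariate logistic regressions plus one multivariable model limited
to two variables to avoid overfitting on a small sample; age and
previous cycle cancellation are always eligible a priori, any other
variable only when its univariate p < 0.15.  Posterior-weighted
membership regression would propagate assignment uncertainty but is
deliberately not implemented: the hard-assignment convention matches
the analysis this package reproduces.

## Willingness to trade

The numeraire is the OHSS chance, modelled continuously per percentage
point.  For a stated worsening of another attribute the MRS is
|ΔV| / |β_OHSS|, in percentage points of OHSS risk; it is invariant to
the common utility scale.  Uncertainty uses the Krinsky–Robb method:
10,000 seeded draws (default) from N(β̂, Σ̂), the per-draw ratio, and
the 2.5/50/97.5 percentiles (percentile rather than normal-theory
intervals, matching median reporting).  Draws whose OHSS coefficient
is below 1e-8 in magnitude are dropped and counted, with a warning
past 10%.  Slightly negative covariance eigenvalues are floored at
1e-12 with a warning; substantively non-PSD covariances are an error.

The class-probability-weighted variant pools draws across latent
classes: each draw samples a class with probability π̂_k and then a
coefficient vector from that class's sampling distribution; the pooled
ratio distribution gives an "overall" trade-off that acknowledges
heterogeneity.  This is one reasonable definition of a
class-probability adjustment — the point estimate is the share-weighted
mean of per-class ratios — and published tables computed under a
different (unstated) adjustment can differ from raw pooled-coefficient
ratios by a couple of tenths of a point.

## Numerical and testing choices

Tolerances: logit convergence at gradient max-norm 1e-8; EM at Δℓ
1e-7; mixture-likelihood oracle agreement at 1e-10 on tiny instances;
gradient-vs-finite-difference agreement at 1e-6 relative.  Recovery
tests use 3 standard errors of the corresponding fit.  Problem sizes
were chosen as the smallest that make the checks sharp: 800
respondents for single-class coefficient recovery in unit tests, 5,000
for the headline conditional-logit recovery, 4,000 for two-class EM
recovery, 500 replicated studies of 2,000 respondents for
Krinsky–Robb interval coverage (accepted band 92–98% around the
nominal 95%).

Known limitations: no mixed/random-parameters or nested logit, no
choice sets with more than two alternatives or an opt-out, no
D-efficient or Bayesian designs, no blocking across respondents
(everyone answers all 16 sets), no imputation of unanswered sets, and
no concomitant-variable latent-class estimation (membership covariates
enter post hoc only).  The EM covariance ignores the uncertainty of
model selection over K, and finite-mixture share estimates carry a
small finite-sample bias at moderate class separation — visible as a
fraction of a percentage point in the 4,000-respondent recovery runs
and well inside their Monte-Carlo error.
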