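# Methods

This note records the statistical model behind `mrmediate`, the conventions
and defaults it fixes where the literature offers several, and what the
synthetic-data generator does and does not emulate.

## Causal model and estimands

The package analyses a three-node linear structural model on summary
statistics: exposure $X$, mediator $M$, binary (or continuous) outcome $Y$.
Per-variant true associations are

- exposure: $\gamma_j$,
- mediator: $\alpha\,\gamma_j + m_j + \delta_j$ (exposure effect $\alpha$,
  the variant's own mediator effect $m_j$, pleiotropy $\delta_j$),
- outcome (log-odds): $\theta_{dir}\,\gamma_j + \theta_M\,(\text{mediator effect})$.

The estimands are the total effect $TE = \theta_{dir} + \alpha\theta_M$, the
indirect effect $IE = \alpha\theta_M$, and the proportion mediated
$PM = IE/TE$. For binary outcomes all effects are combined on the log-odds
scale and odds ratios are exponentiated only for reporting; whether the
outcome betas of a real study are exactly log-ORs is a data-provenance
question the package cannot settle, so the log-odds interpretation is a
stated assumption.

## Estimators

**IVW.** Weighted least squares of outcome on exposure betas through the
origin, weights $1/\mathrm{se}(\hat\Gamma_j)^2$ (first-order; second-order
weights are available as an option). Fixed-effects SE is
$(\sum w_j \hat\gamma_j^2)^{-1/2}$; the multiplicative-random-effects (MRE)
model — the default, matching common practice for heterogeneous instruments —
multiplies it by $\max(1, \sqrt{Q/(J-1)})$ so that heterogeneity can widen
but never narrow the interval. A single instrument degrades gracefully to
the Wald ratio.

**MR-Egger.** Instruments are oriented so exposure betas are non-negative
(negating both betas of a variant is a no-op of allele coding, and the fit
is invariant to it); WLS with intercept; SEs scaled by
$\max(1, \sqrt{Q_{egger}/(J-2)})$. Because the residual dispersion is
estimated on $J-2$ degrees of freedom, Egger slope and intercept p-values
and CIs use the $t_{J-2}$ reference — the convention of the standard R
implementations — while IVW and the weighted median use the normal
reference. Under the generator's balanced-pleiotropy regime (J = 50,
pleiotropy SD 0.01) the intercept test's measured size at $\alpha=0.05$ is
~0.06 with the $t$ reference versus ~0.07 with the normal one.

**Weighted median.** Per-SNP ratios sorted; the estimate interpolates the
sorted ratios at cumulative standardised weight 0.5 with
$p_j = (S_j - w_j/2)/S_{total}$, $w_j$ the first-order inverse-variance
ratio weights. The SE is the standard deviation over a seeded parametric
bootstrap (default 1000 draws) perturbing both beta vectors by their SEs.
Every stochastic operation in the package takes an explicit seed.

**MVMR.** WLS of outcome betas on the $J \times K$ exposure-beta matrix
without intercept, weights $1/\mathrm{se}(\hat\Gamma_j)^2$; rank-deficient
designs are rejected (no perfect collinearity). SEs are scaled by
$\max(1, \sqrt{Q_A/(J-K)})$. $Q_A$ uses per-variant variances
$\sigma_j^2 = \mathrm{se}(\hat\Gamma_j)^2 + \sum_k \theta_k^2\,
\mathrm{se}(\hat\gamma_{jk})^2$ — the standard second-order form with
cross-terms ignored; the literature names the statistic without fixing a
formula, so this choice is recorded here. The conditional F-statistic for
exposure $k$ regresses its betas on the other exposures' betas (WLS,
weights $1/\mathrm{se}(\hat\gamma_{jk})^2$, no intercept) and divides the
weighted residual sum of squares by $J-(K-1)$; alternative df conventions
differ by $O(1/J)$ and exact parity with any particular toolchain is not
claimed.

## Outlier detection

**Simulation-based (MR-PRESSO-style).** The global statistic is the residual
sum of squares around leave-one-out IVW fits; its null distribution comes
from parametric simulation of both beta vectors (default 1000 draws).
Per-variant squared residuals are compared with their simulated
distributions, Bonferroni-adjusted across $J$, and flagged below
$\alpha = 0.05$. The distortion test compares the estimate shift from
removing the flagged set against shifts from 1000 random removals of the
same size (seeded from the report seed + 1); with no outliers it is reported
as absent. Empirical p-values use the add-one convention $(r+1)/(n_{sim}+1)$,
which avoids zeros and puts them on a fixed grid, making reports bit-exactly
reproducible under a fixed seed.

**Radial.** Per-variant contributions $Q_j = W_j(\hat\theta_j-\hat\theta)^2$
to Cochran's $Q$; with first-order weights the radial slope is algebraically
the fixed-effects IVW slope and $\sum_j Q_j$ equals Cochran's $Q$ (asserted
to 1e-10 in the tests). Modified second-order weights iterate
$W_j = [\mathrm{se}(\hat\Gamma_j)^2/\hat\gamma_j^2 + \hat\theta^2
\mathrm{se}(\hat\gamma_j)^2/\hat\gamma_j^2]^{-1}$ to a $10^{-10}$ fixed
point (cap 100 iterations; non-convergence raises with the iteration
trace). The flagging threshold is the $\chi^2_1$ upper quantile at
Bonferroni-corrected $\alpha = 0.05/J$ by default.

## Clustering of ratio estimates

Each ratio is modelled as drawn from one of $K$ substantive normal
components $N(\mu_k, \mathrm{se}_j^2)$, a null component $N(0,
\mathrm{se}_j^2)$, or a junk component with a flat density over
$[\min\hat\theta - 3\max \mathrm{se},\ \max\hat\theta + 3\max \mathrm{se}]$
— a scale-free heavy alternative; fidelity to any particular published junk
form is not claimed. EM runs over $K = 0..k_{max}$ (default 10) with 20
seeded restarts each (means initialised at ratio quantiles — even quantiles
first, random ones after; mixing proportions Dirichlet-uniform), converging
at absolute log-likelihood change $<10^{-8}$ or 500 iterations; $K$ is
chosen by minimum BIC with $2K+1$ free parameters. Variants are labelled
only when their maximum posterior reaches 0.9 (conservative assignment);
empty clusters are dropped and clusters are ordered by mean for stable
labels. Per-cluster IVW estimates fall back to the Wald ratio for
singletons.

## Mediation arithmetic

The difference-method SE is $\sqrt{se_{TE}^2 + se_{DE}^2}$ and the
product-method (Sobel) SE is $\sqrt{\hat\alpha^2 se_{\theta_M}^2 +
\hat\theta_M^2 se_\alpha^2}$; the PM interval uses the ratio delta method
with the covariance term set to zero. Covariances between the constituent
estimates exist (total and direct share instruments and the outcome sample)
and are deliberately ignored, as in the propagation-of-errors convention;
this is a known limitation that tends to make the difference-method interval
conservative. Step 1 of the product method is the univariable
exposure→mediator estimate (the two-step MR convention); a flag switches to
evaluating it on exactly the instruments entering the joint MVMR design.

## Harmonization and instruments

Allele alignment uses the first exposure's coding as reference; swapped or
strand-complement codings negate the beta and reflect the frequency.
Palindromic (A/T, C/G) variants are dropped when the effect-allele frequency
is within 0.08 of 0.5 in either sample or missing in either sample;
otherwise the strand is inferred from frequency concordance. Rows are sorted
by variant id after harmonization, which makes every downstream estimate
invariant to input row order. Instrument selection keeps variants with
exposure $p < 5\times10^{-8}$; greedy clumping against a user-supplied
$r^2$ matrix keeps the most significant variant per correlated group
(p-value ties broken lexicographically by id, for determinism). Steiger
filtering compares point $R^2 = t^2/(t^2+n-2)$ on the two sides; for binary
traits the same formula is applied on the log-odds scale, a documented
approximation. Proxy substitution is a policy hook over a user-supplied
table (minimum $r^2$ 0.8); no remote LD service is queried.

## The synthetic-data generator

Summary statistics are generated directly at the beta/SE level — no
individual-level genotypes — because every downstream method consumes only
summary data; this keeps a full study simulation in milliseconds. Observed
betas are true effects plus independent $N(0, \mathrm{se}_j)$ noise per
trait, giving exact two-sample non-overlap. SEs follow
$1/\sqrt{2\,\mathrm{MAF}_j(1-\mathrm{MAF}_j)\,N}$, with the binary outcome
scaled by $\sqrt{v(1-v)}$ for case fraction $v$ (logistic-information
approximation). Defaults are the regime the package is designed around:
$\alpha=-0.63$, $\theta_M=0.33$, $\theta_{dir}=-0.18$ (hence $TE=-0.388$,
$PM\approx0.536$), 100 instruments per trait, $N=200{,}000$ per sample,
case fraction 0.5, MAF uniform on $[0.05, 0.5]$. Per-SNP effect SD
defaults to 0.05, i.e. ~0.1% of trait variance per variant at MAF 0.25 and
roughly 12% across 100 instruments — a realistic polygenic architecture for
anthropometric traits, and strong enough that most planted instruments reach
genome-wide significance at the default sample sizes (mean $F \gg 10$).

Directional pleiotropy is applied in the exposure-increasing-allele
orientation (the pleiotropic shift is multiplied by the sign of the
variant's exposure effect): allele coding is arbitrary, so a directional
mean attached to raw coding would be cancelled by estimator orientation and
would not represent directional pleiotropy at all. The balanced case is
distributionally unchanged by this convention. InSIDE holds by default
(pleiotropy independent of effect magnitude); `pleiotropy_gamma_corr`
correlates them to stress-test Egger. Reverse-causal variants act on the
outcome directly and induce exposure associations scaled by
`reverse_effect`; with a binary outcome and equal sample sizes the outcome's
larger SE cancels an induced-effect ratio of 0.5, so fixtures probing
Steiger use `reverse_effect = 0.25`, where the outcome side dominates for
any variant strong enough to be selected as an exposure instrument.

What the generator does **not** emulate: linkage disequilibrium (instruments
are independent; clumping is exercised against synthetic LD matrices),
sample overlap between the three studies, allele-frequency mismatch between
samples, non-collapsibility of the odds ratio and other
logistic-scale subtleties (effects are composed linearly on log-odds), and
winner's-curse-inducing discovery designs beyond simple thresholding.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the stated model, not robustness to every artefact of real
GWAS data.

## Numerical and reporting choices

Text round-trips serialise floats at 12 significant digits; the reader
treats `NA` (any case) and empty fields as missing frequencies and drops
rows violating record invariants, reporting the count. Degenerate inputs:
an all-zero exposure-beta vector, fewer instruments than an estimator's
minimum (2 for IVW/Q, 3 for Egger/median/radial/clustering, 4 for the
simulation-based outlier test, $K+1$ for MVMR) and rank-deficient MVMR
designs raise typed errors rather than returning artefacts. Pipeline JSON
output rounds floats to 10 decimal places and sorts keys, so identical
seeds and configs produce byte-identical reports. Simulation sizes in the
test suite (e.g. 100-200 replicates for Monte-Carlo recovery checks, 2000
for the Egger size check) were chosen to keep Monte-Carlo error comfortably
inside the asserted margins while running the whole suite in about two
minutes on a single core.
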