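# Methods

## Model

For subject $i = 1,\dots,n$ and node pair $j = 1,\dots,m$, the observed
Fisher-transformed Pearson correlation $Z_{ij}$ between the BOLD signals of
the pair's two nodes is modelled as a two-component mixture indexed by a
latent connection indicator $W_{ij}$:

$$
\begin{aligned}
Z_{ij} \mid W_{ij}=1 &\sim \mathrm{lN}\!\left(x_i\alpha + a_i,\ \sigma_{1i}^2\right),\\
Z_{ij} \mid W_{ij}=0 &\sim \mathrm{N}\!\left(\mu_{0i},\ \sigma_{0i}^2\right),\\
P(W_{ij}=1 \mid d_i) &= \Phi\!\left(x_i\delta + d_i\right),\\
a_i \sim \mathrm{N}(0, \gamma_a^2),&\qquad d_i \sim \mathrm{N}(0, \gamma_d^2),
\end{aligned}
$$

where $x_i$ is the subject's covariate row (intercept first), $\Phi$ is the
standard normal CDF, and $\mathrm{lN}(\mu, \sigma^2)$ denotes the lognormal
distribution whose logarithm has mean $\mu$ and variance $\sigma^2$.
Conditional on the random effects and covariates, observations are
independent across subjects and pairs.

The component supports encode the scientific assumptions:

* the **connected** component is lognormal on the positive half-line —
  only positive correlations can represent reliable connections, so the
  posterior probability of connection is *identically zero* at $z \le 0$;
* the **non-connected** component is normal with mean near zero, absorbing
  spurious, weak and negative associations (its mean is free to drift
  slightly off zero to accommodate shifts induced by global-signal
  regression during preprocessing);
* because the supports differ, the mixture has no label-switching
  ambiguity and needs no identifiability constraints.

The headline inferential quantity is the posterior probability of
connection,

$$
P(W_{ij}=1 \mid Z_{ij}=z)
 = \frac{\pi_i f_{\mathrm{lN}}(z;\, x_i\alpha + a_i, \sigma^2_{1i})}
        {\pi_i f_{\mathrm{lN}}(z;\,\cdot) + (1-\pi_i) f_{\mathrm{N}}(z;\, \mu_{0i}, \sigma^2_{0i})},
 \qquad \pi_i = \Phi(x_i\delta + d_i),
$$

estimated by its posterior mean over MCMC draws (a Rao-Blackwellized
average of the analytic formula rather than a frequency of sampled 0/1
labels; the two estimators agree within Monte-Carlo error and the former
has lower variance). It is a *within-subject standardized* connectivity
measure: subjects with different overall connectivity map the same
correlation to different probabilities.

## Priors

* $\alpha, \delta$: independent $\mathrm{N}(0, 10^4)$ per coordinate. These
  emulate non-informative priors while keeping every full conditional
  proper and conjugate.
* $\mu_{0i}$: $\mathrm{N}(0, 1)$, zero-centered; the variance is
  configurable (`PriorSpec.mu0_prior_var`).
* All variance components ($\sigma_{0i}^2, \sigma_{1i}^2, \gamma_a^2,
  \gamma_d^2$): inverse-gamma $\mathrm{I}\Gamma(1.5, 10^{-3})$ in the
  shape/rate parameterization with density $\propto
  x^{-\text{shape}-1} e^{-\text{rate}/x}$ — stated explicitly because IG
  conventions differ. This is a proper, conditionally conjugate prior.

## Gibbs sampler

All unknowns have conjugate full conditionals; one systematic scan updates

1. **Labels** $W_{ij} \sim \mathrm{Bernoulli}\!\left(\pi_i f_1 / (\pi_i f_1 +
   (1-\pi_i) f_0)\right)$, computed in log space with probabilities clamped
   to $[10^{-300}, 1-10^{-16}]$; $W = 0$ with probability one at $z \le 0$.
2. **Probit block** via Albert–Chib augmentation: latent scores
   $u_{ij} \sim \mathrm{N}(x_i\delta + d_i, 1)$ truncated to $(0,\infty)$
   if $w_{ij}=1$, else $(-\infty, 0]$; then $\delta$, the $d_i$, and
   $\gamma_d^2 \sim \mathrm{I}\Gamma(1.5 + n/2,\ 10^{-3} + \sum d_i^2/2)$.
3. **Lognormal block** on the working response $y_{ij} = \log z_{ij}$ of
   the currently connected pairs: $\alpha$, the $a_i$,
   $\sigma_{1i}^2 \sim \mathrm{I}\Gamma(1.5 + k_i/2,\ 10^{-3} +
   \mathrm{RSS}_i/2)$ with $k_i$ the subject's connected count (a subject
   with $k_i = 0$ draws from the prior), and $\gamma_a^2$.
4. **Non-connected block**: $\mu_{0i}$ and $\sigma_{0i}^2$ from the
   normal–inverse-gamma conditionals on the currently non-connected pairs.

Two numerical choices matter in practice:

* **Partially collapsed fixed-effect updates.** $\delta$ is drawn from its
  conditional with the $d_i$ integrated out (each subject contributes
  $\bar u_i \sim \mathrm{N}(x_i\delta,\ \gamma_d^2 + 1/m)$), after which the
  $d_i$ are redrawn from their exact conditionals; the same collapse is
  applied to $\alpha$ over $\bar y_i \sim \mathrm{N}(x_i\alpha,\ \gamma_a^2
  + \sigma_{1i}^2/k_i)$. The pair of draws is an exact joint draw from
  $p(\alpha, a \mid \text{rest})$. Without the collapse, the centered scan
  random-walks the fixed effects against the subject effects and fixed-
  effect chains mix an order of magnitude more slowly.
* **Tail-safe truncated normals.** Half-line truncated normals use an
  inverse-CDF transform through the survival function,
  $t = -\Phi^{-1}\!\left(U\,\Phi(\eta)\right)$ for the positive side, which
  stays exact deep in the tail where the naive CDF inversion saturates.

Scan order is fixed (labels, probit, lognormal, non-connected), so runs are
bit-reproducible from the seed; per-chain seeds are spawned from the single
user seed via `numpy.random.SeedSequence`. Defaults: 2 chains, 10,000
iterations, 5,000 burn-in, thinning 5 — all configurable; the small
simulation studies in the tests use shorter, ESS-checked chains.
Initialization is moment-based: pairs above the subject's 90th percentile
(and positive) seed the connected set, components get moment estimates,
random effects start at zero; variances are floored at $10^{-6}$.

### Sampler validation

* **Conjugacy oracles**: each block's draws are compared, on 5-point
  instances, against independently derived conjugate posteriors (exact
  normal moments; inverse-gamma shape $1.5 + k/2$ verified through inverse
  moments with location parameters pinned).
* **Exactness of the label sampler**: on a 2-subject, 6-pair instance with
  all continuous parameters fixed, Gibbs label frequencies match exhaustive
  enumeration over all $2^6$ configurations within 3 Monte-Carlo SE.
* **Joint-distribution ("getting it right") test**: alternating one Gibbs
  sweep with a fresh data draw leaves the prior invariant; chain moments of
  all parameter blocks match closed-form prior moments within 4 SE (3
  subjects × 30 pairs, 2,000 sweeps). This test uses a moderate proper
  prior ($\mathrm{I}\Gamma(3,2)$, coefficient variance 0.5) because the
  analysis default $\mathrm{I}\Gamma(1.5, 10^{-3})$ has infinite variance
  and near-improper coefficient scale, making prior-moment comparison
  ill-posed; the code path is identical for any `PriorSpec`.
* **Recovery/coverage**: data simulated at $n=40$, $m=1000$ with known
  fixed effects and $\gamma_a^2 = \gamma_d^2 = 0.04$ are refit 20 times;
  the nominal 95% credible intervals cover the truth for 17–19 of 20
  replicates per coefficient. Coverage slightly below nominal for the
  probit intercept is expected frequentist behavior of Bayesian intervals
  at a fixed truth with 40 subjects and is not treated as a defect.

## Inference layers

* **Population**: equal-tailed credible intervals for $\alpha$ and
  $\delta$ from empirical quantiles; a covariate is flagged when its
  interval excludes zero.
* **Subject**: posterior mean and interval of
  $\sum_j W_{ij}/m$ from the stored label draws — the subject's proportion
  of connected pairs.
* **Node pair**: mass-univariate OLS of the posterior-mean connection
  probabilities (or, for comparison, the Fisher-z values) on the
  covariates, one regression per pair, with classical two-sided t-tests
  and Bonferroni correction at $\alpha/m$. Only Bonferroni is implemented,
  and p-values are classical by default; an optional Huber robust-
  regression flag exists because a handful of high-probability outliers
  can drive significance when most probabilities sit near zero.
* **Three-component check**: a maximum-likelihood EM fit (multiple
  restarts, closed-form weighted M-steps) of normal + positive lognormal
  + *mirrored* lognormal (density $f_{\mathrm{lN}}(-z)$ on $z<0$) probes
  for an anticorrelated component; its estimated weight near zero supports
  the two-component model.

## Sparsification and validation metrics

Seven rules are compared (`abs_corr`, `abs_pp`, `mixture_pfdr`,
`prop5_corr`, `prop5_pp`, `prop10_corr`, `prop10_pp`):

* **absolute**: value $>$ cutoff, default $10^{-6}$ as a numerically safe
  stand-in for zero; the inequality is strict.
* **proportional**: top $\lfloor \text{fraction} \cdot m \rfloor$ values
  per subject at the 5% and 10% levels; ties broken by pair-index order.
* **pseudo-FDR**: per-subject cutoff $t_i^*$, the smallest $t$ on the grid
  of the subject's sorted positive $z$ (plus 0) with

  $$\mathrm{pFDR}_i(t) = \frac{(1-\hat\pi_i)(1-F_0(t))}
      {(1-\hat\pi_i)(1-F_0(t)) + \hat\pi_i (1-F_1(t))} \le q,$$

  using the model-based tail masses of the fitted components at their
  posterior means ($q = 0.05$ default). The data-adaptive grid guarantees
  an achievable cutoff; $\hat\pi_i = 0$ yields an empty network
  (maximally conservative). The model-based (rather than empirical-tail)
  definition is a recorded design choice.

Directed truth matrices are symmetrized by OR before pair extraction, and
diagonals are discarded, because the model lives on unordered pairs.
TPR, FPR, PPV and accuracy are computed per subject and averaged
unweighted ("mean performance" is the accuracy average); PPV is reported
as missing and excluded from the average when a subject has no predicted
positives, with a count of affected subjects.

## Synthetic-data generator

Two generators are provided. `simulate_dataset` draws from the generative
model itself and is used for calibration studies. For the validation
study, `simulate_ground_truth_study` plants per-subject binary truth
networks with exact edge counts `round(density * m)` (density 2–16% across
subjects in the shipped studies, matching the heterogeneity the model is
designed to handle) and draws $z$ from the connected lognormal component
for true edges (population log-scale mean $-0.7$, log-scale SD $0.5$,
per-subject mean shifts of SD $0.2$) and from a tight
$\mathrm{N}(0, 0.1^2)$ otherwise.

What the generator does *not* emulate: BOLD time series, spatial/temporal
autocorrelation between node pairs of the same node, and dynamic-causal
structure — the original validation data were produced by a DCM-based
simulator, and this package deliberately substitutes mixture-structured
values with known labels. Passing tests therefore certify the estimator
and the thresholding machinery under the model's own assumptions (plus
exact-count truth networks, a mild misspecification of the Bernoulli
labels), not robustness to realistic fMRI artifacts.

## Problem sizes and defaults in the shipped studies

The studies run by the tests and by `scripts/acceptance.py` use 50
subjects × 50 nodes (1,225 pairs) for the validation comparison and 40
subjects × 1,000 pairs for recovery, with chains of 400–2,400 iterations
chosen so that bulk ESS of the fixed effects exceeds several hundred
(verified via the split-R-hat/ESS diagnostics). These sizes exercise every
code path at desk scale; a full-cohort analysis (hundreds of subjects,
36,585 pairs) uses the same code with the default chain settings.

## Known limitations

* Negative connectivity is absorbed by the non-connected component; the
  model cannot represent a genuine anticorrelated class (the
  three-component ML fit exists precisely to check this assumption).
* Fisher-z values are treated as conditionally independent given the
  random effects; shared-node dependence between pairs is ignored.
* The pseudo-FDR rule inherits plug-in error from the posterior-mean
  component parameters; it controls the model-implied FDR, not the exact
  frequentist FDR under misspecification.
* Label-draw storage (`store_w`) costs S × n × m bytes and can be disabled
  at the price of losing subject-level proportion inference.
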