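"""Population-, subject- and node-pair-level inference from posterior draws.

The headline quantity is the posterior probability of connection

    P(W_ij = 1 | Z_ij = z) =
        pi_i f_lN(z; x_i alpha + a_i, sigma1_i^2)
        / [ pi_i f_lN(z; ...) + (1 - pi_i) f_N(z; mu0_i, sigma0_i^2) ],

with pi_i = Phi(x_i delta + d_i), evaluated per retained draw and averaged
(a Rao-Blackwellized estimate with lower Monte-Carlo variance than the
stored 0/1 labels).  It is exactly zero for z <= 0 and is a within-subject
standardized measure: the same correlation can map to very different
posterior probabilities for subjects with different overall connectivity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ConnectivityDataset, CovariateTable
from .gibbs import PosteriorDraws, connection_probability
from .model import lognormal_logpdf

__all__ = [
    "PPMatrix",
    "PosteriorSummary",
    "posterior_probability",
    "subject_connection_proportion",
    "population_credible_intervals",
    "nodepair_regression",
    "ThreeComponentFit",
    "fit_three_component_ml",
    "fit_two_component_ml",
    "posterior_mean_subject_params",
]


@dataclasses.dataclass
class PPMatrix:
    """Posterior-mean connection probabilities, aligned with a dataset."""

    values: np.ndarray                    # (n, m) in [0, 1]
    subject_ids: list[str]
    pair_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")


@dataclasses.dataclass
class PosteriorSummary:
    """Posterior mean/median and equal-tailed credible interval per
    coefficient; ``significant`` marks intervals excluding zero."""

    table: pd.DataFrame
    level: float


def posterior_probability(
    data: ConnectivityDataset,
    covariates: CovariateTable,
    draws: PosteriorDraws,
) -> PPMatrix:
    """Average P(W_ij=1 | z_ij) over all retained draws."""
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    if data.n_subjects != len(draws.subject_ids):
        raise ValueError("draws were fitted on a different number of subjects")
    acc = np.zeros_like(data.z)
    for s in range(draws.n_draws):
        acc += connection_probability(data, draws.parameters_at(s), covariates)
    acc /= draws.n_draws
    acc[data.z <= 0] = 0.0
    return PPMatrix(acc, list(data.subject_ids), list(data.pair_index))


def subject_connection_proportion(
    draws: PosteriorDraws, level: float = 0.95
) -> pd.DataFrame:
    """Posterior mean and credible interval of the per-subject fraction of
    connected pairs, sum_j W_ij / m."""
    if draws.w_draws is None:
        raise ValueError(
            "label draws were not stored; re-run the sampler with store_w=True"
        )
    props = draws.w_draws.mean(axis=2)  # (S, n)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return pd.DataFrame({
        "subject": draws.subject_ids,
        "mean": props.mean(axis=0),
        "lower": np.quantile(props, lo, axis=0),
        "upper": np.quantile(props, hi, axis=0),
    })


def population_credible_intervals(
    draws: PosteriorDraws, level: float = 0.95
) -> PosteriorSummary:
    """Equal-tailed credible intervals for the fixed effects alpha, delta.

    A coefficient is flagged significant when its interval excludes zero —
    the population-level test of whether a covariate relates to connection
    strength (alpha) or the proportion of connections (delta).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    import warnings

    if draws.n_draws < 2 / (1 - level):
        warnings.warn(
            f"only {draws.n_draws} draws: {level:.0%} interval endpoints are "
            "extrapolated empirical quantiles", stacklevel=2,
        )
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for block, arr in (("alpha", draws.alpha), ("delta", draws.delta)):
        for k, name in enumerate(draws.covariate_names):
            col = arr[:, k]
            lower, upper = np.quantile(col, [lo, hi])
            rows.append({
                "parameter": f"{block}[{name}]",
                "mean": col.mean(),
                "median": float(np.median(col)),
                "lower": lower,
                "upper": upper,
                "significant": bool(lower > 0 or upper < 0),
            })
    return PosteriorSummary(pd.DataFrame(rows), level)


def nodepair_regression(
    response: PPMatrix | np.ndarray,
    covariates: CovariateTable,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    robust: bool = False,
) -> pd.DataFrame:
    """Mass-univariate OLS of a per-pair response on the covariates.

    Fits one linear regression per node pair (response across subjects),
    returning a long table with estimate, two-sided t-test p-value and a
    Bonferroni significance flag at level ``alpha / m``.  Run on posterior
    probabilities for the model-based analysis or on Fisher-z values for
    the correlation-based comparison.  ``robust`` switches to Huber
    M-estimation (slower; one model per pair).
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    y = response.values if isinstance(response, PPMatrix) else np.asarray(response)
    y = np.atleast_2d(y.astype(float))
    x = covariates.x
    n, m = y.shape
    p = x.shape[1]
    if n <= p + 1:
        raise ValueError("need n_subjects > n_covariates + 1 for the t-test")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("covariate design matrix is rank-deficient")
    threshold = alpha / m
    if robust:
        import statsmodels.api as sm

        rows = []
        for j in range(m):
            fit = sm.RLM(y[:, j], x, M=sm.robust.norms.HuberT()).fit()
            for k, name in enumerate(covariates.names):
                pv = float(fit.pvalues[k])
                rows.append({"pair": j, "covariate": name,
                             "estimate": float(fit.params[k]), "p": pv,
                             "significant": pv < threshold})
        return pd.DataFrame(rows)

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)                    # (p, m)
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof          # (m,)
    # a numerically constant response carries no evidence about any covariate
    scale = np.maximum(np.abs(y).max(axis=0), 1.0)
    sigma2 = np.where(sigma2 < (1e-12 * scale) ** 2, 0.0, sigma2)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.where(se > 0, pvals, 1.0)           # constant response: no evidence
    out = pd.DataFrame({
        "pair": np.repeat(np.arange(m), p),
        "covariate": np.tile(covariates.names, m),
        "estimate": beta.T.ravel(),
        "p": pvals.T.ravel(),
    })
    out["significant"] = out["p"] < threshold
    return out


def posterior_mean_subject_params(
    draws: PosteriorDraws, covariates: CovariateTable
) -> dict[str, np.ndarray]:
    """Posterior means of the per-subject mixture ingredients.

    Returns ``pi`` (mixing probability), ``mu1`` (connected log-scale
    mean), ``sigma1_sq``, ``mu0`` and ``sigma0_sq``, each of length n —
    the plug-in quantities needed by model-based sparsification rules.
    """
    x = covariates.x
    pi = np.zeros(x.shape[0])
    mu1 = np.zeros(x.shape[0])
    for s in range(draws.n_draws):
        pi += stats.norm.cdf(x @ draws.delta[s] + draws.d[s])
        mu1 += x @ draws.alpha[s] + draws.a[s]
    return {
        "pi": pi / draws.n_draws,
        "mu1": mu1 / draws.n_draws,
        "sigma1_sq": draws.sigma1_sq.mean(axis=0),
        "mu0": draws.mu0.mean(axis=0),
        "sigma0_sq": draws.sigma0_sq.mean(axis=0),
    }


# ---------------------------------------------------------------------------
# Three-component maximum-likelihood check
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ThreeComponentFit:
    """ML fit of normal + positive-lognormal + mirrored-lognormal mixture.

    ``weights`` is (w_neg, w_zero, w_pos); the mirrored component has
    density f_lN(-z) on z < 0 and probes for a genuine anticorrelated
    component in the data.
    """

    weights: tuple[float, float, float]
    mu0: float
    sigma0_sq: float
    mu_pos: float
    sigma_pos_sq: float
    mu_neg: float
    sigma_neg_sq: float
    loglik: float
    converged: bool
    n_iter: int


def _mixture_logliks(z, fit_weights, comps):
    """Stack component log-densities weighted in log space."""
    parts = []
    for wgt, logpdf in zip(fit_weights, comps):
        if wgt <= 0:
            parts.append(np.full_like(z, -np.inf))
        else:
            parts.append(np.log(wgt) + logpdf)
    return np.logaddexp.reduce(np.stack(parts), axis=0)


def _em_three_component(z, w_init, theta_init, max_iter, tol, fix_neg_zero):
    n = len(z)
    neg, pos = z < 0, z > 0
    lz = np.where(pos, np.log(np.where(pos, z, 1.0)), 0.0)
    lnz = np.where(neg, np.log(np.where(neg, -z, 1.0)), 0.0)
    w = np.array(w_init, dtype=float)
    mu0, s0, mup, sp, mun, sn = theta_init

    def joint_logdens(w, theta):
        mu0, s0, mup, sp, mun, sn = theta
        log_comp = np.stack([
            lognormal_logpdf(-z, mun, sn),
            stats.norm.logpdf(z, mu0, np.sqrt(s0)),
            lognormal_logpdf(z, mup, sp),
        ])
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
        return logw[:, None] + log_comp

    ll_old = -np.inf
    converged = False
    for it in range(max_iter):
        joint = joint_logdens(w, (mu0, s0, mup, sp, mun, sn))
        norm = np.logaddexp.reduce(joint, axis=0)
        resp = np.nan_to_num(np.exp(joint - norm))
        # M-step (all closed-form weighted estimates)
        nk = resp.sum(axis=1)
        w = nk / n
        if fix_neg_zero:
            w[0] = 0.0
            w = w / w.sum()
        mu0 = float((resp[1] * z).sum() / max(nk[1], 1e-12))
        s0 = max(float((resp[1] * (z - mu0) ** 2).sum() / max(nk[1], 1e-12)), 1e-10)
        if nk[2] > 1e-8:
            mup = float((resp[2] * lz).sum() / nk[2])
            sp = max(float((resp[2] * (lz - mup) ** 2).sum() / nk[2]), 1e-10)
        if not fix_neg_zero and nk[0] > 1e-8:
            mun = float((resp[0] * lnz).sum() / nk[0])
            sn = max(float((resp[0] * (lnz - mun) ** 2).sum() / nk[0]), 1e-10)
        ll = float(np.logaddexp.reduce(
            joint_logdens(w, (mu0, s0, mup, sp, mun, sn)), axis=0).sum())
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return w, (mu0, s0, mup, sp, mun, sn), ll_old, converged, it + 1


def _fit_mixture_ml(z, n_components, n_restarts, max_iter, tol, seed):
    z = np.asarray(z, dtype=float)
    if len(z) < 50:
        raise ValueError("need at least 50 observations per subject")
    rng = np.random.default_rng(seed)
    fix_neg = n_components == 2
    best = None
    for r in range(n_restarts):
        q = rng.uniform(0.75, 0.95)
        cut = np.quantile(z, q)
        pos_tail = z[(z > cut) & (z > 0)]
        neg_tail = -z[(z < np.quantile(z, 0.02)) & (z < 0)]
        body = z[z <= cut]
        w_neg0 = 0.0 if fix_neg else 0.02 + 0.03 * rng.random()
        w_pos0 = float(np.clip(len(pos_tail) / len(z), 0.02, 0.4))
        w0 = np.array([w_neg0, 1.0 - w_neg0 - w_pos0, w_pos0])
        theta0 = (
            float(body.mean()), max(float(body.var()), 1e-4),
            float(np.log(pos_tail).mean()) if len(pos_tail) else -1.0,
            max(float(np.log(pos_tail).var()), 0.05) if len(pos_tail) > 1 else 0.25,
            float(np.log(neg_tail).mean()) if len(neg_tail) else -1.5,
            max(float(np.log(neg_tail).var()), 0.05) if len(neg_tail) > 1 else 0.25,
        )
        w, theta, ll, conv, nit = _em_three_component(
            z, w0, theta0, max_iter, tol, fix_neg
        )
        if best is None or ll > best[2]:
            best = (w, theta, ll, conv, nit)
    w, theta, ll, conv, nit = best
    return ThreeComponentFit(
        weights=(float(w[0]), float(w[1]), float(w[2])),
        mu0=theta[0], sigma0_sq=theta[1],
        mu_pos=theta[2], sigma_pos_sq=theta[3],
        mu_neg=theta[4], sigma_neg_sq=theta[5],
        loglik=ll, converged=conv, n_iter=nit,
    )


def fit_three_component_ml(
    z: np.ndarray,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> ThreeComponentFit:
    """EM fit of the three-component mixture for one subject's z vector.

    Adds to the two-component model a lognormal mirrored onto the negative
    axis, testing whether the data support an anticorrelated component.
    Multiple restarts guard against local optima; the best fit found is
    returned with a convergence status.
    """
    return _fit_mixture_ml(z, 3, n_restarts, max_iter, tol, seed)


def fit_two_component_ml(
    z: np.ndarray,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> ThreeComponentFit:
    """Same ML machinery with the mirrored component weight fixed at zero."""
    return _fit_mixture_ml(z, 2, n_restarts, max_iter, tol, seed)
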