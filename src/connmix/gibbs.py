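"""Gibbs sampler for the hierarchical normal/lognormal mixture.

Every full conditional is conjugate:

* the latent labels ``W`` are Bernoulli with the posterior odds
  ``pi f1 / ((1-pi) f0)`` computed in log space (``W = 0`` with probability
  one at ``z <= 0``, where the lognormal density vanishes);
* the probit part uses Albert–Chib data augmentation — a latent Gaussian
  score ``u ~ N(x_i delta + d_i, 1)`` truncated to the half-line matching
  ``w`` — after which ``delta`` and the ``d_i`` are ordinary normal
  regressions;
* ``alpha``, the ``a_i`` and ``mu0_i`` are normal regressions on the
  component-labelled observations (working response ``log z`` in the
  connected component);
* all variances get inverse-gamma updates, e.g.
  ``sigma1_i^2 ~ IG(shape + k_i/2, rate + RSS_i/2)`` with ``k_i`` the
  number of connected pairs of subject ``i``.

The scan order is fixed (W, probit block, lognormal block, non-connected
block) so runs are bit-reproducible from the seed.  No label switching can
occur: the component supports differ, so the "connected" label is anchored
to the positive half-line.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .datamodel import ConnectivityDataset, CovariateTable
from .model import (
    LatentState,
    MixtureParameters,
    PriorSpec,
    _stacked_logdensities,
    observed_loglik,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "initialize",
    "sample_truncated_normal",
    "sample_w",
    "sample_probit_block",
    "sample_lognormal_block",
    "sample_nonconnected_block",
    "gibbs_sweep",
    "run_chain",
    "diagnostics",
    "draws_from_dataframe",
]

_VAR_FLOOR = 1e-12


@dataclasses.dataclass
class MCMCConfig:
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 5
    n_chains: int = 2
    seed: int = 0
    init_strategy: str = "moment_based"
    store_w: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.init_strategy not in ("moment_based", "prior_draw", "user_supplied"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclasses.dataclass
class PosteriorDraws:
    """Retained (post burn-in, thinned) draws from one or more chains.

    Parameter draws are stacked chain-major: draw ``s`` belongs to chain
    ``chain_ids[s]``.  ``w_draws`` (optional) stores the binary labels per
    retained draw for subject-level inference.
    """

    alpha: np.ndarray          # (S, p_cov)
    delta: np.ndarray          # (S, p_cov)
    a: np.ndarray              # (S, n)
    d: np.ndarray              # (S, n)
    mu0: np.ndarray            # (S, n)
    sigma0_sq: np.ndarray      # (S, n)
    sigma1_sq: np.ndarray      # (S, n)
    gamma_a_sq: np.ndarray     # (S,)
    gamma_d_sq: np.ndarray     # (S,)
    chain_ids: np.ndarray      # (S,)
    loglik: np.ndarray         # (n_chains, n_iterations) observed loglik trace
    config: MCMCConfig
    covariate_names: list[str]
    subject_ids: list[str]
    w_draws: np.ndarray | None = None  # (S, n, m) int8

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1 if self.n_draws else 0

    def parameters_at(self, s: int) -> MixtureParameters:
        return MixtureParameters(
            alpha=self.alpha[s], delta=self.delta[s], a=self.a[s], d=self.d[s],
            mu0=self.mu0[s], sigma0_sq=self.sigma0_sq[s],
            sigma1_sq=self.sigma1_sq[s],
            gamma_a_sq=float(self.gamma_a_sq[s]),
            gamma_d_sq=float(self.gamma_d_sq[s]),
        )

    def scalar_names(self) -> list[str]:
        names = []
        names += [f"alpha[{c}]" for c in self.covariate_names]
        names += [f"delta[{c}]" for c in self.covariate_names]
        for field in ("a", "d", "mu0", "sigma0_sq", "sigma1_sq"):
            names += [f"{field}[{s}]" for s in self.subject_ids]
        names += ["gamma_a_sq", "gamma_d_sq"]
        return names

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to one row per retained draw, one column per scalar."""
        cols = np.column_stack([
            self.alpha, self.delta, self.a, self.d, self.mu0,
            self.sigma0_sq, self.sigma1_sq,
            self.gamma_a_sq[:, None], self.gamma_d_sq[:, None],
        ])
        df = pd.DataFrame(cols, columns=self.scalar_names())
        df.insert(0, "chain", self.chain_ids)
        return df

    def by_chain(self) -> dict[str, np.ndarray]:
        """Reshape each parameter to (n_chains, draws_per_chain, ...)."""
        out: dict[str, np.ndarray] = {}
        n_chains = self.n_chains
        per = self.n_draws // n_chains
        for name in ("alpha", "delta", "a", "d", "mu0", "sigma0_sq",
                     "sigma1_sq", "gamma_a_sq", "gamma_d_sq"):
            arr = getattr(self, name)
            out[name] = arr.reshape((n_chains, per) + arr.shape[1:])
        return out


def draws_from_dataframe(df: pd.DataFrame, config: MCMCConfig | None = None) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from its flattened table form.

    The inverse of :meth:`PosteriorDraws.to_dataframe`; the observed
    log-likelihood trace and label draws are not part of the table and come
    back empty/absent.
    """
    cov_names = [c[len("alpha["):-1] for c in df.columns if c.startswith("alpha[")]
    subj = [c[len("mu0["):-1] for c in df.columns if c.startswith("mu0[")]
    chain_ids = df["chain"].to_numpy(dtype=int) if "chain" in df else np.zeros(len(df), dtype=int)

    def block(prefix, labels):
        return df[[f"{prefix}[{lab}]" for lab in labels]].to_numpy(dtype=float)

    return PosteriorDraws(
        alpha=block("alpha", cov_names), delta=block("delta", cov_names),
        a=block("a", subj), d=block("d", subj), mu0=block("mu0", subj),
        sigma0_sq=block("sigma0_sq", subj), sigma1_sq=block("sigma1_sq", subj),
        gamma_a_sq=df["gamma_a_sq"].to_numpy(dtype=float),
        gamma_d_sq=df["gamma_d_sq"].to_numpy(dtype=float),
        chain_ids=chain_ids,
        loglik=np.empty((0, 0)),
        config=config or MCMCConfig(seed=0),
        covariate_names=cov_names,
        subject_ids=subj,
    )


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------


def sample_truncated_normal(
    mean: np.ndarray, positive: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(mean, 1) truncated to (0, inf) where ``positive`` else
    (-inf, 0], by tail-safe inverse-CDF transform.

    For the positive half-line the standardized draw is
    ``t = -ndtri(U * Phi(mean))`` with ``U ~ Uniform(0,1)``, which stays
    accurate deep in the tail because the argument of ``ndtri`` is a small
    survival mass rather than a value near one.
    """
    mean = np.asarray(mean, dtype=float)
    u01 = rng.random(mean.shape)
    # positive side: t | t > -mean via survival-function inversion
    arg_pos = np.clip(u01 * ndtr(mean), 1e-300, None)
    out_pos = mean - ndtri(arg_pos)
    # negative side: mirror image
    arg_neg = np.clip(u01 * ndtr(-mean), 1e-300, None)
    out_neg = mean + ndtri(arg_neg)
    out = np.where(positive, out_pos, out_neg)
    # guard against the ~1e-16 rounding window where ndtr saturates at 1
    out = np.where(positive, np.maximum(out, 1e-12), np.minimum(out, 0.0))
    return out


def _sample_inverse_gamma(shape, rate, rng: np.random.Generator):
    """IG(shape, rate) with density ~ x**(-shape-1) exp(-rate/x)."""
    return 1.0 / rng.gamma(np.asarray(shape, dtype=float),
                           1.0 / np.asarray(rate, dtype=float))


def _sample_mvn_from_precision(
    precision: np.ndarray, linear: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(precision^-1 linear, precision^-1) via Cholesky."""
    chol = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, linear)
    noise = np.linalg.solve(chol.T, rng.standard_normal(len(linear)))
    return mean + noise


# ---------------------------------------------------------------------------
# Full-conditional blocks
# ---------------------------------------------------------------------------


def sample_w(
    data: ConnectivityDataset,
    params: MixtureParameters,
    covariates: CovariateTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the labels from P(W=1 | z) = pi f1 / (pi f1 + (1-pi) f0).

    Computed in log space; exactly zero at z <= 0.
    """
    p1 = connection_probability(data, params, covariates)
    return (rng.random(p1.shape) < p1).astype(np.int8)


def connection_probability(
    data: ConnectivityDataset,
    params: MixtureParameters,
    covariates: CovariateTable,
) -> np.ndarray:
    """(n, m) matrix of P(W_ij = 1 | z_ij) under one parameter set."""
    logf0, logf1, logpi, log1mpi = _stacked_logdensities(data, covariates, params)
    with np.errstate(invalid="ignore"):
        diff = (logpi[:, None] + logf1) - (log1mpi[:, None] + logf0)
    p1 = expit(diff)
    p1 = np.clip(p1, 1e-300, 1.0 - 1e-16)
    p1[data.z <= 0] = 0.0
    return p1


def sample_probit_block(
    w: np.ndarray,
    covariates: CovariateTable,
    delta: np.ndarray,
    d: np.ndarray,
    gamma_d_sq: float,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Albert–Chib update of (u, delta, d, gamma_d_sq)."""
    x = covariates.x
    n, m = w.shape
    eta = (x @ delta + d)[:, None]
    u = sample_truncated_normal(np.broadcast_to(eta, (n, m)), w == 1, rng)
    # (delta, d) drawn jointly: delta from its conditional with d integrated
    # out (ubar_i ~ N(x_i delta, gamma_d^2 + 1/m)), then d | delta, u.  The
    # collapsed draw decouples the fixed effect from the subject effects and
    # is what makes the chain mix on delta.
    ubar = u.mean(axis=1)
    v = gamma_d_sq + 1.0 / m
    precision = (x.T @ x) / v + np.eye(x.shape[1]) / prior.coef_prior_var
    delta = _sample_mvn_from_precision(precision, x.T @ ubar / v, rng)
    # d_i | u, delta
    prec_d = m + 1.0 / gamma_d_sq
    mean_d = (u.sum(axis=1) - m * (x @ delta)) / prec_d
    d = mean_d + rng.standard_normal(n) / np.sqrt(prec_d)
    gamma_d_sq = float(_sample_inverse_gamma(
        prior.ig_shape + n / 2.0, prior.ig_rate + np.sum(d**2) / 2.0, rng
    ))
    return u, delta, d, gamma_d_sq


def sample_lognormal_block(
    z: np.ndarray,
    w: np.ndarray,
    covariates: CovariateTable,
    alpha: np.ndarray,
    a: np.ndarray,
    sigma1_sq: np.ndarray,
    gamma_a_sq: float,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Update (alpha, a, sigma1_sq, gamma_a_sq) from the connected pairs."""
    if np.any((w == 1) & (z <= 0)):
        raise ValueError("w = 1 at non-positive z: invariant breach")
    x = covariates.x
    n = len(a)
    conn = w == 1
    k = conn.sum(axis=1).astype(float)
    logz = np.where(conn, np.log(np.where(z > 0, z, 1.0)), 0.0)
    ysum = logz.sum(axis=1)
    # (alpha, a) drawn jointly: alpha from its conditional with the subject
    # effects integrated out — ybar_i ~ N(x_i alpha, gamma_a^2 + sigma1_i^2
    # / k_i) for subjects with k_i > 0 — then a | alpha.  Collapsing avoids
    # the slow random walk between alpha and a of the centered scan.
    has = k > 0
    v = gamma_a_sq + sigma1_sq / np.maximum(k, 1.0)
    weight = np.where(has, 1.0 / v, 0.0)
    ybar = np.where(has, ysum / np.maximum(k, 1.0), 0.0)
    precision = (x.T * weight) @ x + np.eye(x.shape[1]) / prior.coef_prior_var
    linear = x.T @ (weight * ybar)
    alpha = _sample_mvn_from_precision(precision, linear, rng)
    # a_i | y, alpha, sigma1, gamma_a
    xa = x @ alpha
    prec_a = k / sigma1_sq + 1.0 / gamma_a_sq
    mean_a = ((ysum - k * xa) / sigma1_sq) / prec_a
    a = mean_a + rng.standard_normal(n) / np.sqrt(prec_a)
    # sigma1_i^2 | y, alpha, a — IG(shape + k_i/2, rate + RSS_i/2)
    resid = np.where(conn, logz - (xa + a)[:, None], 0.0)
    rss = np.sum(resid**2, axis=1)
    sigma1_sq = _sample_inverse_gamma(
        prior.ig_shape + k / 2.0, prior.ig_rate + rss / 2.0, rng
    )
    gamma_a_sq = float(_sample_inverse_gamma(
        prior.ig_shape + n / 2.0, prior.ig_rate + np.sum(a**2) / 2.0, rng
    ))
    return alpha, a, np.maximum(sigma1_sq, _VAR_FLOOR), gamma_a_sq


def sample_nonconnected_block(
    z: np.ndarray,
    w: np.ndarray,
    mu0: np.ndarray,
    sigma0_sq: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Update (mu0, sigma0_sq) from the non-connected pairs per subject."""
    non = w == 0
    k0 = non.sum(axis=1).astype(float)
    zsum = np.where(non, z, 0.0).sum(axis=1)
    prec = k0 / sigma0_sq + 1.0 / prior.mu0_prior_var
    mean = (zsum / sigma0_sq + prior.mu0_prior_mean / prior.mu0_prior_var) / prec
    mu0 = mean + rng.standard_normal(len(mu0)) / np.sqrt(prec)
    resid = np.where(non, z - mu0[:, None], 0.0)
    rss = np.sum(resid**2, axis=1)
    sigma0_sq = _sample_inverse_gamma(
        prior.ig_shape + k0 / 2.0, prior.ig_rate + rss / 2.0, rng
    )
    return mu0, np.maximum(sigma0_sq, _VAR_FLOOR)


def gibbs_sweep(
    data: ConnectivityDataset,
    covariates: CovariateTable,
    params: MixtureParameters,
    latent: LatentState,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[MixtureParameters, LatentState]:
    """One systematic scan: W, probit block, lognormal block, non-connected."""
    w = sample_w(data, params, covariates, rng)
    u, delta, d, gamma_d_sq = sample_probit_block(
        w, covariates, params.delta, params.d, params.gamma_d_sq, prior, rng
    )
    alpha, a, sigma1_sq, gamma_a_sq = sample_lognormal_block(
        data.z, w, covariates, params.alpha, params.a, params.sigma1_sq,
        params.gamma_a_sq, prior, rng,
    )
    mu0, sigma0_sq = sample_nonconnected_block(
        data.z, w, params.mu0, params.sigma0_sq, prior, rng
    )
    new_params = MixtureParameters(
        alpha=alpha, delta=delta, a=a, d=d, mu0=mu0,
        sigma0_sq=sigma0_sq, sigma1_sq=sigma1_sq,
        gamma_a_sq=gamma_a_sq, gamma_d_sq=gamma_d_sq,
    )
    return new_params, LatentState(w=w, u=u)


# ---------------------------------------------------------------------------
# Initialization and the main loop
# ---------------------------------------------------------------------------


def initialize(
    data: ConnectivityDataset,
    covariates: CovariateTable,
    config: MCMCConfig,
    prior: PriorSpec | None = None,
    rng: np.random.Generator | None = None,
    user_params: MixtureParameters | None = None,
) -> tuple[MixtureParameters, LatentState]:
    """Produce starting values for a chain.

    The moment-based strategy labels as connected the z above each
    subject's 90th percentile (and positive), then sets every parameter to
    the corresponding moment estimate; random effects start at zero.
    """
    prior = prior or PriorSpec()
    n, m = data.z.shape
    p_cov = covariates.n_covariates
    if config.init_strategy == "user_supplied":
        if user_params is None:
            raise ValueError("user_supplied init requires user_params")
        w = (connection_probability(data, user_params, covariates) > 0.5)
        return user_params, LatentState(w=w.astype(np.int8))
    if config.init_strategy == "prior_draw":
        if rng is None:
            raise ValueError("prior_draw init requires an rng")
        params = _draw_from_prior(n, p_cov, prior, rng)
        w = sample_w(data, params, covariates, rng)
        return params, LatentState(w=w)

    if not np.any(data.z > 0):
        raise ValueError("no subject has any positive z: cannot seed a connected component")
    q90 = np.quantile(data.z, 0.9, axis=1)
    w = ((data.z > q90[:, None]) & (data.z > 0)).astype(np.int8)
    mu0 = np.empty(n)
    sigma0_sq = np.empty(n)
    sigma1_sq = np.empty(n)
    logz_all = []
    for i in range(n):
        low = data.z[i][w[i] == 0]
        mu0[i] = low.mean() if low.size else 0.0
        sigma0_sq[i] = max(low.var(), 1e-6) if low.size else 0.01
        hi = data.z[i][w[i] == 1]
        if hi.size:
            logz_all.append(np.log(hi))
            sigma1_sq[i] = max(np.log(hi).var(), 1e-6) if hi.size > 1 else 0.25
        else:
            sigma1_sq[i] = 0.25
    pooled = np.concatenate(logz_all)
    alpha = np.zeros(p_cov)
    alpha[0] = pooled.mean()
    frac = float(np.clip(w.mean(), 1e-3, 1 - 1e-3))
    delta = np.zeros(p_cov)
    delta[0] = ndtri(frac)
    params = MixtureParameters(
        alpha=alpha, delta=delta, a=np.zeros(n), d=np.zeros(n),
        mu0=mu0, sigma0_sq=sigma0_sq, sigma1_sq=sigma1_sq,
        gamma_a_sq=0.01, gamma_d_sq=0.01,
    )
    return params, LatentState(w=w)


def _draw_from_prior(
    n: int, p_cov: int, prior: PriorSpec, rng: np.random.Generator
) -> MixtureParameters:
    gamma_a_sq = float(_sample_inverse_gamma(prior.ig_shape, prior.ig_rate, rng))
    gamma_d_sq = float(_sample_inverse_gamma(prior.ig_shape, prior.ig_rate, rng))
    return MixtureParameters(
        alpha=rng.normal(0, np.sqrt(prior.coef_prior_var), p_cov),
        delta=rng.normal(0, np.sqrt(prior.coef_prior_var), p_cov),
        a=rng.normal(0, np.sqrt(gamma_a_sq), n),
        d=rng.normal(0, np.sqrt(gamma_d_sq), n),
        mu0=rng.normal(prior.mu0_prior_mean, np.sqrt(prior.mu0_prior_var), n),
        sigma0_sq=_sample_inverse_gamma(
            np.full(n, prior.ig_shape), np.full(n, prior.ig_rate), rng),
        sigma1_sq=_sample_inverse_gamma(
            np.full(n, prior.ig_shape), np.full(n, prior.ig_rate), rng),
        gamma_a_sq=gamma_a_sq,
        gamma_d_sq=gamma_d_sq,
    )


def run_chain(
    data: ConnectivityDataset,
    covariates: CovariateTable,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    user_params: MixtureParameters | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return retained draws from all chains."""
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    if data.n_subjects != covariates.n_subjects:
        raise ValueError("dataset and covariates disagree on subject count")
    if np.linalg.matrix_rank(covariates.x) < covariates.n_covariates:
        raise ValueError("covariate design matrix is rank-deficient")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain = (config.n_iterations - config.burn_in) // config.thinning
    collected: dict[str, list] = {k: [] for k in (
        "alpha", "delta", "a", "d", "mu0", "sigma0_sq", "sigma1_sq",
        "gamma_a_sq", "gamma_d_sq", "chain", "w")}
    loglik = np.empty((config.n_chains, config.n_iterations))

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        params, latent = initialize(
            data, covariates, config, prior, rng, user_params
        )
        kept = 0
        for it in range(config.n_iterations):
            params, latent = gibbs_sweep(data, covariates, params, latent, prior, rng)
            ll = observed_loglik(data, covariates, params)
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"non-finite log-likelihood at chain {c}, iteration {it}"
                )
            loglik[c, it] = ll
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if kept == per_chain:
                    continue
                kept += 1
                for name in ("alpha", "delta", "a", "d", "mu0",
                             "sigma0_sq", "sigma1_sq"):
                    collected[name].append(getattr(params, name).copy())
                collected["gamma_a_sq"].append(params.gamma_a_sq)
                collected["gamma_d_sq"].append(params.gamma_d_sq)
                collected["chain"].append(c)
                if config.store_w:
                    collected["w"].append(latent.w.copy())

    return PosteriorDraws(
        alpha=np.array(collected["alpha"]),
        delta=np.array(collected["delta"]),
        a=np.array(collected["a"]),
        d=np.array(collected["d"]),
        mu0=np.array(collected["mu0"]),
        sigma0_sq=np.array(collected["sigma0_sq"]),
        sigma1_sq=np.array(collected["sigma1_sq"]),
        gamma_a_sq=np.array(collected["gamma_a_sq"]),
        gamma_d_sq=np.array(collected["gamma_d_sq"]),
        chain_ids=np.array(collected["chain"], dtype=int),
        loglik=loglik,
        config=config,
        covariate_names=list(covariates.names),
        subject_ids=list(data.subject_ids),
        w_draws=np.array(collected["w"], dtype=np.int8) if config.store_w else None,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat, bulk ESS and Geweke z-scores per scalar parameter.

    A single chain is split in halves.  Parameters with R-hat above
    ``rhat_threshold`` are flagged.  Requires at least 10 retained draws.
    """
    import arviz as az

    if draws.n_draws < 10:
        raise ValueError("need at least 10 retained draws for diagnostics")
    per = draws.by_chain()
    names = draws.covariate_names
    subj = draws.subject_ids
    data_vars = {
        "alpha": (per["alpha"], names), "delta": (per["delta"], names),
        "a": (per["a"], subj), "d": (per["d"], subj),
        "mu0": (per["mu0"], subj),
        "sigma0_sq": (per["sigma0_sq"], subj),
        "sigma1_sq": (per["sigma1_sq"], subj),
        "gamma_a_sq": (per["gamma_a_sq"][..., None], ["."]),
        "gamma_d_sq": (per["gamma_d_sq"][..., None], ["."]),
    }
    rows = []
    for name, (arr, labels) in data_vars.items():
        if arr.shape[0] == 1:  # split a single chain in halves
            half = arr.shape[1] // 2
            arr = np.stack([arr[0, :half], arr[0, half:2 * half]])
        idata = az.convert_to_dataset({name: arr})
        rhat = az.rhat(idata)[name].values
        ess = az.ess(idata)[name].values
        flat = arr.reshape(-1, arr.shape[-1])
        gz = _geweke_z(flat)
        for k, lab in enumerate(labels):
            label = name if lab == "." else f"{name}[{lab}]"
            rows.append({
                "parameter": label,
                "rhat": float(np.atleast_1d(rhat)[k]),
                "ess_bulk": float(np.atleast_1d(ess)[k]),
                "geweke_z": float(gz[k]),
                "mean": float(flat[:, k].mean()),
                "sd": float(flat[:, k].std(ddof=1)),
            })
    report = pd.DataFrame(rows)
    report["flagged"] = report["rhat"] > rhat_threshold
    return report


def _geweke_z(flat: np.ndarray) -> np.ndarray:
    """Mean difference between the first 10% and last 50% of the pooled
    chain, in units of its (independence-approximation) standard error."""
    s = flat.shape[0]
    first = flat[: max(s // 10, 2)]
    last = flat[s // 2:]
    se = np.sqrt(first.var(axis=0, ddof=1) / len(first)
                 + last.var(axis=0, ddof=1) / len(last))
    se = np.where(se == 0, np.inf, se)
    return (first.mean(axis=0) - last.mean(axis=0)) / se
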