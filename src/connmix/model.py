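"""Two-component hierarchical mixture model for Fisher-z connectivity values.

For subject ``i`` (design row ``x_i``) and node pair ``j``::

    W_ij | d_i       ~ Bernoulli( Phi(x_i delta + d_i) )
    Z_ij | W_ij = 1  ~ lognormal( x_i alpha + a_i, sigma1_i^2 )
    Z_ij | W_ij = 0  ~ Normal( mu0_i, sigma0_i^2 )
    a_i ~ N(0, gamma_a^2),   d_i ~ N(0, gamma_d^2)

The lognormal "connected" component lives on the positive half-line: only
positive correlations can represent reliable connections, so any z <= 0 is
non-connected with probability one.  The normal "non-connected" component
has mean near zero and absorbs spurious, weak and negative associations.
Conditional on the random effects and covariates, observations are
independent across subjects and pairs.

This module houses the densities, likelihoods and the generative direction
(simulation), which doubles as the synthetic-data generator for tests and
validation studies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .datamodel import ConnectivityDataset, CovariateTable, upper_triangle_pairs

__all__ = [
    "MixtureParameters",
    "PriorSpec",
    "LatentState",
    "lognormal_pdf",
    "lognormal_logpdf",
    "component_densities",
    "component_logdensities",
    "complete_data_loglik",
    "observed_loglik",
    "simulate_dataset",
    "simulate_ground_truth_study",
]

_NEG_INF = -np.inf


@dataclasses.dataclass
class MixtureParameters:
    """One full set of model unknowns.

    ``alpha``/``delta`` are fixed-effect coefficient vectors (length p_cov)
    for the connected-component log-scale mean and the probit score of the
    mixing probability.  ``a``/``d`` are per-subject Gaussian random effects
    with variances ``gamma_a_sq``/``gamma_d_sq``.  ``mu0``, ``sigma0_sq``
    are the per-subject non-connected normal parameters; ``sigma1_sq`` the
    per-subject connected log-scale variances.
    """

    alpha: np.ndarray
    delta: np.ndarray
    a: np.ndarray
    d: np.ndarray
    mu0: np.ndarray
    sigma0_sq: np.ndarray
    sigma1_sq: np.ndarray
    gamma_a_sq: float
    gamma_d_sq: float

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "a", "d", "mu0", "sigma0_sq", "sigma1_sq"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.a)
        if not (len(self.d) == len(self.mu0) == len(self.sigma0_sq) == len(self.sigma1_sq) == n):
            raise ValueError("subject-indexed parameter vectors have inconsistent lengths")
        if len(self.alpha) != len(self.delta):
            raise ValueError("alpha and delta must have the same length")
        for name in ("sigma0_sq", "sigma1_sq"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.gamma_a_sq <= 0 or self.gamma_d_sq <= 0:
            raise ValueError("random-effect variances must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.a)

    @property
    def n_covariates(self) -> int:
        return len(self.alpha)

    def connected_mean(self, covariates: CovariateTable) -> np.ndarray:
        """Per-subject lognormal log-scale mean x_i alpha + a_i."""
        return covariates.x @ self.alpha + self.a

    def probit_score(self, covariates: CovariateTable) -> np.ndarray:
        """Per-subject probit score x_i delta + d_i."""
        return covariates.x @ self.delta + self.d

    def mixing_probability(self, covariates: CovariateTable) -> np.ndarray:
        """Per-subject prior connection probability Phi(x_i delta + d_i)."""
        return stats.norm.cdf(self.probit_score(covariates))


@dataclasses.dataclass
class PriorSpec:
    """Priors for the Gibbs sampler.

    All variance components get a conditionally conjugate inverse-gamma
    IG(shape, rate) prior with density proportional to
    ``x**(-shape-1) * exp(-rate/x)`` (shape/rate parameterization; defaults
    IG(1.5, 1e-3)).  ``mu0`` gets a zero-centered normal prior.  The
    nominally non-informative priors on ``alpha`` and ``delta`` are
    zero-mean normals with a large variance, keeping every full conditional
    proper and conjugate.
    """

    ig_shape: float = 1.5
    ig_rate: float = 1e-3
    mu0_prior_mean: float = 0.0
    mu0_prior_var: float = 1.0
    coef_prior_var: float = 1e4

    def __post_init__(self) -> None:
        for name in ("ig_shape", "ig_rate", "mu0_prior_var", "coef_prior_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclasses.dataclass
class LatentState:
    """Binary connection indicators W and probit augmentation variables U.

    ``u`` is the Gaussian latent score of the probit data augmentation:
    ``u > 0`` exactly where ``w = 1``.
    """

    w: np.ndarray
    u: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w)
        if not np.isin(self.w, (0, 1)).all():
            raise ValueError("w must be binary")
        self.w = self.w.astype(np.int8)
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.shape != self.w.shape:
                raise ValueError("u and w shapes differ")
            if np.any((self.u > 0) != (self.w == 1)):
                raise ValueError("sign of u inconsistent with w")

    def validate_support(self, z: np.ndarray) -> None:
        """w must be 0 wherever z <= 0 (lognormal support constraint)."""
        if np.any((self.w == 1) & (z <= 0)):
            raise ValueError("w = 1 at a non-positive z: zero-likelihood configuration")


def lognormal_logpdf(z, mu, sigma_sq):
    """Log-density of lognormal(mu, sigma_sq); -inf on z <= 0."""
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    if np.any(sigma_sq <= 0):
        raise ValueError("sigma_sq must be strictly positive")
    z = np.asarray(z, dtype=float)
    logz = np.log(np.where(z > 0, z, 1.0))
    val = -logz - 0.5 * np.log(2 * np.pi * sigma_sq) - (logz - mu) ** 2 / (2 * sigma_sq)
    out = np.where(z > 0, val, _NEG_INF)
    return out if out.ndim else float(out)


def lognormal_pdf(z, mu, sigma_sq):
    """Density of lognormal(mu, sigma_sq); 0 on z <= 0."""
    return np.exp(lognormal_logpdf(z, mu, sigma_sq))


def component_logdensities(
    z, params: MixtureParameters, subject: int, covariates: CovariateTable
):
    """(log f0, log f1, log pi, log(1-pi)) for one subject at values ``z``.

    f0 is the non-connected normal density, f1 the connected lognormal
    density, pi = Phi(x_i delta + d_i) the mixing probability.
    """
    eta = float(covariates.x[subject] @ params.delta + params.d[subject])
    mu1 = float(covariates.x[subject] @ params.alpha + params.a[subject])
    logf0 = stats.norm.logpdf(
        z, params.mu0[subject], np.sqrt(params.sigma0_sq[subject])
    )
    logf1 = lognormal_logpdf(z, mu1, params.sigma1_sq[subject])
    return logf0, logf1, float(log_ndtr(eta)), float(log_ndtr(-eta))


def component_densities(
    z, params: MixtureParameters, subject: int, covariates: CovariateTable
):
    """(f0, f1, pi) for one subject at values ``z`` (natural scale)."""
    logf0, logf1, logpi, _ = component_logdensities(z, params, subject, covariates)
    return np.exp(logf0), np.exp(logf1), float(np.exp(logpi))


def _stacked_logdensities(data, covariates, params):
    """(n, m) arrays of log f0, log f1 and (n,) log pi, log(1-pi)."""
    eta = params.probit_score(covariates)
    mu1 = params.connected_mean(covariates)
    logf0 = stats.norm.logpdf(
        data.z, params.mu0[:, None], np.sqrt(params.sigma0_sq)[:, None]
    )
    logf1 = lognormal_logpdf(data.z, mu1[:, None], params.sigma1_sq[:, None])
    return logf0, logf1, log_ndtr(eta), log_ndtr(-eta)


def observed_loglik(
    data: ConnectivityDataset, covariates: CovariateTable, params: MixtureParameters
) -> float:
    """Log-likelihood with the latent labels marginalized per observation:
    sum_ij log[ pi_i f1(z_ij) + (1 - pi_i) f0(z_ij) ].
    """
    logf0, logf1, logpi, log1mpi = _stacked_logdensities(data, covariates, params)
    return float(
        np.sum(np.logaddexp(logpi[:, None] + logf1, log1mpi[:, None] + logf0))
    )


def complete_data_loglik(
    data: ConnectivityDataset,
    covariates: CovariateTable,
    params: MixtureParameters,
    latent: LatentState,
) -> float:
    """Joint log-likelihood of (Z, W) under the labelled components."""
    latent.validate_support(data.z)
    logf0, logf1, logpi, log1mpi = _stacked_logdensities(data, covariates, params)
    w = latent.w == 1
    total = np.sum(logf1[w]) + np.sum(logf0[~w])
    k1 = w.sum(axis=1)
    total += np.sum(k1 * logpi + (data.n_pairs - k1) * log1mpi)
    return float(total)


def simulate_dataset(
    params: MixtureParameters,
    covariates: CovariateTable,
    m: int,
    seed: int | np.random.Generator,
    draw_random_effects: bool = False,
    subject_ids: list[str] | None = None,
    pair_index: list[tuple[int, int]] | None = None,
) -> tuple[ConnectivityDataset, LatentState]:
    """Draw a dataset from the generative model.

    With ``draw_random_effects`` the subject effects ``a``, ``d`` are
    redrawn from N(0, gamma^2) (the supplied values are ignored); otherwise
    the values stored in ``params`` are used as-is.  A single integer seed
    determines the whole simulation.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    n = covariates.n_subjects
    if params.n_subjects != n:
        raise ValueError("params and covariates disagree on subject count")
    a, d = params.a, params.d
    if draw_random_effects:
        a = rng.normal(0.0, np.sqrt(params.gamma_a_sq), size=n)
        d = rng.normal(0.0, np.sqrt(params.gamma_d_sq), size=n)
    pi = stats.norm.cdf(covariates.x @ params.delta + d)
    mu1 = covariates.x @ params.alpha + a
    w = (rng.random((n, m)) < pi[:, None]).astype(np.int8)
    z_conn = rng.lognormal(mu1[:, None], np.sqrt(params.sigma1_sq)[:, None], (n, m))
    z_non = rng.normal(params.mu0[:, None], np.sqrt(params.sigma0_sq)[:, None], (n, m))
    z = np.where(w == 1, z_conn, z_non)
    # labels must respect the support constraint even for the rare exact zero
    w[z <= 0] = 0
    if subject_ids is None:
        subject_ids = [f"s{k}" for k in range(n)]
    if pair_index is None:
        pair_index = [(0, j + 1) for j in range(m)]
    data = ConnectivityDataset(z, subject_ids, pair_index)
    state = LatentState(w=w)
    state.validate_support(z)
    used = dataclasses.replace(params, a=a, d=d)
    data.true_params = used  # type: ignore[attr-defined]
    return data, state


def simulate_ground_truth_study(
    p_nodes: int,
    n_subjects: int,
    density,
    seed: int | np.random.Generator,
    connected_mean: float = -0.7,
    connected_sd: float = 0.5,
    nonconnected_mean: float = 0.0,
    nonconnected_sd: float = 0.1,
    subject_sd: float = 0.2,
) -> tuple[np.ndarray, ConnectivityDataset]:
    """Simulate a validation study with known binary truth networks.

    Each subject receives a binary upper-triangle truth vector with
    ``round(density * m)`` connected pairs (``density`` may be a per-subject
    vector for heterogeneous edge counts).  Fisher-z values are drawn from
    the connected lognormal component for true edges and from the
    non-connected normal component otherwise.  ``connected_mean`` is the
    population log-scale mean; each subject's own mean is shifted by a
    N(0, subject_sd^2) effect, emulating between-subject differences in
    overall connectivity strength.

    Returns ``(truth, dataset)`` where ``truth`` is an (n x m) binary array.
    """
    if p_nodes < 3:
        raise ValueError("p_nodes must be >= 3")
    rng = np.random.default_rng(seed)
    m = p_nodes * (p_nodes - 1) // 2
    density = np.broadcast_to(np.asarray(density, dtype=float), (n_subjects,))
    if np.any((density <= 0) | (density >= 1)):
        raise ValueError("density must lie strictly inside (0, 1)")
    pair_index = upper_triangle_pairs(p_nodes)
    truth = np.zeros((n_subjects, m), dtype=np.int8)
    z = np.empty((n_subjects, m))
    for i in range(n_subjects):
        k = int(round(density[i] * m))
        edges = rng.choice(m, size=k, replace=False)
        truth[i, edges] = 1
        mu_i = connected_mean + rng.normal(0.0, subject_sd)
        z[i] = rng.normal(nonconnected_mean, nonconnected_sd, size=m)
        z[i, edges] = rng.lognormal(mu_i, connected_sd, size=k)
    data = ConnectivityDataset(
        z, [f"s{k}" for k in range(n_subjects)], pair_index
    )
    return truth, data
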