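"""End-to-end recovery comparison of the seven sparsification methods.

Given a dataset with known binary truth networks and a fitted model, this
module scores absolute thresholding on correlations and on posterior
probabilities, model-based pseudo-FDR thresholding, and proportional
thresholding at the 5% and 10% levels on both value types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import ConnectivityDataset, CovariateTable
from .gibbs import PosteriorDraws
from .inference import PPMatrix, posterior_mean_subject_params, posterior_probability
from .sparsify import (
    SparsifiedNetwork,
    absolute_threshold,
    evaluate_classification,
    proportional_threshold,
    pseudo_fdr_threshold,
)

__all__ = ["METHOD_NAMES", "compare_methods", "validation_report"]

METHOD_NAMES = (
    "abs_corr", "abs_pp", "mixture_pfdr",
    "prop5_corr", "prop5_pp", "prop10_corr", "prop10_pp",
)


def compare_methods(
    data: ConnectivityDataset,
    truth: np.ndarray,
    pp: PPMatrix,
    subject_params: dict[str, np.ndarray],
    cutoff: float = 1e-6,
    q: float = 0.05,
) -> tuple[dict[str, SparsifiedNetwork], pd.DataFrame]:
    """Sparsify with every method and score each against the truth.

    Returns the fitted networks and a tidy table with one row per
    (method, metric-set): TPR, FPR, PPV and mean performance averaged
    over subjects.
    """
    networks = {
        "abs_corr": absolute_threshold(data.z, cutoff, "abs_corr"),
        "abs_pp": absolute_threshold(pp.values, cutoff, "abs_pp"),
        "mixture_pfdr": pseudo_fdr_threshold(
            data.z, subject_params["pi"], subject_params["mu0"],
            subject_params["sigma0_sq"], subject_params["mu1"],
            subject_params["sigma1_sq"], q=q,
        ),
        "prop5_corr": proportional_threshold(data.z, 0.05, "prop5_corr"),
        "prop5_pp": proportional_threshold(pp.values, 0.05, "prop5_pp"),
        "prop10_corr": proportional_threshold(data.z, 0.10, "prop10_corr"),
        "prop10_pp": proportional_threshold(pp.values, 0.10, "prop10_pp"),
    }
    rows = []
    for name in METHOD_NAMES:
        metrics = evaluate_classification(networks[name], truth)
        rows.append({
            "method": name,
            "tpr": metrics.tpr,
            "fpr": metrics.fpr,
            "ppv": metrics.ppv,
            "mean_performance": metrics.mean_performance,
            "mean_edges": float(networks[name].edge_counts.mean()),
        })
    return networks, pd.DataFrame(rows)


def validation_report(
    data: ConnectivityDataset,
    truth: np.ndarray,
    covariates: CovariateTable,
    draws: PosteriorDraws,
    cutoff: float = 1e-6,
    q: float = 0.05,
) -> pd.DataFrame:
    """Convenience wrapper: compute pp and plug-in parameters, then score."""
    pp = posterior_probability(data, covariates, draws)
    subject_params = posterior_mean_subject_params(draws, covariates)
    _, table = compare_methods(data, truth, pp, subject_params, cutoff, q)
    return table
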