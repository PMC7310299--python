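"""Core data containers and text-file I/O for connectivity analysis.

A study consists of ``n`` subjects, each contributing a symmetric ``p x p``
matrix of pairwise Fisher-transformed Pearson correlations between the BOLD
signals of ``p`` brain nodes.  Only the strictly upper triangle carries
information, so a subject is stored as a length-``m`` vector with
``m = p(p-1)/2``, ordered row-major over node pairs ``(i, j)`` with
``i < j``.  Covariates (intercept, age, sex, head motion, cognitive scores,
...) enter the model as one numeric row per subject.

All file formats are plain delimited text so that datasets round-trip
exactly and remain inspectable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityDataset",
    "CovariateTable",
    "fisher_transform",
    "inverse_fisher_transform",
    "matrix_to_pairs",
    "pairs_to_matrix",
    "upper_triangle_pairs",
    "standardize_covariates",
    "read_dataset",
    "read_matrix_files",
    "read_long_table",
    "write_dataset",
    "write_matrix",
    "read_covariates",
    "write_covariates",
]


def upper_triangle_pairs(p: int) -> list[tuple[int, int]]:
    """Ordered node pairs (i, j), i < j, row-major — the canonical edge order."""
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


@dataclasses.dataclass
class ConnectivityDataset:
    """Fisher-z connectivity values for ``n_subjects`` x ``n_pairs`` node pairs.

    Parameters
    ----------
    z
        Array of shape ``(n_subjects, n_pairs)`` of Fisher-transformed
        correlations.  Must be finite.
    subject_ids
        One identifier per subject (row order of ``z``).
    pair_index
        Ordered list of node-index pairs ``(i, j)`` with ``i < j``, one per
        column of ``z``.
    node_labels
        Optional human-readable node names.
    """

    z: np.ndarray
    subject_ids: list[str]
    pair_index: list[tuple[int, int]]
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be a 2-D array (subjects x pairs)")
        if not np.all(np.isfinite(self.z)):
            i, j = np.argwhere(~np.isfinite(self.z))[0]
            raise ValueError(
                f"non-finite value at subject {self.subject_ids[i]!r} "
                f"(row {i}), pair column {j}"
            )
        if len(self.subject_ids) != self.z.shape[0]:
            raise ValueError("subject_ids length does not match z rows")
        if len(self.pair_index) != self.z.shape[1]:
            raise ValueError("pair_index length does not match z columns")
        seen = set()
        for i, j in self.pair_index:
            if not i < j:
                raise ValueError(f"pair ({i}, {j}) violates i < j ordering")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.z.shape[1]

    @property
    def pair_labels(self) -> list[str]:
        return [f"{i}_{j}" for i, j in self.pair_index]


@dataclasses.dataclass
class CovariateTable:
    """Per-subject design matrix with an identically-1 intercept column.

    ``standardization`` records (mean, sd) used for each standardized column
    so that fitted coefficients can be mapped back to the original scale.
    """

    x: np.ndarray
    names: list[str]
    standardized_mask: np.ndarray | None = None
    standardization: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("covariate matrix must be 2-D")
        if len(self.names) != self.x.shape[1]:
            raise ValueError("names length does not match column count")
        if not np.allclose(self.x[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (all 1)")
        if self.standardized_mask is None:
            self.standardized_mask = np.zeros(self.x.shape[1], dtype=bool)
        self.standardized_mask = np.asarray(self.standardized_mask, dtype=bool)

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.x.shape[1]


def fisher_transform(r):
    """Fisher z-transform arctanh(r) = 0.5 * ln((1+r)/(1-r)).

    Variance-stabilizing map of a Pearson correlation; strictly increasing
    and odd.  Raises for ``|r| >= 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_transform requires |r| < 1")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def inverse_fisher_transform(z):
    """Inverse of :func:`fisher_transform` (tanh)."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return out if out.ndim else float(out)


def matrix_to_pairs(
    c: np.ndarray, atol: float = 1e-8
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Vectorize a square symmetric matrix into its strict upper triangle.

    Returns the values in row-major (i, j), i < j order together with the
    pair index.  The diagonal is discarded: self-associations carry no
    connectivity information.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {c.shape}")
    asym = np.max(np.abs(c - c.T)) if c.size else 0.0
    if asym > atol:
        raise ValueError(f"matrix is asymmetric (max |c - c.T| = {asym:.3g})")
    p = c.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    return c[iu, ju].copy(), list(zip(iu.tolist(), ju.tolist()))


def pairs_to_matrix(
    values: np.ndarray, pair_index: Sequence[tuple[int, int]], p: int | None = None
) -> np.ndarray:
    """Inverse of :func:`matrix_to_pairs`; the diagonal is set to 0."""
    values = np.asarray(values, dtype=float)
    if p is None:
        p = 1 + max(j for _, j in pair_index)
    out = np.zeros((p, p), dtype=float)
    for v, (i, j) in zip(values, pair_index):
        out[i, j] = v
        out[j, i] = v
    return out


def standardize_covariates(
    table: CovariateTable, exclude: Sequence[str] = ()
) -> CovariateTable:
    """Center and scale covariate columns to mean 0, sample sd 1.

    The intercept and any column named in ``exclude`` (typically binary
    covariates such as sex) are left untouched.  Scaling constants are
    stored on the returned table for inverse mapping.  Idempotent: already
    standardized columns are unchanged up to floating-point noise.
    """
    for name in exclude:
        if name not in table.names:
            raise KeyError(f"exclude column {name!r} not in covariate table")
    x = table.x.copy()
    mask = np.asarray(table.standardized_mask, dtype=bool).copy()
    constants = dict(table.standardization)
    for k, name in enumerate(table.names):
        if k == 0 or name in exclude:
            continue
        col = x[:, k]
        sd = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance")
        mean = float(np.mean(col))
        x[:, k] = (col - mean) / sd
        if name in constants:
            # compose with the previous affine map so inverse stays exact
            m0, s0 = constants[name]
            constants[name] = (m0 + mean * s0, s0 * sd)
        else:
            constants[name] = (mean, sd)
        mask[k] = True
    return CovariateTable(x, list(table.names), mask, constants)


# ---------------------------------------------------------------------------
# File I/O — delimited text only
# ---------------------------------------------------------------------------


def write_matrix(
    values: np.ndarray,
    pair_index: Sequence[tuple[int, int]],
    path: str | Path,
    subject_ids: Sequence[str] | None = None,
) -> None:
    """Write an (n x m) value matrix as CSV with `i_j` pair-label header."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = [f"{i}_{j}" for i, j in pair_index]
    if subject_ids is None:
        subject_ids = [f"s{k}" for k in range(values.shape[0])]
    df = pd.DataFrame(values, columns=labels, index=list(subject_ids))
    df.index.name = "subject"
    df.to_csv(path, float_format="%.17g")


def _parse_pair_labels(labels: Sequence[str]) -> list[tuple[int, int]]:
    pairs = []
    for lab in labels:
        i, j = lab.split("_")
        pairs.append((int(i), int(j)))
    return pairs


def write_dataset(dataset: ConnectivityDataset, path: str | Path) -> None:
    write_matrix(dataset.z, dataset.pair_index, path, dataset.subject_ids)


def read_dataset(path: str | Path, from_correlations: bool = False) -> ConnectivityDataset:
    """Read an (n x m) pair-vector CSV produced by :func:`write_dataset`.

    ``from_correlations`` must be set explicitly when the file stores raw
    Pearson correlations; values are then Fisher-transformed on load.  The
    default expects Fisher-z values — the two scales are never guessed.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.loc[r, c])
        )
        raise ValueError(f"missing value at subject {row!r}, pair {col!r} in {path}")
    values = df.to_numpy(dtype=float)
    if from_correlations:
        values = fisher_transform(values)
    return ConnectivityDataset(
        z=values,
        subject_ids=[str(s) for s in df.index],
        pair_index=_parse_pair_labels(df.columns),
    )


def read_matrix_files(
    paths: Sequence[str | Path],
    subject_ids: Sequence[str] | None = None,
    from_correlations: bool = False,
    delimiter: str = ",",
) -> ConnectivityDataset:
    """Read one square symmetric matrix file per subject."""
    if subject_ids is None:
        subject_ids = [Path(p).stem for p in paths]
    vectors, pair_index, p_ref = [], None, None
    for sid, path in zip(subject_ids, paths):
        mat = np.loadtxt(path, delimiter=delimiter)
        if np.any(~np.isfinite(mat)):
            r, c = np.argwhere(~np.isfinite(mat))[0]
            raise ValueError(f"non-finite entry at row {r}, col {c} in {path}")
        if p_ref is None:
            p_ref = mat.shape[0]
        elif mat.shape[0] != p_ref:
            raise ValueError(
                f"subject {sid!r} has {mat.shape[0]} nodes, expected {p_ref}"
            )
        vec, pair_index = matrix_to_pairs(mat)
        vectors.append(vec)
    z = np.vstack(vectors)
    if from_correlations:
        z = fisher_transform(z)
    return ConnectivityDataset(z, list(subject_ids), pair_index)


def read_long_table(
    path: str | Path, from_correlations: bool = False
) -> ConnectivityDataset:
    """Read a long-format table with columns subject, node_i, node_j, value."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject", "node_i", "node_j", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    if df["value"].isna().any():
        row = int(df.index[df["value"].isna()][0])
        raise ValueError(f"missing value at data row {row} in {path}")
    lo = np.minimum(df["node_i"], df["node_j"])
    hi = np.maximum(df["node_i"], df["node_j"])
    df = df.assign(node_i=lo, node_j=hi)
    subjects = list(dict.fromkeys(df["subject"].astype(str)))
    wide = df.pivot_table(
        index="subject", columns=["node_i", "node_j"], values="value"
    ).reindex(subjects)
    if wide.isna().any().any():
        raise ValueError("subjects do not share an identical set of node pairs")
    pair_index = [(int(i), int(j)) for i, j in wide.columns]
    z = wide.to_numpy(dtype=float)
    if from_correlations:
        z = fisher_transform(z)
    return ConnectivityDataset(z, subjects, pair_index)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    df = pd.DataFrame(table.x, columns=table.names)
    df.to_csv(path, index=False, float_format="%.17g")


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"missing covariate values in {path}")
    x = df.to_numpy(dtype=float)
    if not np.allclose(x[:, 0], 1.0):
        x = np.column_stack([np.ones(len(df)), x])
        names = ["intercept"] + list(df.columns)
    else:
        names = list(df.columns)
    return CovariateTable(x, names)
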