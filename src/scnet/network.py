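"""Group-level structural covariance network construction.

For one structure and one (lateralized) hemisphere, the nodes are the
atlas regions and the edge between regions i and j is the partial
correlation of their ICV-normalized volumes across the group's subjects,
controlling for age and sex.  Partial correlation is computed as the
Pearson correlation of OLS residuals, which for a single pair given a
fixed covariate set coincides with the inverse-correlation definition.

Negative partial correlations have no canonical treatment in weighted
path-based analysis; two policies are offered: ``zero`` (clip negatives
to 0, the default) and ``abs`` (absolute value).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NormalizedVolumeMatrix
from .errors import (
    DegenerateColumnError,
    InsufficientSampleError,
    ValidationError,
)

WEIGHT_POLICIES = ("zero", "abs")
#: Groups smaller than this yield a wide-variance warning (not an error).
MIN_GROUP_SIZE = 10


# ---------------------------------------------------------------- ndarray core


def residualize_array(X: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """OLS-residualize each column of X on an intercept plus covariates C.

    Rank-deficient designs (e.g. constant covariates) are tolerated via
    least-squares pseudo-inverse.  Residual columns have mean 0.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = 0 if C is None or C.size == 0 else np.atleast_2d(C.T).T.shape[1]
    if n < k + 2:
        raise InsufficientSampleError(
            f"need at least {k + 2} subjects for {k} covariates, got {n}"
        )
    design = np.ones((n, 1 + k))
    if k:
        design[:, 1:] = C
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def pcorr_array(
    X: np.ndarray, C: np.ndarray | None, names=None
) -> np.ndarray:
    """Partial correlation matrix of columns of X controlling for C."""
    resid = residualize_array(X, C)
    sd = resid.std(axis=0)
    scale = np.abs(np.asarray(X, dtype=float)).max(axis=0)
    scale[scale == 0] = 1.0
    dead = sd <= 1e-13 * scale
    if dead.any():
        idx = int(np.flatnonzero(dead)[0])
        region = names[idx] if names is not None else f"column {idx}"
        raise DegenerateColumnError(str(region))
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def apply_weight_policy(r: np.ndarray, policy: str) -> np.ndarray:
    if policy not in WEIGHT_POLICIES:
        raise ValidationError(f"unknown weight policy {policy!r}")
    w = np.abs(r) if policy == "abs" else np.maximum(r, 0.0)
    np.fill_diagonal(w, 0.0)
    return w


# ------------------------------------------------------------ DataFrame layer


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize each column of ``matrix`` on intercept + ``covariates``."""
    resid = residualize_array(matrix.to_numpy(float), covariates.to_numpy(float))
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def partial_correlation_matrix(
    matrix: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise partial correlations of columns, controlling covariates."""
    r = pcorr_array(
        matrix.to_numpy(float), covariates.to_numpy(float), list(matrix.columns)
    )
    return pd.DataFrame(r, index=matrix.columns, columns=matrix.columns)


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency over one structure's regions.

    Invariants: symmetric, zero diagonal, weights in [0, 1], dimension
    equal to the region count.  ``provenance`` records group, policy and
    covariates for the JSON sidecar.
    """

    node_names: tuple[str, ...]
    weights: np.ndarray
    policy: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_names)
        if self.weights.shape != (n, n):
            raise ValidationError("weight matrix shape mismatch with node names")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValidationError("weight matrix not symmetric")
        if np.abs(np.diag(self.weights)).max(initial=0.0) > 1e-12:
            raise ValidationError("weight matrix diagonal not zero")
        if self.weights.min(initial=0.0) < 0 or self.weights.max(initial=0.0) > 1:
            raise ValidationError("weights outside [0, 1]")
        if self.policy not in WEIGHT_POLICIES:
            raise ValidationError(f"unknown weight policy {self.policy!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(
            self.weights, index=self.node_names, columns=self.node_names
        )
        df.to_csv(path, sep="\t", float_format="%.17g")
        if sidecar:
            meta = dict(self.provenance, policy=self.policy)
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, policy: str = "zero") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        provenance = {}
        try:
            with open(str(path) + ".json") as fh:
                provenance = json.load(fh)
            policy = provenance.pop("policy", policy)
        except FileNotFoundError:
            pass
        return cls(tuple(df.columns), df.to_numpy(float), policy, provenance)


def to_connectivity(
    pcorr, policy: str = "zero", provenance: dict | None = None
) -> ConnectivityMatrix:
    """Turn a partial-correlation matrix into a weighted connectivity matrix.

    Accepts a DataFrame (named) or an (names, array) pair; the diagonal
    (1 for a correlation matrix, 0 if already a connectivity weight
    matrix) is zeroed, and negatives are mapped per the policy.  The
    transform is idempotent under either policy.
    """
    if isinstance(pcorr, pd.DataFrame):
        names, r = tuple(pcorr.columns), pcorr.to_numpy(float)
    else:
        names, r = tuple(pcorr[0]), np.asarray(pcorr[1], dtype=float)
    if r.shape[0] != r.shape[1]:
        raise ValidationError("input matrix not square")
    if np.abs(r - r.T).max(initial=0.0) > 1e-10:
        raise ValidationError("input matrix asymmetric beyond 1e-10")
    w = apply_weight_policy(r, policy)
    return ConnectivityMatrix(names, w, policy, provenance or {})


def build_group_network(
    matrix: NormalizedVolumeMatrix,
    structure: str,
    hemisphere: str,
    group: str,
    policy: str = "zero",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> ConnectivityMatrix:
    """Build the covariance network of one group for structure x hemisphere.

    Uses only the subjects of ``group``; warns (but proceeds) below
    ``MIN_GROUP_SIZE`` subjects, since covariance estimates become very
    noisy in small groups.
    """
    mask = (matrix.group == group).to_numpy()
    n = int(mask.sum())
    if n < MIN_GROUP_SIZE:
        warnings.warn(
            f"group {group!r} has only {n} subjects; covariance estimates "
            "will have wide variance",
            stacklevel=2,
        )
    cols = matrix.columns_for(structure, hemisphere)
    X = matrix.values.loc[mask, cols].to_numpy(float)
    C = matrix.covariates.loc[mask, list(covariates)].to_numpy(float)
    from .atlas import atlas_regions

    names = atlas_regions(structure, hemisphere, matrix.atlas)
    r = pcorr_array(X, C, cols)
    return to_connectivity(
        (names, r),
        policy,
        provenance={
            "structure": structure,
            "hemisphere": hemisphere,
            "group": group,
            "covariates": list(covariates),
            "n_subjects": n,
        },
    )
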