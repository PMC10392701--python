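"""Mixture data container, quantile scoring and tabular I/O.

The estimators in this package all consume a :class:`MixtureData`: an
outcome vector, a matrix of exposures scored into quantile groups
(0..q-1), an optional covariate matrix and the associated labels.
Quantile scoring makes the weighted index scale-free and robust to
outliers in the raw exposure distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["MixtureData", "quantize_columns", "read_mixture_csv", "quantized_frame"]

LINKS = ("identity", "logit")


def quantize_columns(X, q: int = 4) -> np.ndarray:
    """Score each column of ``X`` into ``q`` empirical quantile groups.

    Boundaries are the inverted-CDF empirical quantiles at levels
    1/q, ..., (q-1)/q; a value equal to a boundary is assigned to the
    lower class, and scores are 0-based (0..q-1) so a one-unit change in
    the resulting index reads as "one quantile-group increase".

    Parameters
    ----------
    X : array-like, shape (n, c)
        Raw exposure matrix; complete cases only.
    q : int
        Number of quantile groups (4 = quartiles, 10 = deciles, ...).

    Returns
    -------
    ndarray of int, shape (n, c)
        Integer scores in ``0..q-1``; every class is non-empty.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if q < 2:
        raise ValueError("q must be an integer >= 2")
    if not np.isfinite(X).all():
        raise ValueError("complete cases required: missing or non-finite values found")
    n, c = X.shape
    levels = np.arange(1, q) / q
    out = np.empty((n, c), dtype=np.int64)
    for j in range(c):
        col = X[:, j]
        if len(np.unique(col)) < q:
            raise ValueError(f"column {j}: cannot form q groups ({q} requested, "
                             f"fewer distinct values present)")
        bounds = np.quantile(col, levels, method="inverted_cdf")
        scores = np.searchsorted(bounds, col, side="left")
        counts = np.bincount(scores, minlength=q)
        if (counts == 0).any():
            raise ValueError(f"column {j}: cannot form q groups (empty quantile class)")
        out[:, j] = scores
    return out


@dataclass
class MixtureData:
    """Outcome, quantile-scored exposures and covariates for one analysis.

    Attributes
    ----------
    y : ndarray, shape (n,)
        Outcome; continuous for ``link='identity'``, 0/1 for ``'logit'``.
    Q : ndarray of int, shape (n, c)
        Exposure quantile scores, entries in ``0..q-1``.
    Z : ndarray, shape (n, p)
        Covariate matrix (p may be 0).
    component_names, covariate_names : list of str
    q : int
        Number of quantile groups used to build ``Q``.
    link : {'identity', 'logit'}
    """

    y: np.ndarray
    Q: np.ndarray
    Z: np.ndarray = None
    component_names: list = None
    covariate_names: list = None
    q: int = 4
    link: str = "identity"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Q = np.asarray(self.Q)
        n = self.y.shape[0]
        if self.Q.ndim != 2 or self.Q.shape[0] != n:
            raise ValueError("Q must be an (n, c) matrix aligned with y")
        if self.Z is None:
            self.Z = np.empty((n, 0))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        if self.Z.shape[0] != n:
            raise ValueError("Z must have the same number of rows as y")
        c, p = self.Q.shape[1], self.Z.shape[1]
        if self.component_names is None:
            self.component_names = [f"x{i + 1}" for i in range(c)]
        if self.covariate_names is None:
            self.covariate_names = [f"z{i + 1}" for i in range(p)]
        self.component_names = list(self.component_names)
        self.covariate_names = list(self.covariate_names)
        if len(self.component_names) != c or len(self.covariate_names) != p:
            raise ValueError("name lists must match matrix dimensions")
        if len(set(self.component_names)) != c:
            raise ValueError("component_names must be unique")
        if set(self.component_names) & set(self.covariate_names):
            raise ValueError("component and covariate names must be disjoint")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not np.issubdtype(self.Q.dtype, np.integer):
            Qf = self.Q.astype(float)
            if not np.allclose(Qf, np.round(Qf)):
                raise ValueError("Q must contain integer quantile scores")
            self.Q = Qf.astype(np.int64)
        if self.Q.min() < 0 or self.Q.max() > self.q - 1:
            raise ValueError(f"Q entries must lie in [0, {self.q - 1}]")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}")
        if self.link == "logit" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("logit link requires a 0/1 outcome")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def c(self) -> int:
        return self.Q.shape[1]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def subset(self, idx) -> "MixtureData":
        """Row subset (used for splits and bootstrap resamples)."""
        return replace(self, y=self.y[idx], Q=self.Q[idx], Z=self.Z[idx])

    @classmethod
    def from_raw(cls, y, X, Z=None, component_names=None, covariate_names=None,
                 q: int = 4, link: str = "identity") -> "MixtureData":
        """Build from raw (un-scored) exposures by quantile scoring."""
        Q = quantize_columns(X, q)
        return cls(y=y, Q=Q, Z=Z, component_names=component_names,
                   covariate_names=covariate_names, q=q, link=link)


def read_mixture_csv(path, outcome: str, mixture=None, mixture_prefix: str = None,
                     covariates=(), q: int = 4, link: str = "identity",
                     sep: str = ",") -> MixtureData:
    """Read a rectangular CSV and quantile-score the mixture columns.

    Either ``mixture`` (an explicit list of column names) or
    ``mixture_prefix`` (all columns starting with the prefix) must be
    given.  A header row is required.
    """
    df = pd.read_csv(path, sep=sep)
    if mixture is None and mixture_prefix is None:
        raise ValueError("name the mixture columns (list) or give a prefix")
    if mixture is None:
        mixture = [c for c in df.columns
                   if c.startswith(mixture_prefix) and c != outcome]
        if not mixture:
            raise ValueError(f"no columns match prefix {mixture_prefix!r}")
    missing = [c for c in [outcome, *mixture, *covariates] if c not in df.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    sub = df[[outcome, *mixture, *covariates]]
    if sub.isna().any().any():
        raise ValueError("complete cases required: missing values in input")
    Z = df[list(covariates)].to_numpy(float) if covariates else None
    return MixtureData.from_raw(
        y=df[outcome].to_numpy(float), X=df[list(mixture)].to_numpy(float), Z=Z,
        component_names=list(mixture), covariate_names=list(covariates),
        q=q, link=link)


def quantized_frame(data: MixtureData) -> pd.DataFrame:
    """Quantized exposure matrix as a DataFrame with original names."""
    return pd.DataFrame(data.Q, columns=data.component_names)
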