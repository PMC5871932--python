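"""Selection-index construction by principal component regression (PCR).

The index is a linear combination of secondary traits predicting a target
trait (yield per unit area) that cannot be measured on single plants.  The
component count is chosen by leave-one-out cross-validation at minimum RMSE,
and coefficients are back-transformed to the original trait scale.  A Mantel
permutation test checks transferability of the trait correlation structure
between datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionIndexModel",
    "IndexValue",
    "fit_pcr",
    "compute_index",
    "mantel_test",
]


@dataclass
class SelectionIndexModel:
    """Per-trait index weights on the original trait scale plus an intercept."""

    trait_names: list[str]
    coefficients: np.ndarray
    intercept: float = 0.0
    n_components: int = 1
    rmse_profile: np.ndarray | None = None
    scaled: bool = False

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.trait_names):
            raise ValueError("coefficient list must align with trait names")
        if self.n_components < 1 or self.n_components > len(self.trait_names):
            raise ValueError("n_components out of range")
        if self.rmse_profile is not None:
            self.rmse_profile = np.asarray(self.rmse_profile, dtype=float)
            best = np.flatnonzero(self.rmse_profile <= self.rmse_profile.min() + 1e-12)[0]
            if self.n_components != best + 1:
                raise ValueError("n_components must minimize the RMSE profile")

    def to_json(self) -> str:
        return json.dumps(
            {
                "trait_names": self.trait_names,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "n_components": self.n_components,
                "rmse_profile": None if self.rmse_profile is None else self.rmse_profile.tolist(),
                "scaled": self.scaled,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionIndexModel":
        d = json.loads(text)
        return cls(
            d["trait_names"],
            np.array(d["coefficients"], dtype=float),
            d["intercept"],
            d["n_components"],
            None if d["rmse_profile"] is None else np.array(d["rmse_profile"], dtype=float),
            d.get("scaled", False),
        )


@dataclass(frozen=True)
class IndexValue:
    individual_id: object
    value: float
    source: str  # observed | expected | predicted

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("index value must be finite")
        if self.source not in {"observed", "expected", "predicted"}:
            raise ValueError(f"unknown index source {self.source!r}")


def _pcr_coefficients(X: np.ndarray, y: np.ndarray, k: int, scale: bool) -> tuple[np.ndarray, float]:
    """PCR fit with k components; returns (beta on original scale, intercept)."""
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if k > rank:
        raise ValueError(f"requested {k} components but predictor rank is {rank}")
    V = vt[:k].T
    T = Xc @ V
    gamma, *_ = np.linalg.lstsq(T, y - y.mean(), rcond=None)
    beta = V @ gamma
    if scale:
        beta = beta / sd
    intercept = float(y.mean() - x_mean @ beta)
    return beta, intercept


def fit_pcr(
    trait_means: pd.DataFrame,
    yield_values,
    max_components: int | None = None,
    scale: bool = False,
) -> SelectionIndexModel:
    """Principal component regression of yield on trait means with the number
    of components chosen at the smallest leave-one-out RMSE (ties broken
    toward fewer components).  Predictors are mean-centered; set ``scale``
    to also divide by the standard deviation.
    """
    X = trait_means.to_numpy(dtype=float)
    y = np.asarray(yield_values, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if len(y) != n:
        raise ValueError("yield vector length mismatch")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing entries are not allowed")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    # leaving one row out can reduce rank by one
    k_max = min(max_components or p, p, rank, n - 2)
    if k_max < 1:
        raise ValueError("predictor matrix has insufficient rank")

    rmse = np.empty(k_max)
    for k in range(1, k_max + 1):
        sq = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            beta, b0 = _pcr_coefficients(X[keep], y[keep], k, scale)
            pred = b0 + X[i] @ beta
            sq += (pred - y[i]) ** 2
        rmse[k - 1] = np.sqrt(sq / n)

    best_k = int(np.flatnonzero(rmse <= rmse.min() + 1e-12)[0]) + 1
    beta, b0 = _pcr_coefficients(X, y, best_k, scale)
    return SelectionIndexModel(
        list(trait_means.columns), beta, b0, best_k, rmse, scale
    )


def compute_index(
    traits: pd.DataFrame,
    model: SelectionIndexModel,
    source: str = "observed",
    include_intercept: bool = True,
) -> list[IndexValue]:
    """Linear index s_i = [intercept +] sum_j b_j u_ij, aligned by trait name."""
    missing = set(model.trait_names) - set(traits.columns)
    if missing:
        raise ValueError(f"trait columns missing from input: {sorted(missing)}")
    vals = index_scores(traits, model, include_intercept)
    return [IndexValue(iid, float(v), source) for iid, v in zip(traits.index, vals)]


def index_scores(
    traits: pd.DataFrame,
    model: SelectionIndexModel,
    include_intercept: bool = True,
) -> pd.Series:
    """Array-valued form of :func:`compute_index` (a pandas Series keyed by id)."""
    X = traits.reindex(columns=model.trait_names).to_numpy(dtype=float)
    s = X @ model.coefficients
    if include_intercept:
        s = s + model.intercept
    return pd.Series(s, index=traits.index, name="selection_index")


def _offdiag_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(
    corr_a: np.ndarray,
    corr_b: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mantel permutation test of matrix association.

    Statistic: Pearson correlation of the upper off-diagonal entries.  The
    null distribution permutes rows/columns of ``corr_b`` simultaneously;
    the identity permutation is counted in the null set, so the smallest
    attainable p-value is 1/(n_perm+1).
    """
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square with equal dimensions")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    va = _offdiag_upper(a)
    vb = _offdiag_upper(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("off-diagonal entries are constant")
    stat = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    ident = np.arange(n)
    count = 1  # identity permutation contributes once, deterministically
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, ident):
            perm = rng.permutation(n)
        vp = _offdiag_upper(b[np.ix_(perm, perm)])
        r = np.corrcoef(va, vp)[0, 1]
        if alternative == "two-sided":
            hit = abs(r) >= abs(stat) - 1e-12
        elif alternative == "greater":
            hit = r >= stat - 1e-12
        else:
            raise ValueError("alternative must be 'two-sided' or 'greater'")
        count += int(hit)
    return stat, count / (n_perm + 1)
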