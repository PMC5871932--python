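"""Per-trait genomic prediction with G-BLUP.

Single-kinship mixed model y = 1*mu + g + e with g ~ N(0, sigma_g^2 * K),
REML over the variance ratio via the spectral decomposition of K.  Every
model also carries the equivalent ridge (marker-effect) representation, so
kinship-space and marker-space predictions can be cross-checked and new
individuals can be predicted from genotypes alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .index import SelectionIndexModel, IndexValue, index_scores
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GBLUPModel",
    "AccuracyReport",
    "genomic_relationship",
    "fit_gblup",
    "predict_gebv",
    "expected_index",
    "loocv_accuracy",
    "loocv_predictions",
    "frozen_model_decay",
]


# ---------------------------------------------------------------------------
# design matrices and kinship
# ---------------------------------------------------------------------------


def _design(geno: GenotypeMatrix):
    """Imputed, polymorphic, column-centered design matrix plus metadata."""
    v = geno.imputed()
    sd = v.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all marker columns are constant")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d zero-variance marker columns", dropped)
    v = v[:, keep]
    col_means = v.mean(axis=0)
    Z = v - col_means
    c = float(np.trace(Z @ Z.T) / Z.shape[0])
    return Z, col_means, np.asarray(geno.marker_ids)[keep], c


def genomic_relationship(geno: GenotypeMatrix) -> np.ndarray:
    """Genomic kinship K = ZZ'/c, trace-normalized so mean(diag(K)) = 1."""
    if geno.n < 2:
        raise ValueError("need at least two individuals")
    Z, _, _, c = _design(geno)
    return (Z @ Z.T) / c


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_profile(lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Profiled -2 REML criterion (up to constants) and GLS pieces at ratio lam."""
    w = d + lam
    xtw = xt / w
    xx = float(xtw @ xt)
    beta = float(xtw @ yt) / xx
    resid = yt - xt * beta
    r = max(float(resid @ (resid / w)), 1e-300)  # guard degenerate zero-variance y
    n_p = len(yt) - 1
    crit = n_p * np.log(r) + float(np.sum(np.log(w))) + np.log(xx)
    return crit, beta, r


def _solve_reml(K: np.ndarray, y: np.ndarray, bounds=(-10.0, 10.0)):
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones_like(y)

    def obj(loglam):
        return _reml_profile(np.exp(loglam), d, yt, xt)[0]

    res = minimize_scalar(obj, bounds=bounds, method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    _, mu, r = _reml_profile(lam, d, yt, xt)
    sigma_g2 = r / (len(y) - 1)
    sigma_e2 = lam * sigma_g2
    return lam, mu, sigma_g2, sigma_e2, (d, U)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class GBLUPModel:
    """Trained per-trait predictor with equivalent marker-effect representation."""

    trait_name: str
    training_ids: np.ndarray
    marker_ids: np.ndarray
    marker_effects: np.ndarray
    col_means: np.ndarray
    fixed_mean: float
    variance_ratio: float   # lambda = sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    trace_scale: float      # c in K = ZZ'/c
    panel_version: str = ""

    def __post_init__(self):
        if self.variance_ratio <= 0:
            raise ValueError("variance ratio must be positive")
        if len(self.marker_effects) != len(self.marker_ids):
            raise ValueError("marker effects must align with marker ids")

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    def to_json(self) -> str:
        return json.dumps(
            {
                "trait_name": self.trait_name,
                "training_ids": list(self.training_ids),
                "marker_ids": list(self.marker_ids),
                "marker_effects": self.marker_effects.tolist(),
                "col_means": self.col_means.tolist(),
                "fixed_mean": self.fixed_mean,
                "variance_ratio": self.variance_ratio,
                "sigma_g2": self.sigma_g2,
                "sigma_e2": self.sigma_e2,
                "trace_scale": self.trace_scale,
                "panel_version": self.panel_version,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GBLUPModel":
        d = json.loads(text)
        return cls(
            d["trait_name"],
            np.array(d["training_ids"], dtype=object),
            np.array(d["marker_ids"], dtype=object),
            np.array(d["marker_effects"], dtype=float),
            np.array(d["col_means"], dtype=float),
            d["fixed_mean"],
            d["variance_ratio"],
            d["sigma_g2"],
            d["sigma_e2"],
            d["trace_scale"],
            d.get("panel_version", ""),
        )


@dataclass(frozen=True)
class AccuracyReport:
    trait_name: str
    pearson_r: float
    cycle_label: str = ""

    def __post_init__(self):
        if np.isfinite(self.pearson_r) and not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("correlation out of range")


def fit_gblup(
    geno: GenotypeMatrix,
    y,
    trait_name: str = "",
    panel_version: str = "",
) -> GBLUPModel:
    """REML fit of the single-kinship mixed model; marker effects recovered as
    the equivalent ridge solution alpha = Z'(K + lambda I)^{-1}(y - mu)/c."""
    y = np.asarray(y, dtype=float)
    if len(y) != geno.n:
        raise ValueError("phenotype length mismatch")
    if geno.n < 2:
        raise ValueError("need at least two training individuals")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes")
    Z, col_means, kept_ids, c = _design(geno)
    K = (Z @ Z.T) / c
    lam, mu, sg2, se2, (d, U) = _solve_reml(K, y)
    w = U.T @ (y - mu)
    vinv_resid = U @ (w / (d + lam))
    alpha = Z.T @ vinv_resid / c
    return GBLUPModel(
        trait_name,
        np.asarray(geno.individuals, dtype=object).copy(),
        kept_ids.copy(),
        alpha,
        col_means,
        float(mu),
        lam,
        float(sg2),
        float(se2),
        c,
        panel_version,
    )


def _aligned_design(model: GBLUPModel, geno: GenotypeMatrix) -> np.ndarray:
    """New genotypes reindexed to the model panel; markers absent from the new
    data are imputed at the training column mean (centered contribution 0)."""
    frame = geno.to_frame()
    overlap = [m for m in model.marker_ids if m in frame.columns]
    if not overlap:
        raise ValueError("no overlapping markers between model panel and genotypes")
    aligned = frame.reindex(columns=model.marker_ids)
    vals = aligned.to_numpy(dtype=float)
    fill = np.broadcast_to(model.col_means, vals.shape)
    mask = np.isnan(vals)
    vals = np.where(mask, fill, vals)
    return vals - model.col_means


def predict_gebv(model: GBLUPModel, geno: GenotypeMatrix) -> pd.Series:
    """GEBVs = mu + centered-genotypes @ marker effects.

    On the training set this reproduces the fitted ("expected") values exactly;
    for new individuals it gives marker-effect predictions ("predicted").
    """
    Zc = _aligned_design(model, geno)
    g = Zc @ model.marker_effects + model.fixed_mean
    return pd.Series(g, index=geno.individuals, name=model.trait_name)


def expected_index(
    models: dict[str, GBLUPModel],
    geno: GenotypeMatrix,
    index_model: SelectionIndexModel,
    source: str = "expected",
    include_intercept: bool = True,
) -> list[IndexValue]:
    """Selection index applied to per-trait GEBVs (one G-BLUP model per trait)."""
    missing = set(index_model.trait_names) - set(models)
    if missing:
        raise ValueError(f"missing trait models: {sorted(missing)}")
    gebvs = pd.DataFrame(
        {t: predict_gebv(models[t], geno) for t in index_model.trait_names}
    )
    scores = index_scores(gebvs, index_model, include_intercept)
    return [IndexValue(i, float(v), source) for i, v in scores.items()]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _loocv_fast(K: np.ndarray, y: np.ndarray, lam: float,
                mu: float | None = None) -> np.ndarray:
    """Closed-form LOO at fixed lambda.

    With the fixed mean held at ``mu`` (zero-mean kriging identity):
    pred_i = y_i - (P(y-mu))_i / P_ii, P = (K+lam I)^{-1}.  With ``mu=None``
    the mean is implicitly refit per fold (Dubrule's cross-validation
    identity via Q = P - P1(1'P1)^{-1}1'P).
    """
    n = len(y)
    P = np.linalg.inv(K + lam * np.eye(n))
    if mu is None:
        p1 = P @ np.ones(n)
        Q = P - np.outer(p1, p1) / p1.sum()
        return y - (Q @ y) / np.diag(Q)
    r = y - mu
    return y - (P @ r) / np.diag(P)


def _loocv_literal(K: np.ndarray, y: np.ndarray, lam: float,
                   mu: float | None = None,
                   reestimate: bool = False) -> np.ndarray:
    """Literal n-refit LOO: kriging-predict each held-out individual from the
    other n-1.  ``mu=None`` refits the fixed mean on every fold (and, with
    ``reestimate``, the REML ratio too); otherwise the mean is held fixed."""
    n = len(y)
    preds = np.empty(n)
    ones = np.ones(n - 1)
    for i in range(n):
        keep = np.arange(n) != i
        Kt = K[np.ix_(keep, keep)]
        yt = y[keep]
        lam_use = _solve_reml(Kt, yt)[0] if reestimate else lam
        Vt = Kt + lam_use * np.eye(n - 1)
        if mu is None:
            sol = np.linalg.solve(Vt, np.column_stack([yt, ones]))
            vy, v1 = sol[:, 0], sol[:, 1]
            mu_i = float(ones @ vy / (ones @ v1))
            resid_sol = vy - mu_i * v1  # = Vt^{-1}(yt - 1 mu_i)
            preds[i] = mu_i + K[i, keep] @ resid_sol
        else:
            resid_sol = np.linalg.solve(Vt, yt - mu)
            preds[i] = mu + K[i, keep] @ resid_sol
    return preds


def loocv_predictions(
    geno: GenotypeMatrix,
    y,
    method: str = "fast",
    mean_policy: str = "full",
    reestimate: bool = False,
) -> np.ndarray:
    """Leave-one-out G-BLUP predictions for one trait.

    The variance ratio is estimated once on the full data by REML and held
    fixed across folds (``reestimate=True`` re-runs REML per fold; literal
    path only).  ``mean_policy='full'`` (default) also holds the fixed mean
    at its full-data GLS estimate — refitting the mean on every fold makes
    the LOO prediction of individual i depend on the leave-one-out average,
    which drives the null accuracy toward -1 instead of 0.  Use
    ``mean_policy='per_fold'`` for the fully refit variant.  ``method='fast'``
    uses the closed-form identity, which matches the literal refit path to
    numerical precision at fixed lambda.
    """
    y = np.asarray(y, dtype=float)
    Z, _, _, c = _design(geno)
    K = (Z @ Z.T) / c
    lam, mu_full, *_ = _solve_reml(K, y)
    if mean_policy == "full":
        mu = float(mu_full)
    elif mean_policy == "per_fold":
        mu = None
    else:
        raise ValueError("mean_policy must be 'full' or 'per_fold'")
    if reestimate:
        return _loocv_literal(K, y, lam, mu=mu, reestimate=True)
    if method == "fast":
        return _loocv_fast(K, y, lam, mu=mu)
    if method == "literal":
        return _loocv_literal(K, y, lam, mu=mu)
    raise ValueError("method must be 'fast' or 'literal'")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")  # undefined, reported as NaN rather than crashing
    return float(np.corrcoef(a, b)[0, 1])


def loocv_accuracy(
    geno: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    index_model: SelectionIndexModel | None = None,
    cycle_label: str = "",
    method: str = "fast",
) -> list[AccuracyReport]:
    """Per-trait LOOCV accuracy (Pearson r between held-out predictions and
    observations); the selection-index accuracy uses the index computed from
    the per-trait LOOCV predictions."""
    if geno.n < 10:
        raise ValueError("need at least 10 individuals for LOOCV accuracy")
    reports = []
    preds = {}
    for trait in phenotypes.columns:
        yhat = loocv_predictions(geno, phenotypes[trait].to_numpy(), method=method)
        preds[trait] = yhat
        reports.append(AccuracyReport(trait, _pearson(yhat, phenotypes[trait]), cycle_label))
    if index_model is not None:
        pred_frame = pd.DataFrame(preds, index=phenotypes.index)
        s_pred = index_scores(pred_frame, index_model)
        s_obs = index_scores(phenotypes, index_model)
        reports.append(
            AccuracyReport("selection_index", _pearson(s_pred, s_obs), cycle_label)
        )
    return reports


def frozen_model_decay(
    frozen_models: dict[str, GBLUPModel],
    later_cycles: list[tuple[str, GenotypeMatrix, pd.DataFrame]],
    index_model: SelectionIndexModel | None = None,
) -> list[AccuracyReport]:
    """Accuracy of cycle-1 models applied unchanged to later cycles."""
    if not later_cycles:
        raise ValueError("no cycle data supplied")
    reports = []
    for label, geno, phenos in later_cycles:
        pred = {}
        for trait in phenos.columns:
            if trait not in frozen_models:
                continue
            yhat = predict_gebv(frozen_models[trait], geno)
            pred[trait] = yhat
            reports.append(AccuracyReport(trait, _pearson(yhat, phenos[trait]), label))
        if index_model is not None and set(index_model.trait_names) <= set(pred):
            pf = pd.DataFrame(pred, index=phenos.index)
            s_pred = index_scores(pf, index_model)
            s_obs = index_scores(phenos, index_model)
            reports.append(AccuracyReport("selection_index", _pearson(s_pred, s_obs), label))
    return reports
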