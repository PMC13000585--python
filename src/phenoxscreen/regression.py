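"""Standardized multivariate linear model relating descriptors to rates.

The screen's structure-property model is ordinary least squares on
z-scored features:

    k_hat = beta0 + beta1 * x_D + beta2 * x_HB + beta3 * x_BV

where x_D, x_HB, x_BV are the standardized diffusion coefficient,
H-bond protection probability, and percent buried volume. With
standardized predictors the intercept equals the mean rate constant and
the coefficients are directly comparable effect sizes. Standard
deviations use the population (1/n) convention; the choice only
rescales coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedFeatures",
    "LinearModel",
    "FEATURE_COLUMNS",
    "zscore",
    "fit_linear",
    "predict",
    "rank_candidates",
]

FEATURE_COLUMNS = ("D", "p_HB", "V_bur")


@dataclass
class StandardizedFeatures:
    """Z-scored design columns plus the training means/sds for reuse."""

    values: np.ndarray              # (n, 3) standardized columns
    means: np.ndarray               # (3,)
    sds: np.ndarray                 # (3,) population convention
    candidate_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def inverse(self) -> np.ndarray:
        """Original-scale feature matrix."""
        return self.values * self.sds + self.means


@dataclass
class LinearModel:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    r_squared: float
    n: int
    feature_means: np.ndarray
    feature_sds: np.ndarray

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


def zscore(
    table: pd.DataFrame,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> StandardizedFeatures:
    """Z-score feature columns; reuse training moments when provided.

    Passing ``means``/``sds`` standardizes new rows in the training
    context, as required for prediction on unseen candidates.
    """
    if len(table) < 2 and means is None:
        raise ValueError("need at least 2 rows to standardize")
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0)  # population (ddof=0)
        zero = np.flatnonzero(sds == 0)
        if len(zero):
            names = [columns[i] for i in zero]
            raise ValueError(f"zero-variance feature column(s): {names}")
    cids = (
        table["candidate_id"].to_numpy(dtype=int)
        if "candidate_id" in table.columns
        else np.arange(len(table))
    )
    return StandardizedFeatures(
        values=(X - means) / sds, means=np.asarray(means), sds=np.asarray(sds),
        candidate_ids=cids,
    )


def fit_linear(features: StandardizedFeatures, k: np.ndarray) -> LinearModel:
    """OLS with intercept on the standardized design.

    R^2 = 1 - RSS/TSS; a constant response (TSS = 0) is reported as
    R^2 = 0 with a warning rather than an error.
    """
    k = np.asarray(k, dtype=float)
    n = len(k)
    if n < 5:
        raise ValueError("need at least 5 rows to fit")
    X = np.column_stack([np.ones(n), features.values])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"rank-deficient design (condition number {cond:.2e})")
    beta, _, _, _ = np.linalg.lstsq(X, k, rcond=None)
    resid = k - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((k - k.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("constant response: defining R^2 = 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
    return LinearModel(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
        beta3=float(beta[3]), r_squared=r2, n=n,
        feature_means=features.means.copy(), feature_sds=features.sds.copy(),
    )


def predict(model: LinearModel, features: StandardizedFeatures) -> np.ndarray:
    """Evaluate the fitted affine model on standardized rows.

    The rows must have been standardized with the TRAINING moments;
    this is checked against the moments stored in the model.
    """
    if not (
        np.allclose(features.means, model.feature_means)
        and np.allclose(features.sds, model.feature_sds)
    ):
        raise ValueError(
            "features were not standardized with the training means/sds; "
            "pass means=model.feature_means, sds=model.feature_sds to zscore()"
        )
    X = np.column_stack([np.ones(len(features.values)), features.values])
    return X @ model.betas


def rank_candidates(
    model: LinearModel, features: StandardizedFeatures
) -> pd.DataFrame:
    """Candidates ordered by predicted rate constant, ascending.

    Lower predicted k means greater radical stability, so the head of
    the table is the most promising antioxidant. Ties break on
    candidate id for determinism.
    """
    k_hat = predict(model, features)
    df = pd.DataFrame({"candidate_id": features.candidate_ids, "k_hat_ns_inv": k_hat})
    df = df.sort_values(
        ["k_hat_ns_inv", "candidate_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
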