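"""Holdout-referenced deviation metrics.

Two complementary z-score-style measures of abnormality, both referenced
to an untouched healthy *holdout* cohort so that systematic model misfit
is absorbed into the reference rather than inflating deviations:

* ``d_ml`` — aggregate multivariate latent deviation: the Mahalanobis
  distance of a subject's shared latent code from the holdout cohort's
  latent distribution (mean and ridge-regularized covariance).
* ``d_uf`` — per-feature univariate deviation: the reconstruction
  residual (input minus reconstruction) standardized by the holdout
  residual mean and standard deviation.  More negative values indicate
  greater-than-normal loss for volume/FA features; MD abnormality
  appears in the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .dmvae import NormativeModel, encode, reconstruct

__all__ = [
    "HoldoutReference",
    "fit_holdout_reference",
    "compute_dml",
    "compute_duf",
    "deviation_table",
]


@dataclass
class HoldoutReference:
    """Holdout-cohort latent and residual statistics."""

    latent_mean: np.ndarray          # (k_s,)
    latent_cov: np.ndarray           # (k_s, k_s), ridge-regularized
    residual_mean: np.ndarray        # per feature
    residual_sd: np.ndarray          # per feature, ddof=1
    feature_names: list[str]
    holdout_id: str = ""
    n_holdout: int = 0

    def __post_init__(self):
        self._chol = cho_factor(self.latent_cov)

    def mahalanobis(self, Z: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(Z) - self.latent_mean
        sol = cho_solve(self._chol, diff.T)
        return np.sqrt(np.einsum("ij,ji->i", diff, sol))


def fit_holdout_reference(
    model: NormativeModel,
    holdout: pd.DataFrame,
    holdout_id: str = "",
    ridge_scale: float = 1e-6,
) -> HoldoutReference:
    """Estimate the reference statistics from the holdout cohort.

    The latent covariance receives a ridge ``ridge_scale * trace / k_s``
    on the diagonal to guarantee invertibility; a covariance that is
    still not positive definite (e.g. a holdout of identical subjects)
    raises.
    """
    ks = model.k_shared
    n = len(holdout)
    if n <= ks + 2:
        raise ValueError(f"holdout too small: need > k_shared + 2 = {ks + 2} rows")
    code = encode(model, holdout)
    Z = code.shared
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = cov + ridge_scale * (np.trace(cov) / ks) * np.eye(ks)

    recon = reconstruct(model, holdout)
    feats = model.feature_names
    resid = holdout[feats].to_numpy(float) - recon[feats].to_numpy(float)
    mu_r = resid.mean(axis=0)
    sd_r = resid.std(axis=0, ddof=1)
    if (sd_r <= 0).any():
        bad = [f for f, s in zip(feats, sd_r) if s <= 0]
        raise ValueError(f"degenerate holdout residuals for features: {bad[:5]}")
    try:
        ref = HoldoutReference(
            latent_mean=mu,
            latent_cov=cov,
            residual_mean=mu_r,
            residual_sd=sd_r,
            feature_names=list(feats),
            holdout_id=holdout_id,
            n_holdout=n,
        )
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate holdout latent covariance") from err
    return ref


def compute_dml(
    model: NormativeModel, ref: HoldoutReference, data: pd.DataFrame
) -> pd.Series:
    """Aggregate latent deviation per subject-visit row (non-negative)."""
    code = encode(model, data)
    if code.shared.shape[1] != len(ref.latent_mean):
        raise ValueError("latent dimension mismatch between model and reference")
    return pd.Series(ref.mahalanobis(code.shared), index=data.index, name="d_ml")


def compute_duf(
    model: NormativeModel, ref: HoldoutReference, data: pd.DataFrame
) -> pd.DataFrame:
    """Signed per-feature deviation z-scores referenced to the holdout."""
    if list(ref.feature_names) != list(model.feature_names):
        raise ValueError("reference features do not match model features")
    recon = reconstruct(model, data)
    feats = ref.feature_names
    resid = data[feats].to_numpy(float) - recon[feats].to_numpy(float)
    duf = (resid - ref.residual_mean) / ref.residual_sd
    return pd.DataFrame(duf, columns=feats, index=data.index)


def deviation_table(
    model: NormativeModel, ref: HoldoutReference, data: pd.DataFrame
) -> pd.DataFrame:
    """Combined output table: subject_id, visit, d_ml, then d_uf columns."""
    dml = compute_dml(model, ref, data)
    duf = compute_duf(model, ref, data)
    lead = {}
    for col in ("subject_id", "visit"):
        if col in data.columns:
            lead[col] = data[col]
    return pd.concat([pd.DataFrame(lead, index=data.index), dml, duf], axis=1)
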