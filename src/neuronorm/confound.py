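"""Covariate adjustment: nonlinear age, linear sex and ICV, control z-scoring.

Each feature is modelled on a control cohort as

    feature ~ intercept + f(age) + b_sex * sex + b_icv * ICV

where f is a penalized natural cubic regression spline (the
one-dimensional analogue of a thin-plate regression spline), with the
smoothing parameter chosen per feature by generalized cross-validation.
Applying the fitted model replaces each feature by the residual from the
model prediction, standardized by the residual mean and standard
deviation of the fitting (control) cohort — i.e. control-referenced
z-scores.  Natural-spline bases are linear beyond the boundary knots, so
ages outside the fitted range are extrapolated linearly (with a warning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfoundModel", "fit_confound_model", "apply_confound_model"]

_LAMBDA_GRID = np.logspace(-4, 4, 25)


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (K knots -> K-2 columns), linear outside."""
    x = np.asarray(x, dtype=float)
    K = len(knots)
    kK, kKm1 = knots[-1], knots[-2]

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - kK, 0.0) ** 3
        return num / (kK - knots[k])

    dKm1 = d(K - 2)
    cols = [d(k) - dKm1 for k in range(K - 2)]
    return np.column_stack(cols) if cols else np.empty((len(x), 0))


def _curvature_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative of the basis, by quadrature."""
    grid = np.linspace(knots[0], knots[-1], 401)
    h = grid[1] - grid[0]
    B = _natural_spline_basis(grid, knots)
    D2 = (B[2:] - 2 * B[1:-1] + B[:-2]) / h**2
    return D2.T @ D2 * h


@dataclass
class ConfoundModel:
    """Fitted per-feature confound regression plus control z-statistics."""

    feature_names: list[str]
    knots: np.ndarray                      # shared age knots
    coef: np.ndarray                       # (n_features, p) rows: model coefficients
    lambdas: np.ndarray                    # per-feature GCV-selected smoothing
    control_mean: np.ndarray               # residual mean on fitting cohort
    control_sd: np.ndarray                 # residual sd (ddof=1)
    age_range: tuple[float, float]
    basis_proj: np.ndarray = None          # (2, K-2): projection of basis on [1, age]
    fit_cohort_id: str = ""
    excluded: list[str] = field(default_factory=list)

    def design(self, age, sex, icv) -> np.ndarray:
        age = np.asarray(age, float)
        B = _natural_spline_basis(age, self.knots)
        if self.basis_proj is not None:
            # spline block orthogonalized against {1, age} so the linear
            # age coefficient stays identified
            B = B - np.column_stack([np.ones(len(B)), age]) @ self.basis_proj
        return np.column_stack(
            [np.ones(len(B)), age, np.asarray(sex, float),
             np.asarray(icv, float), B]
        )

    def predict(self, age, sex, icv) -> np.ndarray:
        return self.design(age, sex, icv) @ self.coef.T

    # round-trip-exact serialization (repr of floats preserves bits)
    def save(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "knots": self.knots.tolist(),
            "coef": self.coef.tolist(),
            "lambdas": self.lambdas.tolist(),
            "control_mean": self.control_mean.tolist(),
            "control_sd": self.control_sd.tolist(),
            "age_range": list(self.age_range),
            "basis_proj": None if self.basis_proj is None else self.basis_proj.tolist(),
            "fit_cohort_id": self.fit_cohort_id,
            "excluded": self.excluded,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ConfoundModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            feature_names=p["feature_names"],
            knots=np.array(p["knots"]),
            coef=np.array(p["coef"]),
            lambdas=np.array(p["lambdas"]),
            control_mean=np.array(p["control_mean"]),
            control_sd=np.array(p["control_sd"]),
            age_range=tuple(p["age_range"]),
            basis_proj=None if p["basis_proj"] is None else np.array(p["basis_proj"]),
            fit_cohort_id=p["fit_cohort_id"],
            excluded=p["excluded"],
        )


def fit_confound_model(
    controls: pd.DataFrame,
    feature_names: list[str],
    basis_dim: int = 10,
    fit_cohort_id: str = "",
) -> ConfoundModel:
    """Fit the per-feature confound regression on a control cohort.

    ``basis_dim`` is the number of age knots (placed at quantiles); the
    effective degrees of freedom per feature are selected by GCV over a
    fixed log-spaced smoothing grid.  Constant features are excluded with
    a warning; a rank-deficient covariate design raises.
    """
    if len(controls) == 0:
        raise ValueError("control cohort is empty")
    for c in ("age", "sex", "icv"):
        if c not in controls.columns:
            raise ValueError(f"missing covariate column {c!r}")
    n = len(controls)
    if n < basis_dim + 3:
        raise ValueError(f"need at least basis_dim + 3 = {basis_dim + 3} rows, got {n}")

    age = controls["age"].to_numpy(float)
    knots = np.unique(np.quantile(age, np.linspace(0, 1, basis_dim)))
    if len(knots) < 4:
        raise ValueError("too few distinct ages for a spline fit")

    Y = controls[feature_names].to_numpy(float)
    sd0 = Y.std(axis=0)
    keep = sd0 > 0
    excluded = [f for f, k in zip(feature_names, keep) if not k]
    if excluded:
        warnings.warn(f"excluding constant features: {excluded}")
    kept = [f for f, k in zip(feature_names, keep) if k]
    Y = Y[:, keep]

    B = _natural_spline_basis(age, knots)
    lin = np.column_stack([np.ones(n), age])
    basis_proj = np.linalg.lstsq(lin, B, rcond=None)[0]
    B = B - lin @ basis_proj
    X = np.column_stack(
        [np.ones(n), age, controls["sex"].to_numpy(float),
         controls["icv"].to_numpy(float), B]
    )
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient covariate design")

    P = np.zeros((p, p))
    P[4:, 4:] = _curvature_penalty(knots)
    # normalize penalty scale so the lambda grid is comparable across datasets
    tr = np.trace(P[4:, 4:])
    if tr > 0:
        P *= p / tr

    XtX = X.T @ X
    XtY = X.T @ Y
    n_feat = Y.shape[1]
    best_gcv = np.full(n_feat, np.inf)
    best_coef = np.zeros((n_feat, p))
    best_lam = np.zeros(n_feat)
    for lam in _LAMBDA_GRID:
        A = XtX + lam * P
        coef = np.linalg.solve(A, XtY)           # (p, n_feat)
        H_tr = np.trace(np.linalg.solve(A, XtX))  # effective df, same all features
        resid = Y - X @ coef
        rss = np.square(resid).sum(axis=0)
        gcv = n * rss / (n - H_tr) ** 2
        better = gcv < best_gcv
        best_gcv[better] = gcv[better]
        best_coef[better] = coef.T[better]
        best_lam[better] = lam

    resid = Y - X @ best_coef.T
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.all():
        bad = [f for f, o in zip(kept, ok) if not o]
        warnings.warn(f"excluding zero-residual features: {bad}")
        excluded += bad
        kept = [f for f, o in zip(kept, ok) if o]
        best_coef, best_lam = best_coef[ok], best_lam[ok]
        mean, sd = mean[ok], sd[ok]

    return ConfoundModel(
        feature_names=kept,
        knots=knots,
        coef=best_coef,
        lambdas=best_lam,
        control_mean=mean,
        control_sd=sd,
        age_range=(float(age.min()), float(age.max())),
        basis_proj=basis_proj,
        fit_cohort_id=fit_cohort_id,
        excluded=excluded,
    )


def apply_confound_model(model: ConfoundModel, data: pd.DataFrame) -> pd.DataFrame:
    """Replace features by control-referenced z-scores of model residuals."""
    missing = [f for f in model.feature_names if f not in data.columns]
    if missing:
        raise ValueError(f"data lacks fitted features: {missing[:5]}...")
    age = data["age"].to_numpy(float)
    lo, hi = model.age_range
    if ((age < lo) | (age > hi)).any():
        warnings.warn(
            "ages outside the fitted range; spline extended linearly beyond "
            f"[{lo:.1f}, {hi:.1f}]"
        )
    pred = model.predict(age, data["sex"].to_numpy(float), data["icv"].to_numpy(float))
    out = data.copy()
    Y = data[model.feature_names].to_numpy(float)
    out[model.feature_names] = (Y - pred - model.control_mean) / model.control_sd
    return out
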