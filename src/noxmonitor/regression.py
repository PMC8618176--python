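"""Kernel regression from isolated NOx spectra to combined NOx-N (mg-N/L).

Absorbances at every 0.5 nm grid point in 200-245 nm (91 features) are the
predictors; the response is the combined nitrate + nitrite nitrogen
concentration.  Features and labels are min-max scaled to [-1, +1] before
support-vector regression (epsilon-insensitive, RBF kernel by default), the
convention that keeps the solver well conditioned.  Hyperparameters come
from an exhaustive grid search scored by pooled 10-fold cross-validation
RMSE; RMSE rather than the squared-correlation R-squared is the selection
metric because the latter is blind to affine distortions of the
predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .errors import ConfigurationError, NotFittedError, NumericalError
from .metrics import r_squared, rmse
from .spectra import ANCHOR_NM, Spectrum
from .compensation import NOxSpectrum

SCHEMA_VERSION = 1

#: default hyperparameter grids for the exhaustive search
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)
#: default epsilon-insensitive margin, in scaled label units
DEFAULT_EPSILON = 0.001
#: ceiling of the training design; predictions above it are extrapolations
DEFAULT_MAX_LABEL = 2.4
#: feature window: the NOx signal lives below the 245 nm anchor
FEATURE_WINDOW = (200.0, ANCHOR_NM)


def features_from_spectra(
    spectra: list[Spectrum | NOxSpectrum], window: tuple[float, float] = FEATURE_WINDOW
) -> np.ndarray:
    """Stack the absorbances within a wavelength window into a feature matrix."""
    rows = []
    for s in spectra:
        if isinstance(s, NOxSpectrum):
            rows.append(s.features(window))
        else:
            wl = s.grid.wavelengths
            mask = (wl >= window[0] - 1e-9) & (wl <= window[1] + 1e-9)
            rows.append(s.absorbance[mask])
    X = np.array(rows)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ConfigurationError("spectra do not cover the feature window")
    return X


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-feature affine map sending the training min/max to -1/+1.

    Constant features map to 0.  Values outside the training range map
    outside [-1, +1]; no clipping, so extrapolation stays visible.
    """

    def fit(self, X, y=None) -> "SymmetricMinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 1:
            raise ValueError("need at least one row")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in scaler input")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        span = self.data_max_ - self.data_min_
        self.scale_ = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
        self.center_ = 0.5 * (self.data_min_ + self.data_max_)
        self.n_features_in_ = X.shape[1]
        return self

    def _check(self, X) -> np.ndarray:
        if not hasattr(self, "scale_"):
            raise NotFittedError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        X = self._check(X)
        return (X - self.center_) * self.scale_

    def inverse_transform(self, X) -> np.ndarray:
        X = self._check(X)
        # constant features invert to their training value
        inv_scale = np.where(self.scale_ > 0, 1.0 / np.where(self.scale_ > 0, self.scale_, 1.0), 0.0)
        return X * inv_scale + self.center_


def _kernel(name: str, X: np.ndarray, SV: np.ndarray, gamma: float, coef0: float, degree: int) -> np.ndarray:
    if name == "rbf":
        d2 = ((X[:, None, :] - SV[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-gamma * d2)
    if name == "linear":
        return X @ SV.T
    if name == "polynomial":
        return (gamma * (X @ SV.T) + coef0) ** degree
    if name == "sigmoid":
        return np.tanh(gamma * (X @ SV.T) + coef0)
    raise ValueError(f"unknown kernel {name!r}")


_SKLEARN_KERNEL = {"rbf": "rbf", "linear": "linear", "polynomial": "poly", "sigmoid": "sigmoid"}


class NOxRegressor(RegressorMixin, BaseEstimator):
    """Support-vector regression from NOx spectra features to mg-N/L.

    Parameters
    ----------
    kernel : {'rbf', 'linear', 'polynomial', 'sigmoid'}, default 'rbf'
    C : float, default 100
        Penalty on deviations beyond the epsilon tube.
    gamma : float, default 0.1
        Kernel width (RBF curvature).
    epsilon : float, default 0.001
        Insensitivity margin, in scaled label units.
    degree, coef0 : polynomial/sigmoid kernel shape parameters.

    Predictions are inverse-scaled back to mg-N/L and clipped at zero;
    values above the training maximum (2.4 mg-N/L for the default standards
    design) are flagged as extrapolations by :meth:`predict_with_flags`.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 100.0,
        gamma: float = 0.1,
        epsilon: float = DEFAULT_EPSILON,
        degree: int = 3,
        coef0: float = 0.0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.degree = degree
        self.coef0 = coef0

    def fit(self, X, y) -> "NOxRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, m) and y (n,) with matching n")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training values")
        if np.any(y < 0):
            raise ValueError("labels are concentrations and must be >= 0")
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")
        if self.kernel not in _SKLEARN_KERNEL:
            raise ValueError(f"kernel must be one of {tuple(_SKLEARN_KERNEL)}")
        self.feature_scaler_ = SymmetricMinMaxScaler().fit(X)
        self.label_scaler_ = SymmetricMinMaxScaler().fit(y)
        Xs = self.feature_scaler_.transform(X)
        ys = self.label_scaler_.transform(y).ravel()
        svr = SVR(
            kernel=_SKLEARN_KERNEL[self.kernel],
            C=self.C,
            gamma=self.gamma,
            epsilon=self.epsilon,
            degree=self.degree,
            coef0=self.coef0,
        ).fit(Xs, ys)
        self.support_vectors_ = svr.support_vectors_.copy()
        self.dual_coef_ = svr.dual_coef_.ravel().copy()
        self.intercept_ = float(svr.intercept_[0])
        self.max_label_ = float(y.max())
        self.n_features_in_ = X.shape[1]
        self.n_samples_ = X.shape[0]
        self._svr = svr  # kept for in-session cross-checks; not persisted
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "support_vectors_"):
            raise NotFittedError("NOxRegressor is not fitted")

    def _decision(self, Xs: np.ndarray) -> np.ndarray:
        """Kernel expansion over the stored support vectors (scaled units)."""
        K = _kernel(self.kernel, Xs, self.support_vectors_, self.gamma, self.coef0, self.degree)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Predicted NOx-N in mg-N/L, clipped at zero."""
        values, _ = self.predict_with_flags(X)
        return values

    def predict_with_flags(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus a boolean extrapolation flag per sample.

        The flag is raised when the (unclipped) prediction exceeds the
        training maximum, where the standards design no longer supports the
        value.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xs = self.feature_scaler_.transform(X)
        raw = self.label_scaler_.inverse_transform(self._decision(Xs)).ravel()
        extrapolated = raw > self.max_label_ + 1e-12
        return np.maximum(raw, 0.0), extrapolated

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "nox_regressor",
            "params": self.get_params(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "feature_scaler": {
                "data_min": self.feature_scaler_.data_min_.tolist(),
                "data_max": self.feature_scaler_.data_max_.tolist(),
            },
            "label_scaler": {
                "data_min": self.label_scaler_.data_min_.tolist(),
                "data_max": self.label_scaler_.data_max_.tolist(),
            },
            "max_label": self.max_label_,
            "n_samples": self.n_samples_,
            "feature_window_nm": list(FEATURE_WINDOW),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "NOxRegressor":
        model = cls(**d["params"])
        model.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        for attr, key in (("feature_scaler_", "feature_scaler"), ("label_scaler_", "label_scaler")):
            sc = SymmetricMinMaxScaler()
            sc.data_min_ = np.asarray(d[key]["data_min"], dtype=float)
            sc.data_max_ = np.asarray(d[key]["data_max"], dtype=float)
            span = sc.data_max_ - sc.data_min_
            sc.scale_ = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
            sc.center_ = 0.5 * (sc.data_min_ + sc.data_max_)
            sc.n_features_in_ = sc.data_min_.shape[0]
            setattr(model, attr, sc)
        model.max_label_ = float(d["max_label"])
        model.n_samples_ = int(d["n_samples"])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model

    @classmethod
    def load(cls, path: str | Path) -> "NOxRegressor":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class CVReport:
    """Cross-validation and grid-search record for one training run."""

    folds: int
    seed: int
    selected_C: float
    selected_gamma: float
    kernel: str
    epsilon: float
    pooled_val_r2: float
    pooled_val_rmse: float
    pooled_train_r2: float
    pooled_train_rmse: float
    per_fold: list[dict] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )


def _safe_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Per-fold R2; NaN for folds too small or too degenerate to score."""
    if obs.size < 2:
        return float("nan")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return r_squared(obs, pred)


def grid_search_train(
    X,
    y,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    epsilon: float = DEFAULT_EPSILON,
    folds: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
) -> tuple[NOxRegressor, CVReport]:
    """Exhaustive (C, gamma) search scored by pooled k-fold validation RMSE.

    Folds are a seeded shuffle (labels are continuous, so no
    stratification).  Ties break toward smaller C, then smaller gamma.  The
    selected model is refit on all data; the report carries per-fold and
    pooled R-squared / RMSE for both the training and validation sides of
    the selected parameters, plus the full search trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < folds:
        raise ConfigurationError(
            f"need at least {folds} samples for {folds}-fold CV, got {X.shape[0]}"
        )
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    trace: list[dict] = []
    best: tuple[float, float, float] | None = None  # (rmse, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            pooled_obs, pooled_pred = [], []
            for train_idx, val_idx in splits:
                model = NOxRegressor(kernel=kernel, C=C, gamma=gamma, epsilon=epsilon)
                model.fit(X[train_idx], y[train_idx])
                pooled_pred.append(model.predict(X[val_idx]))
                pooled_obs.append(y[val_idx])
            obs = np.concatenate(pooled_obs)
            pred = np.concatenate(pooled_pred)
            val_rmse = rmse(obs, pred)
            trace.append(
                {"C": C, "gamma": gamma, "val_rmse": val_rmse, "val_r2": r_squared(obs, pred)}
            )
            if best is None or val_rmse < best[0]:
                best = (val_rmse, C, gamma)
    assert best is not None
    _, C_sel, gamma_sel = best
    per_fold: list[dict] = []
    pooled = {"train_obs": [], "train_pred": [], "val_obs": [], "val_pred": []}
    for k, (train_idx, val_idx) in enumerate(splits):
        model = NOxRegressor(kernel=kernel, C=C_sel, gamma=gamma_sel, epsilon=epsilon)
        model.fit(X[train_idx], y[train_idx])
        tp = model.predict(X[train_idx])
        vp = model.predict(X[val_idx])
        per_fold.append(
            {
                "fold": k,
                "train_r2": _safe_r2(y[train_idx], tp),
                "train_rmse": rmse(y[train_idx], tp),
                "val_r2": _safe_r2(y[val_idx], vp),
                "val_rmse": rmse(y[val_idx], vp),
            }
        )
        pooled["train_obs"].append(y[train_idx])
        pooled["train_pred"].append(tp)
        pooled["val_obs"].append(y[val_idx])
        pooled["val_pred"].append(vp)
    report = CVReport(
        folds=folds,
        seed=seed,
        selected_C=C_sel,
        selected_gamma=gamma_sel,
        kernel=kernel,
        epsilon=epsilon,
        pooled_val_r2=r_squared(
            np.concatenate(pooled["val_obs"]), np.concatenate(pooled["val_pred"])
        ),
        pooled_val_rmse=rmse(
            np.concatenate(pooled["val_obs"]), np.concatenate(pooled["val_pred"])
        ),
        pooled_train_r2=r_squared(
            np.concatenate(pooled["train_obs"]), np.concatenate(pooled["train_pred"])
        ),
        pooled_train_rmse=rmse(
            np.concatenate(pooled["train_obs"]), np.concatenate(pooled["train_pred"])
        ),
        per_fold=per_fold,
        trace=trace,
    )
    final = NOxRegressor(kernel=kernel, C=C_sel, gamma=gamma_sel, epsilon=epsilon).fit(X, y)
    return final, report


def predict_nox(
    model: NOxRegressor, spectrum: NOxSpectrum
) -> tuple[float, bool]:
    """Predict relative NOx-N for one isolated spectrum; returns
    (mg-N/L, extrapolation flag)."""
    x = spectrum.features(FEATURE_WINDOW)
    values, flags = model.predict_with_flags(x[None, :])
    return float(values[0]), bool(flags[0])


class LocalCalibration(RegressorMixin, BaseEstimator):
    """Site-specific linear correction ``lab = slope * predicted + intercept``.

    Relates model predictions to laboratory NOx measurements from the same
    site; applying it maps raw predictions to locally calibrated values.
    """

    def fit(self, predicted, lab) -> "LocalCalibration":
        x = np.asarray(predicted, dtype=float).ravel()
        y = np.asarray(lab, dtype=float).ravel()
        if x.size != y.size or x.size < 2:
            raise ValueError("need >= 2 paired points")
        if np.ptp(x) <= 1e-15:
            raise NumericalError("all predicted values identical: line is rank deficient")
        slope, intercept = np.polyfit(x, y, 1)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = r_squared(y, slope * x + intercept)
        self.n_points_ = int(x.size)
        return self

    def predict(self, predicted) -> np.ndarray:
        if not hasattr(self, "slope_"):
            raise NotFittedError("LocalCalibration is not fitted")
        x = np.asarray(predicted, dtype=float)
        return self.slope_ * x + self.intercept_


def fit_local_calibration(predicted, lab) -> LocalCalibration:
    return LocalCalibration().fit(predicted, lab)


# re-exported for convenience alongside the estimators
fit_scaler = SymmetricMinMaxScaler
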