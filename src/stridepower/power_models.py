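"""Peak-horizontal-power estimators: elastic net and a small neural network.

Both estimators follow the Model/Results pattern: construct a model from a
response vector and feature matrix, call :meth:`fit`, and work with the
returned Results object (coefficients, predictions, ``summary()``).

The elastic net minimizes

    sum_i (P_i - b0 - x_i' b)^2 + lambda * sum_j [(1-gamma)/2 b_j^2 + gamma |b_j|]

with the intercept unpenalized; gamma mixes ridge (0) and lasso (1) and
defaults to 0.5.  The neural network is a single hidden layer of 10
tan-sigmoid units with a linear output, trained by Levenberg-Marquardt on
sum-of-squares loss with early stopping on an internal validation split
(scheme NN15: 80/15/5 development/validation/hold-out, NN35: 60/35/5).

Features are z-scored with development-set statistics before either fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet as _SkElasticNet
from sklearn.model_selection import GroupKFold, KFold

__all__ = [
    "Normalizer",
    "ElasticNetPower",
    "ElasticNetPowerResults",
    "NeuralNetPower",
    "NeuralNetPowerResults",
    "select_best_model",
    "fit_elastic_net",
    "fit_neural_net",
]


@dataclass
class Normalizer:
    """Per-feature z-score statistics, fitted on development data only."""

    mean: np.ndarray
    scale: np.ndarray
    feature_names: list
    constant_mask: np.ndarray = field(default=None)

    @classmethod
    def fit(cls, X: np.ndarray, feature_names=None) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        constant = scale == 0.0
        if constant.any():
            names = (np.asarray(feature_names)[constant].tolist()
                     if feature_names is not None else np.flatnonzero(constant).tolist())
            warnings.warn(f"constant feature(s) after normalization: {names}; "
                          "their coefficients are fixed at 0")
        safe = np.where(constant, 1.0, scale)
        return cls(mean=mean, scale=safe,
                   feature_names=list(feature_names) if feature_names is not None else None,
                   constant_mask=constant)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        if self.constant_mask is not None and self.constant_mask.any():
            Z[:, self.constant_mask] = 0.0
        return Z


def _as_matrix(exog, feature_names):
    if isinstance(exog, pd.DataFrame):
        return exog.to_numpy(float), list(exog.columns)
    X = np.asarray(exog, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(feature_names)


def _check_features(model_names, exog):
    if isinstance(exog, pd.DataFrame):
        if list(exog.columns) != list(model_names):
            missing = set(model_names) - set(exog.columns)
            if missing:
                raise KeyError(f"prediction data lacks feature(s): {sorted(missing)}")
            exog = exog[list(model_names)]
        return exog.to_numpy(float)
    X = np.asarray(exog, dtype=float)
    if X.shape[1] != len(model_names):
        raise KeyError(
            f"prediction data has {X.shape[1]} features, model expects {len(model_names)}"
        )
    return X


# ---------------------------------------------------------------------------
# Elastic net


class ElasticNetPower:
    """Elastic-net model of per-second peak horizontal power.

    Parameters
    ----------
    endog : array-like
        Response (reference power, W), one value per row of ``exog``.
    exog : DataFrame or ndarray
        Feature matrix (selected features, unnormalized).
    gamma : float
        L1/L2 mix in [0, 1]; 0.5 by default.
    """

    def __init__(self, endog, exog, gamma: float = 0.5, feature_names=None,
                 condition: str | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog, self.feature_names = _as_matrix(exog, feature_names)
        if self.endog.size != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        self.gamma = gamma
        self.condition = condition

    @classmethod
    def from_table(cls, table, gamma: float = 0.5, features=None):
        feats = features if features is not None else table.feature_columns
        return cls(table.P.to_numpy(float), table.frame[feats], gamma=gamma)

    # -- lambda grid -------------------------------------------------------
    def lambda_max(self) -> float:
        """Smallest penalty that zeroes every coefficient (gamma > 0)."""
        Z = Normalizer.fit(self.exog, self.feature_names).transform(self.exog)
        y = self.endog - self.endog.mean()
        gamma = max(self.gamma, 1e-3)
        return float(2.0 * np.max(np.abs(Z.T @ y)) / gamma)

    def default_lambda_grid(self, n_points: int = 100, decades: float = 4.0) -> np.ndarray:
        lmax = self.lambda_max()
        return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_points)

    def _truncate_path(self, Z, y, grid, fdev: float = 1e-5) -> np.ndarray:
        """Stop the descending penalty path once the fit saturates.

        Mirrors coordinate-descent path conventions: walking from the
        strongest penalty down, the path ends when the fraction of deviance
        explained improves by less than ``fdev``; smaller penalties only
        relax shrinkage noise into the coefficients.
        """
        tss = float(np.sum((y - y.mean()) ** 2))
        prev_dev = -np.inf
        for i, lam in enumerate(grid):
            b0, b = self._solve(Z, y, lam)
            dev = 1.0 - float(np.sum((y - b0 - Z @ b) ** 2)) / tss
            if i > 0 and dev - prev_dev < fdev * dev:
                return grid[: i + 1]
            prev_dev = dev
        return grid

    # -- solvers -----------------------------------------------------------
    def _solve(self, Z, y, lam) -> tuple[float, np.ndarray]:
        n = y.size
        if lam == 0.0:
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), Z]), y, rcond=None)
            return float(beta[0]), beta[1:]
        if self.gamma == 0.0:
            # ridge closed form on centred data; penalty lambda/2 * ||b||^2
            yc = y - y.mean()
            k = Z.shape[1]
            beta = np.linalg.solve(Z.T @ Z + (lam / 2.0) * np.eye(k), Z.T @ yc)
            return float(y.mean() - Z.mean(axis=0) @ beta), beta
        # sklearn objective is 1/(2n) RSS + alpha*(l1 |b| + (1-l1)/2 b^2)
        sk = _SkElasticNet(alpha=lam / (2.0 * n), l1_ratio=self.gamma,
                           fit_intercept=True, max_iter=50_000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk.fit(Z, y)
        return float(sk.intercept_), sk.coef_.copy()

    def _bic_select(self, Z, y, grid) -> tuple[float, pd.DataFrame]:
        """Pick the penalty via BIC over the path's distinct supports.

        Each distinct support encountered while walking the penalty path
        downwards is scored by the BIC of its ordinary-least-squares refit
        (shrinkage bias would otherwise pollute the likelihood term); the
        returned penalty is the smallest on the grid attaining the
        BIC-minimal support, i.e. the least-shrunk fit of that support.
        """
        n = y.size
        rows = []
        supports: dict = {}
        for lam in grid:
            b0, b = self._solve(Z, y, lam)
            supp = tuple(np.flatnonzero(b != 0.0))
            if supp in supports:
                supports[supp]["lambda_min"] = lam
                continue
            cols = list(supp)
            A = np.column_stack([np.ones(n), Z[:, cols]]) if cols else np.ones((n, 1))
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ coef) ** 2))
            bic = n * np.log(max(rss, 1e-300) / n) + (len(cols) + 1) * np.log(n)
            supports[supp] = {"bic": bic, "lambda_min": lam}
            rows.append({"n_features": len(cols), "bic": bic, "lambda_first": lam})
        best = min(supports.values(), key=lambda d: d["bic"])
        return float(best["lambda_min"]), pd.DataFrame(rows)

    def fit(self, lambda_: float | None = None, lambda_grid=None, cv: int = 5,
            selection: str = "path_bic", groups=None,
            seed: int = 0) -> "ElasticNetPowerResults":
        """Fit at a fixed penalty or select one along the penalty path.

        Without ``lambda_``, the grid (default: 100 log-spaced points
        spanning 4 decades below the all-zero penalty, truncated where the
        deviance saturates) is searched by the ``selection`` rule:

        * ``'path_bic'`` (default) — BIC over ordinary-least-squares refits
          of the supports along the path; selection-consistent, so planted
          sparse signals are recovered without shrinkage-noise features.
        * ``'1se'`` — K-fold CV, largest penalty within one standard error
          of the CV-error minimum.
        * ``'min'`` — K-fold CV, error minimizer.

        ``groups`` (e.g. participant labels) makes the CV folds grouped so
        no group straddles a fold boundary — appropriate when rows within a
        group are strongly dependent.
        """
        norm = Normalizer.fit(self.exog, self.feature_names)
        Z = norm.transform(self.exog)
        y = self.endog
        cv_table = None
        if lambda_ is None:
            grid = (np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
                    else self.default_lambda_grid())
            grid = np.sort(grid)[::-1]  # descending: sparsest first
            grid = self._truncate_path(Z, y, grid)
            if selection == "path_bic":
                lambda_, cv_table = self._bic_select(Z, y, grid)
            elif selection in ("1se", "min"):
                if groups is not None:
                    groups = np.asarray(groups)
                    n_splits = min(cv, np.unique(groups).size)
                    if n_splits < 2:
                        raise ValueError("grouped CV needs at least 2 groups")
                    splits = list(GroupKFold(n_splits=n_splits).split(Z, y, groups))
                else:
                    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
                    splits = list(folds.split(Z))
                cv = len(splits)
                errs = np.zeros((grid.size, cv))
                for f, (tr, va) in enumerate(splits):
                    for i, lam in enumerate(grid):
                        b0, b = self._solve(Z[tr], y[tr], lam)
                        errs[i, f] = np.mean((y[va] - b0 - Z[va] @ b) ** 2)
                mean_err = errs.mean(axis=1)
                se = errs.std(axis=1, ddof=1) / np.sqrt(cv)
                i_min = int(np.argmin(mean_err))
                if selection == "min":
                    i_pick = i_min
                else:  # largest penalty within one SE of the minimum
                    within = np.flatnonzero(mean_err <= mean_err[i_min] + se[i_min])
                    i_pick = int(within[0])
                lambda_ = float(grid[i_pick])
                cv_table = pd.DataFrame({"lambda": grid, "cv_mse": mean_err, "cv_se": se})
            else:
                raise ValueError("selection must be 'path_bic', '1se' or 'min'")
        b0, beta = self._solve(Z, y, float(lambda_))
        return ElasticNetPowerResults(model=self, normalizer=norm,
                                      intercept=b0, beta=beta,
                                      lambda_=float(lambda_), cv_table=cv_table)


@dataclass
class ElasticNetPowerResults:
    """Fitted elastic net: coefficients on z-scored features."""

    model: ElasticNetPower
    normalizer: Normalizer
    intercept: float
    beta: np.ndarray
    lambda_: float
    cv_table: pd.DataFrame | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.feature_names, name="beta")

    @property
    def nonzero(self) -> list:
        return [n for n, b in zip(self.model.feature_names, self.beta) if b != 0.0]

    def predict(self, exog) -> np.ndarray:
        X = _check_features(self.model.feature_names, exog)
        return self.intercept + self.normalizer.transform(X) @ self.beta

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def summary(self) -> str:
        resid = self.model.endog - self.fittedvalues
        lines = [
            "Elastic-net horizontal power model",
            "=" * 44,
            f"observations:        {self.model.endog.size}",
            f"features:            {len(self.beta)} ({len(self.nonzero)} nonzero)",
            f"gamma (L1 mix):      {self.model.gamma}",
            f"lambda:              {self.lambda_:.6g}",
            f"intercept (W):       {self.intercept:.2f}",
            f"residual RMS (W):    {np.sqrt(np.mean(resid ** 2)):.2f}",
            "",
            "largest standardized coefficients:",
        ]
        top = self.params.abs().sort_values(ascending=False).head(10)
        for name in top.index:
            lines.append(f"  {name:20s} {self.params[name]:+10.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Neural network (Levenberg-Marquardt)

_SCHEMES = {"NN15": (0.80, 0.15, 0.05), "NN35": (0.60, 0.35, 0.05)}


class NeuralNetPower:
    """One-hidden-layer (10 tanh units) network for peak horizontal power.

    The row split scheme is internal to training: the validation share
    drives early stopping and the small hold-out is kept untouched for a
    final sanity error; neither overlaps the participant-wise test set.
    """

    def __init__(self, endog, exog, scheme: str = "NN15", n_hidden: int = 10,
                 feature_names=None, condition: str | None = None):
        if scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {sorted(_SCHEMES)}")
        self.endog = np.asarray(endog, dtype=float)
        self.exog, self.feature_names = _as_matrix(exog, feature_names)
        if self.endog.size != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.scheme = scheme
        self.n_hidden = n_hidden
        self.condition = condition

    @classmethod
    def from_table(cls, table, scheme: str = "NN15", features=None):
        feats = features if features is not None else table.feature_columns
        return cls(table.P.to_numpy(float), table.frame[feats], scheme=scheme)

    @property
    def n_params(self) -> int:
        k = self.exog.shape[1]
        return self.n_hidden * (k + 1) + self.n_hidden + 1

    # -- forward pass and Jacobian ----------------------------------------
    @staticmethod
    def _unpack(theta, k, h):
        W1 = theta[: h * k].reshape(h, k)
        b1 = theta[h * k: h * k + h]
        w2 = theta[h * k + h: h * k + 2 * h]
        b2 = theta[-1]
        return W1, b1, w2, b2

    @staticmethod
    def _forward(theta, X, h):
        k = X.shape[1]
        W1, b1, w2, b2 = NeuralNetPower._unpack(theta, k, h)
        H = np.tanh(X @ W1.T + b1)
        return H @ w2 + b2, H

    def _jacobian(self, theta, X, H):
        n, k = X.shape
        h = self.n_hidden
        _, _, w2, _ = self._unpack(theta, k, h)
        dtan = (1.0 - H ** 2) * w2  # (n, h)
        J = np.empty((n, self.n_params))
        J[:, : h * k] = (dtan[:, :, None] * X[:, None, :]).reshape(n, h * k)
        J[:, h * k: h * k + h] = dtan
        J[:, h * k + h: h * k + 2 * h] = H
        J[:, -1] = 1.0
        return J

    def fit(self, seed: int = 0, max_epochs: int = 200, patience: int = 6,
            mu0: float = 1e-2, mu_factor: float = 10.0) -> "NeuralNetPowerResults":
        """Train by Levenberg-Marquardt with validation early stopping.

        Each epoch solves (J'J + mu I) d = J'r; mu shrinks after an
        improving step and grows otherwise (damped Gauss-Newton). Training
        stops when the validation loss has not improved for ``patience``
        epochs; the best-validation weights are returned. A warning is
        raised (not an error) if the epoch budget runs out first.
        """
        if self.endog.size < 50:
            raise ValueError("need at least 50 rows to train the network")
        rng = np.random.default_rng(seed)
        norm = Normalizer.fit(self.exog, self.feature_names)
        Z = norm.transform(self.exog)
        y_mean, y_sd = self.endog.mean(), self.endog.std(ddof=0)
        y_sd = y_sd if y_sd > 0 else 1.0
        y = (self.endog - y_mean) / y_sd

        n = y.size
        f_dev, f_val, _ = _SCHEMES[self.scheme]
        perm = rng.permutation(n)
        n_dev = int(round(f_dev * n))
        n_val = int(round(f_val * n))
        dev, val, hold = perm[:n_dev], perm[n_dev:n_dev + n_val], perm[n_dev + n_val:]

        k, h = Z.shape[1], self.n_hidden
        limit = np.sqrt(6.0 / (k + h))
        theta = np.concatenate([
            rng.uniform(-limit, limit, h * k),
            np.zeros(h),
            rng.uniform(-1.0, 1.0, h) / np.sqrt(h),
            [0.0],
        ])

        Xd, yd = Z[dev], y[dev]
        Xv, yv = Z[val], y[val]
        mu = mu0
        pred, H = self._forward(theta, Xd, h)
        r = yd - pred
        loss = float(r @ r)
        best_theta = theta.copy()
        best_val = np.inf
        stall = 0
        history = []
        converged = False
        eye = np.eye(self.n_params)
        for epoch in range(max_epochs):
            J = self._jacobian(theta, Xd, H)
            JtJ = J.T @ J
            Jtr = J.T @ r
            improved = False
            for _ in range(8):  # inner damping search
                try:
                    step = np.linalg.solve(JtJ + mu * eye, Jtr)
                except np.linalg.LinAlgError:
                    mu *= mu_factor
                    continue
                cand = theta + step
                pred_c, H_c = self._forward(cand, Xd, h)
                r_c = yd - pred_c
                loss_c = float(r_c @ r_c)
                if loss_c < loss:
                    theta, r, loss, H = cand, r_c, loss_c, H_c
                    mu = max(mu / mu_factor, 1e-12)
                    improved = True
                    break
                mu *= mu_factor
            val_pred, _ = self._forward(theta, Xv, h)
            val_loss = float(np.mean((yv - val_pred) ** 2))
            history.append((epoch, loss / max(1, n_dev), val_loss))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_theta = theta.copy()
                stall = 0
            else:
                stall += 1
            if stall >= patience:
                converged = True
                break
            if not improved and mu > 1e10:
                converged = True  # damping exhausted: local minimum
                break
        if not converged:
            warnings.warn("Levenberg-Marquardt reached the epoch budget; "
                          "returning best-validation weights")
        hold_pred, _ = self._forward(best_theta, Z[hold], h)
        hold_mse = float(np.mean((y[hold] - hold_pred) ** 2)) if hold.size else np.nan
        return NeuralNetPowerResults(
            model=self, normalizer=norm, theta=best_theta,
            y_mean=y_mean, y_sd=y_sd, seed=seed,
            val_mse=best_val, holdout_mse=hold_mse,
            history=pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"]),
        )


@dataclass
class NeuralNetPowerResults:
    """Trained network weights with the scaling needed to apply them."""

    model: NeuralNetPower
    normalizer: Normalizer
    theta: np.ndarray
    y_mean: float
    y_sd: float
    seed: int
    val_mse: float
    holdout_mse: float
    history: pd.DataFrame

    def predict(self, exog) -> np.ndarray:
        X = _check_features(self.model.feature_names, exog)
        Z = self.normalizer.transform(X)
        pred, _ = NeuralNetPower._forward(self.theta, Z, self.model.n_hidden)
        return self.y_mean + self.y_sd * pred

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def summary(self) -> str:
        return "\n".join([
            f"Neural-network horizontal power model ({self.model.scheme})",
            "=" * 44,
            f"observations:        {self.model.endog.size}",
            f"features:            {self.model.exog.shape[1]}",
            f"hidden units:        {self.model.n_hidden}",
            f"parameters:          {self.model.n_params}",
            f"epochs run:          {len(self.history)}",
            f"validation MSE:      {self.val_mse * self.y_sd ** 2:.2f} W^2",
            f"hold-out MSE:        {self.holdout_mse * self.y_sd ** 2:.2f} W^2",
        ])


# ---------------------------------------------------------------------------
# Functional wrappers and model selection


def fit_elastic_net(Xd, Pd, gamma: float = 0.5, lambda_grid=None,
                    lambda_: float | None = None, seed: int = 0) -> ElasticNetPowerResults:
    return ElasticNetPower(Pd, Xd, gamma=gamma).fit(
        lambda_=lambda_, lambda_grid=lambda_grid, seed=seed)


def fit_neural_net(Xd, Pd, scheme: str = "NN15", seed: int = 0,
                   **fit_kw) -> NeuralNetPowerResults:
    return NeuralNetPower(Pd, Xd, scheme=scheme).fit(seed=seed, **fit_kw)


def select_best_model(candidates: dict, X_val, y_val) -> tuple[str, dict]:
    """Label of the candidate with the lowest validation MAE (W).

    ``candidates`` maps labels (e.g. EN/NN15/NN35) to fitted Results.
    Ties prefer the elastic net (the simpler model), then label order.
    """
    y_val = np.asarray(y_val, dtype=float)
    maes = {}
    for label, res in candidates.items():
        maes[label] = float(np.mean(np.abs(y_val - res.predict(X_val))))
    order = sorted(maes, key=lambda l: (maes[l], 0 if l.upper() == "EN" else 1, l))
    return order[0], maes
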