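"""Immune scoring, evasion labelling, parameter scaling, and regularized regression.

The immune score is the geometric mean of immune-marker expression; per-type
markers are selected by positive Spearman correlation with neoantigen load;
immune-evasion samples combine a high (> 70th percentile) load with a low
(< 30th percentile) marker signature; resistance parameters are min-max
scaled to [0, 1] (prediction scores, already in [0, 1], pass through); and
resistance/evasion is regressed on the scaled parameters with simple, lasso,
elastic-net, and ridge linear models under 5-fold cross validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold

from .cnn_binding import roc_auc
from .errors import ConfigError, DegenerateDistribution, DegenerateLabels, MarkerError

REGRESSION_METHODS = ("simple", "lasso", "elastic_net", "ridge")
DEFAULT_PENALTY_GRID = tuple(np.logspace(-4, 1, 20))
ELASTIC_NET_MIXING = 0.5

LOAD_PERCENTILE = 70.0
SIGNATURE_PERCENTILE = 30.0


def immune_score(expr_row: pd.Series, markers: list[str],
                 pseudocount: float = 1.0) -> float:
    """Geometric mean of marker expression: exp(mean(ln(x + pseudocount))).

    The default pseudocount of 1 guards zeros on the log2-count scale; pass
    ``pseudocount=0`` for strictly positive inputs.
    """
    present = [m for m in markers if m in expr_row.index]
    if not present:
        raise MarkerError("no marker genes intersect the expression row")
    values = expr_row[present].to_numpy(dtype=float) + pseudocount
    if np.any(values <= 0):
        raise ValueError("non-positive values under the chosen pseudocount")
    return float(np.exp(np.mean(np.log(values))))


def select_markers(expr: pd.DataFrame, loads: pd.Series, n_markers: int,
                   candidates: list[str] | None = None) -> list[str]:
    """Top-n candidate markers by positive Spearman correlation with load.

    Ties are broken alphabetically; candidates anticorrelated (or
    uncorrelated) with load are never selected.
    """
    if candidates is None:
        from .synthetic_data import ALL_MARKERS
        candidates = ALL_MARKERS
    loads = loads.reindex(expr.index)
    rows = []
    for gene in candidates:
        if gene not in expr.columns:
            continue
        rho = spearmanr(expr[gene].to_numpy(), loads.to_numpy()).statistic
        if np.isfinite(rho) and rho > 0:
            rows.append((gene, float(rho)))
    if not rows:
        raise MarkerError("no candidate marker positively correlates with load")
    rows.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in rows[:n_markers]]


def evasion_labels(loads: pd.Series, signatures: pd.Series) -> pd.Series:
    """Evader iff load > 70th percentile AND signature < 30th percentile.

    Percentiles use the linear-interpolation convention; both comparisons
    are strict.
    """
    loads = loads.astype(float)
    signatures = signatures.reindex(loads.index).astype(float)
    if len(loads) < 10:
        raise ConfigError("need at least 10 samples")
    if loads.nunique() == 1 or signatures.nunique() == 1:
        raise DegenerateDistribution("constant load or signature vector")
    load_cut = np.percentile(loads.to_numpy(), LOAD_PERCENTILE)
    sig_cut = np.percentile(signatures.to_numpy(), SIGNATURE_PERCENTILE)
    return pd.Series((loads > load_cut) & (signatures < sig_cut),
                     index=loads.index, name="evader")


def scale_parameter(values: pd.Series, is_score: bool = False) -> pd.Series:
    """Min-max scale to [0, 1]; prediction scores pass through unscaled."""
    values = values.astype(float)
    if is_score:
        if values.min() < 0 or values.max() > 1:
            raise ConfigError("prediction scores must already lie in [0, 1]")
        return values
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateDistribution("constant parameter vector cannot be scaled")
    return (values - lo) / (hi - lo)


def fit_single(method: str, X: np.ndarray, y: np.ndarray, alpha: float = 0.0,
               fit_intercept: bool = True):
    """One linear model of the given family; returns the fitted estimator."""
    if method == "simple":
        est = LinearRegression(fit_intercept=fit_intercept)
    elif method == "lasso":
        est = Lasso(alpha=alpha, fit_intercept=fit_intercept, max_iter=50000)
    elif method == "elastic_net":
        est = ElasticNet(alpha=alpha, l1_ratio=ELASTIC_NET_MIXING,
                         fit_intercept=fit_intercept, max_iter=50000)
    elif method == "ridge":
        est = Ridge(alpha=alpha, fit_intercept=fit_intercept)
    else:
        raise ConfigError(f"unknown regression method {method!r}")
    est.fit(X, y)
    return est


@dataclass
class MethodReport:
    auc: float
    penalty: float
    coefficients: pd.Series
    importance: pd.Series  # |standardized coefficient|, descending


def fit_regressions(features: pd.DataFrame, labels: pd.Series, folds: int = 5,
                    seed: int = 0,
                    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
                    ) -> dict[str, MethodReport]:
    """Simple / lasso / elastic-net / ridge regression of a binary outcome.

    For penalized methods the penalty is chosen by ``folds``-fold
    cross-validated mean squared error; the reported AUC comes from the
    cross-validated predictions at that penalty, and variable importance is
    the ranking of absolute standardized coefficients of the full-data fit.
    """
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("labels contain a single class")
    splits = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(X))

    def cv_predictions(method: str, alpha: float) -> np.ndarray:
        pred = np.zeros(len(y))
        for train_idx, test_idx in splits:
            est = fit_single(method, X[train_idx], y[train_idx], alpha=alpha)
            pred[test_idx] = est.predict(X[test_idx])
        return pred

    reports: dict[str, MethodReport] = {}
    feat_std = X.std(axis=0, ddof=0)
    for method in REGRESSION_METHODS:
        if method == "simple":
            best_alpha, pred = 0.0, cv_predictions(method, 0.0)
        else:
            best_alpha, best_mse, pred = None, np.inf, None
            for alpha in penalty_grid:
                p = cv_predictions(method, alpha)
                mse = float(np.mean((p - y) ** 2))
                if mse < best_mse:
                    best_alpha, best_mse, pred = float(alpha), mse, p
        est = fit_single(method, X, y, alpha=best_alpha)
        coefs = pd.Series(est.coef_, index=features.columns, name="coefficient")
        if np.ptp(pred) == 0 or (method != "simple" and np.allclose(coefs, 0.0)):
            auc = 0.5  # intercept-only model carries no ranking information
        else:
            auc = roc_auc(pred, y.astype(int))
        importance = (coefs.abs() * feat_std).sort_values(ascending=False)
        reports[method] = MethodReport(auc=auc, penalty=best_alpha,
                                       coefficients=coefs, importance=importance)
    return reports
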