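"""Multiple linear regression pIC50 prediction.

Forward and stepwise descriptor selection driven by partial-F p-values
(classic statistical-package semantics: enter while p < 0.01, stepwise
additionally removes included terms whose p rises above 0.05), model
choice across bootstrap 70/30 resplits by predictive R^2, and the
published 11-descriptor TRPA1 activity equation as a fixed predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MLRModel:
    terms: list[tuple[str, float]]
    intercept: float
    r2: float = float("nan")
    r2_pred: float = float("nan")
    rmsec: float = float("nan")
    rmsev: float = float("nan")

    def __post_init__(self) -> None:
        names = [n for n, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor in MLR model")

    def predict(self, vector: Mapping[str, float]) -> float:
        total = self.intercept
        for name, coef in self.terms:
            if name not in vector:
                raise KeyError(f"descriptor {name!r} missing from vector")
            total += coef * float(vector[name])
        return total

    def predict_table(self, table: pd.DataFrame) -> pd.Series:
        out = pd.Series(self.intercept, index=table.index, dtype=float)
        for name, coef in self.terms:
            if name not in table.columns:
                raise KeyError(f"descriptor {name!r} missing from table")
            out = out + coef * table[name].astype(float)
        return out

    @classmethod
    def from_mapping(cls, data: Mapping) -> "MLRModel":
        return cls(
            terms=[(str(n), float(c)) for n, c in data["terms"]],
            intercept=float(data["intercept"]),
        )

    @classmethod
    def load(cls, path: str | None = None) -> "MLRModel":
        """Load a model JSON; default = the published TRPA1 MLR equation."""
        if path is None:
            text = resources.files("screenmine.data").joinpath("trpa1_pic50_mlr.json").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(json.loads(text))


#: the published TRPA1 pIC50 regression (11 descriptors).
TRPA1_MLR = MLRModel(
    terms=[
        ("GRAV4", 0.0004),
        ("khs.dO", -0.3038),
        ("nHBAcc", -0.0954),
        ("C2SP3", 0.2523),
        ("DPSA3", 0.0117),
        ("khs.ssCH2", -0.0944),
        ("nAcid", -1.1296),
        ("khs.ddsN", 1.2054),
        ("C2SP2", -0.0600),
        ("MDEN13", -3.2101),
        ("C3SP2", 0.0939),
    ],
    intercept=4.2769,
)


def predict_pic50(descriptor_vector: Mapping[str, float], model: MLRModel | None = None) -> float:
    """pIC50 from the published equation (or any fitted MLR model)."""
    return (model or TRPA1_MLR).predict(descriptor_vector)


# ---------------------------------------------------------------------------
# splits


def bootstrap_splits(
    n: int, n_splits: int = 10, train_fraction: float = 0.7, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random 70/30 repartitions (without replacement within
    each split), reproducible for a fixed seed."""
    if n < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    k = int(round(train_fraction * n))
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:k]), np.sort(perm[k:])))
    return out


# ---------------------------------------------------------------------------
# forward / stepwise selection


def _partial_f_pvalue(y: np.ndarray, X_base: np.ndarray, x_new: np.ndarray) -> float:
    """p-value of the nested-model F test for adding one column."""
    n = len(y)
    X0 = sm.add_constant(X_base) if X_base.size else np.ones((n, 1))
    X1 = np.column_stack([X0, x_new])
    if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
        return 1.0  # collinear: never enters
    rss0 = _rss(y, X0)
    rss1 = _rss(y, X1)
    df_resid = n - X1.shape[1]
    if df_resid <= 0 or rss1 <= 0:
        return 1.0
    f = (rss0 - rss1) / (rss1 / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _term_pvalues(y: np.ndarray, X: pd.DataFrame) -> pd.Series:
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return fit.pvalues.drop("const")


def fit_mlr(
    table: pd.DataFrame,
    response: Sequence[float],
    method: str = "stepwise",
    p_enter: float = 0.01,
    p_remove: float = 0.05,
) -> MLRModel:
    """Forward or stepwise MLR on the candidate descriptor table.

    Forward: repeatedly add the descriptor with the smallest partial-F
    p-value while it is below ``p_enter``.  Stepwise: after each
    addition, remove any included descriptor whose p-value has risen
    above ``p_remove``.  Terminates when no addition qualifies; with no
    qualifying descriptor at all the model is intercept-only.
    """
    if method not in ("forward", "stepwise"):
        raise ValueError("method must be 'forward' or 'stepwise'")
    y = np.asarray(response, dtype=float)
    included: list[str] = []
    candidates = [c for c in table.columns if np.ptp(table[c].to_numpy(dtype=float)) > 0]
    while True:
        remaining = [c for c in candidates if c not in included]
        if not remaining:
            break
        X_base = table[included].to_numpy(dtype=float) if included else np.empty((len(y), 0))
        pvals = {
            c: _partial_f_pvalue(y, X_base, table[c].to_numpy(dtype=float)) for c in remaining
        }
        best = min(pvals, key=pvals.get)
        if pvals[best] >= p_enter:
            break
        included.append(best)
        if method == "stepwise" and len(included) > 1:
            while len(included) > 1:
                term_p = _term_pvalues(y, table[included])
                worst = term_p.idxmax()
                if term_p[worst] > p_remove:
                    included.remove(worst)
                else:
                    break
    return _ols_model(table, y, included)


def _ols_model(table: pd.DataFrame, y: np.ndarray, included: list[str]) -> MLRModel:
    if included:
        X = sm.add_constant(table[included].astype(float))
        fit = sm.OLS(y, X).fit()
        terms = [(name, float(fit.params[name])) for name in included]
        intercept = float(fit.params["const"])
        r2 = float(fit.rsquared)
        rmsec = float(np.sqrt(np.mean(fit.resid**2)))
    else:
        terms, intercept = [], float(y.mean())
        r2, rmsec = 0.0, float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    return MLRModel(terms=terms, intercept=intercept, r2=r2, rmsec=rmsec)


# ---------------------------------------------------------------------------
# evaluation / model choice


def evaluate_regression(
    model: MLRModel, table: pd.DataFrame, observed: Sequence[float]
) -> tuple[float, float]:
    """(R^2_pred as squared Pearson correlation, RMSE) on a test set.

    R^2 is NaN when either the observations or the predictions have zero
    variance.
    """
    y = np.asarray(observed, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict_table(table).to_numpy()
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        return float("nan"), rmse
    r = np.corrcoef(y, pred)[0, 1]
    return float(r**2), rmse


def select_best_model(
    models: Sequence[MLRModel],
    evaluations: Sequence[tuple[float, float]],
) -> MLRModel:
    """Highest R^2_pred, tie-break lowest RMSE; evaluations pair with
    models positionally."""
    if not models:
        raise ValueError("no models")
    ranked = sorted(
        zip(models, evaluations),
        key=lambda t: (-(t[1][0] if np.isfinite(t[1][0]) else -np.inf), t[1][1]),
    )
    best, (r2p, rmsev) = ranked[0]
    best.r2_pred, best.rmsev = float(r2p), float(rmsev)
    return best


def fit_mlr_bootstrap(
    table: pd.DataFrame,
    response: Sequence[float],
    method: str = "stepwise",
    n_splits: int = 10,
    seed: int = 0,
    **kwargs,
) -> MLRModel:
    """Fit one model per bootstrap resplit and keep the best validated one."""
    y = np.asarray(response, dtype=float)
    models, evals = [], []
    for train, test in bootstrap_splits(len(y), n_splits=n_splits, seed=seed):
        m = fit_mlr(table.iloc[train], y[train], method=method, **kwargs)
        evals.append(evaluate_regression(m, table.iloc[test], y[test]))
        models.append(m)
    return select_best_model(models, evals)
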