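"""Global logistic ranking model and blood-brain-barrier filter.

The final screening stage combines three upstream outputs per candidate
— the predicted activity class (0/1), the MLR-predicted pIC50 and an
externally supplied docking score dG (kcal/mol) — into a single
probability of potent inhibition through a logistic model:

    P = 1 / (1 + exp(-(b_class*Class + b_pic50*pIC50pred + b_dg*dG + b0)))

The published TRPA1 coefficients (2.725, 3.967, -0.404, -29.986) ship
as a packaged model; :func:`fit_logistic` refits the same form on new
data.  Candidates are ranked by probability and optionally filtered by
CNS-permeability physicochemical rules (MW < 500, 2 <= AlogP <= 5,
PSA < 90 A^2, HBD <= 3, HBA <= 7).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


@dataclass
class LogisticModel:
    b_class: float
    b_pic50: float
    b_dg: float
    intercept: float
    separable: bool = False  # flagged when the fit was perfectly separable

    def linear_predictor(self, activity_class: float, pic50_pred: float, dg: float) -> float:
        return (
            self.b_class * activity_class
            + self.b_pic50 * pic50_pred
            + self.b_dg * dg
            + self.intercept
        )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "LogisticModel":
        return cls(
            b_class=float(data["b_class"]),
            b_pic50=float(data["b_pic50"]),
            b_dg=float(data["b_dg"]),
            intercept=float(data["intercept"]),
        )

    @classmethod
    def load(cls, path: str | None = None) -> "LogisticModel":
        """Load a model JSON; default = the published TRPA1 ranking model."""
        if path is None:
            text = (
                resources.files("screenmine.data").joinpath("trpa1_ranking_logit.json").read_text()
            )
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(json.loads(text))


#: the published TRPA1 global ranking model.
TRPA1_LOGIT = LogisticModel(b_class=2.725, b_pic50=3.967, b_dg=-0.404, intercept=-29.986)


def inhibition_probability(
    activity_class: int,
    pic50_pred: float,
    dg: float,
    model: LogisticModel | None = None,
) -> float:
    """Probability of potent inhibition from the logistic model."""
    model = model or TRPA1_LOGIT
    z = model.linear_predictor(activity_class, pic50_pred, dg)
    # numerically safe logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def fit_logistic(
    activity_class: Sequence[int],
    pic50_pred: Sequence[float],
    dg: Sequence[float],
    labels: Sequence[int],
    max_abs_coef: float = 50.0,
) -> LogisticModel:
    """Maximum-likelihood logistic fit on (class, pIC50pred, dG).

    Perfect separation is flagged and coefficients are capped at
    ``max_abs_coef`` instead of diverging.
    """
    y = np.asarray(labels, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required to fit")
    X = sm.add_constant(
        pd.DataFrame(
            {
                "activity_class": np.asarray(activity_class, dtype=float),
                "pic50_pred": np.asarray(pic50_pred, dtype=float),
                "dg": np.asarray(dg, dtype=float),
            }
        ),
        has_constant="add",
    )
    separable = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        params = fit.params
        if not fit.mle_retvals.get("converged", True):
            separable = True
    except Exception:
        separable = True
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit_regularized(disp=False, alpha=1e-6, maxiter=500)
        params = fit.params
    coefs = {
        "intercept": float(params["const"]),
        "b_class": float(params["activity_class"]),
        "b_pic50": float(params["pic50_pred"]),
        "b_dg": float(params["dg"]),
    }
    if any(abs(v) > max_abs_coef for v in coefs.values()):
        separable = True
        coefs = {k: float(np.clip(v, -max_abs_coef, max_abs_coef)) for k, v in coefs.items()}
        log.warning("logistic fit looks separable; coefficients capped at %.0f", max_abs_coef)
    return LogisticModel(
        b_class=coefs["b_class"],
        b_pic50=coefs["b_pic50"],
        b_dg=coefs["b_dg"],
        intercept=coefs["intercept"],
        separable=separable,
    )


# ---------------------------------------------------------------------------
# BBB filter


@dataclass(frozen=True)
class BBBRules:
    """CNS-permeability bounds. 'under' bounds are strict; ranges and
    'or fewer' counts are inclusive."""

    max_mw: float = 500.0
    min_alogp: float = 2.0
    max_alogp: float = 5.0
    max_psa: float = 90.0
    max_hbd: int = 3
    max_hba: int = 7


def bbb_filter(
    mw: float,
    alogp: float,
    psa: float,
    hbd: int,
    hba: int,
    rules: BBBRules = BBBRules(),
) -> tuple[bool, list[str]]:
    """(pass, violated-rule names) for the physicochemical CNS filter."""
    failures = []
    if not mw < rules.max_mw:
        failures.append("MW")
    if not rules.min_alogp <= alogp <= rules.max_alogp:
        failures.append("AlogP")
    if not psa < rules.max_psa:
        failures.append("PSA")
    if not hbd <= rules.max_hbd:
        failures.append("HBD")
    if not hba <= rules.max_hba:
        failures.append("HBA")
    return (not failures, failures)


# ---------------------------------------------------------------------------
# ranking


def rank_candidates(
    candidates: pd.DataFrame,
    model: LogisticModel | None = None,
    probability_thresholds: Sequence[float] = (0.5, 0.9, 0.95, 0.99),
    bbb_rules: BBBRules | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rank candidates by inhibition probability.

    ``candidates`` needs columns activity_class, pic50_pred, dg (rows
    with missing dg are excluded and logged) and, when ``bbb_rules`` is
    given, MW/ALogP/TPSA/nHBDon/nHBAcc.  Ties break by mining score
    (descending, when a ``score`` column exists) then id ascending, so
    output files are deterministic.  Returns (ranked table, report with
    counts above each threshold pre- and post-BBB).
    """
    model = model or TRPA1_LOGIT
    df = candidates.copy()
    missing = df["dg"].isna()
    if missing.any():
        for ident in df.index[missing]:
            log.warning("%s: missing dg, excluded from ranking", ident)
        df = df[~missing]
    df["probability"] = [
        inhibition_probability(int(c), float(p), float(g), model)
        for c, p, g in zip(df["activity_class"], df["pic50_pred"], df["dg"])
    ]
    if bbb_rules is not None:
        passes, fails = [], []
        for _, row in df.iterrows():
            ok, f = bbb_filter(
                row["MW"], row["ALogP"], row["TPSA"], row["nHBDon"], row["nHBAcc"], bbb_rules
            )
            passes.append(ok)
            fails.append(";".join(f))
        df["bbb_pass"] = passes
        df["bbb_failures"] = fails
    sort_cols = ["probability"] + (["score"] if "score" in df.columns else [])
    df = (
        df.reset_index()
        .sort_values(sort_cols + ["id"], ascending=[False] * len(sort_cols) + [True], kind="mergesort")
        .set_index("id")
    )
    report: dict = {"n_ranked": int(len(df))}
    for t in probability_thresholds:
        key = f"P>{t:g}"
        report[key] = int((df["probability"] > t).sum())
        if bbb_rules is not None:
            report[key + "_bbb"] = int(((df["probability"] > t) & df["bbb_pass"]).sum())
    return df, report
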