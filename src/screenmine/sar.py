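"""Statistical SAR mining.

Feature enrichment by two-sample t-test on pIC50 (pooled-variance by
default, matching classic statistical-package behaviour; Welch by
config), the mean-difference/range weighted index, per-descriptor ROC
AUC via the rank statistic, molecular similarity pairs and activity
cliffs, and descriptive statistics.

The similarity metric is pluggable: register any callable taking two
RDKit molecules and returning a value in [0, 1].  The default is a
Morgan circular-fingerprint Tanimoto; the 0.80 threshold used for
pair/cliff mining is configurable and its absolute meaning is
metric-dependent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats


@dataclass
class EnrichmentRow:
    feature: str
    n_present: int
    mean_present: float
    sd_present: float
    mean_difference: float
    p_value: float
    significant: bool
    testable: bool = True


# ---------------------------------------------------------------------------
# similarity metric registry

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_tanimoto(a: Chem.Mol, b: Chem.Mol) -> float:
    return DataStructs.TanimotoSimilarity(
        _MORGAN_GEN.GetFingerprint(a), _MORGAN_GEN.GetFingerprint(b)
    )


SIMILARITY_METRICS: dict[str, Callable[[Chem.Mol, Chem.Mol], float]] = {
    "morgan_tanimoto": morgan_tanimoto,
}


def register_similarity_metric(name: str, fn: Callable[[Chem.Mol, Chem.Mol], float]) -> None:
    SIMILARITY_METRICS[name] = fn


def _resolve_metric(metric) -> Callable[[Chem.Mol, Chem.Mol], float]:
    if callable(metric):
        return metric
    try:
        return SIMILARITY_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown similarity metric {metric!r}; registered: {sorted(SIMILARITY_METRICS)}"
        ) from None


# ---------------------------------------------------------------------------
# enrichment


def feature_enrichment(
    pic50: Sequence[float],
    features: pd.DataFrame,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> list[EnrichmentRow]:
    """Per-feature comparison of mean pIC50, present vs absent.

    Features present in every compound (or in none) have no comparison
    group and are excluded; zero-variance comparisons are flagged
    untestable.
    """
    y = np.asarray(pic50, dtype=float)
    if len(y) != len(features):
        raise ValueError("pIC50 and feature table lengths differ")
    rows: list[EnrichmentRow] = []
    for feat in features.columns:
        mask = features[feat].to_numpy(dtype=bool)
        n_p = int(mask.sum())
        if n_p == 0 or n_p == len(y):
            import logging

            logging.getLogger(__name__).warning(
                "feature %s present in %s compounds: no comparison group, excluded",
                feat, "all" if n_p else "no",
            )
            continue
        present, absent = y[mask], y[~mask]
        diff = float(present.mean() - absent.mean())
        pooled = np.concatenate([present, absent])
        if np.ptp(pooled) == 0 or (present.std(ddof=0) == 0 and absent.std(ddof=0) == 0):
            rows.append(
                EnrichmentRow(feat, n_p, float(present.mean()),
                              float(present.std(ddof=1)) if n_p > 1 else 0.0,
                              diff, np.nan, False, testable=False)
            )
            continue
        t = stats.ttest_ind(present, absent, equal_var=equal_var)
        rows.append(
            EnrichmentRow(
                feature=feat,
                n_present=n_p,
                mean_present=float(present.mean()),
                sd_present=float(present.std(ddof=1)) if n_p > 1 else 0.0,
                mean_difference=diff,
                p_value=float(t.pvalue),
                significant=bool(t.pvalue < alpha),
            )
        )
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "n_present": r.n_present,
                "mean_present": r.mean_present,
                "sd_present": r.sd_present,
                "mean_difference": r.mean_difference,
                "p_value": r.p_value,
                "significant": r.significant,
                "testable": r.testable,
            }
            for r in rows
        ]
    )


def weighted_index(values: Sequence[float], labels: Sequence[int]) -> float:
    """|mean(active) - mean(inactive)| / pooled range.

    NaN is returned (and flagged by callers) when the pooled range is
    zero.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if set(np.unique(lab)) - {0, 1} or len(set(lab)) < 2:
        raise ValueError("labels must contain both 0 and 1")
    rng = float(np.ptp(v))
    if rng == 0:
        return float("nan")
    return abs(float(v[lab == 1].mean() - v[lab == 0].mean())) / rng


def descriptor_auc(values: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC as the Mann-Whitney rank statistic, oriented >= 0.5.

    Equals the probability that a random active exceeds a random
    inactive, counting ties as 1/2.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    act, inact = v[lab == 1], v[lab == 0]
    if len(act) == 0 or len(inact) == 0:
        raise ValueError("labels must contain both 0 and 1")
    u = stats.mannwhitneyu(act, inact, alternative="two-sided").statistic
    auc = u / (len(act) * len(inact))
    return float(max(auc, 1.0 - auc))


# ---------------------------------------------------------------------------
# similarity pairs / activity cliffs


def similarity_pairs(
    set_a: Sequence[tuple[str, Chem.Mol]],
    set_b: Sequence[tuple[str, Chem.Mol]],
    metric="morgan_tanimoto",
    threshold: float = 0.80,
) -> list[tuple[str, str, float]]:
    """All cross-set pairs with similarity >= threshold."""
    fn = _resolve_metric(metric)
    out = []
    for (ida, ma), (idb, mb) in itertools.product(set_a, set_b):
        s = fn(ma, mb)
        if s >= threshold:
            out.append((ida, idb, float(s)))
    return out


def activity_cliffs(
    dataset: Sequence[tuple[str, Chem.Mol, float]],
    metric="morgan_tanimoto",
    sim_threshold: float = 0.80,
    gap: float = 2.0,
) -> list[tuple[str, str, float, float]]:
    """Pairs with similarity >= sim_threshold and |dpIC50| >= gap.

    Each unordered pair is reported once as (id_low, id_high, sim, dpIC50).
    """
    fn = _resolve_metric(metric)
    out = []
    for (ida, ma, ya), (idb, mb, yb) in itertools.combinations(dataset, 2):
        delta = abs(ya - yb)
        if delta < gap:
            continue
        s = fn(ma, mb)
        if s >= sim_threshold:
            first, second = sorted([ida, idb])
            out.append((first, second, float(s), float(delta)))
    return out


def summary_statistics(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """mean/SD/min/max per column (druglikeness report)."""
    if columns is not None:
        table = table[list(columns)]
    num = table.select_dtypes("number")
    if num.empty:
        return pd.DataFrame(columns=["mean", "sd", "min", "max"])
    return pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1).fillna(0.0),
            "min": num.min(),
            "max": num.max(),
        }
    )
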