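"""Cutoff-vote binary activity classifier.

Strong inhibitors (pIC50 > 7) are labelled active, weak inhibitors
(pIC50 < 6) inactive; moderate compounds are excluded from training.
Candidate descriptors pass a t-test / weighted-index / ROC-AUC pipeline
with greedy intercorrelation pruning, each survivor gets a single
cutoff chosen on the ROC curve (Youden J), and classification is a vote:
a compound is predicted active when at least ``vote_threshold`` of the
per-descriptor cutoffs agree.

The published four-descriptor TRPA1 model (DPSA3/ECCEN/SP6/SPC4 with
their printed cutoffs) ships as a packaged model file and as
:data:`TRPA1_CLASSIFIER`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sar import descriptor_auc, weighted_index


@dataclass(frozen=True)
class CutoffClassifier:
    descriptor: str
    cutoff: float
    direction: str = "above"  # active side of the cutoff

    def votes(self, value: float) -> int:
        if self.direction == "above":
            return int(value > self.cutoff)
        return int(value < self.cutoff)


@dataclass
class ClassifierModel:
    classifiers: list[CutoffClassifier]
    vote_threshold: int

    def __post_init__(self) -> None:
        names = [c.descriptor for c in self.classifiers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor in classifier model")
        if not 1 <= self.vote_threshold <= len(self.classifiers):
            raise ValueError("vote_threshold out of range")

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifiers": [
                    {"descriptor": c.descriptor, "cutoff": c.cutoff, "direction": c.direction}
                    for c in self.classifiers
                ],
                "vote_threshold": self.vote_threshold,
            },
            indent=1,
        )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ClassifierModel":
        return cls(
            classifiers=[CutoffClassifier(**c) for c in data["classifiers"]],
            vote_threshold=int(data["vote_threshold"]),
        )

    @classmethod
    def load(cls, path: str | None = None) -> "ClassifierModel":
        """Load a model JSON; default = the published TRPA1 classifier."""
        if path is None:
            text = (
                resources.files("screenmine.data")
                .joinpath("trpa1_activity_classifier.json")
                .read_text()
            )
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(json.loads(text))


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    f1: float


# ---------------------------------------------------------------------------
# labelling


def label_activity_classes(pic50: Sequence[float]) -> np.ndarray:
    """0 = weak (pIC50 < 6), 1 = strong (pIC50 > 7), NaN = moderate
    (6 <= pIC50 <= 7, excluded from classifier training)."""
    y = np.asarray(pic50, dtype=float)
    out = np.full(len(y), np.nan)
    out[y < 6.0] = 0.0
    out[y > 7.0] = 1.0
    return out


# ---------------------------------------------------------------------------
# descriptor selection


def select_classifier_descriptors(
    table: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = 0.05,
    min_weight: float = 0.2,
    min_auc: float = 0.8,
    max_corr: float = 0.9,
) -> list[str]:
    """t-test significance -> weighted index -> AUC -> greedy pruning of
    |Pearson r| > ``max_corr`` pairs (keeping the higher-AUC member)."""
    lab = np.asarray(labels)
    if len(set(lab)) < 2:
        raise ValueError("both classes required")
    survivors: list[tuple[str, float]] = []
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        act, inact = v[lab == 1], v[lab == 0]
        if np.ptp(v) == 0:
            continue
        p = stats.ttest_ind(act, inact, equal_var=True).pvalue
        if not p < alpha:
            continue
        if not weighted_index(v, lab) > min_weight:
            continue
        auc = descriptor_auc(v, lab)
        if auc > min_auc:
            survivors.append((col, auc))
    survivors.sort(key=lambda t: -t[1])
    kept: list[tuple[str, float]] = []
    for name, auc in survivors:
        v = table[name].to_numpy(dtype=float)
        if all(
            abs(np.corrcoef(v, table[other].to_numpy(dtype=float))[0, 1]) <= max_corr
            for other, _ in kept
        ):
            kept.append((name, auc))
    if not kept:
        import logging

        logging.getLogger(__name__).warning("no descriptor survived selection")
    return [name for name, _ in kept]


def choose_cutoff(values: Sequence[float], labels: Sequence[int]) -> tuple[float, str]:
    """Cutoff maximizing Youden J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive distinct
    values; the active direction is taken from the class means; ties on
    J resolve to the cutoff closest to the midpoint of the class means.
    Returns (cutoff, direction).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    act, inact = v[lab == 1], v[lab == 0]
    if len(act) == 0 or len(inact) == 0:
        raise ValueError("both classes required")
    direction = "above" if act.mean() >= inact.mean() else "below"
    uniq = np.unique(v)
    if len(uniq) == 1:
        return float(uniq[0]), direction
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_j = -np.inf
    best: list[float] = []
    for c in cands:
        pred = v > c if direction == "above" else v < c
        sens = pred[lab == 1].mean()
        spec = (~pred[lab == 0]).mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, [float(c)]
        elif abs(j - best_j) <= 1e-12:
            best.append(float(c))
    mid = (act.mean() + inact.mean()) / 2.0
    return min(best, key=lambda c: abs(c - mid)), direction


def fit_classifier(
    table: pd.DataFrame,
    labels: Sequence[int],
    descriptors: Sequence[str] | None = None,
    vote_threshold: int | None = None,
) -> ClassifierModel:
    """Select descriptors (unless given) and set per-descriptor cutoffs."""
    if descriptors is None:
        descriptors = select_classifier_descriptors(table, labels)
    if not descriptors:
        raise ValueError("no descriptors to build a classifier from")
    classifiers = []
    for name in descriptors:
        cutoff, direction = choose_cutoff(table[name], labels)
        classifiers.append(CutoffClassifier(name, cutoff, direction))
    if vote_threshold is None:
        vote_threshold = max(1, int(np.ceil(len(classifiers) * 0.75)))
    return ClassifierModel(classifiers=classifiers, vote_threshold=vote_threshold)


# ---------------------------------------------------------------------------
# application


def vote_count(descriptor_vector: Mapping[str, float], model: ClassifierModel) -> int:
    """Number of per-descriptor cutoffs voting active (ordinal 0..k)."""
    votes = 0
    for clf in model.classifiers:
        if clf.descriptor not in descriptor_vector:
            raise KeyError(f"descriptor {clf.descriptor!r} missing from vector")
        votes += clf.votes(float(descriptor_vector[clf.descriptor]))
    return votes


def classify(descriptor_vector: Mapping[str, float], model: ClassifierModel) -> int:
    return int(vote_count(descriptor_vector, model) >= model.vote_threshold)


def classify_table(table: pd.DataFrame, model: ClassifierModel) -> pd.DataFrame:
    """Per-row vote counts and class for a descriptor table."""
    votes = [vote_count(row, model) for row in table.to_dict("records")]
    return pd.DataFrame(
        {"votes": votes, "activity_class": [int(v >= model.vote_threshold) for v in votes]},
        index=table.index,
    )


def evaluate_classifier(
    predictions: Sequence[int],
    labels: Sequence[int],
    scores: Sequence[float] | None = None,
) -> ClassMetrics:
    """Confusion-matrix metrics; AUC from ``scores`` (e.g. the ordinal
    vote count) when given, else from the hard predictions."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if len(pred) != len(lab):
        raise ValueError("length mismatch")
    tp = int(((pred == 1) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(lab)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    if len(set(lab.tolist())) < 2:
        auc = float("nan")
    else:
        auc = descriptor_auc(scores if scores is not None else pred, lab)
    return ClassMetrics(sens, spec, acc, auc, f1)


def train_test_split_stratified(
    n: int, labels: Sequence[int], train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible stratified 70/30 index split."""
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    train_idx: list[int] = []
    for cls in np.unique(lab):
        idx = np.flatnonzero(lab == cls)
        k = int(round(train_fraction * len(idx)))
        train_idx.extend(rng.permutation(idx)[:k].tolist())
    train = np.array(sorted(train_idx))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


#: the published four-descriptor TRPA1 cutoff model (3-of-4 vote).
TRPA1_CLASSIFIER = ClassifierModel(
    classifiers=[
        CutoffClassifier("DPSA3", 65.36, "above"),
        CutoffClassifier("ECCEN", 440.0, "above"),
        CutoffClassifier("SP6", 3.67, "above"),
        CutoffClassifier("SPC4", 3.98, "above"),
    ],
    vote_threshold=3,
)
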