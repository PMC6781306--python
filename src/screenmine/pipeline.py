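"""End-to-end screening pipeline.

Chains the stages — prepare -> descriptors -> scaffolds/features ->
enrichment -> mining score -> classify -> predict pIC50 -> rank/BBB —
on an activity table plus a candidate library, writing one CSV per
stage and a JSON manifest (seed, thresholds, per-stage counts) so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from . import __version__
from .chem_io import (
    ActivityRecord,
    prepare_inhibitor_dataset,
    prepare_screening_library,
    write_prepared_csv,
)
from .classifier import ClassifierModel, TRPA1_CLASSIFIER, classify_table
from .descriptors import descriptor_matrix
from .mining import MiningConfig, mining_score, score_distribution
from .ranking import BBBRules, LogisticModel, TRPA1_LOGIT, rank_candidates
from .regression import MLRModel, TRPA1_MLR
from .sar import enrichment_frame, feature_enrichment
from .scaffolds import FeatureLibrary, detect_features

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    decoy_ic50_threshold_nM: float = 2000.0
    min_library_mw: float = 100.0
    enrichment_alpha: float = 0.01
    min_score: int = 3
    similarity_point: bool = True
    vote_threshold: int = 3
    probability_thresholds: tuple[float, ...] = (0.5, 0.9, 0.95, 0.99)
    apply_bbb: bool = True
    seed: int = 42
    grav_variant: str = "G4"


def run_pipeline(
    activity_records: list[ActivityRecord],
    library: pd.DataFrame,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    classifier_model: ClassifierModel | None = None,
    mlr_model: MLRModel | None = None,
    logistic_model: LogisticModel | None = None,
    feature_library: FeatureLibrary | None = None,
) -> dict:
    """Run every stage and write per-stage CSVs plus ``manifest.json``.

    ``library`` must have columns smiles and dg (docking scores are an
    external input).  Returns the manifest dict.
    """
    config = config or PipelineConfig()
    classifier_model = classifier_model or TRPA1_CLASSIFIER
    mlr_model = mlr_model or TRPA1_MLR
    logistic_model = logistic_model or TRPA1_LOGIT
    feature_library = feature_library or FeatureLibrary.load()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"screenmine {__version__}",
        "config": {
            **{k: v for k, v in asdict(config).items()},
        },
        "counts": {},
    }
    counts = manifest["counts"]

    # 1. prepare activity data
    prepared = prepare_inhibitor_dataset(activity_records, config.decoy_ic50_threshold_nM)
    write_prepared_csv(prepared, out / "prepared.csv")
    counts["inhibitors"] = len(prepared.inhibitors)
    counts["decoys"] = len(prepared.decoys)
    counts["dropped"] = len(prepared.dropped)

    # 2. prepare candidate library
    if "dg" not in library.columns:
        raise ValueError("library table lacks required 'dg' docking-score column")
    cleaned = prepare_screening_library(
        [(str(i), s) for i, s in library["smiles"].items()], config.min_library_mw
    )
    lib = pd.DataFrame(cleaned, columns=["id", "smiles"]).set_index("id")
    lib["dg"] = library["dg"].reindex(lib.index)
    counts["library"] = len(lib)

    inh_mols = [(r.id, Chem.MolFromSmiles(r.smiles)) for r in prepared.inhibitors]
    lib_mols = [(str(i), Chem.MolFromSmiles(s)) for i, s in lib["smiles"].items()]

    # 3. features + enrichment on the inhibitor set
    inh_features = pd.DataFrame(
        [detect_features(m, feature_library).flags for _, m in inh_mols],
        index=[i for i, _ in inh_mols],
    )
    pic50 = [r.pIC50 for r in prepared.inhibitors]
    enrich = enrichment_frame(
        feature_enrichment(pic50, inh_features, alpha=config.enrichment_alpha)
    )
    enrich.to_csv(out / "enrichment.csv", index=False)
    counts["features_significant"] = int(enrich["significant"].sum()) if len(enrich) else 0

    # 4. mining score on the library
    mining_cfg = MiningConfig(
        scoring_features=list(feature_library.scoring_features),
        similarity_point=config.similarity_point,
        min_score=config.min_score,
    )
    scores = []
    for ident, mol in lib_mols:
        fv = detect_features(mol, feature_library)
        scores.append(mining_score(fv, has_similarity=False, config=mining_cfg))
    lib["score"] = scores
    lib.to_csv(out / "mining_scores.csv")
    selected = lib[lib["score"] >= mining_cfg.min_score].copy()
    counts["mining_selected"] = len(selected)
    if len(scores):
        mn, mx, mean, sd = score_distribution(scores)
        manifest["score_distribution"] = {"min": mn, "max": mx, "mean": mean, "sd": sd}

    # 5. descriptors for selected candidates
    sel_mols = [(i, m) for i, m in lib_mols if i in set(selected.index)]
    desc = descriptor_matrix(sel_mols, seed=config.seed, grav_variant=config.grav_variant)
    desc.to_csv(out / "descriptors.csv")

    # 6. classify + predict pIC50
    model = ClassifierModel(
        classifiers=classifier_model.classifiers, vote_threshold=config.vote_threshold
    )
    cls = classify_table(desc, model)
    counts["classified_active"] = int(cls["activity_class"].sum())
    pred = mlr_model.predict_table(desc)

    # 7. rank
    cand = pd.DataFrame(
        {
            "score": selected["score"].reindex(desc.index),
            "activity_class": cls["activity_class"],
            "pic50_pred": pred,
            "dg": selected["dg"].reindex(desc.index),
            "MW": desc["MW"],
            "ALogP": desc["ALogP"],
            "TPSA": desc["TPSA"],
            "nHBDon": desc["nHBDon"],
            "nHBAcc": desc["nHBAcc"],
        },
        index=desc.index,
    )
    cand.index.name = "id"
    ranked, report = rank_candidates(
        cand,
        model=logistic_model,
        probability_thresholds=config.probability_thresholds,
        bbb_rules=BBBRules() if config.apply_bbb else None,
    )
    ranked.to_csv(out / "ranked.csv", float_format="%.6g")
    manifest["ranking"] = report
    counts["ranked"] = report["n_ranked"]
    counts["p_gt_0.5"] = report.get("P>0.5", 0)
    if config.apply_bbb:
        counts["p_gt_0.5_bbb"] = report.get("P>0.5_bbb", 0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
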