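"""Synthetic fixture datasets with planted structure-activity signal.

Generates inhibitor, decoy and screening-library sets whose statistical
structure matches what the pipeline assumes: each molecule is assembled
from a small fragment grammar of scaffold cores and substituents that
deliberately carry the library's structural features (thiazole and
dione ring systems, phenyl, cyclopentane, quaternary carbons, hydroxyl
groups, ...), and its pIC50 is drawn as

    pIC50 = baseline + sum of per-feature effects + N(0, noise_sd)

so enrichment analysis, classification and regression stages can be
validated by parameter recovery.  Decoys carry '>' qualifiers with
IC50 above the weak-activity threshold; the screening library gets a
simulated docking-score column drawn from a truncated normal matching
the range a docking engine typically reports for druglike ligands.

Default condition sizes mirror the reference study: 371 inhibitors,
76 decoys.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .chem_io import ActivityRecord
from .scaffolds import FeatureLibrary, detect_features

log = logging.getLogger(__name__)

#: default per-feature pIC50 shifts, scaled after the enrichment the
#: reference SAR analysis reports for the high-activity features.
DEFAULT_FEATURE_EFFECTS: dict[str, float] = {
    "PR-1": 0.9,
    "PR-3": 1.1,
    "PR-6": 1.1,
    "PR-7": 1.5,
    "PR-8": 1.4,
    "AG-4": 0.8,
    "AG-5": 1.0,
    "AG-7": 0.9,
    "AG-8": 1.0,
    "AG-10": 0.9,
    "AG-12": 1.0,
}


@dataclass
class SimulationConfig:
    n_inhibitors: int = 371
    n_decoys: int = 76
    n_library: int = 500
    feature_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS)
    )
    baseline_pic50: float = 5.3
    noise_sd: float = 0.5
    decoy_ic50_low_nM: float = 2500.0
    decoy_ic50_high_nM: float = 50000.0
    dg_mean: float = -7.3
    dg_sd: float = 1.0
    dg_range: tuple[float, float] = (-10.4, -4.1)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_inhibitors, self.n_decoys, self.n_library) < 0:
            raise ValueError("set sizes must be non-negative")


# ---------------------------------------------------------------------------
# fragment grammar
#
# Cores carry the planted ring features; {R} marks the substitution
# point.  Substituents carry atom-group features (hydroxyl, quaternary
# carbon, halogens, ...).  ~30 fragments total, all parseable.

CORES: tuple[str, ...] = (
    "c1ccc({R})cc1",                 # benzene (PR-6)
    "c1csc({R})n1",                  # 1,3-thiazole (PR-8 / MCR-1, AG-12, AG-6)
    "c1ccc(-c2nccs2)cc1{R}",         # phenyl-thiazole
    "O=C1NC(=O)c2ccccc2N1{R}",       # quinazoline-2,4-dione (PR-1)
    "O=C1NC(=O)c2ccsc2N1{R}",        # thieno-pyrimidinedione (PR-3)
    "C1CCC(C1)C({R})C1CCCCC1",       # cyclopentane/cyclohexane (PR-7)
    "c1ccc2ccccc2c1{R}",             # naphthalene
    "c1ccc(CC2CCCCN2{R})cc1",        # phenyl-piperidine (AG-7 when N-substituted)
    "c1ccoc1{R}",                    # furan (AG-10)
    "c1ccc(N2CCOCC2)c({R})c1",       # aryl morpholine
    "C1CCCCC1{R}",                   # cyclohexane
    "c1cnc({R})cn1",                 # pyrazine (AG-6)
)

SUBSTITUENTS: tuple[str, ...] = (
    "C",             # methyl
    "CC",            # ethyl
    "O",             # hydroxyl (AG-8)
    "CO",            # hydroxymethyl (AG-8)
    "C(C)(C)C",      # tert-butyl (AG-4)
    "C1(O)CCCCC1",   # 1-hydroxycyclohexyl (AG-4 + AG-8)
    "F",             # fluoro (AG-11)
    "Cl",            # chloro (AG-13)
    "OC",            # methoxy
    "N",             # amino
    "CN(C)C",        # dimethylaminomethyl
    "C(F)(F)F",      # trifluoromethyl (AG-4)
    "C(=O)O",        # carboxyl (AG-9, nAcid)
    "C#N",           # nitrile
    "[N+](=O)[O-]",  # nitro (ddsN)
    "CCN",           # aminoethyl
    "",              # unsubstituted core
)


def _assemble(rng: np.random.Generator) -> str:
    """One molecule from the grammar; resamples until parseable."""
    for _ in range(20):
        core = CORES[rng.integers(len(CORES))]
        sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        if sub:
            smi = core.replace("{R}", sub)
        else:
            smi = core.replace("({R})", "").replace("{R}", "")
        if Chem.MolFromSmiles(smi) is not None:
            return Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        log.debug("grammar produced unparsable %r, resampled", smi)
    raise RuntimeError("fragment grammar failed to produce a parseable structure")


def _planted_pic50(
    smiles: str, config: SimulationConfig, library: FeatureLibrary, rng: np.random.Generator
) -> float:
    mol = Chem.MolFromSmiles(smiles)
    fv = detect_features(mol, library)
    effect = sum(config.feature_effects.get(f, 0.0) for f in fv.present())
    return config.baseline_pic50 + effect + rng.normal(0.0, config.noise_sd)


def generate_inhibitor_dataset(
    config: SimulationConfig | None = None, library: FeatureLibrary | None = None
) -> list[ActivityRecord]:
    """Inhibitors with exact IC50 values and feature-driven pIC50."""
    config = config or SimulationConfig()
    library = library or FeatureLibrary.load()
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_inhibitors):
        smi = _assemble(rng)
        pic50 = _planted_pic50(smi, config, library, rng)
        ic50_nM = 10.0 ** (9.0 - pic50)
        records.append(
            ActivityRecord(id=f"INH{i:04d}", smiles=smi, ic50_value=ic50_nM, qualifier="exact")
        )
    return records


def generate_decoys(config: SimulationConfig | None = None) -> list[ActivityRecord]:
    """Censored weak actives: qualifier '>' and IC50 above threshold."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)
    records = []
    for i in range(config.n_decoys):
        smi = _assemble(rng)
        ic50 = float(rng.uniform(config.decoy_ic50_low_nM, config.decoy_ic50_high_nM))
        records.append(
            ActivityRecord(
                id=f"DEC{i:04d}", smiles=smi, ic50_value=ic50, qualifier="greater_than"
            )
        )
    return records


def generate_screening_library(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Druglike candidate table with a simulated docking-score column.

    dg ~ N(dg_mean, dg_sd) truncated to ``dg_range`` (kcal/mol).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.dg_range
    a, b = (lo - config.dg_mean) / config.dg_sd, (hi - config.dg_mean) / config.dg_sd
    dist = stats.truncnorm(a, b, loc=config.dg_mean, scale=config.dg_sd)
    rows = []
    for i in range(config.n_library):
        smi = _assemble(rng)
        rows.append({"id": f"LIB{i:04d}", "smiles": smi, "dg": float(dist.ppf(rng.uniform()))})
    return pd.DataFrame(rows, columns=["id", "smiles", "dg"]).set_index("id")
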