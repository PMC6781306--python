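"""Structure/activity I/O and dataset preparation.

Reads SMILES, SDF (V2000) and CSV activity tables and applies the
preparation rules used throughout the pipeline: records with inexact
IC50 qualifiers are either routed to a decoy set (estimated value above
a weak-activity threshold) or dropped, duplicate structures are merged
by arithmetic-mean IC50, and pIC50 is derived for the retained
inhibitors.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

QUALIFIERS = ("exact", "greater_than", "less_than", "approx")

#: multiplicative factors to nM
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "M": 1e9, "mM": 1e6}


@dataclass
class ActivityRecord:
    """One structure with a measured IC50 (nM) and optional derived pIC50."""

    id: str
    smiles: str
    ic50_value: float  # nM
    qualifier: str = "exact"
    pIC50: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_value <= 0:
            raise ValueError(f"{self.id}: IC50 must be positive, got {self.ic50_value}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"{self.id}: unknown qualifier {self.qualifier!r}")


@dataclass
class PreparedDatasets:
    inhibitors: list[ActivityRecord] = field(default_factory=list)
    decoys: list[ActivityRecord] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def pic50_from_nM(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in mol/L); input in nM."""
    return -math.log10(ic50_nM * 1e-9)


def to_nM(value: float, units: str = "nM") -> float:
    try:
        return value * _UNIT_TO_NM[units]
    except KeyError:
        raise ValueError(f"unknown concentration unit {units!r}") from None


def canonical_smiles(smiles: str, desalt: bool = True, neutralize: bool = True) -> str | None:
    """Canonical SMILES after keeping the largest organic fragment and
    neutralizing charges; None for unparsable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if desalt and len(Chem.GetMolFrags(mol)) > 1:
        mol = largest_organic_fragment(mol)
        if mol is None:
            return None
    if neutralize:
        try:
            mol = rdMolStandardize.Uncharger().uncharge(mol)
        except Exception:  # pragma: no cover - RDKit internal failure
            pass
    return Chem.MolToSmiles(mol)


def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Largest fragment containing at least one carbon (by heavy-atom count)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    best = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    Chem.SanitizeMol(best)
    return best


# ---------------------------------------------------------------------------
# loading


def load_structures(path: str | Path, format: str | None = None) -> list[tuple[str, str]]:
    """Load (id, smiles) pairs from a SMILES, SDF or CSV file.

    Unparsable records are skipped and logged with their position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "SMILES", ".sdf": "SDF", ".csv": "CSV"}.get(path.suffix.lower(), "SMILES")
    format = format.upper()
    if format == "SMILES":
        return _load_smiles(path)
    if format == "SDF":
        return _load_sdf(path)
    if format == "CSV":
        return [(r.id, r.smiles) for r in load_activity_csv(path, require_ic50=False)]
    raise ValueError(f"unknown structure format {format!r}")


def _load_smiles(path: Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            if Chem.MolFromSmiles(smi) is None:
                log.warning("%s line %d: unparsable SMILES %r, skipped", path, lineno, smi)
                continue
            out.append((name, smi))
    return out


def _load_sdf(path: Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("%s record %d: unparsable SDF record, skipped", path, i + 1)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
        out.append((name, Chem.MolToSmiles(mol)))
    return out


def load_activity_csv(path: str | Path, require_ic50: bool = True) -> list[ActivityRecord]:
    """Read an activity table: columns id, smiles, ic50, qualifier, units.

    ``qualifier`` accepts ``exact``/``>``/``<``/``~`` (default exact);
    ``units`` defaults to nM.
    """
    qual_map = {
        "": "exact", "=": "exact", "exact": "exact",
        ">": "greater_than", "greater_than": "greater_than",
        "<": "less_than", "less_than": "less_than",
        "~": "approx", "approx": "approx",
    }
    records: list[ActivityRecord] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            smi = row["smiles"].strip()
            if Chem.MolFromSmiles(smi) is None:
                log.warning("%s row %d: unparsable SMILES %r, skipped", path, i, smi)
                continue
            ident = row.get("id", "").strip() or f"mol{i - 1}"
            raw = row.get("ic50", "")
            if raw in (None, ""):
                if require_ic50:
                    log.warning("%s row %d: missing ic50, skipped", path, i)
                    continue
                value = 1.0
            else:
                value = to_nM(float(raw), (row.get("units") or "nM").strip())
            records.append(
                ActivityRecord(
                    id=ident,
                    smiles=smi,
                    ic50_value=value,
                    qualifier=qual_map[(row.get("qualifier") or "").strip()],
                )
            )
    return records


# ---------------------------------------------------------------------------
# preparation


def prepare_inhibitor_dataset(
    records: Sequence[ActivityRecord], decoy_ic50_threshold_nM: float = 2000.0
) -> PreparedDatasets:
    """Partition activity records into inhibitors, decoys and dropped entries.

    Non-exact records with an estimated value above the threshold become
    decoys; non-exact records at or below it are dropped as unusable.
    Exact records sharing a canonical structure are merged into one entry
    with the arithmetic-mean IC50, and pIC50 is computed for every
    retained inhibitor.
    """
    if not records:
        raise ValueError("empty activity table")
    out = PreparedDatasets()
    merged: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    for rec in sorted(records, key=lambda r: r.id):
        canon = canonical_smiles(rec.smiles)
        if canon is None:
            out.dropped.append((rec.id, "unparsable"))
            continue
        if rec.qualifier != "exact":
            if rec.ic50_value > decoy_ic50_threshold_nM:
                out.decoys.append(replace(rec, smiles=canon))
            else:
                out.dropped.append((rec.id, "inexact"))
            continue
        if canon not in merged:
            merged[canon] = []
            order.append(canon)
        merged[canon].append(rec)
    for canon in order:
        group = merged[canon]
        mean_ic50 = sum(r.ic50_value for r in group) / len(group)
        out.inhibitors.append(
            ActivityRecord(
                id=group[0].id,
                smiles=canon,
                ic50_value=mean_ic50,
                qualifier="exact",
                pIC50=pic50_from_nM(mean_ic50),
            )
        )
    if not out.inhibitors:
        log.warning("all %d records were inexact or unparsable; inhibitor set is empty", len(records))
    return out


def prepare_screening_library(
    structures: Iterable[tuple[str, str]], min_mw: float = 100.0
) -> list[tuple[str, str]]:
    """Filter a candidate library: desalt, drop inorganics (no carbon) and
    molecules below ``min_mw`` g/mol."""
    kept: list[tuple[str, str]] = []
    for ident, smi in structures:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            log.warning("%s: unparsable, skipped", ident)
            continue
        mol = largest_organic_fragment(mol)
        if mol is None:
            log.info("%s: inorganic, removed", ident)
            continue
        if Descriptors.MolWt(mol) < min_mw:
            log.info("%s: MW below %g, removed", ident, min_mw)
            continue
        kept.append((ident, Chem.MolToSmiles(mol)))
    return kept


def write_prepared_csv(datasets: PreparedDatasets, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "ic50_nM", "qualifier", "pIC50", "set"])
        for rec in datasets.inhibitors:
            w.writerow([rec.id, rec.smiles, f"{rec.ic50_value:.6g}", rec.qualifier,
                        f"{rec.pIC50:.4f}", "inhibitor"])
        for rec in datasets.decoys:
            w.writerow([rec.id, rec.smiles, f"{rec.ic50_value:.6g}", rec.qualifier, "", "decoy"])
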