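"""Scaffold decomposition and structural feature detection.

Decomposes molecules into three scaffold layers used by the SAR mining
stage:

* **Bemis-Murcko skeleton** - rings plus linkers with every atom turned
  into carbon and every bond into a single bond;
* **plain ring systems** - fused ring assemblies with substituents and
  linkers removed but atom/bond types kept; atoms attached to a ring by
  a double bond (e.g. the carbonyl oxygens of quinazoline-2,4-dione
  cores) are retained so dione-type rings keep their identity;
* **most central rings** - the individual plain rings topologically
  closest to the graph center of the molecule.

Feature identity is canonical-SMILES equality of the extracted typed
ring graphs (not substructure matching), so benzene stays distinct from
fused aromatics.  Atom-group (AG) features are presence flags on the
Kier-Hall E-state fragment counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .descriptors import estate_fragment_counts


@dataclass
class ScaffoldSet:
    bm_skeleton: str  # empty for acyclic molecules
    plain_ring_systems: frozenset[str]
    individual_plain_rings: frozenset[str]
    most_central_rings: frozenset[str]


@dataclass
class FeatureVector:
    """Boolean structural-feature flags plus the mining bookkeeping."""

    flags: dict[str, bool] = field(default_factory=dict)
    similarity_flag: bool = False
    score: int = 0

    def present(self) -> list[str]:
        return sorted(k for k, v in self.flags.items() if v)


# ---------------------------------------------------------------------------
# canonicalization helper


def _canon(mol: Chem.Mol) -> str | None:
    """Canonical SMILES via a sanitize round-trip; None if invalid."""
    try:
        smi = Chem.MolToSmiles(mol)
        back = Chem.MolFromSmiles(smi)
        if back is None:
            return None
        return Chem.MolToSmiles(back)
    except Exception:
        return None


def canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Bemis-Murcko


def bemis_murcko_skeleton(mol: Chem.Mol) -> str:
    """Canonical all-carbon single-bond framework; '' for acyclic input."""
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    core = MurckoScaffold.GetScaffoldForMol(mol)
    skeleton = MurckoScaffold.MakeScaffoldGeneric(core)
    # genericizing turns exocyclic double-bonded atoms (e.g. carbonyl O)
    # into single-bonded carbons; strip them so they count as side chains
    skeleton = MurckoScaffold.GetScaffoldForMol(skeleton)
    return Chem.MolToSmiles(skeleton)


# ---------------------------------------------------------------------------
# plain rings


def _ring_systems_atom_sets(mol: Chem.Mol) -> list[set[int]]:
    """Fused ring systems as atom-index sets (rings sharing an atom fuse)."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        systems = rest + [merged]
    return systems


def _with_exocyclic_doubles(mol: Chem.Mol, atoms: set[int]) -> set[int]:
    """Add atoms double-bonded to the selection (keeps dione carbonyls)."""
    extra: set[int] = set()
    for idx in atoms:
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            other = bond.GetOtherAtom(mol.GetAtomWithIdx(idx)).GetIdx()
            if other in atoms:
                continue
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                extra.add(other)
    return atoms | extra


def _extract_fragment(mol: Chem.Mol, atoms: set[int]) -> str | None:
    """Canonical SMILES of the substructure induced by ``atoms``.

    Builds from kekulized parent bond orders so aromaticity of the
    fragment is re-perceived from scratch (a ring cut out of a fused
    aromatic must not inherit stale aromatic flags).
    """
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception:
        kek = mol
    emol = Chem.RWMol()
    mapping: dict[int, int] = {}
    for idx in sorted(atoms):
        old = kek.GetAtomWithIdx(idx)
        atom = Chem.Atom(old.GetAtomicNum())
        atom.SetFormalCharge(old.GetFormalCharge())
        mapping[idx] = emol.AddAtom(atom)
    for bond in kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atoms and j in atoms:
            emol.AddBond(mapping[i], mapping[j], bond.GetBondType())
    frag = emol.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        return None
    return _canon(frag)


def plain_ring_systems(mol: Chem.Mol) -> frozenset[str]:
    """Canonical SMILES of each fused ring system (typed, desubstituted,
    exocyclic double-bond atoms kept)."""
    out = set()
    for atoms in _ring_systems_atom_sets(mol):
        smi = _extract_fragment(mol, _with_exocyclic_doubles(mol, atoms))
        if smi:
            out.add(smi)
    return frozenset(out)


def split_individual_rings(mol: Chem.Mol) -> frozenset[str]:
    """Canonical SMILES of each smallest ring (typed, with exocyclic
    double-bond atoms)."""
    out = set()
    for ring in mol.GetRingInfo().AtomRings():
        smi = _extract_fragment(mol, _with_exocyclic_doubles(mol, set(ring)))
        if smi:
            out.add(smi)
    return frozenset(out)


def most_central_rings(mol: Chem.Mol) -> frozenset[str]:
    """Rings minimally distant from the molecule's graph center.

    The graph center is the set of heavy atoms with minimum eccentricity;
    a ring's distance is the minimum topological distance from any of its
    atoms to any center atom.  All rings achieving the minimum are
    returned (ties allowed).
    """
    rings = mol.GetRingInfo().AtomRings()
    if not rings:
        return frozenset()
    dm = Chem.GetDistanceMatrix(mol)
    ecc = dm.max(axis=1)
    center = {i for i in range(mol.GetNumAtoms()) if ecc[i] == ecc.min()}
    dist = []
    for ring in rings:
        dist.append(min(dm[a, c] for a in ring for c in center))
    dmin = min(dist)
    out = set()
    for ring, d in zip(rings, dist):
        if d == dmin:
            smi = _extract_fragment(mol, _with_exocyclic_doubles(mol, set(ring)))
            if smi:
                out.add(smi)
    return frozenset(out)


def scaffold_set(mol: Chem.Mol) -> ScaffoldSet:
    return ScaffoldSet(
        bm_skeleton=bemis_murcko_skeleton(mol),
        plain_ring_systems=plain_ring_systems(mol),
        individual_plain_rings=split_individual_rings(mol),
        most_central_rings=most_central_rings(mol),
    )


# ---------------------------------------------------------------------------
# feature library


@dataclass
class FeatureLibrary:
    """Named structural features: BM skeletons, plain rings (PR), most
    central rings (MCR) as canonical SMILES, and atom groups (AG) as khs
    descriptor names."""

    bm: dict[str, str]
    pr: dict[str, str]
    mcr: dict[str, str]
    ag: dict[str, str]
    scoring_features: list[str]

    @classmethod
    def from_mapping(cls, data: Mapping) -> "FeatureLibrary":
        norm_bm = {}
        for name, smi in data.get("bm", {}).items():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"{name}: bad skeleton SMILES {smi!r}")
            norm_bm[name] = bemis_murcko_skeleton(mol) or Chem.MolToSmiles(mol)
        return cls(
            bm=norm_bm,
            pr={k: canonical(v) for k, v in data.get("pr", {}).items()},
            mcr={k: canonical(v) for k, v in data.get("mcr", {}).items()},
            ag=dict(data.get("ag", {})),
            scoring_features=list(data.get("scoring_features", [])),
        )

    @classmethod
    def load(cls, path: str | None = None) -> "FeatureLibrary":
        """Load a feature library JSON; default = the packaged TRPA1 set."""
        if path is None:
            text = resources.files("screenmine.data").joinpath("feature_library.json").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(json.loads(text))

    def feature_names(self) -> list[str]:
        return [*self.bm, *self.pr, *self.mcr, *self.ag]


def detect_features(mol: Chem.Mol, library: FeatureLibrary) -> FeatureVector:
    """Flag each library feature present in the molecule.

    PR features match against both individual plain rings and whole
    plain ring systems (bi/tricyclic library entries are systems); MCR
    features require membership of the most-central-ring set (any most
    central ring counts when there are ties); BM features are skeleton
    identity; AG features are nonzero khs fragment counts.
    """
    sset = scaffold_set(mol)
    khs = estate_fragment_counts(mol)
    ring_pool = sset.individual_plain_rings | sset.plain_ring_systems
    flags: dict[str, bool] = {}
    for name, smi in library.bm.items():
        flags[name] = bool(sset.bm_skeleton) and sset.bm_skeleton == smi
    for name, smi in library.pr.items():
        flags[name] = smi in ring_pool
    for name, smi in library.mcr.items():
        flags[name] = smi in sset.most_central_rings
    for name, khs_name in library.ag.items():
        flags[name] = khs.get(khs_name, 0) > 0
    return FeatureVector(flags=flags)


def feature_table(
    molecules: Iterable[tuple[str, Chem.Mol]], library: FeatureLibrary
):
    """DataFrame of boolean feature flags, one row per molecule."""
    import pandas as pd

    rows, index = [], []
    for ident, mol in molecules:
        index.append(ident)
        rows.append(detect_features(mol, library).flags)
    return pd.DataFrame(rows, index=pd.Index(index, name="id"), dtype=bool)
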