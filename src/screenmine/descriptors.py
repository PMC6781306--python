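"""Molecular descriptors for the QSAR models.

Implements the CDK-style descriptors the activity models consume:
Kier-Hall E-state fragment counts (khs.*), the eccentric connectivity
index (ECCEN), simple Kier-Hall chi path (SP6) and path-cluster (SPC4)
indices, the heavy-atom gravitational index (GRAV4), the charge-weighted
partial-surface-area difference (DPSA3), the primary/tertiary-nitrogen
molecular distance edge (MDEN13), carbon-connectivity counts (C2SP2,
C2SP3, C3SP2) and standard druglikeness properties.

Geometry-dependent descriptors (GRAV4, DPSA3) need one embedded 3D
conformer (:func:`embed_conformer`); partial charges are Gasteiger and
per-atom solvent-accessible surface areas come from an own Shrake-Rupley
implementation (probe 1.4 A, 960 deterministic sphere points, Bondi
radii), so descriptor tables are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.EState import AtomTypes as _EStateAtomTypes

#: khs fragment counts exposed in the descriptor table (the atom groups
#: referenced by the SAR analysis and the published models).
KHS_NAMES = (
    "khs.ssCH2", "khs.dssC", "khs.aaaC", "khs.ssssC", "khs.dsN", "khs.aaN",
    "khs.aasN", "khs.sOH", "khs.dO", "khs.aaO", "khs.sF", "khs.aaS",
    "khs.sCl", "khs.ddsN",
)

#: fixed, documented column order of the descriptor table
DESCRIPTOR_COLUMNS = (
    "GRAV4", "ECCEN", "SP6", "SPC4", "DPSA3", "MDEN13",
    *KHS_NAMES,
    "nHBAcc", "nHBDon", "nAcid", "nRotB", "C2SP2", "C2SP3", "C3SP2",
    "MW", "ALogP", "TPSA",
)

GRAV_VARIANTS = ("G1", "G2", "G3", "G4", "G5", "G6")

# Bondi van der Waals radii (A); fallback 1.7 for elements not listed.
_BONDI = {
    1: 1.20, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 15: 1.80, 16: 1.80,
    17: 1.75, 35: 1.85, 53: 1.98,
}

_ACID_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=O)[OX2H1]",          # carboxylic acid
        "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid
        "[PX4](=O)([OX2H1])[OX2H1,OX2R0]",  # phosphonic acid
    )
]


# ---------------------------------------------------------------------------
# E-state fragment counts


def estate_fragment_counts(mol: Chem.Mol) -> dict[str, int]:
    """Count atoms per Kier-Hall E-state atom type (khs.* fragments)."""
    if mol is None:
        raise ValueError("molecule is None")
    types = _EStateAtomTypes.TypeAtoms(mol)
    counts = {name: 0 for name in KHS_NAMES}
    for atom_types in types:
        for t in atom_types:
            key = f"khs.{t}"
            if key in counts:
                counts[key] += 1
    return counts


# ---------------------------------------------------------------------------
# topological descriptors


def _heavy_distance_matrix(mol: Chem.Mol) -> np.ndarray:
    return Chem.GetDistanceMatrix(mol)


def eccentric_connectivity_index(mol: Chem.Mol) -> int:
    """Sum over heavy atoms of eccentricity x heavy-atom degree.

    On disconnected input the index is computed on the largest fragment.
    """
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        import logging

        logging.getLogger(__name__).warning(
            "disconnected molecule: ECCEN computed on largest fragment"
        )
        mol = max(Chem.GetMolFrags(mol, asMols=True), key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumHeavyAtoms() < 2:
        return 0
    dm = _heavy_distance_matrix(mol)
    ecc = dm.max(axis=1)
    deg = np.array([a.GetDegree() for a in mol.GetAtoms()], dtype=float)
    return int(round(float((ecc * deg).sum())))


def chi_path(mol: Chem.Mol, order: int) -> float:
    """Simple Kier-Hall chi path index: sum over simple paths with
    ``order`` edges of 1/sqrt(product of heavy-atom degrees along the
    path), each path counted once."""
    if order < 0:
        raise ValueError("order must be >= 0")
    deg = [a.GetDegree() for a in mol.GetAtoms()]
    if order == 0:
        return float(sum(1.0 / math.sqrt(d) for d in deg if d > 0))
    total = 0.0
    for path in Chem.FindAllPathsOfLengthN(mol, order, useBonds=True):
        atoms = _bond_path_atoms(mol, path)
        if atoms is None:  # not a simple path (revisits an atom)
            continue
        prod = 1.0
        for idx in atoms:
            prod *= deg[idx]
        total += 1.0 / math.sqrt(prod)
    return total


def _bond_path_atoms(mol: Chem.Mol, bond_ids: Sequence[int]) -> list[int] | None:
    """Atom sequence of a bond path; None if an atom repeats."""
    atoms: set[int] = set()
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    if len(atoms) != len(bond_ids) + 1:
        return None
    return list(atoms)


def chi_path_cluster(mol: Chem.Mol, order: int) -> float:
    """Simple Kier-Hall chi path-cluster index.

    Sums 1/sqrt(product of molecular heavy-atom degrees of involved
    atoms) over connected ``order``-edge subgraphs classified as
    path-cluster: at least one vertex of subgraph degree >= 3 while
    being neither a pure star nor a simple path.
    """
    if order < 4:
        raise ValueError("path-cluster indices are defined for order >= 4")
    deg = [a.GetDegree() for a in mol.GetAtoms()]
    total = 0.0
    for sub in Chem.FindAllSubgraphsOfLengthN(mol, order):
        atoms, subdeg = _subgraph_degrees(mol, sub)
        if _is_path_cluster(subdeg, len(sub)):
            prod = 1.0
            for idx in atoms:
                prod *= deg[idx]
            total += 1.0 / math.sqrt(prod)
    return total


def _subgraph_degrees(mol: Chem.Mol, bond_ids: Sequence[int]) -> tuple[list[int], list[int]]:
    count: dict[int, int] = {}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        for idx in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
            count[idx] = count.get(idx, 0) + 1
    return list(count), list(count.values())


def _is_path_cluster(subdeg: Sequence[int], n_edges: int) -> bool:
    if max(subdeg) < 3:
        return False
    # pure star: one center adjacent to every edge, all others degree 1
    if max(subdeg) == n_edges and sorted(subdeg)[:-1] == [1] * (len(subdeg) - 1):
        return False
    return True


def mden13(mol: Chem.Mol) -> float:
    """Molecular distance edge between primary and tertiary nitrogens.

    n = number of (primary N, tertiary N) pairs, g = geometric-mean-like
    aggregate (product of pairwise topological distances)^(1/(2n));
    returns n/g^2, or 0 when no pair exists.
    """
    primary, tertiary = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7:
            continue
        d = atom.GetDegree()
        if d == 1:
            primary.append(atom.GetIdx())
        elif d == 3:
            tertiary.append(atom.GetIdx())
    pairs = [(i, j) for i in primary for j in tertiary]
    if not pairs:
        return 0.0
    dm = _heavy_distance_matrix(mol)
    n = len(pairs)
    log_prod = sum(math.log(dm[i, j]) for i, j in pairs)
    g = math.exp(log_prod / (2 * n))
    return n / g**2


# ---------------------------------------------------------------------------
# geometry, charges, surface


def embed_conformer(mol: Chem.Mol, seed: int = 42, fallback_seeds: Iterable[int] = (7, 0xF00D)) -> Chem.Mol:
    """Return a copy with explicit hydrogens and one deterministic,
    MMFF-minimized 3D conformer."""
    molH = Chem.AddHs(Chem.Mol(mol))
    for s in (seed, *fallback_seeds):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(s) & 0x7FFFFFFF
        if AllChem.EmbedMolecule(molH, params) == 0:
            try:
                AllChem.MMFFOptimizeMolecule(molH)
            except Exception:
                AllChem.UFFOptimizeMolecule(molH)
            return molH
    raise ValueError(f"could not embed molecule {Chem.MolToSmiles(mol)}")


def shrake_rupley_areas(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Uses a fixed golden-spiral point set, so results are deterministic.
    """
    pts = _sphere_points(n_points)
    expanded = radii + probe
    n = len(coords)
    areas = np.zeros(n)
    # pairwise neighbor cutoff
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        ri = expanded[i]
        neighbors = [
            j for j in range(n)
            if j != i and d2[i, j] < (ri + expanded[j]) ** 2
        ]
        surface = coords[i] + ri * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            dj2 = ((surface - coords[j]) ** 2).sum(-1)
            accessible &= dj2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * ri**2 * accessible.mean()
    return areas


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral unit-sphere point set (deterministic)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _require_conformer(mol: Chem.Mol) -> np.ndarray:
    if mol.GetNumConformers() == 0:
        raise ValueError("no 3D coordinates: call embed_conformer first")
    return mol.GetConformer().GetPositions()


def gravitational_index(mol3d: Chem.Mol, variant: str = "G4") -> float:
    """Gravitational index over heavy atoms.

    Base index G = sum over heavy-atom pairs of m_i*m_j/r_ij^2.
    Variants: G1 = all-pairs G, G2 = sqrt(G1), G3 = cbrt(G1),
    G4 = cbrt(G1) (the table default, see docs/methods.md),
    G5 = sqrt and G6 = cbrt of the bonded-pairs-only base index.
    """
    if variant not in GRAV_VARIANTS:
        raise ValueError(f"unknown gravitational variant {variant!r}")
    coords = _require_conformer(mol3d)
    heavy = [a.GetIdx() for a in mol3d.GetAtoms() if a.GetAtomicNum() > 1]
    masses = {i: mol3d.GetAtomWithIdx(i).GetMass() for i in heavy}

    def base(pairs: Iterable[tuple[int, int]]) -> float:
        g = 0.0
        for i, j in pairs:
            r2 = float(((coords[i] - coords[j]) ** 2).sum())
            g += masses[i] * masses[j] / r2
        return g

    if variant in ("G1", "G2", "G3", "G4"):
        g = base(itertools.combinations(heavy, 2))
    else:
        bonded = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            for b in mol3d.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
        ]
        g = base(bonded)
    if variant in ("G1",):
        return g
    if variant in ("G2", "G5"):
        return math.sqrt(g)
    return g ** (1.0 / 3.0) if g > 0 else 0.0


def dpsa3(mol3d: Chem.Mol) -> float:
    """Charge-weighted partial positive minus partial negative SASA.

    PPSA3 = sum of q_a * SA_a over positively charged atoms, PNSA3 the
    negative analogue; DPSA3 = PPSA3 - PNSA3 >= 0.
    """
    coords = _require_conformer(mol3d)
    AllChem.ComputeGasteigerCharges(mol3d)
    charges = []
    for atom in mol3d.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            raise ValueError(
                f"Gasteiger charge failed for atom {atom.GetIdx()} ({atom.GetSymbol()})"
            )
        charges.append(q)
    radii = np.array([_BONDI.get(a.GetAtomicNum(), 1.7) for a in mol3d.GetAtoms()])
    areas = shrake_rupley_areas(coords, radii)
    q = np.asarray(charges)
    ppsa3 = float((q[q > 0] * areas[q > 0]).sum())
    pnsa3 = float((q[q < 0] * areas[q < 0]).sum())
    return ppsa3 - pnsa3


# ---------------------------------------------------------------------------
# simple counts


def simple_counts(mol: Chem.Mol) -> dict[str, float]:
    """Druglikeness properties and carbon-connectivity counts."""
    c2sp2 = c2sp3 = c3sp2 = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        n_c = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 6)
        hyb = atom.GetHybridization()
        if hyb == Chem.HybridizationType.SP3 and n_c == 2:
            c2sp3 += 1
        elif hyb == Chem.HybridizationType.SP2 and n_c == 2:
            c2sp2 += 1
        elif hyb == Chem.HybridizationType.SP2 and n_c == 3:
            c3sp2 += 1
    n_acid = sum(len(mol.GetSubstructMatches(p)) for p in _ACID_SMARTS)
    return {
        "nHBAcc": rdMolDescriptors.CalcNumHBA(mol),
        "nHBDon": rdMolDescriptors.CalcNumHBD(mol),
        "nAcid": n_acid,
        "nRotB": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "C2SP2": c2sp2,
        "C2SP3": c2sp3,
        "C3SP2": c3sp2,
        "MW": Descriptors.MolWt(mol),
        "ALogP": Crippen.MolLogP(mol),
        "TPSA": rdMolDescriptors.CalcTPSA(mol),
    }


# ---------------------------------------------------------------------------
# descriptor table


def descriptor_vector(
    mol: Chem.Mol, seed: int = 42, grav_variant: str = "G4", mol3d: Chem.Mol | None = None
) -> dict[str, float]:
    """All descriptors for one molecule (embedding a conformer if needed)."""
    if mol3d is None:
        mol3d = embed_conformer(mol, seed=seed)
    vec: dict[str, float] = {
        "GRAV4": gravitational_index(mol3d, grav_variant),
        "ECCEN": eccentric_connectivity_index(mol),
        "SP6": chi_path(mol, 6),
        "SPC4": chi_path_cluster(mol, 4) if mol.GetNumBonds() >= 4 else 0.0,
        "DPSA3": dpsa3(mol3d),
        "MDEN13": mden13(mol),
    }
    vec.update(estate_fragment_counts(mol))
    vec.update(simple_counts(mol))
    return vec


def descriptor_matrix(
    molecules: Sequence[tuple[str, Chem.Mol]], seed: int = 42, grav_variant: str = "G4"
) -> pd.DataFrame:
    """Descriptor table: one row per molecule, columns in fixed order."""
    rows = []
    index = []
    for ident, mol in molecules:
        index.append(ident)
        rows.append(descriptor_vector(mol, seed=seed, grav_variant=grav_variant))
    df = pd.DataFrame(rows, index=pd.Index(index, name="id"))
    return df.reindex(columns=list(DESCRIPTOR_COLUMNS)) if len(df) else pd.DataFrame(
        columns=list(DESCRIPTOR_COLUMNS), index=pd.Index([], name="id")
    )


def drop_constant(table: pd.DataFrame) -> pd.DataFrame:
    """Remove columns with a single distinct value."""
    keep = [c for c in table.columns if table[c].nunique(dropna=False) > 1]
    return table[keep]
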