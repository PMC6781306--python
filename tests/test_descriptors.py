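import math

import numpy as np
import pytest
from rdkit import Chem

from screenmine import descriptors as D

import oracles


def mol(smi):
    m = Chem.MolFromSmiles(smi)
    assert m is not None
    return m


class TestEstateFragments:
    @pytest.mark.parametrize(
        "smi,expected",
        [
            ("CCO", {"khs.sOH": 1, "khs.ssCH2": 1}),
            ("c1ccc2ccccc2c1", {"khs.aaaC": 2}),
            ("C", {}),  # methane: every tracked count zero
            ("CC(=O)O", {"khs.dO": 1, "khs.sOH": 1, "khs.dssC": 1}),
            ("c1ccccc1[N+](=O)[O-]", {"khs.ddsN": 1, "khs.dO": 1}),
            ("O=[N](=O)c1ccccc1", {"khs.ddsN": 1, "khs.dO": 1}),  # pentavalent depiction
            ("c1cscn1", {"khs.aaS": 1, "khs.aaN": 1}),
            ("CN(C)CC(c1ccc(O)cc1)C1(O)CCCCC1",
             {"khs.ssssC": 1, "khs.sOH": 2, "khs.ssCH2": 6}),
        ],
    )
    def test_counts(self, smi, expected):
        counts = D.estate_fragment_counts(mol(smi))
        for name in D.KHS_NAMES:
            assert counts[name] == expected.get(name, 0), name

    def test_invariant_under_atom_permutation(self):
        a = D.estate_fragment_counts(mol("OC(=O)c1ccc(Cl)cc1"))
        b = D.estate_fragment_counts(mol("Clc1ccc(cc1)C(O)=O"))
        assert a == b


class TestTopologicalIndices:
    @pytest.mark.parametrize(
        "smi,expected",
        [("C", 0), ("CCCC", 14), ("C1CCCCC1", 36)],
    )
    def test_eccen_examples(self, smi, expected):
        assert D.eccentric_connectivity_index(mol(smi)) == expected

    @pytest.mark.parametrize(
        "smi,order,expected",
        [
            ("CCCCCC", 6, 0.0),                     # only 5 edges
            ("CCCCCCC", 6, 1 / math.sqrt(32)),      # the single spanning path
            ("c1ccccc1", 6, 0.0),                   # a 6-cycle has no simple 6-edge path
        ],
    )
    def test_chi_path_examples(self, smi, order, expected):
        assert D.chi_path(mol(smi), order) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "smi,expected",
        [
            ("CCCCC", 0.0),                 # no branch vertex
            ("CCC(C)C", 1 / math.sqrt(6)),  # single path-cluster subgraph
            ("CC(C)(C)C", 0.0),             # the only 4-edge subgraph is a pure star
        ],
    )
    def test_chi_path_cluster_examples(self, smi, expected):
        assert D.chi_path_cluster(mol(smi), 4) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "smi,expected",
        [
            ("CCO", 0.0),            # no nitrogen
            ("CN(C)CCN", 1 / 3),     # one primary/tertiary pair at distance 3
            ("NCCCN(C)C", 0.25),     # one pair at distance 4 -> 1/4
        ],
    )
    def test_mden13_examples(self, smi, expected):
        assert D.mden13(mol(smi)) == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement_on_fixture_set(self, small_mols):
        """ECCEN, SP6, SPC4, MDEN13 vs exhaustive enumeration (>= 50 mols)."""
        assert len(small_mols) >= 50
        for smi, m in small_mols:
            assert D.eccentric_connectivity_index(m) == oracles.eccen_oracle(m), smi
            assert D.chi_path(m, 6) == pytest.approx(oracles.chi_path_oracle(m, 6), abs=1e-9), smi
            if m.GetNumBonds() >= 4:
                assert D.chi_path_cluster(m, 4) == pytest.approx(
                    oracles.chi_path_cluster_oracle(m, 4), abs=1e-9
                ), smi
            assert D.mden13(m) == pytest.approx(oracles.mden13_oracle(m), abs=1e-9), smi


class TestGeometric:
    def test_gravitational_two_atoms(self):
        m = D.embed_conformer(mol("CC"), seed=42)
        coords = m.GetConformer().GetPositions()
        heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() == 6]
        r2 = float(((coords[heavy[0]] - coords[heavy[1]]) ** 2).sum())
        expected = 12.011**2 / r2
        assert D.gravitational_index(m, "G1") == pytest.approx(expected, rel=1e-9)
        assert D.gravitational_index(m, "G4") == pytest.approx(expected ** (1 / 3), rel=1e-9)

    def test_gravitational_inverse_square_scaling(self):
        m = D.embed_conformer(mol("CC"), seed=42)
        g1 = D.gravitational_index(m, "G1")
        conf = m.GetConformer()
        for i in range(m.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (2 * p.x, 2 * p.y, 2 * p.z))
        assert D.gravitational_index(m, "G1") == pytest.approx(g1 / 4.0, rel=1e-9)

    def test_gravitational_requires_conformer(self):
        with pytest.raises(ValueError, match="embed"):
            D.gravitational_index(mol("CC"), "G4")

    def test_single_heavy_atom_index_zero(self):
        m = D.embed_conformer(mol("C"), seed=42)
        assert D.gravitational_index(m, "G1") == 0.0

    def test_dpsa3_nonnegative_and_rotation_invariant(self):
        m = D.embed_conformer(mol("CC(=O)Oc1ccccc1C(=O)O"), seed=42)
        val = D.dpsa3(m)
        assert val >= 0
        # translation is exact; rotation is invariant up to the angular
        # discretization of the fixed 960-point surface grid
        conf = m.GetConformer()
        pts0 = conf.GetPositions() + np.array([1.0, -2.0, 3.0])
        for i, p in enumerate(pts0):
            conf.SetAtomPosition(i, p.tolist())
        assert D.dpsa3(m) == pytest.approx(val, rel=1e-9)
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        pts = conf.GetPositions() @ rot.T
        for i, p in enumerate(pts):
            conf.SetAtomPosition(i, p.tolist())
        assert D.dpsa3(m) == pytest.approx(val, rel=0.05)

    def test_dpsa3_brute_force_sum(self):
        """DPSA3 equals an independent per-atom sign-split summation."""
        m = D.embed_conformer(mol("CCO"), seed=42)
        from rdkit.Chem import AllChem

        AllChem.ComputeGasteigerCharges(m)
        q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()])
        radii = np.array([D._BONDI.get(a.GetAtomicNum(), 1.7) for a in m.GetAtoms()])
        areas = D.shrake_rupley_areas(m.GetConformer().GetPositions(), radii)
        expected = sum(qi * ai for qi, ai in zip(q, areas) if qi > 0) - sum(
            qi * ai for qi, ai in zip(q, areas) if qi < 0
        )
        assert D.dpsa3(m) == pytest.approx(expected, rel=1e-9)

    def test_shrake_rupley_isolated_sphere(self):
        areas = D.shrake_rupley_areas(np.zeros((1, 3)), np.array([1.7]))
        assert areas[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_embed_deterministic(self):
        m1 = D.embed_conformer(mol("CCOC(=O)c1ccccc1"), seed=7)
        m2 = D.embed_conformer(mol("CCOC(=O)c1ccccc1"), seed=7)
        assert np.allclose(m1.GetConformer().GetPositions(), m2.GetConformer().GetPositions())

    def test_methane_tetrahedral(self):
        m = D.embed_conformer(mol("C"), seed=42)
        assert m.GetNumAtoms() == 5
        coords = m.GetConformer().GetPositions()
        c, hs = coords[0], coords[1:]
        for i in range(4):
            for j in range(i + 1, 4):
                v1, v2 = hs[i] - c, hs[j] - c
                ang = math.degrees(
                    math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                )
                assert abs(ang - 109.47) < 2.0


class TestSimpleCounts:
    @pytest.mark.parametrize(
        "smi,key,expected",
        [
            ("CCC", "C2SP3", 1),
            ("c1ccccc1", "C2SP2", 6),
            ("c1ccccc1", "C3SP2", 0),
            ("Cc1ccccc1", "C3SP2", 1),
            ("CC(=O)O", "nAcid", 1),
            ("CS(=O)(=O)O", "nAcid", 1),
            ("CCO", "nHBDon", 1),
        ],
    )
    def test_counts(self, smi, key, expected):
        assert D.simple_counts(mol(smi))[key] == expected


class TestDescriptorMatrix:
    def test_matrix_and_drop_constant(self):
        mols = [(f"m{i}", mol(s)) for i, s in enumerate(["CCO", "CCO", "CCCO"])]
        df = D.descriptor_matrix(mols, seed=42)
        assert list(df.columns) == list(D.DESCRIPTOR_COLUMNS)
        assert len(df) == 3
        reduced = D.drop_constant(df)
        # constant columns (all three molecules lack e.g. sulfur) removed
        assert "khs.aaS" not in reduced.columns
        assert "MW" in reduced.columns

    def test_identical_molecules_all_constant(self):
        mols = [(f"m{i}", mol("CCO")) for i in range(3)]
        df = D.drop_constant(D.descriptor_matrix(mols, seed=42))
        assert df.shape[1] == 0

    def test_empty_input(self):
        df = D.descriptor_matrix([])
        assert len(df) == 0
        assert list(df.columns) == list(D.DESCRIPTOR_COLUMNS)
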