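"""Feature detection, interaction extraction, subsampling and validity."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.stats import chisquare

from phoregen.featurize import (
    DEFAULT_RULES,
    ComplementarityRule,
    NoInteractionsError,
    detect_ligand_features,
    detect_pocket_features,
    extract_interaction_pharmacophore,
    subsample,
    validity,
)
from phoregen.fixtures import FixtureSpec, make_toy_pocket
from phoregen.io import _mol_to_conformer
from phoregen.types import (
    Conformer,
    FeatureType,
    LigandRecord,
    Pharmacophore,
    PharmacophoreCenter,
    Pocket,
    PocketAtom,
)


def _conf_from_smiles(smiles: str, seed: int = 3) -> Conformer:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    mol = Chem.RemoveHs(mol)
    return _mol_to_conformer(mol)


class TestLigandFeatures:
    def test_benzene_gives_one_aromatic_at_centroid(self):
        conf = _conf_from_smiles("c1ccccc1")
        feats = detect_ligand_features(conf)
        aro = [pos for t, pos in feats if t is FeatureType.AROMATIC]
        assert len(aro) == 1
        assert np.allclose(aro[0], conf.coords.mean(axis=0), atol=1e-9)
        # aromatic carbons are excluded from hydrophobic clustering
        assert not any(t is FeatureType.HYDROPHOBIC for t, _ in feats)

    def test_methanol_is_donor_and_acceptor_on_oxygen(self):
        conf = _conf_from_smiles("CO")
        feats = detect_ligand_features(conf)
        o_pos = conf.coords[[e == "O" for e in conf.elements].index(True)]
        donors = [pos for t, pos in feats if t is FeatureType.HYDROGEN_DONOR]
        acceptors = [pos for t, pos in feats if t is FeatureType.HYDROGEN_ACCEPTOR]
        assert len(donors) == 1 and len(acceptors) == 1
        assert np.allclose(donors[0], o_pos) and np.allclose(acceptors[0], o_pos)

    def test_acetate_negative_ion_at_hand_computed_centroid(self):
        # hand-placed planar acetate: carboxylate C at origin, O's symmetric
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # carboxyl C
                [1.1, 0.7, 0.0],  # O (double bond)
                [1.1, -0.7, 0.0],  # O(-)
                [-1.5, 0.0, 0.0],  # methyl C
            ]
        )
        conf = Conformer(
            coords=coords,
            elements=["C", "O", "O", "C"],
            formal_charges=[0, 0, -1, 0],
            bonds=[(0, 1, 2), (0, 2, 1), (0, 3, 1)],
        )
        feats = detect_ligand_features(conf)
        neg = [pos for t, pos in feats if t is FeatureType.NEGATIVE_ION]
        expected = coords[:3].mean(axis=0)  # (0.7333, 0, 0) by hand
        assert len(neg) == 1
        assert np.allclose(neg[0], expected, atol=1e-9)
        assert np.allclose(expected, [2.2 / 3.0, 0.0, 0.0])

    def test_charged_nitrogen_is_positive_ion_not_acceptor(self):
        conf = _conf_from_smiles("C[NH3+]")
        feats = detect_ligand_features(conf)
        assert any(t is FeatureType.POSITIVE_ION for t, _ in feats)
        assert not any(t is FeatureType.HYDROGEN_ACCEPTOR for t, _ in feats)

    def test_propane_hydrophobic_cluster_centroid(self):
        conf = _conf_from_smiles("CCC")
        feats = detect_ligand_features(conf)
        hyd = [pos for t, pos in feats if t is FeatureType.HYDROPHOBIC]
        assert len(hyd) == 1
        assert np.allclose(hyd[0], conf.coords.mean(axis=0), atol=1e-9)


def _residue(resname, names_elements_positions, chain="A", seq=1):
    return [
        PocketAtom(element=el, position=np.asarray(p, float), residue=f"{chain}:{seq}:{resname}", atom_name=nm)
        for nm, el, p in names_elements_positions
    ]


class TestPocketFeatures:
    def test_single_glycine_backbone_donor_and_acceptor_only(self):
        atoms = _residue(
            "GLY",
            [
                ("N", "N", (0, 0, 0)),
                ("CA", "C", (1.45, 0, 0)),
                ("C", "C", (2.0, 1.4, 0)),
                ("O", "O", (3.2, 1.6, 0)),
            ],
        )
        feats = detect_pocket_features(Pocket(atoms=atoms))
        types = sorted(t.name for t, _ in feats)
        assert types == ["HYDROGEN_ACCEPTOR", "HYDROGEN_DONOR"]
        by_type = {t: pos for t, pos in feats}
        assert np.allclose(by_type[FeatureType.HYDROGEN_DONOR], (0, 0, 0))
        assert np.allclose(by_type[FeatureType.HYDROGEN_ACCEPTOR], (3.2, 1.6, 0))

    def test_aspartate_contributes_negative_ion_at_carboxylate_centroid(self):
        side = [("CG", "C", (0, 0, 0)), ("OD1", "O", (1.0, 0.8, 0)), ("OD2", "O", (1.0, -0.8, 0))]
        atoms = _residue("ASP", side)
        feats = detect_pocket_features(Pocket(atoms=atoms))
        neg = [pos for t, pos in feats if t is FeatureType.NEGATIVE_ION]
        assert len(neg) == 1
        assert np.allclose(neg[0], np.array([2.0 / 3.0, 0.0, 0.0]), atol=1e-9)

    def test_unknown_residues_contribute_nothing(self):
        atoms = _residue("XYZ", [("C1", "C", (0, 0, 0)), ("N", "N", (1, 0, 0))])
        assert detect_pocket_features(Pocket(atoms=atoms)) == []

    def test_planted_fixture_sites_detected_exactly(self):
        pocket, planted = make_toy_pocket(FixtureSpec(seed=5))
        detected = detect_pocket_features(pocket)
        assert len(detected) == len(planted)
        for (pt, ppos), (dt, dpos) in zip(planted, detected):
            assert pt is dt
            assert np.abs(ppos - dpos).max() < 1e-9


class TestInteractionExtraction:
    def _pocket_with_acceptor(self, pos):
        atoms = _residue("GLY", [("O", "O", pos), ("C", "C", np.asarray(pos) + [0, 0, 1.23])])
        return Pocket(atoms=atoms)

    def _donor_ligand(self, pos):
        # methanol posed with its oxygen at ``pos``
        coords = np.array([pos, np.asarray(pos) + [1.43, 0, 0]])
        conf = Conformer(coords, ["O", "C"], [0, 0], [(0, 1, 1)])
        return LigandRecord(mol_id="lig", conformers=[conf])

    def test_donor_within_threshold_is_retained(self):
        pocket = self._pocket_with_acceptor((0, 0, 0))
        ligand = self._donor_ligand((0, 2.8, 0))  # 2.8 < 4.0 threshold
        ph = extract_interaction_pharmacophore(pocket, ligand)
        assert any(
            c.ftype is FeatureType.HYDROGEN_DONOR and np.allclose(c.position, (0, 2.8, 0))
            for c in ph.centers
        )

    def test_donor_beyond_all_thresholds_dropped(self):
        pocket = self._pocket_with_acceptor((0, 0, 0))
        ligand = self._donor_ligand((0, 9.0, 0))
        with pytest.raises(NoInteractionsError):
            extract_interaction_pharmacophore(pocket, ligand)

    def test_featureless_ligand_raises(self):
        conf = Conformer(np.array([[0.0, 0, 0], [1.5, 0, 0]]), ["C", "C"], [0, 0], [(0, 1, 1)])
        ligand = LigandRecord(mol_id="cc", conformers=[conf])
        pocket = self._pocket_with_acceptor((0, 0, 0))
        with pytest.raises(NoInteractionsError):
            extract_interaction_pharmacophore(pocket, ligand)

    def test_extraction_is_subset_of_ligand_features(self):
        pocket, _ = make_toy_pocket(FixtureSpec(seed=5))
        coords = np.array([[6.6, 0, 0], [6.6 + 1.43, 0, 0]])
        conf = Conformer(coords, ["O", "C"], [0, 0], [(0, 1, 1)])
        ligand = LigandRecord(mol_id="m", conformers=[conf])
        ph = extract_interaction_pharmacophore(pocket, ligand)
        lig_feats = detect_ligand_features(conf)
        for c in ph.centers:
            assert any(
                t is c.ftype and np.allclose(p, c.position) for t, p in lig_feats
            )


def _ph(n, rng):
    return Pharmacophore(
        [
            PharmacophoreCenter(rng.uniform(-5, 5, 3), FeatureType(int(rng.integers(6))))
            for _ in range(n)
        ]
    )


class TestSubsample:
    def test_sizes_bounded_and_subset_of_input(self):
        rng = np.random.default_rng(0)
        ph = _ph(10, rng)
        for _ in range(50):
            sub = subsample(ph, rng)
            assert 3 <= len(sub) <= 8
            for c in sub.centers:
                assert any(c is orig for orig in ph.centers)

    def test_minimum_size_input_returned_whole(self):
        rng = np.random.default_rng(1)
        ph = _ph(3, rng)
        sub = subsample(ph, rng)
        assert [id(c) for c in sub.centers] == [id(c) for c in ph.centers]

    def test_too_small_input_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            subsample(_ph(2, rng), rng)

    def test_center_inclusion_is_uniform(self):
        # over many draws every center of a 10-center input should be included
        # equally often (chi-square on inclusion counts)
        rng = np.random.default_rng(3)
        ph = _ph(10, rng)
        counts = np.zeros(10)
        n_draws = 10_000
        index = {id(c): i for i, c in enumerate(ph.centers)}
        for _ in range(n_draws):
            for c in subsample(ph, rng).centers:
                counts[index[id(c)]] += 1
        _, p = chisquare(counts)
        assert p > 0.001


class TestValidity:
    def _pocket(self):
        pocket, planted = make_toy_pocket(FixtureSpec(seed=5))
        return pocket, planted

    def test_center_on_complementary_feature_scores_one(self):
        pocket, planted = self._pocket()
        st, pos = planted[0]  # protein acceptor -> ligand donor center
        ph = Pharmacophore([PharmacophoreCenter(pos, FeatureType.HYDROGEN_DONOR)])
        assert validity(ph, pocket) == 1.0

    def test_far_center_scores_zero(self):
        pocket, _ = self._pocket()
        ph = Pharmacophore(
            [PharmacophoreCenter(np.array([100.0, 0, 0]), FeatureType.HYDROGEN_DONOR)]
        )
        assert validity(ph, pocket) == 0.0

    def test_half_valid_scores_half(self):
        pocket, planted = self._pocket()
        _, pos = planted[0]
        ph = Pharmacophore(
            [
                PharmacophoreCenter(pos, FeatureType.HYDROGEN_DONOR),
                PharmacophoreCenter(np.array([100.0, 0, 0]), FeatureType.AROMATIC),
            ]
        )
        assert validity(ph, pocket) == 0.5

    def test_monotone_under_threshold_shrinkage(self):
        pocket, planted = self._pocket()
        rng = np.random.default_rng(7)
        centers = [
            PharmacophoreCenter(pos + rng.standard_normal(3) * 2.0, FeatureType.HYDROGEN_DONOR)
            for _, pos in planted
        ]
        ph = Pharmacophore(centers)
        last = 1.1
        for factor in (1.0, 0.5, 0.25, 0.1):
            v = validity(ph, pocket, DEFAULT_RULES.scaled(factor))
            assert v <= last + 1e-12
            last = v


def test_rule_table_round_trips_and_validates():
    rules = ComplementarityRule.from_dict(DEFAULT_RULES.to_dict())
    assert rules.to_dict() == DEFAULT_RULES.to_dict()
    with pytest.raises(ValueError):
        ComplementarityRule({FeatureType.HYDROGEN_DONOR: {FeatureType.HYDROGEN_ACCEPTOR: 4.0}})
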