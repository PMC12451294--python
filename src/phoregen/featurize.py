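"""Pharmacophore feature detection and training-data extraction.

Ligand-side rules (applied to a conformer):

* HydrogenDonor — N or O bearing at least one hydrogen (explicit or implicit).
* HydrogenAcceptor — N or O with an available lone pair and no positive
  formal charge (aromatic N–H nitrogens are excluded).
* Aromatic — centroid of each 5- or 6-membered aromatic ring.
* Hydrophobic — centroid of each connected cluster of >= 3 non-aromatic
  carbons none of which touches a heteroatom.
* PositiveIon — N with positive formal charge, or the central carbon of an
  amidine/guanidine group.
* NegativeIon — centroid of a carboxylate/sulfate/phosphate group, or any
  other atom with negative formal charge.

Pocket-side rules are residue-based (backbone N-H donor, backbone C=O
acceptor, side-chain features per residue name).  The same complementarity
threshold table drives both training extraction and the validity metric, so
the two cannot drift apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .types import Conformer, FeatureType, LigandRecord, Pharmacophore, PharmacophoreCenter, Pocket

logger = logging.getLogger(__name__)

Feature = tuple[FeatureType, np.ndarray]


# ---------------------------------------------------------------------------
# Complementarity rules

@dataclass
class ComplementarityRule:
    """Which protein feature types complement a ligand feature, and how far away.

    ``table`` maps a ligand FeatureType to a dict of {protein FeatureType:
    interaction distance threshold in Angstrom}.
    """

    table: dict[FeatureType, dict[FeatureType, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.table:
            self.table = _default_rule_table()
        for ftype in FeatureType:
            if ftype not in self.table or not self.table[ftype]:
                raise ValueError(f"no complementarity rule for {ftype.label}")
            for thr in self.table[ftype].values():
                if not thr > 0:
                    raise ValueError("interaction thresholds must be > 0")

    def partners(self, ligand_type: FeatureType) -> dict[FeatureType, float]:
        return self.table[ligand_type]

    def scaled(self, factor: float) -> "ComplementarityRule":
        """A copy with every threshold multiplied by ``factor`` (> 0)."""
        return ComplementarityRule(
            {lt: {pt: thr * factor for pt, thr in d.items()} for lt, d in self.table.items()}
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "ComplementarityRule":
        table = {
            FeatureType.from_label(lt): {
                FeatureType.from_label(pt): float(thr) for pt, thr in d.items()
            }
            for lt, d in raw.items()
        }
        return cls(table)

    def to_dict(self) -> dict:
        return {
            lt.label: {pt.label: thr for pt, thr in d.items()}
            for lt, d in self.table.items()
        }


def _default_rule_table() -> dict[FeatureType, dict[FeatureType, float]]:
    A, D, H, R, N, P = FeatureType  # acceptor, donor, hydrophobic, aromatic, neg, pos
    return {
        D: {A: 4.0},
        A: {D: 4.0},
        H: {H: 5.0},
        R: {R: 5.0, P: 5.0},  # pi stacking and cation-pi
        N: {P: 5.0},
        P: {N: 5.0, R: 5.0},
    }


DEFAULT_RULES = ComplementarityRule()


# ---------------------------------------------------------------------------
# Ligand-side detection

_BOND_ORDERS = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    12: Chem.BondType.AROMATIC,
}


def conformer_to_mol(conf: Conformer) -> Chem.Mol:
    """Build a sanitized RDKit molecule (with this geometry) from a conformer."""
    rw = Chem.RWMol()
    for sym, chg in zip(conf.elements, conf.formal_charges):
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(int(chg))
        rw.AddAtom(atom)
    for i, j, order in conf.bonds:
        rw.AddBond(int(i), int(j), _BOND_ORDERS[int(order)])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    rdconf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(conf.coords):
        rdconf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(rdconf)
    return mol


def _ensure_mol(conf: Conformer, mol_id: str = "?") -> Chem.Mol:
    if conf.mol is not None:
        return conf.mol
    try:
        conf.mol = conformer_to_mol(conf)
    except Exception as exc:
        raise ValueError(f"cannot perceive molecule {mol_id!r}: {exc}") from exc
    return conf.mol


_NEG_GROUP_SMARTS = [
    # carboxylate / carboxylic acid: centroid over C and both oxygens
    Chem.MolFromSmarts("[CX3](=[OX1])[OX1-,OX2H1]"),
    # sulfate/sulfonate
    Chem.MolFromSmarts("[SX4](=[OX1])(=[OX1])[OX1-,OX2H1]"),
    # phosphate/phosphonate
    Chem.MolFromSmarts("[PX4](=[OX1])([OX1-,OX2H1])"),
]
_POS_GROUP_SMARTS = [
    # amidine / guanidine central carbon
    Chem.MolFromSmarts("[NX3][CX3]=[NX2]"),
]


def detect_ligand_features(
    conformer: Conformer, mol_id: str = "?"
) -> list[Feature]:
    """Detect pharmacophore features on one ligand conformer."""
    mol = _ensure_mol(conformer, mol_id)
    coords = conformer.coords
    feats: list[Feature] = []

    neg_group_atoms: set[int] = set()
    for patt in _NEG_GROUP_SMARTS:
        for match in mol.GetSubstructMatches(patt):
            centroid = coords[list(match)].mean(axis=0)
            feats.append((FeatureType.NEGATIVE_ION, centroid))
            neg_group_atoms.update(match)
    pos_group_atoms: set[int] = set()
    for patt in _POS_GROUP_SMARTS:
        for match in mol.GetSubstructMatches(patt):
            carbon = next(i for i in match if mol.GetAtomWithIdx(i).GetSymbol() == "C")
            if carbon not in pos_group_atoms:
                feats.append((FeatureType.POSITIVE_ION, coords[carbon].copy()))
                pos_group_atoms.add(carbon)

    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        chg = atom.GetFormalCharge()
        if sym in ("N", "O"):
            n_h = atom.GetTotalNumHs(includeNeighbors=True)
            if n_h >= 1:
                feats.append((FeatureType.HYDROGEN_DONOR, coords[i].copy()))
            lone_pair_ok = chg <= 0 and not (atom.GetIsAromatic() and sym == "N" and n_h >= 1)
            if sym == "N":
                # quaternary / fully substituted nitrogens have no lone pair
                lone_pair_ok = lone_pair_ok and atom.GetTotalValence() <= 3
            if lone_pair_ok:
                feats.append((FeatureType.HYDROGEN_ACCEPTOR, coords[i].copy()))
        if chg > 0 and sym == "N":
            feats.append((FeatureType.POSITIVE_ION, coords[i].copy()))
        if chg < 0 and i not in neg_group_atoms:
            feats.append((FeatureType.NEGATIVE_ION, coords[i].copy()))

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if len(ring) in (5, 6) and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            feats.append((FeatureType.AROMATIC, coords[list(ring)].mean(axis=0)))

    feats.extend(_hydrophobic_clusters(mol, coords))
    return feats


def _hydrophobic_clusters(mol: Chem.Mol, coords: np.ndarray) -> list[Feature]:
    """Connected clusters of >=3 non-aromatic carbons with no heteroatom contact."""
    eligible = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIsAromatic():
            continue
        if any(nb.GetSymbol() not in ("C", "H") for nb in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    seen: set[int] = set()
    out: list[Feature] = []
    for start in sorted(eligible):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= 3:
            out.append((FeatureType.HYDROPHOBIC, coords[comp].mean(axis=0)))
    return out


# ---------------------------------------------------------------------------
# Pocket-side detection

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_HYDROPHOBIC_SIDECHAIN = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
}
_NEG_SIDECHAIN = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}
_POS_SIDECHAIN = {"LYS": ("NZ",), "ARG": ("CZ", "NE", "NH1", "NH2")}
_OH_SIDECHAIN = {"SER": "OG", "THR": "OG1", "TYR": "OH"}
_AMIDE_SIDECHAIN = {"ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2")}


def detect_pocket_features(pocket: Pocket) -> list[Feature]:
    """Detect complementary (protein-side) features in a pocket.

    Residues are processed independently; unknown residue names contribute
    nothing.  Partial residues (missing atoms) contribute only the features
    whose atoms are all present.
    """
    by_residue: dict[str, dict[str, np.ndarray]] = {}
    res_order: list[str] = []
    for atom in pocket.atoms:
        if atom.residue not in by_residue:
            by_residue[atom.residue] = {}
            res_order.append(atom.residue)
        by_residue[atom.residue].setdefault(atom.atom_name, atom.position)

    feats: list[Feature] = []
    for res in res_order:
        resname = res.rsplit(":", 1)[-1]
        atoms = by_residue[res]
        if resname not in _STANDARD_AA:
            logger.debug("detect_pocket_features: skipping residue %s", res)
            continue
        if "N" in atoms and resname != "PRO":
            feats.append((FeatureType.HYDROGEN_DONOR, atoms["N"].copy()))
        if "O" in atoms:
            feats.append((FeatureType.HYDROGEN_ACCEPTOR, atoms["O"].copy()))
        if resname in _RING_ATOMS and all(a in atoms for a in _RING_ATOMS[resname]):
            pts = np.array([atoms[a] for a in _RING_ATOMS[resname]])
            feats.append((FeatureType.AROMATIC, pts.mean(axis=0)))
        if resname == "HIS" and all(a in atoms for a in _RING_ATOMS["HIS"]):
            pts = np.array([atoms[a] for a in _RING_ATOMS["HIS"]])
            feats.append((FeatureType.POSITIVE_ION, pts.mean(axis=0)))
        if resname in _HYDROPHOBIC_SIDECHAIN and all(
            a in atoms for a in _HYDROPHOBIC_SIDECHAIN[resname]
        ):
            pts = np.array([atoms[a] for a in _HYDROPHOBIC_SIDECHAIN[resname]])
            feats.append((FeatureType.HYDROPHOBIC, pts.mean(axis=0)))
        if resname in _NEG_SIDECHAIN and all(a in atoms for a in _NEG_SIDECHAIN[resname]):
            pts = np.array([atoms[a] for a in _NEG_SIDECHAIN[resname]])
            feats.append((FeatureType.NEGATIVE_ION, pts.mean(axis=0)))
        if resname in _POS_SIDECHAIN and all(a in atoms for a in _POS_SIDECHAIN[resname]):
            pts = np.array([atoms[a] for a in _POS_SIDECHAIN[resname]])
            feats.append((FeatureType.POSITIVE_ION, pts.mean(axis=0)))
        if resname in _OH_SIDECHAIN and _OH_SIDECHAIN[resname] in atoms:
            pos = atoms[_OH_SIDECHAIN[resname]]
            feats.append((FeatureType.HYDROGEN_DONOR, pos.copy()))
            feats.append((FeatureType.HYDROGEN_ACCEPTOR, pos.copy()))
        if resname in _AMIDE_SIDECHAIN:
            o_name, n_name = _AMIDE_SIDECHAIN[resname]
            if o_name in atoms:
                feats.append((FeatureType.HYDROGEN_ACCEPTOR, atoms[o_name].copy()))
            if n_name in atoms:
                feats.append((FeatureType.HYDROGEN_DONOR, atoms[n_name].copy()))
    return feats


# ---------------------------------------------------------------------------
# Interaction pharmacophores, subsampling, validity

class NoInteractionsError(ValueError):
    pass


def _pocket_features(pocket: Pocket, pocket_features: Optional[list[Feature]]) -> list[Feature]:
    if pocket_features is not None:
        return pocket_features
    if pocket.complementary_features is not None:
        return pocket.complementary_features
    return detect_pocket_features(pocket)


def extract_interaction_pharmacophore(
    pocket: Pocket,
    ligand: LigandRecord,
    rules: ComplementarityRule = DEFAULT_RULES,
    conformer_index: int = 0,
    radius: float = 1.0,
) -> Pharmacophore:
    """Keep the ligand features that interact with a complementary pocket feature.

    The ligand must already be posed in the pocket frame.  A ligand feature
    survives when some complementary pocket feature lies within that type
    pair's distance threshold; the center position is the ligand feature's.
    """
    lig_feats = detect_ligand_features(ligand.conformers[conformer_index], ligand.mol_id)
    if not lig_feats:
        raise NoInteractionsError(f"ligand {ligand.mol_id!r} has no detectable features")
    pkt_feats = _pocket_features(pocket, None)
    centers = []
    for ftype, pos in lig_feats:
        if _has_complement(ftype, pos, pkt_feats, rules):
            centers.append(PharmacophoreCenter(position=pos, ftype=ftype, radius=radius))
    if not centers:
        raise NoInteractionsError(
            f"no interactions: ligand {ligand.mol_id!r} features have no "
            "complementary pocket feature in range"
        )
    return Pharmacophore(centers=centers)


def _has_complement(
    ftype: FeatureType,
    pos: np.ndarray,
    pocket_feats: Sequence[Feature],
    rules: ComplementarityRule,
) -> bool:
    partners = rules.partners(ftype)
    for ptype, ppos in pocket_feats:
        thr = partners.get(ptype)
        if thr is not None and np.linalg.norm(pos - ppos) <= thr:
            return True
    return False


def subsample(
    ph: Pharmacophore,
    rng: np.random.Generator,
    min_n: int = 3,
    max_n: int = 8,
) -> Pharmacophore:
    """Uniformly subsample a pharmacophore to between min_n and max_n centers.

    The size is drawn uniformly from [min_n, min(max_n, |ph|)] and the subset
    uniformly without replacement; original center order is preserved.
    """
    n = len(ph)
    if n < min_n:
        raise ValueError(f"pharmacophore has {n} centers; need at least {min_n}")
    hi = min(max_n, n)
    size = int(rng.integers(min_n, hi + 1))
    idx = np.sort(rng.choice(n, size=size, replace=False))
    return Pharmacophore(centers=[ph.centers[i] for i in idx])


def validity(
    ph: Pharmacophore,
    pocket: Pocket,
    rules: ComplementarityRule = DEFAULT_RULES,
    pocket_features: Optional[list[Feature]] = None,
) -> float:
    """Fraction of centers within threshold distance of a complementary pocket feature."""
    pkt_feats = _pocket_features(pocket, pocket_features)
    good = sum(
        _has_complement(c.ftype, c.position, pkt_feats, rules) for c in ph.centers
    )
    return good / len(ph)
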