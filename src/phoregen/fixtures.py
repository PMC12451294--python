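"""Synthetic fixtures with exact ground truth.

The toy pocket is a shell of inert carbon atoms (unknown residue name, so
the pocket featurizer ignores them) surrounding planted "site" residues
that are co-designed with `detect_pocket_features`: each site residue
yields exactly one protein-side feature whose position equals the planted
site to floating precision.  Training pairs place complementary
ligand-side centers at the planted sites plus Gaussian jitter, so at zero
jitter every pair has validity exactly 1.

The screening library embeds a truth pharmacophore into each active
conformer (within 0.5 Angstrom) and builds decoys by radially scaling the
truth geometry, which moves every pairwise distance by far more than the
matcher's tolerance allows — actives must match, decoys (with >= 2 query
centers) cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .featurize import Feature
from .types import (
    Conformer,
    FeatureType,
    LigandRecord,
    Pharmacophore,
    PharmacophoreCenter,
    Pocket,
    PocketAtom,
)

#: protein-side site type -> ligand-side complementary center type
COMPLEMENT = {
    FeatureType.HYDROGEN_ACCEPTOR: FeatureType.HYDROGEN_DONOR,
    FeatureType.HYDROGEN_DONOR: FeatureType.HYDROGEN_ACCEPTOR,
    FeatureType.HYDROPHOBIC: FeatureType.HYDROPHOBIC,
    FeatureType.AROMATIC: FeatureType.AROMATIC,
    FeatureType.NEGATIVE_ION: FeatureType.POSITIVE_ION,
    FeatureType.POSITIVE_ION: FeatureType.NEGATIVE_ION,
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    n_sites: int = 6
    site_types: Optional[list[FeatureType]] = None  # protein-side; default: all 6
    site_positions: Optional[np.ndarray] = None  # (n_sites, 3)
    jitter_sd: float = 0.2  # Angstrom, ligand-center jitter about sites
    n_train: int = 2000
    n_actives: int = 20
    n_decoys: int = 180
    conformers_per_molecule: int = 3
    n_shell: int = 48  # inert shell atoms
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _default_layout(n_sites: int) -> tuple[list[FeatureType], np.ndarray]:
    """Octahedral site layout with per-site radii chosen to break symmetry."""
    dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    radii = np.array([6.6, 6.0, 5.4, 6.3, 5.7, 6.9])
    types = [
        FeatureType.HYDROGEN_ACCEPTOR,
        FeatureType.HYDROGEN_DONOR,
        FeatureType.HYDROPHOBIC,
        FeatureType.AROMATIC,
        FeatureType.NEGATIVE_ION,
        FeatureType.POSITIVE_ION,
    ]
    idx = [i % 6 for i in range(n_sites)]
    return [types[i] for i in idx], dirs[idx] * radii[idx, None]


def _perp(u: np.ndarray) -> np.ndarray:
    a = np.zeros(3)
    a[np.argmin(np.abs(u))] = 1.0
    v = np.cross(u, a)
    return v / np.linalg.norm(v)


_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)


def _site_residue(
    site_type: FeatureType, pos: np.ndarray, seq: int
) -> list[PocketAtom]:
    """A minimal residue whose detected feature sits exactly at ``pos``."""
    u = pos / np.linalg.norm(pos)  # outward, away from the pocket center
    v = _perp(u)
    w = np.cross(u, v)

    def atom(el, name, p, resname):
        return PocketAtom(element=el, position=p, residue=f"A:{seq}:{resname}", atom_name=name)

    if site_type == FeatureType.HYDROGEN_DONOR:
        # backbone amide N; CA carbon behind it distinguishes it from a lone N
        return [atom("N", "N", pos, "GLY"), atom("C", "CA", pos + 1.47 * u, "GLY")]
    if site_type == FeatureType.HYDROGEN_ACCEPTOR:
        return [atom("O", "O", pos, "GLY"), atom("C", "C", pos + 1.23 * u, "GLY")]
    if site_type == FeatureType.POSITIVE_ION:
        return [atom("N", "NZ", pos, "LYS")]
    if site_type == FeatureType.NEGATIVE_ION:
        half = math.radians(63.0)
        e1 = math.cos(half) * u + math.sin(half) * v
        e2 = math.cos(half) * u - math.sin(half) * v
        cg = pos - (1.25 * (e1 + e2) / 3.0)
        return [
            atom("C", "CG", cg, "ASP"),
            atom("O", "OD1", cg + 1.25 * e1, "ASP"),
            atom("O", "OD2", cg + 1.25 * e2, "ASP"),
        ]
    if site_type == FeatureType.AROMATIC:
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        out = []
        for i, name in enumerate(names):
            ang = 2.0 * math.pi * i / 6.0
            p = pos + 1.39 * (math.cos(ang) * v + math.sin(ang) * w)
            out.append(atom("C", name, p, "PHE"))
        return out
    if site_type == FeatureType.HYDROPHOBIC:
        names = ("CB", "CG", "CD1", "CD2")
        frame = np.stack([v, w, u], axis=1)
        return [
            atom("C", name, pos + 1.1 * (frame @ t), "LEU")
            for name, t in zip(names, _TETRA)
        ]
    raise ValueError(site_type)


def make_toy_pocket(spec: FixtureSpec) -> tuple[Pocket, list[Feature]]:
    """Build a toy pocket; returns (pocket, planted protein-side features)."""
    ss = np.random.SeedSequence(spec.seed)
    shell_rng = np.random.default_rng(ss.spawn(1)[0])

    if spec.site_types is not None:
        types = list(spec.site_types)
        positions = np.asarray(spec.site_positions, dtype=float)
    else:
        types, positions = _default_layout(spec.n_sites)

    atoms: list[PocketAtom] = []
    planted: list[Feature] = []
    for i, (st, pos) in enumerate(zip(types, positions)):
        atoms.extend(_site_residue(st, np.asarray(pos, dtype=float), seq=i + 1))
        planted.append((st, np.asarray(pos, dtype=float)))

    # inert anisotropic shell: generic geometry keeps the pocket's principal
    # axes well defined (the sampler's canonical frame relies on this)
    axis_scale = np.array([1.15, 1.0, 0.87])
    for j in range(spec.n_shell):
        d = shell_rng.standard_normal(3)
        d /= np.linalg.norm(d)
        r = shell_rng.uniform(8.5, 10.5)
        atoms.append(
            PocketAtom(
                element="C",
                position=d * r * axis_scale,
                residue="S:900:UNK",
                atom_name=f"C{j}",
            )
        )
    pocket = Pocket(atoms=atoms, complementary_features=planted)
    return pocket, planted


def make_training_pairs(spec: FixtureSpec) -> list[tuple[Pocket, Pharmacophore]]:
    """Training pairs: ligand-side centers at complementary sites plus jitter."""
    pocket, planted = make_toy_pocket(spec)
    max_n = min(8, len(planted))
    min_n = min(3, max_n)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    pairs = []
    for _ in range(spec.n_train):
        c = int(rng.integers(min_n, max_n + 1))
        idx = rng.choice(len(planted), size=c, replace=False)
        centers = []
        for i in np.sort(idx):
            st, pos = planted[i]
            jitter = rng.standard_normal(3) * spec.jitter_sd
            centers.append(
                PharmacophoreCenter(position=pos + jitter, ftype=COMPLEMENT[st])
            )
        pairs.append((pocket, Pharmacophore(centers=centers)))
    return pairs


# ---------------------------------------------------------------------------
# Fragment scaffolds whose detected feature lands at a requested point

_FRAG_BOND = {"single": 1, "aromatic": 12}


def _rand_frame(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


def _fragment(ftype: FeatureType, p: np.ndarray, rng: np.random.Generator):
    """(elements, charges, coords, bonds) of a fragment featuring ``ftype`` at p."""
    R = _rand_frame(rng)
    u, v = R[:, 0], R[:, 1]
    if ftype == FeatureType.HYDROGEN_ACCEPTOR:  # dimethyl ether oxygen
        half = math.radians(55.5)
        c1 = p + 1.43 * (math.cos(half) * u + math.sin(half) * v)
        c2 = p + 1.43 * (math.cos(half) * u - math.sin(half) * v)
        return ["O", "C", "C"], [0, 0, 0], [p, c1, c2], [(0, 1, 1), (0, 2, 1)]
    if ftype == FeatureType.HYDROGEN_DONOR:  # methanol oxygen (also an acceptor)
        return ["O", "C"], [0, 0], [p, p + 1.43 * u], [(0, 1, 1)]
    if ftype == FeatureType.POSITIVE_ION:  # methylammonium nitrogen
        return ["N", "C"], [1, 0], [p, p + 1.49 * u], [(0, 1, 1)]
    if ftype == FeatureType.NEGATIVE_ION:  # acetate carboxylate, centroid at p
        half = math.radians(63.0)
        e1 = math.cos(half) * u + math.sin(half) * v
        e2 = math.cos(half) * u - math.sin(half) * v
        cc = p - 1.25 * (e1 + e2) / 3.0
        cm = cc - 1.52 * u
        return (
            ["C", "O", "O", "C"],
            [0, 0, -1, 0],
            [cc, cc + 1.25 * e1, cc + 1.25 * e2, cm],
            [(0, 1, 2), (0, 2, 1), (0, 3, 1)],
        )
    if ftype == FeatureType.AROMATIC:  # benzene, centroid at p
        coords = [
            p + 1.39 * (math.cos(2 * math.pi * i / 6) * u + math.sin(2 * math.pi * i / 6) * v)
            for i in range(6)
        ]
        bonds = [(i, (i + 1) % 6, 12) for i in range(6)]
        return ["C"] * 6, [0] * 6, coords, bonds
    if ftype == FeatureType.HYDROPHOBIC:  # propane, carbon centroid at p
        theta = math.radians(112.0)
        d = 1.54
        c1 = np.array([-d * math.sin(theta / 2), d * math.cos(theta / 2), 0.0])
        c3 = np.array([d * math.sin(theta / 2), d * math.cos(theta / 2), 0.0])
        local = np.stack([c1, np.zeros(3), c3])
        local -= local.mean(axis=0)
        coords = [p + R @ x for x in local]
        return ["C"] * 3, [0] * 3, coords, [(0, 1, 1), (1, 2, 1)]
    raise ValueError(ftype)


def _assemble(fragments) -> Conformer:
    elements, charges, coords, bonds = [], [], [], []
    for els, chgs, xyz, bds in fragments:
        off = len(elements)
        elements += els
        charges += chgs
        coords += [np.asarray(x, dtype=float) for x in xyz]
        bonds += [(i + off, j + off, o) for i, j, o in bds]
    return Conformer(
        coords=np.array(coords), elements=elements, formal_charges=charges, bonds=bonds
    )


def _conformer_at(
    targets: list[tuple[FeatureType, np.ndarray]], rng: np.random.Generator
) -> Conformer:
    return _assemble([_fragment(ft, np.asarray(p, dtype=float), rng) for ft, p in targets])


DECOY_SCALE = 2.2  # radial scaling; moves every pairwise distance >> 2*rmsd_tol


def make_toy_library(
    spec: FixtureSpec, ph_truth: Pharmacophore
) -> list[LigandRecord]:
    """Actives embed the truth pharmacophore; decoys are scaled out of reach."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    truth = [(c.ftype, c.position) for c in ph_truth.centers]
    center = ph_truth.positions.mean(axis=0)

    def decoy_targets():
        R = _rand_frame(rng)
        shift = rng.uniform(-3, 3, size=3)
        return [
            (ft, center + DECOY_SCALE * (R @ (p - center)) + shift) for ft, p in truth
        ]

    def distractors(n=2):
        out = []
        for _ in range(n):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            ft = FeatureType(int(rng.integers(0, 6)))
            out.append((ft, d * rng.uniform(13.0, 16.0)))
        return out

    records = []
    for i in range(spec.n_actives):
        jittered = []
        for ft, p in truth:
            j = rng.standard_normal(3)
            j = j / np.linalg.norm(j) * rng.uniform(0.0, 0.3)
            jittered.append((ft, p + j))
        extra = distractors()
        match_idx = int(rng.integers(0, spec.conformers_per_molecule))
        confs = []
        for ci in range(spec.conformers_per_molecule):
            targets = (jittered if ci == match_idx else decoy_targets()) + extra
            confs.append(_conformer_at(targets, rng))
        records.append(
            LigandRecord(mol_id=f"active_{i:04d}", conformers=confs, active_label=True)
        )
    for i in range(spec.n_decoys):
        confs = [
            _conformer_at(decoy_targets(), rng)
            for _ in range(spec.conformers_per_molecule)
        ]
        records.append(
            LigandRecord(mol_id=f"decoy_{i:04d}", conformers=confs, active_label=False)
        )
    return records


def truth_pharmacophore(spec: FixtureSpec) -> tuple[Pocket, Pharmacophore]:
    """The pocket plus the noise-free complementary pharmacophore over all sites."""
    pocket, planted = make_toy_pocket(spec)
    centers = [
        PharmacophoreCenter(position=pos, ftype=COMPLEMENT[st]) for st, pos in planted
    ]
    return pocket, Pharmacophore(centers=centers)


# ---------------------------------------------------------------------------
# Strain-energy fixtures: small real molecules with scripted distortions

def make_strain_fixture(
    smiles: str = "CCCC", stretch: float = 0.0, seed: int = 7
) -> Conformer:
    """A UFF-minimized conformer, optionally with one bond stretched.

    ``stretch`` displaces everything on one side of the first rotatable
    C-C bond along the bond axis, producing a strictly positive strain that
    grows with the displacement.
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    AllChem.UFFOptimizeMolecule(mol, maxIters=5000)
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions())
    if stretch != 0.0:
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
        i, j = heavy[0], heavy[1]
        axis = coords[j] - coords[i]
        axis /= np.linalg.norm(axis)
        # move atom i's side of the bond
        side = _bond_side(mol, i, j)
        coords[list(side)] -= stretch * axis
        for k in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(k, [float(x) for x in coords[k]])
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    return Conformer(coords=coords, elements=elements, formal_charges=charges, bonds=bonds, mol=mol)


def _bond_side(mol: Chem.Mol, i: int, j: int) -> set[int]:
    """Atoms reachable from i without crossing the i-j bond."""
    seen = {i, j}
    stack = [i]
    side = {i}
    while stack:
        a = stack.pop()
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            k = nb.GetIdx()
            if k not in seen:
                seen.add(k)
                side.add(k)
                stack.append(k)
    return side
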