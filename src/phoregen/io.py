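"""Readers and writers: PDB pockets, SDF conformer libraries, query JSON.

The pharmacophore query dialect is a Pharmit-style JSON object::

    {"points": [{"name": "Aromatic", "x": .., "y": .., "z": ..,
                 "radius": 1.0, "enabled": true}, ...]}

``parse_query(write_query(ph))`` is the identity on pharmacophores.
"""

from __future__ import annotations

import io as _io
import json
import logging
from typing import Sequence, Union

import gemmi
import numpy as np
from rdkit import Chem

from .types import (
    Conformer,
    FeatureType,
    LigandRecord,
    Pharmacophore,
    PharmacophoreCenter,
    Pocket,
    PocketAtom,
)

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: residue selector entries look like "A:42" (chain:seqnum)
ResidueSelector = Sequence[str]
LigandSelector = np.ndarray  # (L, 3) reference-ligand coordinates


class PDBParseError(ValueError):
    pass


class EmptyPocketError(ValueError):
    pass


def _prescan_pdb(pdb_text: str) -> None:
    """Validate coordinate fields of ATOM/HETATM records, reporting line numbers."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed coordinate field in ATOM/HETATM record"
            ) from None


def read_pocket(
    pdb_text: str,
    selector: Union[LigandSelector, ResidueSelector],
    radius: float = 8.0,
) -> Pocket:
    """Extract a binding pocket from PDB text.

    The pocket is selected either through a reference ligand (``selector`` is
    an (L, 3) coordinate array; atoms within ``radius`` Angstrom of any ligand
    atom are kept) or through a list of residues (``selector`` is a sequence
    of "chain:seqnum" strings).  Waters and atoms coincident with the
    reference ligand are always excluded.
    """
    _prescan_pdb(pdb_text)
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc

    ligand_mode = isinstance(selector, np.ndarray) or (
        len(selector) > 0 and not isinstance(selector[0], str)
    )
    if ligand_mode:
        lig = np.asarray(selector, dtype=float).reshape(-1, 3)
        if radius <= 0:
            raise ValueError("radius must be > 0 in ligand mode")
        wanted_residues = None
    else:
        wanted_residues = set(selector)

    atoms: list[PocketAtom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.name.strip()
                if resname in _WATER_NAMES:
                    continue
                res_key = f"{chain.name}:{residue.seqid.num}"
                if wanted_residues is not None and res_key not in wanted_residues:
                    continue
                for atom in residue:
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if ligand_mode:
                        d = np.linalg.norm(lig - pos, axis=1)
                        if d.min() < 1e-3:  # the reference ligand itself
                            continue
                        if d.min() > radius:
                            continue
                    atoms.append(
                        PocketAtom(
                            element=atom.element.name,
                            position=pos,
                            residue=f"{res_key}:{resname}",
                            atom_name=atom.name.strip(),
                        )
                    )
        break  # first model only
    if not atoms:
        raise EmptyPocketError("empty pocket: selector matched no protein atoms")
    return Pocket(atoms=atoms)


def _mol_to_conformer(mol: Chem.Mol) -> Conformer:
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        order = 12 if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Conformer(coords, elements, charges, bonds, mol=mol)


def read_ligand_library(sdf_text: str) -> list[LigandRecord]:
    """Parse a multi-record V2000/V3000 SDF into ligand records.

    Consecutive SDF records sharing a molecule title are grouped into one
    record's conformer list.
    """
    if not sdf_text.strip():
        logger.warning("read_ligand_library: empty SDF input")
        return []
    supplier = Chem.ForwardSDMolSupplier(
        _io.BytesIO(sdf_text.encode()), sanitize=True, removeHs=False
    )
    groups: dict[str, list[Conformer]] = {}
    order: list[str] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"SDF record {idx}: unreadable or truncated molecule block")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not name:
            name = f"mol_{idx}"
        if name not in groups:
            groups[name] = []
            order.append(name)
        groups[name].append(_mol_to_conformer(mol))
    return [LigandRecord(mol_id=name, conformers=groups[name]) for name in order]


def write_ligand_library(records: Sequence[LigandRecord]) -> str:
    """Serialize ligand records (all conformers) as a multi-record SDF string."""
    from .featurize import conformer_to_mol

    buf = _io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for rec in records:
        for conf in rec.conformers:
            mol = conf.mol if conf.mol is not None else conformer_to_mol(conf)
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", rec.mol_id)
            writer.write(mol)
    writer.close()
    return buf.getvalue()


def write_pocket_pdb(pocket: Pocket) -> str:
    """Serialize a pocket as minimal PDB ATOM records (round-trips read_pocket)."""
    # gemmi containers copy on add, so build residues/chains fully first
    by_residue: dict[str, list] = {}
    res_order: list[str] = []
    for atom in pocket.atoms:
        if atom.residue not in by_residue:
            by_residue[atom.residue] = []
            res_order.append(atom.residue)
        by_residue[atom.residue].append(atom)

    chains: dict[str, gemmi.Chain] = {}
    chain_order: list[str] = []
    for res_key in res_order:
        chain_name, seq, resname = res_key.split(":")
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(int(seq), " ")
        for atom in by_residue[res_key]:
            a = gemmi.Atom()
            a.name = atom.atom_name or atom.element
            a.element = gemmi.Element(atom.element)
            a.pos = gemmi.Position(*atom.position)
            a.occ = 1.0
            res.add_atom(a)
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
            chain_order.append(chain_name)
        chains[chain_name].add_residue(res)

    model = gemmi.Model("1")
    for name in chain_order:
        model.add_chain(chains[name])
    st = gemmi.Structure()
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_query(ph: Pharmacophore) -> str:
    """Serialize a pharmacophore as Pharmit-dialect query JSON."""
    points = [
        {
            "name": c.ftype.label,
            "x": float(c.position[0]),
            "y": float(c.position[1]),
            "z": float(c.position[2]),
            "radius": float(c.radius),
            "enabled": True,
        }
        for c in ph.centers
    ]
    return json.dumps({"points": points}, indent=2)


def parse_query(json_text: str) -> Pharmacophore:
    """Parse Pharmit-dialect query JSON; disabled points are skipped."""
    obj = json.loads(json_text)
    if "points" not in obj:
        raise ValueError("query JSON must contain a 'points' array")
    centers = []
    for pt in obj["points"]:
        if not pt.get("enabled", True):
            continue
        ftype = FeatureType.from_label(pt["name"])
        centers.append(
            PharmacophoreCenter(
                position=np.array([pt["x"], pt["y"], pt["z"]], dtype=float),
                ftype=ftype,
                radius=float(pt.get("radius", 1.0)),
            )
        )
    return Pharmacophore(centers=centers)


def read_labels_csv(text: str) -> dict[str, bool]:
    """Parse an actives/decoys label list: ``molecule_id,label`` per line.

    Labels may be 0/1 or true/false; a header line is tolerated.
    """
    labels: dict[str, bool] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith("molecule_id"):
            continue
        mol_id, raw = (tok.strip() for tok in line.split(",", 1))
        labels[mol_id] = raw.lower() in {"1", "true", "active"}
    return labels


def write_labels_csv(labels: dict[str, bool]) -> str:
    lines = ["molecule_id,label"]
    lines += [f"{mid},{int(lab)}" for mid, lab in labels.items()]
    return "\n".join(lines) + "\n"
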