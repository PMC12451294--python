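"""Pharmacophore matching, screening metrics and conformer strain energy.

A molecule matches a query when some injective, type-consistent assignment
of its conformer features to *all* query centers admits a rigid
least-squares superposition with RMSD at or below the tolerance (1 Angstrom
by default).  The matcher enumerates assignments with dynamic
pairwise-distance pruning (sound against the best RMSD found so far) and
scores each with a closed-form Kabsch superposition; the search returns the
exact minimum-RMSD assignment at query scale (<= 8 centers).

Enrichment factor is the active fraction among hits divided by the active
fraction in the database; EF is undefined (and the query excluded from
aggregation) when a query returns no hits.  F1 uses the harmonic
precision/recall formula, with precision defined as 0 for zero-hit queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .featurize import Feature, detect_ligand_features, _ensure_mol
from .types import Conformer, FeatureType, LigandRecord, Pharmacophore, Pocket

logger = logging.getLogger(__name__)

DEFAULT_RMSD_TOL = 1.0


# ---------------------------------------------------------------------------
# Rigid superposition

def kabsch_rmsd(query: np.ndarray, candidate: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of candidate onto query.

    Returns (rmsd, rotation R, translation tvec) with the candidate mapped by
    x -> x @ R.T + tvec.  Proper rotations only (reflections are excluded via
    the determinant correction).
    """
    n = query.shape[0]
    qc, cc = query.mean(axis=0), candidate.mean(axis=0)
    q, c = query - qc, candidate - cc
    if n == 1:
        return 0.0, np.eye(3), qc - cc
    H = c.T @ q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = q - c @ R.T
    rmsd = float(np.sqrt((diff**2).sum() / n))
    tvec = qc - cc @ R.T
    return rmsd, R, tvec


# ---------------------------------------------------------------------------
# Matching

@dataclass
class MatchResult:
    matched: bool
    rmsd: float  # +inf when no type-consistent assignment exists
    assignment: Optional[tuple[int, ...]]  # feature index per query center
    rotation: Optional[np.ndarray] = None
    translation: Optional[np.ndarray] = None


def match(
    ph: Pharmacophore,
    features: Sequence[Feature],
    rmsd_tol: float = DEFAULT_RMSD_TOL,
) -> MatchResult:
    """Best type-consistent rigid alignment of conformer features to the query."""
    n = len(ph)
    q_pos = ph.positions
    q_types = ph.types
    cand: list[list[int]] = [
        [i for i, (ft, _) in enumerate(features) if ft == qt] for qt in q_types
    ]
    if any(not c for c in cand):
        return MatchResult(False, float("inf"), None)
    f_pos = np.array([pos for _, pos in features], dtype=float).reshape(len(features), 3)
    q_d = np.linalg.norm(q_pos[:, None] - q_pos[None, :], axis=-1)
    f_d = np.linalg.norm(f_pos[:, None] - f_pos[None, :], axis=-1)

    best = MatchResult(False, float("inf"), None)
    assign: list[int] = []
    sqrt_n = np.sqrt(n)

    def backtrack(i: int):
        nonlocal best
        if i == n:
            rmsd, R, tvec = kabsch_rmsd(q_pos, f_pos[list(assign)])
            if rmsd < best.rmsd:
                best = MatchResult(rmsd <= rmsd_tol, rmsd, tuple(assign), R, tvec)
            return
        # a pairwise-distance deviation D certifies rmsd >= D / (2 sqrt(n)),
        # so pruning against the current best keeps the search exact
        bound = 2.0 * sqrt_n * best.rmsd
        for j in cand[i]:
            if j in assign:
                continue
            if any(abs(q_d[i, k] - f_d[j, assign[k]]) > bound for k in range(i)):
                continue
            assign.append(j)
            backtrack(i + 1)
            assign.pop()

    backtrack(0)
    return best


# ---------------------------------------------------------------------------
# Screening

@dataclass
class Hit:
    mol_id: str
    conformer_index: int
    rmsd: float
    match: MatchResult = field(repr=False, default=None)


@dataclass
class ScreenResult:
    """Per-query hit list: at most one (best) conformer per molecule."""

    query_id: str
    hits: list[Hit]
    labels: dict[str, bool] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def hit_ids(self) -> set[str]:
        return {h.mol_id for h in self.hits}


def screen(
    ph: Pharmacophore,
    library: Sequence[LigandRecord],
    rmsd_tol: float = DEFAULT_RMSD_TOL,
    query_id: str = "query",
    labels: Optional[dict[str, bool]] = None,
) -> ScreenResult:
    """Screen a conformer library; a molecule hits when any conformer matches."""
    hits: list[Hit] = []
    for rec in library:
        best: Optional[Hit] = None
        for ci, conf in enumerate(rec.conformers):
            feats = detect_ligand_features(conf, rec.mol_id)
            res = match(ph, feats, rmsd_tol)
            if res.matched and (best is None or res.rmsd < best.rmsd):
                best = Hit(rec.mol_id, ci, res.rmsd, res)
        if best is not None:
            hits.append(best)
    joined: dict[str, bool] = {}
    for rec in library:
        lab = labels.get(rec.mol_id) if labels else rec.active_label
        if lab is not None:
            joined[rec.mol_id] = bool(lab)
    return ScreenResult(query_id=query_id, hits=hits, labels=joined)


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class MetricReport:
    ef: Optional[float]  # None when undefined (zero hits)
    precision: float
    recall: float
    f1: float


def enrichment_factor(
    result: ScreenResult, n_actives_db: int, n_total_db: int
) -> Optional[float]:
    """EF = (active fraction among hits) / (active fraction in database).

    Returns None (undefined) for zero-hit queries; such queries are excluded
    from aggregation by callers.
    """
    if n_total_db <= 0:
        raise ValueError("database size must be > 0")
    if n_actives_db <= 0:
        raise ValueError("database must contain at least one active")
    if result.n_hits == 0:
        return None
    n_active_hits = sum(result.labels.get(mid, False) for mid in result.hit_ids)
    return (n_active_hits / result.n_hits) / (n_actives_db / n_total_db)


def precision_recall_f1(result: ScreenResult, actives: set[str]) -> MetricReport:
    """Precision/recall/F1 of a hit list against the database's active set."""
    hit_ids = result.hit_ids
    tp = len(hit_ids & actives)
    fp = len(hit_ids - actives)
    fn = len(actives - hit_ids)
    precision = tp / (tp + fp) if hit_ids else 0.0
    recall = tp / (tp + fn) if actives else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricReport(ef=None, precision=precision, recall=recall, f1=f1)


def filter_queries(
    results: Sequence[ScreenResult], max_hits: int
) -> list[ScreenResult]:
    """Keep queries whose hit count is at most ``max_hits``.

    The conventional cutoff is 1% of the screened database size, dropping
    pharmacophores that lack specificity.
    """
    if max_hits < 0:
        raise ValueError("max_hits must be >= 0")
    return [r for r in results if r.n_hits <= max_hits]


# ---------------------------------------------------------------------------
# Strain energy

class UFFEvaluator:
    """Universal Force Field energy/minimization contract (RDKit-backed)."""

    def __init__(self, max_iters: int = 2000, energy_tol: float = 1e-8):
        self.max_iters = max_iters
        self.energy_tol = energy_tol

    def _ff(self, mol: Chem.Mol):
        if not AllChem.UFFHasAllMoleculeParams(mol):
            raise ValueError("molecule cannot be parameterized by UFF")
        return AllChem.UFFGetMoleculeForceField(mol)

    def single_point(self, mol: Chem.Mol) -> float:
        """UFF energy of the molecule's current geometry, kcal/mol."""
        return float(self._ff(mol).CalcEnergy())

    def minimize(self, mol: Chem.Mol) -> tuple[Chem.Mol, float]:
        """Locally minimize a copy; returns (minimized mol, its energy)."""
        m = Chem.Mol(mol)
        ff = self._ff(m)
        ff.Minimize(maxIts=self.max_iters, energyTol=self.energy_tol)
        return m, float(ff.CalcEnergy())


def strain_energy(
    conformer: Conformer,
    energy_evaluator: Optional[UFFEvaluator] = None,
    mol_id: str = "?",
) -> float:
    """Energy difference (kcal/mol) between the input and locally minimized geometry."""
    ev = energy_evaluator if energy_evaluator is not None else UFFEvaluator()
    try:
        mol = _ensure_mol(conformer, mol_id)
        e0 = ev.single_point(mol)
        _, e1 = ev.minimize(mol)
    except ValueError as exc:
        raise ValueError(f"strain_energy: molecule {mol_id!r}: {exc}") from exc
    return e0 - e1


# ---------------------------------------------------------------------------
# Optional receptor-exclusion post-filter

def receptor_exclusion_filter(
    result: ScreenResult,
    library: Sequence[LigandRecord],
    pocket: Pocket,
    clash_distance: float = 1.5,
) -> ScreenResult:
    """Drop hits whose aligned feature positions clash with pocket heavy atoms."""
    by_id = {rec.mol_id: rec for rec in library}
    heavy = np.array(
        [a.position for a in pocket.atoms if a.element != "H"], dtype=float
    )
    kept = []
    for hit in result.hits:
        m = hit.match
        if m is None or m.rotation is None:
            kept.append(hit)
            continue
        conf = by_id[hit.mol_id].conformers[hit.conformer_index]
        feats = detect_ligand_features(conf, hit.mol_id)
        pos = np.array([p for _, p in feats])[list(m.assignment)]
        aligned = pos @ m.rotation.T + m.translation
        dmin = np.linalg.norm(aligned[:, None, :] - heavy[None, :, :], axis=-1).min()
        if dmin >= clash_distance:
            kept.append(hit)
    return ScreenResult(query_id=result.query_id, hits=kept, labels=result.labels)
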