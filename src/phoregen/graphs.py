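"""Heterogeneous pocket-pharmacophore graphs.

Pharmacophore nodes are fully connected among themselves; each center is
also connected to its k nearest pocket atoms, and retained pocket atoms are
connected to each other within a distance cutoff.  Edges are stored
directed-symmetric (both directions) for message passing.

Translation is handled by the frame, not the network: `center_frame` moves
the protein centroid to the origin and records the offset so the original
coordinates can be restored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .types import N_ATOM_TYPES, N_FEATURE_TYPES, Pharmacophore, Pocket

logger = logging.getLogger(__name__)

DEFAULT_K = 8
DEFAULT_PROTEIN_CUTOFF = 4.5


@dataclass
class HeteroGraph:
    """Pocket + pharmacophore graph with one-hot node encodings.

    Edge arrays are (E, 2) integer arrays of (source, target) indices; pharm
    and protein nodes live in separate index spaces.  For pharm-protein
    edges the convention is (protein index, pharm index).
    """

    pharm_pos: np.ndarray  # (N, 3)
    pharm_feat: np.ndarray  # (N, 6)
    prot_pos: np.ndarray  # (M, 3)
    prot_feat: np.ndarray  # (M, na) one-hot
    edges_pp: np.ndarray  # pharm-pharm, (E, 2)
    edges_lp: np.ndarray  # protein->pharm, (E, 2) = (prot, pharm)
    edges_ll: np.ndarray  # protein-protein, (E, 2)
    frame_offset: np.ndarray  # (3,) translation applied so far

    @property
    def n_pharm(self) -> int:
        return self.pharm_pos.shape[0]

    @property
    def n_prot(self) -> int:
        return self.prot_pos.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "pharm_pos": self.pharm_pos.tolist(),
            "pharm_feat": self.pharm_feat.tolist(),
            "prot_pos": self.prot_pos.tolist(),
            "prot_feat": self.prot_feat.tolist(),
            "edges_pp": self.edges_pp.tolist(),
            "edges_lp": self.edges_lp.tolist(),
            "edges_ll": self.edges_ll.tolist(),
            "frame_offset": self.frame_offset.tolist(),
        }


def _knn_indices(centers: np.ndarray, points: np.ndarray, k: int) -> np.ndarray:
    """(n_centers, k) indices of each center's k nearest points."""
    d = np.linalg.norm(centers[:, None, :] - points[None, :, :], axis=-1)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def build_graph_arrays(
    prot_pos: np.ndarray,
    prot_feat: np.ndarray,
    pharm_pos: np.ndarray,
    pharm_feat: np.ndarray,
    k: int = DEFAULT_K,
    protein_cutoff: float = DEFAULT_PROTEIN_CUTOFF,
    frame_offset: np.ndarray | None = None,
) -> HeteroGraph:
    """Core topology builder on raw arrays (used for clean and noised states)."""
    n = pharm_pos.shape[0]
    m_all = prot_pos.shape[0]
    if n < 1 or m_all < 1:
        raise ValueError("need at least one pharm node and one pocket atom")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m_all:
        logger.warning("k=%d exceeds pocket size %d; clamping", k, m_all)
        k = m_all

    nn = _knn_indices(pharm_pos, prot_pos, k)  # (n, k) in full-pocket indexing
    retained = np.unique(nn.ravel())
    remap = -np.ones(m_all, dtype=int)
    remap[retained] = np.arange(retained.size)

    # pharm-pharm: complete, both directions
    if n > 1:
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = ii != jj
        edges_pp = np.stack([ii[mask], jj[mask]], axis=1)
    else:
        edges_pp = np.zeros((0, 2), dtype=int)

    # protein -> pharm (each center's k nearest retained atoms)
    src = remap[nn.ravel()]
    dst = np.repeat(np.arange(n), k)
    edges_lp = np.stack([src, dst], axis=1)

    # protein-protein within cutoff among retained
    rpos = prot_pos[retained]
    if retained.size > 1:
        d = np.linalg.norm(rpos[:, None, :] - rpos[None, :, :], axis=-1)
        ai, aj = np.nonzero((d <= protein_cutoff) & ~np.eye(retained.size, dtype=bool))
        edges_ll = np.stack([ai, aj], axis=1)
    else:
        edges_ll = np.zeros((0, 2), dtype=int)

    return HeteroGraph(
        pharm_pos=np.array(pharm_pos, dtype=float),
        pharm_feat=np.array(pharm_feat, dtype=float),
        prot_pos=np.array(rpos, dtype=float),
        prot_feat=np.array(prot_feat[retained], dtype=float),
        edges_pp=edges_pp,
        edges_lp=edges_lp,
        edges_ll=edges_ll,
        frame_offset=np.zeros(3) if frame_offset is None else np.array(frame_offset, dtype=float),
    )


def build_graph(
    pocket: Pocket,
    ph: Pharmacophore,
    k: int = DEFAULT_K,
    protein_cutoff: float = DEFAULT_PROTEIN_CUTOFF,
) -> HeteroGraph:
    """Build the heterogeneous graph for a pocket and a pharmacophore."""
    return build_graph_arrays(
        pocket.positions,
        pocket.atom_one_hot(),
        ph.positions,
        ph.one_hot(),
        k=k,
        protein_cutoff=protein_cutoff,
    )


def center_frame(g: HeteroGraph) -> HeteroGraph:
    """Translate all coordinates so the protein centroid sits at the origin."""
    shift = -g.prot_pos.mean(axis=0)
    return replace(
        g,
        pharm_pos=g.pharm_pos + shift,
        prot_pos=g.prot_pos + shift,
        frame_offset=g.frame_offset + shift,
    )


def uncenter(g: HeteroGraph) -> HeteroGraph:
    """Undo all accumulated translation, restoring original coordinates."""
    return replace(
        g,
        pharm_pos=g.pharm_pos - g.frame_offset,
        prot_pos=g.prot_pos - g.frame_offset,
        frame_offset=np.zeros(3),
    )
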