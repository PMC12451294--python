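"""The E(3)-equivariant denoiser.

Geometric message passing over the heterogeneous graph: node scalar
channels are updated from neighbor scalars and radial-basis-encoded
distances; the predicted coordinate noise is an equivariant vector head — a
learned scalar-weighted sum of edge difference vectors — so coordinate
outputs rotate with the inputs while feature outputs are invariant.
Distances, the edge difference vectors and the time embedding are constants
of each forward pass; gradients flow only through the learned parameters.

Everything runs in float64 numpy via the package's autodiff engine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, parameter
from .graphs import HeteroGraph
from .types import N_ATOM_TYPES, N_FEATURE_TYPES

TIME_FREQS = 4  # sinusoidal time-embedding frequency pairs
TIME_DIM = 1 + 2 * TIME_FREQS


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters."""

    n_layers: int = 4
    hidden: int = 64  # scalar channel width
    n_vec: int = 16  # vector channels in the coordinate head
    n_rbf: int = 16  # radial basis functions for distances
    rbf_cutoff: float = 10.0  # Angstrom
    activation: str = "lrelu"  # "lrelu" (fast on CPU) or "silu"
    na: int = N_ATOM_TYPES
    nf: int = N_FEATURE_TYPES


@dataclass
class DenoiserParams:
    """Learned parameters plus the architecture they belong to."""

    config: DenoiserConfig
    params: dict[str, np.ndarray]
    trained: bool = False

    def save(self, path) -> None:
        meta = json.dumps({"version": 1, "config": asdict(self.config), "trained": self.trained})
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "DenoiserParams":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            params = {k: data[k].copy() for k in data.files if k != "__config__"}
        return cls(
            config=DenoiserConfig(**meta["config"]),
            params=params,
            trained=bool(meta["trained"]),
        )


def init_params(cfg: DenoiserConfig, rng: np.random.Generator) -> DenoiserParams:
    """Initialize parameters.

    Edge blocks that conceptually act on [h_src, h_dst, rbf] are stored as
    three split weight matrices so the forward pass can project node
    features before gathering them onto edges (far fewer flops).
    """
    h, nv, nr = cfg.hidden, cfg.n_vec, cfg.n_rbf

    def lin(name, fan_in, fan_out, scale=1.0):
        p[f"{name}_W"] = rng.standard_normal((fan_in, fan_out)) * scale / np.sqrt(fan_in)
        p[f"{name}_b"] = np.zeros(fan_out)

    def mat(name, fan_in, fan_out, scale=1.0):
        p[f"{name}_W"] = rng.standard_normal((fan_in, fan_out)) * scale / np.sqrt(fan_in)

    p: dict[str, np.ndarray] = {}
    lin("embed_pharm", cfg.nf + TIME_DIM, h)
    lin("embed_prot", cfg.na, h)
    for l in range(cfg.n_layers):
        mat(f"edge{l}_src", h, h)
        mat(f"edge{l}_dst", h, h)
        lin(f"edge{l}_rbf", nr, h)
        lin(f"edge{l}_2", h, h)
        mat(f"node{l}_self", h, h)
        mat(f"node{l}_agg", h, h)
        p[f"node{l}_b"] = np.zeros(h)
        lin(f"node{l}_2", h, h, scale=0.5)
    mat("coord_src", h, h)
    mat("coord_dst", h, h)
    lin("coord_rbf", nr, h)
    lin("coord_2", h, nv, scale=0.1)
    p["coord_theta"] = rng.standard_normal(nv) * 0.1
    lin("feat_1", h, h)
    lin("feat_2", h, cfg.nf, scale=0.1)
    return DenoiserParams(config=cfg, params=p)


def time_embedding(t_frac: np.ndarray) -> np.ndarray:
    """(n,) fractional times t/T -> (n, TIME_DIM) embedding."""
    t_frac = np.asarray(t_frac, dtype=float)
    cols = [t_frac]
    for j in range(TIME_FREQS):
        w = (2.0**j) * np.pi
        cols.append(np.sin(w * t_frac))
        cols.append(np.cos(w * t_frac))
    return np.stack(cols, axis=1)


def _rbf(d: np.ndarray, cfg: DenoiserConfig) -> np.ndarray:
    centers = np.linspace(0.0, cfg.rbf_cutoff, cfg.n_rbf)
    width = cfg.rbf_cutoff / max(cfg.n_rbf - 1, 1)
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))


@dataclass
class Batch:
    """A (possibly multi-graph) collated forward-pass input.

    Nodes are stacked pharm-first: indices [0, n_pharm) are pharmacophore
    nodes, [n_pharm, n_pharm + n_prot) are protein nodes.
    """

    n_pharm: int
    n_prot: int
    pharm_feat: np.ndarray  # (N, nf) noised scaled features
    prot_feat: np.ndarray  # (M, na)
    t_frac: np.ndarray  # (N,) per pharm node
    edge_src: np.ndarray  # (E,)
    edge_dst: np.ndarray  # (E,)
    edge_rbf: np.ndarray  # (E, n_rbf)
    edge_vec: np.ndarray  # (E, 3) (x_dst - x_src) / (d + 1)


def make_batch(
    graphs: list[HeteroGraph],
    t_fracs: list[float],
    cfg: DenoiserConfig,
) -> Batch:
    """Collate graphs into one disjoint batch; geometry becomes edge constants."""
    n_total = sum(g.n_pharm for g in graphs)
    srcs, dsts, vecs, dists = [], [], [], []
    pharm_feat, prot_feat, tfr = [], [], []
    p_off, m_off = 0, 0
    for g, tf in zip(graphs, t_fracs):
        N, M = g.n_pharm, g.n_prot
        coords = np.vstack([g.pharm_pos, g.prot_pos])

        def _local(idx_pairs, src_is_prot, dst_is_prot):
            if idx_pairs.size == 0:
                return
            src = idx_pairs[:, 0] + (n_total + m_off if src_is_prot else p_off)
            dst = idx_pairs[:, 1] + (n_total + m_off if dst_is_prot else p_off)
            a = idx_pairs[:, 0] + (N if src_is_prot else 0)
            b = idx_pairs[:, 1] + (N if dst_is_prot else 0)
            v = coords[b] - coords[a]
            d = np.linalg.norm(v, axis=1)
            srcs.append(src)
            dsts.append(dst)
            vecs.append(v / (d[:, None] + 1.0))
            dists.append(d)

        _local(g.edges_pp, False, False)
        _local(g.edges_lp, True, False)  # protein -> pharm
        _local(g.edges_lp[:, ::-1], False, True)  # pharm -> protein
        _local(g.edges_ll, True, True)
        pharm_feat.append(g.pharm_feat)
        prot_feat.append(g.prot_feat)
        tfr.append(np.full(N, tf))
        p_off += N
        m_off += M
    d_all = np.concatenate(dists) if dists else np.zeros(0)
    return Batch(
        n_pharm=n_total,
        n_prot=m_off,
        pharm_feat=np.vstack(pharm_feat),
        prot_feat=np.vstack(prot_feat),
        t_frac=np.concatenate(tfr),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=int),
        edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=int),
        edge_rbf=_rbf(d_all, cfg),
        edge_vec=np.vstack(vecs) if vecs else np.zeros((0, 3)),
    )


def forward(
    weights: dict[str, Tensor], cfg: DenoiserConfig, batch: Batch
) -> tuple[Tensor, Tensor]:
    """Run the denoiser; returns (eps_hat_coords (N,3), eps_hat_feats (N,nf))."""
    N, M = batch.n_pharm, batch.n_prot
    V = N + M

    def lin(name, x):
        return x @ weights[f"{name}_W"] + weights[f"{name}_b"]

    def act(x):
        return x.lrelu() if cfg.activation == "lrelu" else x.silu()

    pharm_in = np.hstack([batch.pharm_feat, time_embedding(batch.t_frac)])
    h_pharm = act(lin("embed_pharm", Tensor(pharm_in)))
    h_prot = act(lin("embed_prot", Tensor(batch.prot_feat)))
    h = concat([h_pharm, h_prot], axis=0)

    src, dst, rbf = batch.edge_src, batch.edge_dst, batch.edge_rbf
    for l in range(cfg.n_layers):
        # project on nodes, gather onto edges
        hs = (h @ weights[f"edge{l}_src_W"]).take(src)
        hd = (h @ weights[f"edge{l}_dst_W"]).take(dst)
        m1 = act(hs + hd + lin(f"edge{l}_rbf", Tensor(rbf)))
        m = act(lin(f"edge{l}_2", m1))
        agg = m.segment_sum(dst, V)
        upd = act(
            h @ weights[f"node{l}_self_W"]
            + agg @ weights[f"node{l}_agg_W"]
            + weights[f"node{l}_b"]
        )
        h = h + lin(f"node{l}_2", upd)

    # equivariant coordinate head on edges that point into pharm nodes
    mask = dst < N
    e_src, e_dst = src[mask], dst[mask]
    c1 = act(
        (h @ weights["coord_src_W"]).take(e_src)
        + (h @ weights["coord_dst_W"]).take(e_dst)
        + lin("coord_rbf", Tensor(rbf[mask]))
    )
    w = lin("coord_2", c1)  # (E, nv)
    contrib = w.reshape(-1, cfg.n_vec, 1) * Tensor(batch.edge_vec[mask][:, None, :])
    v = contrib.segment_sum(e_dst, N)  # (N, nv, 3)
    eps_x = (v * weights["coord_theta"].reshape(1, cfg.n_vec, 1)).sum(axis=1)

    h_ph = h.take(np.arange(N))
    eps_f = lin("feat_2", act(lin("feat_1", h_ph)))
    return eps_x, eps_f


def _wrap(params: DenoiserParams, trainable: bool) -> dict[str, Tensor]:
    make = parameter if trainable else Tensor
    return {k: make(v) for k, v in params.params.items()}


def denoise_step(
    params: DenoiserParams, g: HeteroGraph, t: int, T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the noise on a (centered) graph's pharm nodes at step t.

    Deterministic given (params, g, t); raises on non-finite output and on an
    uncentered graph.
    """
    centroid = g.prot_pos.mean(axis=0)
    if np.linalg.norm(centroid) > 1e-6:
        raise ValueError("denoise_step requires a centered graph (protein centroid at origin)")
    batch = make_batch([g], [t / T], params.config)
    eps_x, eps_f = forward(_wrap(params, trainable=False), params.config, batch)
    out_x, out_f = eps_x.data, eps_f.data
    if not (np.all(np.isfinite(out_x)) and np.all(np.isfinite(out_f))):
        raise FloatingPointError(f"non-finite denoiser output at step t={t}")
    return out_x, out_f
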