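"""Denoiser training: Adam on the noise-prediction MSE.

Each optimization step draws a per-sample time step uniformly, noises the
pharmacophore nodes (coordinates and scaled one-hot features alike), builds
the graph from the *noised* center positions — matching what the sampler
sees at generation time — and regresses the drawn noise.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, parameter
from .denoiser import Batch, DenoiserConfig, DenoiserParams, forward, init_params, make_batch
from .graphs import DEFAULT_K, DEFAULT_PROTEIN_CUTOFF, build_graph_arrays, center_frame
from .schedule import FEATURE_SCALE, NoiseSchedule, make_schedule
from .types import Pharmacophore, Pocket

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the full-scale recipe)."""

    epochs: int = 80
    batch_size: int = 24
    lr: float = 1e-4
    T: int = 1000
    schedule_power: float = 2.0
    grad_clip: float = 1.0
    k: int = DEFAULT_K
    protein_cutoff: float = DEFAULT_PROTEIN_CUTOFF
    arch: DenoiserConfig = field(default_factory=DenoiserConfig)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    loss_csv: Optional[str] = None
    checkpoint: Optional[str] = None


@dataclass
class _Sample:
    prot_pos: np.ndarray
    prot_feat: np.ndarray
    x0: np.ndarray  # (N, 3) clean center coordinates
    f0: np.ndarray  # (N, nf) scaled one-hot features


def _prepare(dataset: Sequence[tuple[Pocket, Pharmacophore]]) -> list[_Sample]:
    # the diffusion acts on pocket-centroid-relative coordinates so the
    # variance-preserving endpoint N(0, I) sits at the pocket center
    out = []
    for pocket, ph in dataset:
        c = pocket.centroid
        out.append(
            _Sample(
                prot_pos=pocket.positions - c,
                prot_feat=pocket.atom_one_hot(),
                x0=ph.positions - c,
                f0=ph.one_hot() * FEATURE_SCALE,
            )
        )
    return out


def _noised_graph(
    s: _Sample, sched: NoiseSchedule, t: int, rng: np.random.Generator, cfg: TrainConfig
):
    a, sg = sched.alpha[t], sched.sigma[t]
    eps_x = rng.standard_normal(s.x0.shape)
    eps_f = rng.standard_normal(s.f0.shape)
    zx = a * s.x0 + sg * eps_x
    zf = a * s.f0 + sg * eps_f
    g = build_graph_arrays(
        s.prot_pos, s.prot_feat, zx, zf, k=cfg.k, protein_cutoff=cfg.protein_cutoff
    )
    return center_frame(g), eps_x, eps_f


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.step_count = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.cfg
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, c.grad_clip / (norm + 1e-12))
        self.step_count += 1
        b1t = 1 - c.adam_beta1**self.step_count
        b2t = 1 - c.adam_beta2**self.step_count
        for k, g in grads.items():
            g = g * scale
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g**2
            params[k] -= c.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.adam_eps)


def train_step(
    params: DenoiserParams,
    batch: Batch,
    eps_x: np.ndarray,
    eps_f: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """One forward/backward pass; returns (loss, gradients)."""
    weights = {k: parameter(v) for k, v in params.params.items()}
    out_x, out_f = forward(weights, params.config, batch)
    dx = out_x - Tensor(eps_x)
    df = out_f - Tensor(eps_f)
    denom = float(eps_x.size + eps_f.size)
    loss = ((dx * dx).sum() + (df * df).sum()) / denom
    loss.backward()
    grads = {k: w.grad for k, w in weights.items() if w.grad is not None}
    return float(loss.data), grads


def train(
    dataset: Sequence[tuple[Pocket, Pharmacophore]],
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[DenoiserParams, list[float]]:
    """Train a denoiser; returns the parameters and per-epoch mean losses."""
    if not dataset:
        raise ValueError("empty training dataset")
    for _, ph in dataset:
        if not 3 <= len(ph) <= 8:
            raise ValueError("training pharmacophores must carry 3-8 centers")

    init_rng, noise_rng, shuffle_rng = rng.spawn(3)
    samples = _prepare(dataset)
    sched = make_schedule(config.T, config.schedule_power)
    params = init_params(config.arch, init_rng)
    opt = _Adam(params.params, config)

    history: list[float] = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(samples))
        losses = []
        for lo in range(0, len(samples), config.batch_size):
            chunk = [samples[i] for i in order[lo : lo + config.batch_size]]
            ts = noise_rng.integers(1, config.T + 1, size=len(chunk))
            graphs, ex, ef = [], [], []
            for s, t in zip(chunk, ts):
                g, eps_x, eps_f = _noised_graph(s, sched, int(t), noise_rng, config)
                graphs.append(g)
                ex.append(eps_x)
                ef.append(eps_f)
            batch = make_batch(graphs, [t / config.T for t in ts], config.arch)
            loss, grads = train_step(params, batch, np.vstack(ex), np.vstack(ef))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(params.params, grads)
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        logger.info("epoch %d: mean loss %.5f", epoch, mean_loss)

    params.trained = True
    if config.loss_csv:
        with open(config.loss_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "mean_loss"])
            w.writerows(enumerate(history))
    if config.checkpoint:
        params.save(config.checkpoint)
    return params, history
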