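"""Ancestral sampling: generate a pharmacophore for a pocket.

A user-specified number of centers is initialized with random feature
vectors and random coordinates near the pocket center, then denoised over T
steps with the variance-preserving ancestral update.  Diffusion acts on
pocket-centroid-relative coordinates; results are returned in the original
pocket frame.

Coordinate noise is drawn in a pocket-canonical frame (principal axes of
the pocket atoms with deterministic sign fixing), so running the sampler on
a rotated pocket with the same seed produces the rotated pharmacophore
path for path — equivariance holds per sample, not merely in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .denoiser import DenoiserParams, denoise_step
from .graphs import DEFAULT_K, DEFAULT_PROTEIN_CUTOFF, build_graph_arrays, center_frame
from .schedule import FEATURE_SCALE, make_schedule
from .types import FeatureType, N_FEATURE_TYPES, Pharmacophore, PharmacophoreCenter, Pocket


@dataclass
class GenerationConfig:
    """Sampler settings."""

    n_centers: int = 4
    T: int = 1000  # diffusion time steps
    schedule_power: float = 2.0
    init_spread: float = 2.0  # Angstrom, std of initial coordinates about pocket center
    seed: int = 0
    k: int = DEFAULT_K
    protein_cutoff: float = DEFAULT_PROTEIN_CUTOFF
    rewire: bool = True  # rebuild graph topology from current positions each step
    allow_untrained: bool = False
    center_radius: float = 1.0
    # clean-state clamping: the implied x0 estimate is clipped to a ball of
    # this radius (Angstrom) about the pocket center; None -> auto from the
    # pocket extent.  Keeps the high-t posterior update (which amplifies
    # noise-prediction error by 1/alpha) from diverging.
    x0_clip: float | None = None
    feat_clip: float = 2.0  # same clamp for the scaled feature channels

    def __post_init__(self):
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def canonical_rotation(points: np.ndarray) -> np.ndarray:
    """Deterministic pocket-canonical axes (columns), covariant under rotation.

    Principal axes of the centered point cloud, ordered by decreasing
    variance; signs fixed by the third moment along each axis (falling back
    to the first moment of squared projections for near-symmetric clouds);
    the last axis is flipped if needed to make the basis right-handed.
    """
    c = points - points.mean(axis=0)
    w, V = np.linalg.eigh(c.T @ c)
    V = V[:, ::-1].copy()
    for i in range(3):
        proj = c @ V[:, i]
        s = np.sum(proj**3)
        if abs(s) < 1e-8 * (np.abs(proj).max() + 1e-12) ** 3:
            s = np.sum(proj * np.abs(proj))
        if s < 0:
            V[:, i] = -V[:, i]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return V


def generate(
    pocket: Pocket,
    params: DenoiserParams,
    cfg: GenerationConfig,
    rng: np.random.Generator | None = None,
) -> Pharmacophore:
    """Generate one pharmacophore with exactly ``cfg.n_centers`` centers."""
    if not params.trained and not cfg.allow_untrained:
        raise ValueError(
            "denoiser parameters are untrained; set allow_untrained=True to sample anyway"
        )
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sched = make_schedule(cfg.T, cfg.schedule_power)

    centroid = pocket.centroid
    prot_pos = pocket.positions - centroid
    prot_feat = pocket.atom_one_hot()
    frame = canonical_rotation(pocket.positions)

    def draw_coords(n: int) -> np.ndarray:
        return rng.standard_normal((n, 3)) @ frame.T

    x0_clip = cfg.x0_clip
    if x0_clip is None:
        x0_clip = float(np.linalg.norm(prot_pos, axis=1).max()) + 2.0

    n = cfg.n_centers
    zx = cfg.init_spread * draw_coords(n)
    zf = rng.standard_normal((n, N_FEATURE_TYPES))

    g0 = center_frame(
        build_graph_arrays(prot_pos, prot_feat, zx, zf, cfg.k, cfg.protein_cutoff)
    )
    topology = g0  # reused when rewiring is off

    for t in range(cfg.T, 0, -1):
        if cfg.rewire:
            g = center_frame(
                build_graph_arrays(prot_pos, prot_feat, zx, zf, cfg.k, cfg.protein_cutoff)
            )
        else:
            # fixed topology: refresh only the pharm state, keep the wiring
            g = replace(topology, pharm_pos=zx + topology.frame_offset, pharm_feat=zf)
        eps_x, eps_f = denoise_step(params, g, t, cfg.T)

        a_t, s_t = sched.alpha[t], sched.sigma[t]
        a_s, s_s = sched.alpha[t - 1], sched.sigma[t - 1]
        a_ts = a_t / a_s
        var_ts = s_t**2 - a_ts**2 * s_s**2

        x0_hat = (zx - s_t * eps_x) / a_t
        f0_hat = (zf - s_t * eps_f) / a_t
        norms = np.linalg.norm(x0_hat, axis=1, keepdims=True)
        x0_hat = np.where(norms > x0_clip, x0_hat * (x0_clip / norms), x0_hat)
        f0_hat = np.clip(f0_hat, -cfg.feat_clip, cfg.feat_clip)
        c_z = a_ts * s_s**2 / s_t**2
        c_x0 = a_s * var_ts / s_t**2
        zx = c_z * zx + c_x0 * x0_hat
        zf = c_z * zf + c_x0 * f0_hat
        if t > 1:  # final step is noise-free
            std = np.sqrt(var_ts * s_s**2 / s_t**2)
            zx = zx + std * draw_coords(n)
            zf = zf + std * rng.standard_normal(zf.shape)
        if not (np.all(np.isfinite(zx)) and np.all(np.isfinite(zf))):
            raise FloatingPointError(f"non-finite sampler state after step t={t}")

    types = np.argmax(zf / FEATURE_SCALE, axis=1)
    coords = zx + centroid
    centers = [
        PharmacophoreCenter(
            position=coords[i], ftype=FeatureType(int(types[i])), radius=cfg.center_radius
        )
        for i in range(n)
    ]
    return Pharmacophore(centers=centers)


def generate_batch(
    pocket: Pocket,
    params: DenoiserParams,
    sizes: list[int],
    reps: int,
    seed: int,
    base_cfg: GenerationConfig | None = None,
) -> list[Pharmacophore]:
    """Generate ``reps`` pharmacophores of each requested size.

    Each sample runs on an independent seeded substream, so the list is
    reproducible as a whole and per entry.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    base = base_cfg if base_cfg is not None else GenerationConfig()
    streams = np.random.SeedSequence(seed).spawn(len(sizes) * reps)
    out: list[Pharmacophore] = []
    i = 0
    for size in sizes:
        for _ in range(reps):
            cfg = GenerationConfig(
                n_centers=size,
                T=base.T,
                schedule_power=base.schedule_power,
                init_spread=base.init_spread,
                seed=base.seed,
                k=base.k,
                protein_cutoff=base.protein_cutoff,
                rewire=base.rewire,
                allow_untrained=base.allow_untrained,
                center_radius=base.center_radius,
            )
            out.append(generate(pocket, params, cfg, rng=np.random.default_rng(streams[i])))
            i += 1
    return out
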