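"""Variance-preserving polynomial noise schedule and forward noising.

The forward process is q(z_t | z_0) = N(z_t | alpha_t z_0, sigma_t^2 I),
applied identically to pharmacophore coordinates and (scaled) one-hot
feature vectors; protein nodes are never noised.  The schedule satisfies
alpha_t^2 + sigma_t^2 = 1 exactly by construction, with alpha decreasing
from ~1 at t=0 to ~0 at t=T along a clipped polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: one-hot features are multiplied by this before noising and divided after
FEATURE_SCALE = 0.25


@dataclass(frozen=True)
class NoiseSchedule:
    """Arrays alpha_t, sigma_t for t = 0..T with alpha_t^2 + sigma_t^2 = 1."""

    T: int
    alpha: np.ndarray  # (T+1,)
    sigma: np.ndarray  # (T+1,)

    def __post_init__(self):
        if self.alpha.shape != (self.T + 1,) or self.sigma.shape != (self.T + 1,):
            raise ValueError("schedule arrays must have length T+1")
        dev = np.abs(self.alpha**2 + self.sigma**2 - 1.0).max()
        if dev > 1e-9:
            raise ValueError(f"variance-preserving identity violated by {dev:g}")


def make_schedule(T: int, power: float = 2.0, clip: float = 1e-7) -> NoiseSchedule:
    """Polynomial variance-preserving schedule.

    alpha_t^2 follows (1 - (t/T)^power)^2 rescaled into [clip, 1 - clip] so
    that alpha_0 ~ 1 and alpha_T ~ 0 without ever reaching the exact
    endpoints (numerical stability of the ancestral-posterior ratios).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if power <= 0:
        raise ValueError("power must be > 0")
    t = np.arange(T + 1, dtype=float) / T
    raw = (1.0 - t**power) ** 2
    alpha2 = clip + (1.0 - 2.0 * clip) * raw
    alpha = np.sqrt(alpha2)
    sigma = np.sqrt(1.0 - alpha2)
    return NoiseSchedule(T=T, alpha=alpha, sigma=sigma)


@dataclass
class NoisedSample:
    """A noised pharmacophore state plus the exact noise that produced it."""

    coords: np.ndarray  # (N, 3) noised coordinates
    feats: np.ndarray  # (N, 6) noised (scaled) features
    eps_coords: np.ndarray
    eps_feats: np.ndarray
    t: int


def noise_sample(
    coords0: np.ndarray,
    feats0: np.ndarray,
    sched: NoiseSchedule,
    t: int,
    rng: np.random.Generator,
) -> NoisedSample:
    """Draw z_t = alpha_t z_0 + sigma_t eps with iid standard Gaussian eps.

    ``feats0`` is used as given; callers apply FEATURE_SCALE to one-hot
    features before noising.
    """
    if not 0 <= t <= sched.T:
        raise ValueError(f"t={t} outside [0, {sched.T}]")
    a, s = sched.alpha[t], sched.sigma[t]
    eps_x = rng.standard_normal(coords0.shape)
    eps_f = rng.standard_normal(feats0.shape)
    return NoisedSample(
        coords=a * coords0 + s * eps_x,
        feats=a * feats0 + s * eps_f,
        eps_coords=eps_x,
        eps_feats=eps_f,
        t=t,
    )


def mse_loss(
    eps_hat_coords: np.ndarray,
    eps_hat_feats: np.ndarray,
    eps_coords: np.ndarray,
    eps_feats: np.ndarray,
) -> float:
    """Mean squared error over all coordinate and feature components."""
    if eps_hat_coords.shape != eps_coords.shape or eps_hat_feats.shape != eps_feats.shape:
        raise ValueError("shape mismatch between predicted and true noise")
    num = ((eps_hat_coords - eps_coords) ** 2).sum() + (
        (eps_hat_feats - eps_feats) ** 2
    ).sum()
    den = eps_coords.size + eps_feats.size
    return float(num / den)
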