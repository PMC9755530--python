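"""Wilson prior on structure factor amplitudes.

Under the assumption that atoms are uniformly distributed in the unit
cell, the amplitude of a reflection with multiplicity ``epsilon``
follows

* centric:   half-normal,  p(F) = sqrt(2 / (pi*eps)) * exp(-F^2 / (2*eps))
* acentric:  Rayleigh form, p(F) = (2/eps) * F * exp(-F^2 / eps)

Both branches have second raw moment ``eps`` — the symmetry-driven
enhancement of average intensity.  The prior is scale-free (independent
of the per-observation scale), which is what lets the scale function be
inferred jointly with the amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = ["WilsonPrior", "wilson_log_density", "wilson_sample"]


def _check_epsilon(epsilon):
    eps = np.asarray(epsilon, dtype=np.float64)
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValueError("epsilon must be finite and > 0")
    return eps


def wilson_log_density(F, epsilon, centric) -> np.ndarray:
    """Log prior density, elementwise; -inf outside the support
    (F < 0 everywhere; F = 0 for the acentric branch)."""
    eps = _check_epsilon(epsilon)
    F = np.asarray(F, dtype=np.float64)
    cen = np.asarray(centric, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_cen = 0.5 * (math.log(2.0 / math.pi) - np.log(eps)) - F ** 2 / (2.0 * eps)
        log_acen = math.log(2.0) - np.log(eps) + np.log(F) - F ** 2 / eps
    out = np.where(cen, log_cen, log_acen)
    out = np.where(F < 0, -np.inf, out)
    out = np.where((F == 0) & ~cen, -np.inf, out)
    return out


def wilson_sample(epsilon, centric, n: int | None = None, seed=None) -> np.ndarray:
    """Draw amplitudes from the prior.

    ``epsilon``/``centric`` broadcast; with ``n`` given, draws an
    (n,)-shaped sample per scalar spec or an (n, k) block for vector
    specs.  ``seed`` may be an int or a numpy Generator.
    """
    eps = _check_epsilon(epsilon)
    cen = np.broadcast_to(np.asarray(centric, dtype=bool), eps.shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = eps.shape if n is None else (n,) + eps.shape
    z = rng.standard_normal(shape)
    half = np.abs(z) * np.sqrt(eps)  # |N(0, eps)|
    u = rng.uniform(size=shape)
    rayl = np.sqrt(-eps * np.log1p(-u))  # inverse-CDF Rayleigh, E[F^2]=eps
    return np.where(cen, half, rayl)


@dataclass(frozen=True)
class WilsonPrior:
    """Vectorized prior over a set of unique reflections."""

    epsilon: np.ndarray
    centric: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "epsilon", _check_epsilon(self.epsilon))
        object.__setattr__(self, "centric", np.asarray(self.centric, dtype=bool))

    def log_prob(self, F) -> np.ndarray:
        return wilson_log_density(F, self.epsilon, self.centric)

    def log_prob_t(self, F: "ad.Tensor") -> "ad.Tensor":
        """Differentiable log density for reparameterized samples F > 0."""
        eps = self.epsilon
        cen = self.centric.astype(np.float64)
        c_cen = 0.5 * (math.log(2.0 / math.pi) - np.log(eps))
        c_acen = math.log(2.0) - np.log(eps)
        F2 = ad.square(F)
        log_cen = ad.add(ad.mul(F2, -0.5 / eps), c_cen)
        log_acen = ad.add(ad.add(ad.mul(F2, -1.0 / eps), ad.log(F)), c_acen)
        return ad.add(ad.mul(log_cen, cen), ad.mul(log_acen, 1.0 - cen))

    def sample(self, seed=None, n: int | None = None) -> np.ndarray:
        return wilson_sample(self.epsilon, self.centric, n=n, seed=seed)

    def mean(self) -> np.ndarray:
        """Closed-form prior means: sqrt(2*eps/pi) centric,
        sqrt(pi*eps)/2 acentric."""
        return np.where(self.centric,
                        np.sqrt(2.0 * self.epsilon / math.pi),
                        np.sqrt(math.pi * self.epsilon) / 2.0)
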