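"""Observation models relating intensities to amplitudes and scales.

The observed intensity of one reflection observation is modeled around
the location ``F^2 * Sigma`` with the integration-reported ``sigma_I``
as the scale parameter:

* ``normal``   — Normal(I | F^2 Sigma, sigma_I), for clean data;
* ``student_t``— StudentT(I | nu, F^2 Sigma, sigma_I), whose degrees of
  freedom ``nu`` titrate robustness toward outliers (nu -> inf recovers
  the normal model).

For polychromatic (Laue) data, reflections on one central ray are
superposed in a single spot, so the likelihood location is the sum of
``F^2 * Sigma`` over the ray's contributors and there is one observed
(I, sigma) per ray.  On all-singleton partitions this reduces exactly to
the monochromatic case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from . import autodiff as ad
from .autodiff import Tensor
from .symmetry import HarmonicGroups

__all__ = ["LikelihoodConfig", "loglik_mono", "loglik_laue"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LikelihoodConfig:
    """family in {normal, student_t}; dof required (finite, > 0) for
    student_t and ignored for normal."""

    family: str = "normal"
    dof: float | None = None

    def __post_init__(self):
        if self.family not in ("normal", "student_t"):
            raise ValueError(f"unknown likelihood family: {self.family!r}")
        if self.family == "student_t":
            if self.dof is None or not np.isfinite(self.dof) or self.dof <= 0:
                raise ValueError("student_t requires finite dof > 0")


def _log_density(I_obs: np.ndarray, sigma: np.ndarray, location: Tensor,
                 config: LikelihoodConfig) -> Tensor:
    I_obs = np.asarray(I_obs, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma_I must be strictly positive")
    resid = ad.sub(I_obs, location)
    if config.family == "normal":
        const = -np.log(sigma) - _LOG_SQRT_2PI
        return ad.add(ad.mul(ad.square(resid), -0.5 / sigma ** 2), const)
    nu = float(config.dof)
    const = (sp.gammaln((nu + 1.0) / 2.0) - sp.gammaln(nu / 2.0)
             - 0.5 * math.log(nu * math.pi) - np.log(sigma))
    z2 = ad.mul(ad.square(resid), 1.0 / (nu * sigma ** 2))
    return ad.add(ad.mul(ad.log(ad.add(z2, 1.0)), -(nu + 1.0) / 2.0), const)


def loglik_mono(I_obs, sigma_I, F_sample, Sigma_sample,
                config: LikelihoodConfig | None = None) -> Tensor:
    """Per-observation log-likelihood with location F^2 * Sigma.

    ``F_sample``/``Sigma_sample`` are per-observation draws (tensors for
    training, arrays for evaluation).
    """
    config = config or LikelihoodConfig()
    location = ad.mul(ad.square(ad.as_tensor(F_sample)),
                      ad.as_tensor(Sigma_sample))
    return _log_density(I_obs, sigma_I, location, config)


def loglik_laue(groups: HarmonicGroups, F_samples, Sigma_samples,
                config: LikelihoodConfig | None = None) -> Tensor:
    """Per-ray log-likelihood for harmonically superposed reflections.

    The location of ray r is sum over members of F^2 * Sigma; the
    observed intensity and sigma are the single per-ray values recorded
    in ``groups``.
    """
    config = config or LikelihoodConfig()
    if groups.n_rays == 0:
        raise ValueError("no rays to evaluate")
    contrib = ad.mul(ad.square(ad.as_tensor(F_samples)),
                     ad.as_tensor(Sigma_samples))
    location = ad.segment_sum(contrib, groups.ray_id, groups.n_rays)
    return _log_density(groups.ray_intensity, groups.ray_sigma,
                        location, config)
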