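"""The probabilistic scale function.

Each observation's multiplicative scale Sigma is given a normal
surrogate distribution whose mean and standard deviation are computed
from the observation's standardized metadata by a multilayer perceptron
with leaky-ReLU activations:

    {mu_Sigma, sigma_Sigma} = f_theta(M)

Square hidden kernels are initialized to the identity and biases to
zero, so at initialization the network is a (leaky) identity on its
inputs; the final linear layer has two units (mean, pre-constraint
standard deviation) and starts at zero kernel with bias chosen so the
initial scale distribution is Normal(0, 1) for every observation.

For serial (per-still-image) data, optional image-specific layers are
appended after the global stack and before the final layer, giving each
image its own local refinement of the global scale function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .posteriors import constrain, constrain_inverse

__all__ = ["ScaleConfig", "ScaleFunctionParams", "ScaleOutput",
           "init_params", "scale_forward", "scale_rsample"]


@dataclass
class ScaleConfig:
    """Architecture knobs for the scale MLP.

    depth: number of global square layers (default twenty).
    n_img_layers: per-image layers appended after the global stack
        (0 disables them; serial data typically uses 1-2).
    slope: leaky-ReLU negative slope.
    transform: positivity transform for sigma_Sigma (same one the
        amplitude posterior uses).
    """

    depth: int = 20
    n_img_layers: int = 0
    slope: float = 0.3
    transform: str = "exp"
    width: int | None = None  # hidden units; None = metadata dimension


@dataclass
class ScaleOutput:
    mu: Tensor      # per-observation mean of the scale distribution
    sigma: Tensor   # per-observation sd, strictly positive

    @property
    def mu_np(self) -> np.ndarray:
        return self.mu.data

    @property
    def sigma_np(self) -> np.ndarray:
        return self.sigma.data


@dataclass
class ScaleFunctionParams:
    """Trainable parameters theta of the scale function."""

    kernels: list            # depth x Tensor(w, w)
    biases: list             # depth x Tensor(w,)
    w_mu: Tensor             # (w,) first unit of the final linear layer
    w_sigma: Tensor          # (w,) second unit
    b_mu: Tensor             # scalar
    b_sigma: Tensor          # scalar (pre-constraint)
    proj_kernel: Tensor = None  # (d, w) leading projection when width != d
    proj_bias: Tensor = None    # (w,)
    image_kernels: dict = field(default_factory=dict)  # image_id -> [Tensor(w,w)]
    image_biases: dict = field(default_factory=dict)   # image_id -> [Tensor(w,)]
    config: ScaleConfig = field(default_factory=ScaleConfig)

    def parameters(self, include_image_layers: bool = True):
        out = list(self.kernels) + list(self.biases)
        out += [self.w_mu, self.w_sigma, self.b_mu, self.b_sigma]
        if self.proj_kernel is not None:
            out += [self.proj_kernel, self.proj_bias]
        if include_image_layers:
            for ks in self.image_kernels.values():
                out.extend(ks)
            for bs in self.image_biases.values():
                out.extend(bs)
        return out

    @property
    def d(self) -> int:
        """Input (metadata) dimension."""
        if self.proj_kernel is not None:
            return self.proj_kernel.data.shape[0]
        return self.kernels[0].data.shape[0]

    @property
    def width(self) -> int:
        return self.kernels[0].data.shape[0]

    # -- persistence (plain JSON-able dict) -------------------------------
    def to_dict(self) -> dict:
        return {
            "config": {"depth": self.config.depth,
                       "n_img_layers": self.config.n_img_layers,
                       "slope": self.config.slope,
                       "transform": self.config.transform,
                       "width": self.config.width},
            "kernels": [k.data.tolist() for k in self.kernels],
            "biases": [b.data.tolist() for b in self.biases],
            "w_mu": self.w_mu.data.tolist(),
            "w_sigma": self.w_sigma.data.tolist(),
            "b_mu": float(self.b_mu.data),
            "b_sigma": float(self.b_sigma.data),
            "proj_kernel": (None if self.proj_kernel is None
                            else self.proj_kernel.data.tolist()),
            "proj_bias": (None if self.proj_bias is None
                          else self.proj_bias.data.tolist()),
            "image_kernels": {str(i): [k.data.tolist() for k in ks]
                              for i, ks in self.image_kernels.items()},
            "image_biases": {str(i): [b.data.tolist() for b in bs]
                             for i, bs in self.image_biases.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleFunctionParams":
        cfg = ScaleConfig(**d["config"])
        t = lambda x: Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
        return cls(
            kernels=[t(k) for k in d["kernels"]],
            biases=[t(b) for b in d["biases"]],
            w_mu=t(d["w_mu"]), w_sigma=t(d["w_sigma"]),
            b_mu=t(d["b_mu"]), b_sigma=t(d["b_sigma"]),
            proj_kernel=(None if d.get("proj_kernel") is None
                         else t(d["proj_kernel"])),
            proj_bias=(None if d.get("proj_bias") is None
                       else t(d["proj_bias"])),
            image_kernels={int(i): [t(k) for k in ks]
                           for i, ks in d["image_kernels"].items()},
            image_biases={int(i): [t(b) for b in bs]
                          for i, bs in d["image_biases"].items()},
            config=cfg)

    def copy(self) -> "ScaleFunctionParams":
        return ScaleFunctionParams.from_dict(self.to_dict())


def init_params(d: int, config: ScaleConfig | None = None,
                n_images: int = 0) -> ScaleFunctionParams:
    """Identity-kernel / zero-bias initialization.

    The final layer starts with zero kernels and bias ``(0, s0)`` where
    ``s0`` maps through the positivity transform to 1, so initially
    every observation gets the metadata-independent scale distribution
    Normal(0, 1).  Image layers (if configured) are initialized
    identically for every image.
    """
    config = config or ScaleConfig()
    if d < 1 or config.depth < 1:
        raise ValueError("need metadata dimension >= 1 and depth >= 1")
    if config.n_img_layers > 0 and n_images <= 0:
        raise ValueError("image layers configured but no images supplied")
    t = lambda x: Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    w = d if config.width is None else int(config.width)
    proj_k = proj_b = None
    if w != d:
        # leading linear projection: channel j reads input dim j mod d with
        # alternating sign, and spread biases place the activation kinks at
        # distinct points of the (standardized) input range
        P = np.zeros((d, w))
        for j in range(w):
            P[j % d, j] = 1.0 if (j // d) % 2 == 0 else -1.0
        proj_k = t(P)
        proj_b = t(np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(w))
    kernels = [t(np.eye(w)) for _ in range(config.depth)]
    biases = [t(np.zeros(w)) for _ in range(config.depth)]
    s0 = float(constrain_inverse(1.0, config.transform))
    img_k, img_b = {}, {}
    if config.n_img_layers > 0:
        for i in range(n_images):
            img_k[i] = [t(np.eye(w)) for _ in range(config.n_img_layers)]
            img_b[i] = [t(np.zeros(w)) for _ in range(config.n_img_layers)]
    return ScaleFunctionParams(
        kernels=kernels, biases=biases,
        w_mu=t(np.zeros(w)), w_sigma=t(np.zeros(w)),
        b_mu=t(0.0), b_sigma=t(s0),
        proj_kernel=proj_k, proj_bias=proj_b,
        image_kernels=img_k, image_biases=img_b, config=config)


def scale_forward(X: np.ndarray, image_ids: np.ndarray,
                  params: ScaleFunctionParams) -> ScaleOutput:
    """Run the MLP on a design matrix (rows x d standardized metadata).

    Rows pass through the global layers, then their image's layers when
    configured, then the final linear layer.  Deterministic given
    parameters and inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.d:
        raise ValueError("design matrix dimension does not match parameters")
    slope = params.config.slope
    h = Tensor(X)
    if params.proj_kernel is not None:
        h = ad.add(ad.matmul(h, params.proj_kernel), params.proj_bias)
    for W, b in zip(params.kernels, params.biases):
        h = ad.dense_leaky(h, W, b, slope)
    if params.config.n_img_layers > 0:
        image_ids = np.asarray(image_ids)
        pieces = []
        for img in np.unique(image_ids):
            if int(img) not in params.image_kernels:
                raise KeyError(f"no image layers for image_id {int(img)}")
            idx = np.nonzero(image_ids == img)[0]
            hi = ad.gather(h, idx)
            for W, b in zip(params.image_kernels[int(img)],
                            params.image_biases[int(img)]):
                hi = ad.dense_leaky(hi, W, b, slope)
            pieces.append((idx, hi))
        h = ad.scatter_rows(pieces, X.shape[0])
    mu = ad.add(ad.matvec(h, params.w_mu), params.b_mu)
    sigma = constrain(ad.add(ad.matvec(h, params.w_sigma), params.b_sigma),
                      params.config.transform)
    return ScaleOutput(mu, sigma)


def scale_rsample(output: ScaleOutput, noise: np.ndarray) -> Tensor:
    """Reparameterized normal draw Sigma = mu + sigma * noise."""
    return ad.add(output.mu, ad.mul(output.sigma, noise))
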