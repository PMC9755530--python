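"""Variational scaling-and-merging: objective, optimizer loop, outputs.

The model treats every unique reflection's amplitude F as a latent
variable with a Wilson prior and a truncated-normal surrogate posterior,
and every observation's scale Sigma as a normal surrogate computed from
metadata by the scale MLP.  With an uninformative prior on scales, the
objective is

    ELBO = E_q[ log p(I | F^2 Sigma) ] - D_KL( q_F || p_Wilson )

estimated by S reparameterized Monte-Carlo samples (S = 1 by default)
and maximized with Adam (alpha = 1e-3, beta1 = 0.9, beta2 = 0.99).
Joint multi-dataset merging keeps one amplitude set per dataset while
all observations share the scale function; freezing the scale function
supports half-dataset cross-validation and transfer of learned weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .likelihoods import LikelihoodConfig, loglik_laue, loglik_mono
from .posteriors import AmplitudePosterior, tn_moments
from .priors import WilsonPrior
from .reflection_io import (MergedTable, ReflectionTable,
                            apply_standardization, standardize_metadata)
from .scale_model import (ScaleConfig, ScaleFunctionParams, init_params,
                          scale_forward, scale_rsample)
from .symmetry import annotate, group_harmonics, spacegroup_ops

__all__ = [
    "TrainingConfig", "UniqueMap", "FitResult",
    "build_unique_map", "elbo_estimate", "fit",
    "predict_moments", "extract_merged",
    "save_scale_params", "load_scale_params",
]

_KEY = ["asu_h", "asu_k", "asu_l", "friedel_branch", "dataset_id"]


@dataclass
class TrainingConfig:
    iterations: int = 30_000
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    mc_samples: int = 1
    seed: int = 0
    freeze_scale: bool = False
    #: average the trainable parameters over the last fraction of
    #: iterations (Polyak averaging) — removes the stationary jitter the
    #: single-sample gradient estimator leaves in the iterates; 0 disables.
    polyak_fraction: float = 0.25

    def __post_init__(self):
        if self.mc_samples < 1 or self.learning_rate <= 0:
            raise ValueError("need mc_samples >= 1 and learning_rate > 0")
        if not 0.0 <= self.polyak_fraction <= 1.0:
            raise ValueError("polyak_fraction must be in [0, 1]")


@dataclass
class UniqueMap:
    """Bijection between (asu_index, friedel_branch, dataset_id) triples
    and dense posterior indices, plus the per-row index."""

    unique: pd.DataFrame      # one row per posterior entry
    row_index: np.ndarray     # (n_rows,) posterior index of each observation

    def __len__(self):
        return len(self.unique)

    def lookup(self, df: pd.DataFrame) -> np.ndarray:
        """Posterior indices for annotated rows; -1 where the triple was
        never observed in the mapped data."""
        key = _branch_frame(df)
        merged = key.merge(
            self.unique[_KEY].reset_index(names="_uid"), how="left", on=_KEY)
        return merged["_uid"].fillna(-1).to_numpy(np.int64)


def _branch_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Friedel branch labels from annotation columns.

    Centric reflections are never split by Friedel sign (their anomalous
    difference is identically zero)."""
    sign = df["friedel_sign"].to_numpy()
    centric = df["centric"].to_numpy(bool)
    branch = np.where(centric | (sign == 0), "merged",
                      np.where(sign > 0, "plus", "minus"))
    out = df[["asu_h", "asu_k", "asu_l", "dataset_id"]].copy()
    out["friedel_branch"] = branch
    return out[_KEY]


def build_unique_map(annotated: pd.DataFrame, anomalous: bool = False) -> UniqueMap:
    """Index unique reflections present in the data.

    Without anomalous merging every row's branch is ``merged`` (Friedel
    mates share one posterior entry); with it, acentric mates get
    separate ``plus``/``minus`` entries per dataset.
    """
    df = annotated.copy()
    if not anomalous:
        df = df.assign(friedel_sign=0)
    key = _branch_frame(df)
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(key), sort=True)
    uniq = pd.DataFrame(list(uniques), columns=_KEY)
    grp = df.groupby(codes)
    uniq["epsilon"] = grp["epsilon"].first().to_numpy(np.float64)
    uniq["centric"] = grp["centric"].first().to_numpy(bool)
    uniq["n_obs"] = grp.size().to_numpy(np.int64)
    uniq["mean_intensity"] = grp["intensity"].mean().to_numpy(np.float64)
    if "dspacing" in df.columns:
        uniq["dspacing"] = grp["dspacing"].mean().to_numpy(np.float64)
    return UniqueMap(uniq, np.asarray(codes, dtype=np.int64))


@dataclass
class FitResult:
    posterior: AmplitudePosterior
    scale_params: ScaleFunctionParams
    elbo_trace: np.ndarray
    unique_map: UniqueMap
    metadata_columns: list
    centers: np.ndarray
    spreads: np.ndarray
    spacegroup: object
    anomalous: bool
    likelihood: LikelihoodConfig
    training: TrainingConfig
    annotated: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# ELBO

def _elbo_graph(I_obs, sigma_I, X, image_ids, row_index, posterior,
                scale_params, prior, likelihood, rng, S, groups=None) -> Tensor:
    """Monte-Carlo ELBO as an autodiff graph (mean over S samples)."""
    total = None
    n_post = len(posterior)
    n_rows = len(row_index)
    for _ in range(S):
        u = rng.uniform(size=n_post)
        noise = rng.standard_normal(n_rows)
        F = posterior.rsample_t(u)
        out = scale_forward(X, image_ids, scale_params)
        Sigma = scale_rsample(out, noise)
        F_rows = ad.gather(F, row_index)
        if groups is None:
            ll = loglik_mono(I_obs, sigma_I, F_rows, Sigma, likelihood)
        else:
            ll = loglik_laue(groups, F_rows, Sigma, likelihood)
        kl = ad.sub(posterior.log_prob_t(F), prior.log_prob_t(F))
        piece = ad.sub(ad.tsum(ll), ad.tsum(kl))
        total = piece if total is None else ad.add(total, piece)
    return ad.mul(total, 1.0 / S) if S > 1 else total


def elbo_estimate(table, unique_map: UniqueMap, posterior: AmplitudePosterior,
                  scale_params: ScaleFunctionParams, prior: WilsonPrior,
                  likelihood: LikelihoodConfig | None = None,
                  metadata_columns=None, centers=None, spreads=None,
                  S: int = 1, seed: int = 0, groups=None) -> float:
    """One Monte-Carlo estimate of the ELBO (scalar, for diagnostics)."""
    df = table.df if isinstance(table, ReflectionTable) else table
    cols = metadata_columns
    if centers is None:
        X, centers, spreads = standardize_metadata(table, cols)
    else:
        X = apply_standardization(df, cols, centers, spreads)
    rng = np.random.default_rng(seed)
    g = _elbo_graph(df["intensity"].to_numpy(), df["sigma_I"].to_numpy(),
                    X, df["image_id"].to_numpy(), unique_map.row_index,
                    posterior, scale_params, prior,
                    likelihood or LikelihoodConfig(), rng, S, groups)
    return g.item()


# ---------------------------------------------------------------------------
# fitting

def fit(table: ReflectionTable, spacegroup="P1", *,
        metadata_columns=None, anomalous: bool = False,
        likelihood: LikelihoodConfig | None = None,
        scale_config: ScaleConfig | None = None,
        training: TrainingConfig | None = None,
        laue: bool = False,
        scale_params: ScaleFunctionParams | None = None,
        standardization=None) -> FitResult:
    """Jointly infer amplitude posteriors and the scale function.

    Parameters of note:

    laue
        Use the harmonic-deconvolution likelihood: observations are
        grouped onto central rays per image and the likelihood location
        is the sum of members' F^2 Sigma.
    scale_params / training.freeze_scale
        Supplying ``scale_params`` warm-starts the scale function (e.g.
        transfer learning); with ``freeze_scale`` those weights are held
        fixed and only the amplitude posterior is optimized
        (half-dataset cross-validation mode).
    standardization
        ``(centers, spreads)`` from a previous fit, so held-out or
        half-dataset rows reuse the training transform.
    """
    likelihood = likelihood or LikelihoodConfig()
    scale_config = scale_config or ScaleConfig()
    training = training or TrainingConfig()
    ops = spacegroup_ops(spacegroup)
    metadata_columns = list(metadata_columns or table.metadata_columns)

    df = annotate(table, ops, anomalous=anomalous)
    umap = build_unique_map(df, anomalous=anomalous)
    prior = WilsonPrior(umap.unique["epsilon"].to_numpy(),
                        umap.unique["centric"].to_numpy())

    if standardization is None:
        X, centers, spreads = standardize_metadata(table, metadata_columns)
    else:
        centers, spreads = standardization
        X = apply_standardization(df, metadata_columns, centers, spreads)

    rng = np.random.default_rng(training.seed)
    posterior = AmplitudePosterior.from_data(
        umap.unique["mean_intensity"].to_numpy(),
        epsilon=umap.unique["epsilon"].to_numpy(),
        transform=scale_config.transform)
    if scale_params is None:
        scale_params = init_params(X.shape[1], scale_config,
                                   n_images=table.n_images)
    else:
        scale_params = scale_params.copy()
        scale_config = scale_params.config

    groups = group_harmonics(df) if laue else None

    params = posterior.parameters()
    if not training.freeze_scale:
        params = params + scale_params.parameters()
    opt = Adam(params, lr=training.learning_rate,
               beta1=training.beta1, beta2=training.beta2)

    I_obs = df["intensity"].to_numpy(np.float64)
    sig = df["sigma_I"].to_numpy(np.float64)
    img = df["image_id"].to_numpy()
    trace = np.empty(training.iterations)
    avg_start = int(np.ceil(training.iterations *
                            (1.0 - training.polyak_fraction)))
    avg = [np.zeros_like(p.data) for p in params]
    n_avg = 0
    for it in range(training.iterations):
        opt.zero_grad()
        elbo = _elbo_graph(I_obs, sig, X, img, umap.row_index, posterior,
                           scale_params, prior, likelihood, rng,
                           training.mc_samples, groups)
        val = elbo.item()
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite ELBO at iteration {it}")
        ad.neg(elbo).backward()
        opt.step()
        trace[it] = val
        if it >= avg_start:
            for a, p in zip(avg, params):
                a += p.data
            n_avg += 1
    if n_avg > 0:
        for a, p in zip(avg, params):
            p.data = a / n_avg

    return FitResult(posterior=posterior, scale_params=scale_params,
                     elbo_trace=trace, unique_map=umap,
                     metadata_columns=metadata_columns,
                     centers=np.asarray(centers), spreads=np.asarray(spreads),
                     spacegroup=ops, anomalous=anomalous,
                     likelihood=likelihood, training=training, annotated=df)


# ---------------------------------------------------------------------------
# predictions and merged output

def predict_moments(rows: pd.DataFrame, fit_result: FitResult):
    """Expected intensity and its standard deviation per observation row.

    <I> = mu_Sigma * (<F>^2 + var_F);   var(I) = <F^4>(sigma_Sigma^2 +
    mu_Sigma^2) - <I>^2, using the analytic truncated-normal moments.
    Rows referencing reflections absent from the fit get NaN.
    """
    if not {"asu_h", "friedel_sign"} <= set(rows.columns):
        rows = annotate(rows, fit_result.spacegroup,
                        anomalous=fit_result.anomalous)
    if not fit_result.anomalous:
        rows = rows.assign(friedel_sign=0)
    idx = fit_result.unique_map.lookup(rows)
    X = apply_standardization(rows, fit_result.metadata_columns,
                              fit_result.centers, fit_result.spreads)
    out = scale_forward(X, rows["image_id"].to_numpy(),
                        fit_result.scale_params)
    mu_s, sd_s = out.mu_np, out.sigma_np
    mean, var, m4 = fit_result.posterior.moments()
    ok = idx >= 0
    safe = np.where(ok, idx, 0)
    F2 = (mean ** 2 + var)[safe]
    I_hat = mu_s * F2
    I_var = m4[safe] * (sd_s ** 2 + mu_s ** 2) - I_hat ** 2
    if np.any(I_var[ok] < -1e-8 * np.maximum(I_hat[ok] ** 2, 1.0)):
        raise RuntimeError("negative predicted variance beyond round-off")
    I_sd = np.sqrt(np.maximum(I_var, 0.0))
    I_hat[~ok] = np.nan
    I_sd[~ok] = np.nan
    return I_hat, I_sd


def extract_merged(fit_result: FitResult,
                   wilson_b: float | None = None) -> MergedTable:
    """Posterior means/sds as a merged table.

    With ``wilson_b`` set, F and SigF are both multiplied by
    exp(-B / (4 d^2)) using each reflection's resolution d (a global
    Wilson B-factor to restore a resolution falloff for downstream
    software that expects one).
    """
    uniq = fit_result.unique_map.unique
    F = fit_result.posterior.mean
    SigF = fit_result.posterior.std
    if wilson_b is not None and wilson_b != 0.0:
        if "dspacing" not in uniq.columns:
            raise ValueError("wilson_b requires per-reflection resolution")
        damp = np.exp(-wilson_b / (4.0 * uniq["dspacing"].to_numpy() ** 2))
        F, SigF = F * damp, SigF * damp
    df = pd.DataFrame({
        "h": uniq["asu_h"], "k": uniq["asu_k"], "l": uniq["asu_l"],
        "F": F, "SigF": SigF, "n_obs": uniq["n_obs"],
        "friedel_branch": uniq["friedel_branch"],
        "dataset_id": uniq["dataset_id"]})
    if "dspacing" in uniq.columns:
        df["dspacing"] = uniq["dspacing"].to_numpy()
    return MergedTable(df)


# ---------------------------------------------------------------------------
# persistence of learned scale-function weights (transfer / freeze modes)

def save_scale_params(params: ScaleFunctionParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh)


def load_scale_params(path) -> ScaleFunctionParams:
    with open(path) as fh:
        return ScaleFunctionParams.from_dict(json.load(fh))
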