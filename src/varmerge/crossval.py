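"""Cross-validation and merging-quality statistics.

Two modes:

1. **Half-dataset consistency.**  Train on the full data, freeze the
   learned scale-function weights, split the images randomly in half,
   merge each half separately, and correlate the two amplitude sets —
   an analogue of the crystallographic CC_1/2 (and, for anomalous
   differences, CC_anom), reported in equal-population resolution bins.

2. **Hold-out prediction.**  Hold out a fraction of observations, train
   on the rest, predict the held-out intensities from the learned scale
   function and posteriors, and report a rank correlation (Spearman by
   recommendation — robust to outliers), the statistic used to titrate
   the Student-t degrees of freedom.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .inference import TrainingConfig, extract_merged, fit, predict_moments
from .reflection_io import MergedTable, ReflectionTable

__all__ = [
    "split_half_by_image", "resolution_bins",
    "cc_half", "cc_anom",
    "holdout_predict_score", "half_dataset_crossval",
]

_KEY = ["h", "k", "l", "dataset_id"]


def split_half_by_image(table: ReflectionTable, seed: int = 0):
    """Randomly partition the data into halves *by image* — every row
    follows its image.  Images are shuffled under ``seed`` and assigned
    alternately, so the halves differ in size by at most one image."""
    n_img = table.n_images
    if n_img < 2:
        raise ValueError("need at least 2 images to split by image")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_img)
    in_a = np.zeros(n_img, dtype=bool)
    in_a[order[::2]] = True
    mask = in_a[table.df["image_id"].to_numpy()]
    return table.subset(mask), table.subset(~mask)


def resolution_bins(d: np.ndarray, n_bins: int):
    """Equal-population resolution bin index per reflection (0 = lowest
    resolution / largest d)."""
    d = np.asarray(d, dtype=np.float64)
    ranks = stats.rankdata(-d, method="ordinal") - 1
    return (ranks * n_bins // len(d)).astype(int)


def _corr(x, y, method: str, w=None) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0])
    if method == "weighted":
        w = np.asarray(w, dtype=np.float64)
        mx, my = np.average(x, weights=w), np.average(y, weights=w)
        cov = np.average((x - mx) * (y - my), weights=w)
        vx = np.average((x - mx) ** 2, weights=w)
        vy = np.average((y - my) ** 2, weights=w)
        return float(cov / np.sqrt(vx * vy))
    raise ValueError(f"unknown correlation method: {method!r}")


def _binned_correlation(joined: pd.DataFrame, xcol, ycol, n_bins,
                        method="pearson", wcol=None) -> pd.DataFrame:
    if "dspacing" not in joined.columns:
        raise ValueError("resolution (dspacing) required for binning")
    bins = resolution_bins(joined["dspacing"].to_numpy(), n_bins)
    rows = []
    for b in range(n_bins):
        sel = joined[bins == b]
        if len(sel) < 3:
            rows.append({"bin": b, "d_min": np.nan, "d_max": np.nan,
                         "statistic": np.nan, "n": len(sel)})
            continue
        w = sel[wcol].to_numpy() if wcol else None
        rows.append({
            "bin": b,
            "d_min": float(sel["dspacing"].min()),
            "d_max": float(sel["dspacing"].max()),
            "statistic": _corr(sel[xcol].to_numpy(), sel[ycol].to_numpy(),
                               method, w),
            "n": len(sel)})
    w = joined[wcol].to_numpy() if wcol else None
    overall = _corr(joined[xcol].to_numpy(), joined[ycol].to_numpy(), method, w)
    out = pd.DataFrame(rows)
    out.attrs["overall"] = overall
    return out


def cc_half(merged_a: MergedTable, merged_b: MergedTable,
            n_bins: int = 15, method: str = "pearson") -> pd.DataFrame:
    """Correlation of half-dataset amplitudes over shared unique
    reflections, per resolution bin; overall value in ``.attrs``."""
    key = _KEY + ["friedel_branch"]
    joined = merged_a.df.merge(merged_b.df, on=key, suffixes=("_a", "_b"))
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared unique reflections")
    joined = joined.rename(columns={"dspacing_a": "dspacing"})
    return _binned_correlation(joined, "F_a", "F_b", n_bins, method)


def _anom_diff(merged: MergedTable) -> pd.DataFrame:
    df = merged.df
    plus = df[df["friedel_branch"] == "plus"]
    minus = df[df["friedel_branch"] == "minus"]
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("no Friedel pairs: merge with anomalous=True")
    both = plus.merge(minus, on=_KEY, suffixes=("_p", "_m"))
    out = both[_KEY].copy()
    out["danom"] = both["F_p"].to_numpy() - both["F_m"].to_numpy()
    out["w"] = 1.0 / (both["SigF_p"].to_numpy() ** 2
                      + both["SigF_m"].to_numpy() ** 2)
    if "dspacing_p" in both.columns:
        out["dspacing"] = both["dspacing_p"].to_numpy()
    return out


def cc_anom(merged_a: MergedTable, merged_b: MergedTable,
            method: str = "pearson", n_bins: int = 15) -> pd.DataFrame:
    """Correlation of half-dataset anomalous differences F(+) - F(-)
    (pearson, spearman, or inverse-variance weighted pearson)."""
    da, db = _anom_diff(merged_a), _anom_diff(merged_b)
    joined = da.merge(db, on=_KEY, suffixes=("_a", "_b"))
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared Friedel pairs")
    joined = joined.rename(columns={"dspacing_a": "dspacing"})
    joined["w"] = joined["w_a"] + joined["w_b"]
    wcol = "w" if method == "weighted" else None
    return _binned_correlation(joined, "danom_a", "danom_b", n_bins,
                               method, wcol)


def half_dataset_crossval(table: ReflectionTable, spacegroup="P1", *,
                          seed: int = 0, n_bins: int = 15,
                          anomalous: bool = False, full_fit=None,
                          **fit_kwargs):
    """Half-dataset mode: full fit, then per-half refits with the
    learned scale weights frozen; returns (cc table, merged_a, merged_b,
    full fit)."""
    if full_fit is None:
        full_fit = fit(table, spacegroup, anomalous=anomalous, **fit_kwargs)
    half_a, half_b = split_half_by_image(table, seed=seed)
    training = fit_kwargs.get("training") or TrainingConfig()
    half_training = replace(training, freeze_scale=True)
    merged = []
    for half in (half_a, half_b):
        res = fit(half, spacegroup, anomalous=anomalous,
                  metadata_columns=full_fit.metadata_columns,
                  likelihood=full_fit.likelihood,
                  training=half_training,
                  scale_params=full_fit.scale_params,
                  standardization=(full_fit.centers, full_fit.spreads),
                  laue=fit_kwargs.get("laue", False))
        merged.append(extract_merged(res))
    stat = (cc_anom if anomalous else cc_half)(merged[0], merged[1],
                                               n_bins=n_bins)
    return stat, merged[0], merged[1], full_fit


def holdout_predict_score(table: ReflectionTable, spacegroup="P1", *,
                          fraction: float = 0.1, seed: int = 0,
                          method: str = "spearman", **fit_kwargs):
    """Hold-out mode: train on 1-f of the observations, predict the
    held-out intensities, and report the rank correlation between
    observed and predicted.

    Held-out rows whose reflection was never observed in training are
    excluded from the score and counted in the report.  Returns
    ``(score, report dict, fit result)``.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("holdout fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(table)
    held = np.zeros(n, dtype=bool)
    held[rng.choice(n, size=max(1, int(round(fraction * n))),
                    replace=False)] = True
    train = ReflectionTable(table.df.loc[~held].copy(),
                            list(table.metadata_columns))
    test_df = table.df.loc[held].copy()
    result = fit(train, spacegroup, **fit_kwargs)
    I_hat, _ = predict_moments(test_df, result)
    ok = np.isfinite(I_hat)
    obs = test_df["intensity"].to_numpy()[ok]
    if ok.sum() < 3:
        raise ValueError("too few scorable held-out rows")
    score = _corr(obs, I_hat[ok], method)
    report = {"n_held_out": int(held.sum()),
              "n_scored": int(ok.sum()),
              "n_excluded_unseen": int((~ok).sum())}
    return score, report, result
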