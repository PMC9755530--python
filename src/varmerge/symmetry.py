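"""Space-group bookkeeping for merging.

Reflections related by crystal symmetry share one amplitude, so every
observation is annotated with:

* the canonical ASU representative of its Miller index (the
  lexicographically maximal image under the reciprocal-space action of
  the rotation group, with Friedel inversion folded in unless anomalous
  merging keeps the mates separate),
* the multiplicity ``epsilon`` (order of the reflection's
  reciprocal-space stabilizer), which enters the Wilson prior,
* the centric flag (some rotation maps ``h`` to ``-h``), and
* the Friedel sign (+1/-1) when anomalous merging is on.

Rotation operators come from gemmi's space-group tables (rotation parts
only, deduplicated); translation parts play no role for intensities.
Harmonic (central-ray) grouping for Laue data also lives here: within an
image, Miller indices that are positive integer multiples of a common
primitive index are superposed in one spot and share one observed
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflection_io import ReflectionTable, ValidationError

__all__ = [
    "SpaceGroupOps",
    "SymmetryAnnotation",
    "HarmonicGroups",
    "BUILTIN_GROUPS",
    "spacegroup_ops",
    "epsilon_of",
    "is_centric",
    "map_to_asu",
    "annotate",
    "group_harmonics",
]

#: short label -> Hermann-Mauguin name understood by gemmi
BUILTIN_GROUPS = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "P212121": "P 21 21 21",
    "P63": "P 63",
    "P43212": "P 43 21 2",
}


@dataclass(frozen=True)
class SpaceGroupOps:
    """Rotation parts of a space group (reciprocal-space action h' = h R)."""

    rotations: np.ndarray  # (n_ops, 3, 3) integer
    identifier: str = ""

    def __post_init__(self):
        R = np.asarray(self.rotations, dtype=np.int64)
        if R.ndim != 3 or R.shape[1:] != (3, 3):
            raise ValueError("rotations must be (n, 3, 3)")
        dets = np.linalg.det(R.astype(float)).round().astype(int)
        if not np.all(np.abs(dets) == 1):
            raise ValueError("rotation determinants must be +/-1")
        object.__setattr__(self, "rotations", R)

    @property
    def order(self) -> int:
        return len(self.rotations)


@dataclass(frozen=True)
class SymmetryAnnotation:
    asu_index: tuple
    epsilon: int
    centric: bool
    friedel_sign: int


def spacegroup_ops(name) -> SpaceGroupOps:
    """Build :class:`SpaceGroupOps` from a label, an HM symbol, or an
    explicit iterable of 3x3 integer matrices."""
    if isinstance(name, SpaceGroupOps):
        return name
    if not isinstance(name, str):
        return SpaceGroupOps(np.asarray(list(name)), "custom")
    import gemmi
    hm = BUILTIN_GROUPS.get(name, name)
    sg = gemmi.find_spacegroup_by_name(hm)
    if sg is None:
        raise KeyError(f"unknown space group: {name!r}")
    rots, seen = [], set()
    for op in sg.operations():
        R = (np.array(op.rot, dtype=np.int64) // op.DEN)
        key = R.tobytes()
        if key not in seen:
            seen.add(key)
            rots.append(R)
    return SpaceGroupOps(np.stack(rots), name)


def _check_h(h):
    h = np.asarray(h, dtype=np.int64)
    if h.shape != (3,):
        raise ValueError("Miller index must be a 3-vector")
    if not h.any():
        raise ValueError("Miller index (0,0,0) is unphysical")
    return h


def epsilon_of(h, ops: SpaceGroupOps) -> int:
    """Multiplicity: number of rotations with h R = h."""
    h = _check_h(h)
    images = h @ ops.rotations
    return int((images == h).all(axis=1).sum())


def is_centric(h, ops: SpaceGroupOps) -> bool:
    """True iff some rotation maps h to -h (Friedel mate in the orbit)."""
    h = _check_h(h)
    images = h @ ops.rotations
    return bool((images == -h).all(axis=1).any())


def _lex_max(rows: np.ndarray) -> np.ndarray:
    """Lexicographically maximal row of an (n, 3) integer array."""
    order = np.lexsort((rows[:, 2], rows[:, 1], rows[:, 0]))
    return rows[order[-1]]


def map_to_asu(h, ops: SpaceGroupOps, anomalous: bool = False) -> SymmetryAnnotation:
    """Canonical ASU representative, multiplicity, centricity, Friedel sign.

    The representative is the lexicographically maximal image under the
    group, including Friedel inversion when ``anomalous`` is off or the
    reflection is centric; equivalent inputs map to the same index.
    With ``anomalous`` on, acentric Friedel mates share the same
    ``asu_index`` but carry opposite ``friedel_sign``.
    """
    h = _check_h(h)
    plus = h @ ops.rotations
    minus = -plus
    centric = bool((plus == -h).all(axis=1).any())
    eps = int((plus == h).all(axis=1).sum())
    rep = _lex_max(np.concatenate([plus, minus]))
    if anomalous and not centric:
        in_plus = (plus == rep).all(axis=1).any()
        sign = 1 if in_plus else -1
    else:
        sign = 1
    return SymmetryAnnotation(tuple(int(x) for x in rep), eps, centric, sign)


def annotate(table, ops, anomalous: bool = False) -> pd.DataFrame:
    """Vectorized symmetry annotation of a reflection table (or its
    DataFrame).

    Returns a copy of the frame with columns ``asu_h, asu_k, asu_l,
    epsilon, centric, friedel_sign`` appended.
    """
    ops = spacegroup_ops(ops)
    frame = table.df if isinstance(table, ReflectionTable) else table
    H = frame[["h", "k", "l"]].to_numpy(np.int64)
    uniq, inverse = np.unique(H, axis=0, return_inverse=True)
    ann = [map_to_asu(h, ops, anomalous) for h in uniq]
    asu = np.array([a.asu_index for a in ann], dtype=np.int64)[inverse]
    df = frame.copy()
    df["asu_h"], df["asu_k"], df["asu_l"] = asu[:, 0], asu[:, 1], asu[:, 2]
    df["epsilon"] = np.array([a.epsilon for a in ann])[inverse]
    df["centric"] = np.array([a.centric for a in ann])[inverse]
    df["friedel_sign"] = np.array([a.friedel_sign for a in ann])[inverse]
    return df


# ---------------------------------------------------------------------------
# harmonic (central-ray) grouping for Laue data

@dataclass
class HarmonicGroups:
    """Partition of observations into central-ray groups.

    ``ray_id`` assigns every row of the source table to one ray (dense
    0-based ids); ``ray_intensity``/``ray_sigma`` hold the single
    observed value per ray.  Monochromatic data yields all singletons.
    """

    ray_id: np.ndarray
    ray_intensity: np.ndarray
    ray_sigma: np.ndarray

    @property
    def n_rays(self) -> int:
        return len(self.ray_intensity)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.ray_id, minlength=self.n_rays)


def group_harmonics(table_or_df, rtol: float = 1e-9) -> HarmonicGroups:
    """Group each image's observations by central ray.

    Rows whose Miller indices are positive integer multiples of a common
    gcd-reduced primitive index, on the same image (and dataset), form
    one group carrying a single observed intensity.  Members must agree
    on the observed (I, sigma) within ``rtol``; conflicts raise a
    :class:`ValidationError` naming the image and ray.
    """
    df = table_or_df.df if isinstance(table_or_df, ReflectionTable) else table_or_df
    H = df[["h", "k", "l"]].to_numpy(np.int64)
    g = np.gcd.reduce(np.abs(H), axis=1)
    prim = H // g[:, None]
    key = pd.DataFrame({
        "dataset_id": df["dataset_id"].to_numpy(),
        "image_id": df["image_id"].to_numpy(),
        "ph": prim[:, 0], "pk": prim[:, 1], "pl": prim[:, 2]})
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(key), sort=False)
    ray_id = np.asarray(codes, dtype=np.int64)
    n_rays = ray_id.max() + 1 if len(ray_id) else 0
    I = df["intensity"].to_numpy(np.float64)
    S = df["sigma_I"].to_numpy(np.float64)
    ray_I = np.empty(n_rays)
    ray_S = np.empty(n_rays)
    order = np.argsort(ray_id, kind="stable")
    sorted_ids = ray_id[order]
    starts = np.searchsorted(sorted_ids, np.arange(n_rays))
    ends = np.searchsorted(sorted_ids, np.arange(n_rays), side="right")
    for r in range(n_rays):
        rows = order[starts[r]:ends[r]]
        vals_I, vals_S = I[rows], S[rows]
        tol = rtol * max(1.0, abs(vals_I[0]))
        if np.any(np.abs(vals_I - vals_I[0]) > tol) or \
           np.any(np.abs(vals_S - vals_S[0]) > rtol * max(1.0, vals_S[0])):
            img = int(df["image_id"].iloc[rows[0]])
            ray = tuple(int(x) for x in prim[rows[0]])
            raise ValidationError(
                f"conflicting observed intensities on image {img}, ray {ray}")
        ray_I[r], ray_S[r] = vals_I[0], vals_S[0]
    return HarmonicGroups(ray_id, ray_I, ray_S)
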