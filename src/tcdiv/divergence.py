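"""The divergence score: per ortholog pair, score = (1 - |A|) x B.

A is the Pearson correlation between the two groups' baseline-anchored
temporal response curves (shape agreement, scale invariant); B is the
absolute area between the piecewise-linear interpolants of the two curves
(magnitude of divergence, in log2-ratio x hours).  The product is large
only when the shapes disagree (|A| far from 1) *and* the curves are far
apart (B large): identical, positively scaled, and sign-flipped curve
pairs all score 0, so the ranking isolates genuinely different temporal
responses rather than amplitude differences.

Two area conventions are provided.  The default, ``crossing``, is the
exact geometric area between the interpolants: segments where the
difference changes sign are split at the zero crossing.  The alternative,
``trapezoid_abs``, applies the trapezoid rule to the absolute endpoint
differences, which over-counts sign-crossing segments; it is exposed so
the two readings of "absolute area between the curves" can be compared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import OrthologMap, SchemaError
from .preprocess import NormalizedProfiles

__all__ = [
    "pearson_shape",
    "integrated_difference",
    "divergence_score",
    "score_all",
]


def pearson_shape(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Pearson correlation A between two curves on a shared grid.

    Requires >= 3 points.  If either curve has zero variance the
    correlation is undefined; by convention A := 0 so that a flat curve
    against a responsive one scores the full area rather than being
    dropped.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError(f"curves on mismatched grids: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 3:
        raise SchemaError("Pearson shape term needs >= 3 shared time points")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = float(da @ db) / np.sqrt(va * vb)
    return float(np.clip(r, -1.0, 1.0))


def integrated_difference(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    times: np.ndarray,
    method: str = "crossing",
) -> float:
    """Absolute area B between the piecewise-linear interpolants of two curves.

    ``crossing`` (default) splits each segment at any sign change of the
    difference, so B is the exact geometric area and B = 0 iff the curves
    agree at every grid point.  ``trapezoid_abs`` integrates the
    trapezoid of |difference| at the endpoints without splitting.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    t = np.asarray(times, dtype=float)
    if a.shape != b.shape or a.shape != t.shape:
        raise SchemaError("curves and times must have identical shapes")
    if a.ndim != 1 or len(a) < 2:
        raise SchemaError("area term needs >= 2 time points")
    if not np.all(np.diff(t) > 0):
        raise SchemaError("times must be strictly increasing")
    d = a - b
    d0, d1 = d[:-1], d[1:]
    dt = np.diff(t)
    if method == "trapezoid_abs":
        return float(np.sum(0.5 * (np.abs(d0) + np.abs(d1)) * dt))
    if method != "crossing":
        raise ValueError(f"unknown area method {method!r}")
    crossing = d0 * d1 < 0
    # no crossing: trapezoid of |d| is exact (|d| linear on the segment)
    plain = 0.5 * (np.abs(d0) + np.abs(d1)) * dt
    # crossing at tc = t0 + |d0|/(|d0|+|d1|) * dt: two triangles
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.abs(d0) / (np.abs(d0) + np.abs(d1))
    split = 0.5 * np.abs(d0) * frac * dt + 0.5 * np.abs(d1) * (1.0 - frac) * dt
    return float(np.sum(np.where(crossing, split, plain)))


def divergence_score(a: float, b: float) -> float:
    """score = (1 - |A|) x B."""
    if not (-1.0 <= a <= 1.0):
        raise ValueError(f"A must lie in [-1, 1], got {a}")
    if b < 0:
        raise ValueError(f"B must be non-negative, got {b}")
    return (1.0 - abs(a)) * b


def score_all(
    profiles_a: NormalizedProfiles,
    profiles_b: NormalizedProfiles,
    ortholog_map: OrthologMap,
    q: float = 75.0,
    *,
    include_baseline: bool = True,
    area_method: str = "crossing",
) -> pd.DataFrame:
    """Score every mapped, complete ortholog pair and flag the top tail.

    The cutoff is the ``q``-th percentile (linear interpolation) of all
    finite scores; a pair is flagged iff its score is strictly above the
    cutoff — mirroring a "scores > cutoff, corresponding to the q-th
    percentile" selection.  Rows are sorted by descending score, ties by
    the group-A feature id; ``rank`` is the dense rank of the score.

    ``include_baseline=False`` drops the t=0 point (0 in both curves by
    construction) from the Pearson term only; the area is always over the
    full grid.  Incomplete pairs are skipped and counted in the returned
    frame's ``attrs["n_skipped"]``.
    """
    if not np.array_equal(profiles_a.times, profiles_b.times):
        raise SchemaError("profile sets must share one time grid")
    times = profiles_a.times
    set_a = set(profiles_a.feature_ids)
    set_b = set(profiles_b.feature_ids)

    rows = []
    n_skipped = 0
    for fa, fb in ortholog_map.pairs.itertuples(index=False):
        if fa not in set_a or fb not in set_b:
            n_skipped += 1
            continue
        ca = profiles_a.curves.loc[fa].to_numpy()
        cb = profiles_b.curves.loc[fb].to_numpy()
        a_term = pearson_shape(
            ca if include_baseline else ca[1:],
            cb if include_baseline else cb[1:],
        )
        b_term = integrated_difference(ca, cb, times, method=area_method)
        rows.append(
            {"feature_a": fa, "feature_b": fb, "A": a_term, "B": b_term,
             "score": divergence_score(a_term, b_term)}
        )
    if not rows:
        raise SchemaError(
            "no complete ortholog pair found between the two profile sets"
        )
    table = pd.DataFrame(rows)
    cutoff = float(np.percentile(table["score"].to_numpy(), q))
    table["rank"] = table["score"].rank(method="dense", ascending=False).astype(int)
    table["cutoff"] = cutoff
    table["flagged"] = table["score"] > cutoff
    table = (
        table.sort_values(["score", "feature_a"], ascending=[False, True])
        .reset_index(drop=True)
    )
    table.attrs["n_skipped"] = n_skipped
    table.attrs["cutoff"] = cutoff
    return table
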