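"""Per-timepoint differential calls, temporal-profile clustering, overlap.

Differential testing is deliberately simple and self-contained: a Welch
two-sample t-test on log2(value + pseudocount), each time point against
the within-group baseline, with Benjamini-Hochberg adjustment across
features separately per (group, time) stratum.  This is a documented
stand-in for moderated count/intensity models (voom/limma-style): its
calls feed the same downstream set algebra (per-timepoint call sets,
cross-layer overlap through the ortholog map) without requiring those
model internals.

Clustering groups ortholog pairs by the concatenated two-group temporal
profile [curve_A || curve_B], z-scored per feature, using Ward linkage on
Euclidean distance; the tree is cut into k groups and labels are roman
numerals I..k ordered by decreasing cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data_model import OrthologMap, SchemaError, TimeCourseMatrix
from .preprocess import NormalizedProfiles

__all__ = [
    "per_timepoint_de",
    "bh_adjust",
    "ClusterAssignment",
    "cluster_profiles",
    "OverlapResult",
    "cross_layer_overlap",
]

#: Floor on the per-sample variance (log2 scale) so that replicate sets
#: with zero spread still yield a finite, extreme statistic.
VARIANCE_FLOOR = 1e-8


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1.

    Computes q_(i) = min_{j >= i} p_(j) * m / j literally (not the
    algebraically equivalent p / (j/m), which can differ in the last ulp).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, df and two-sided p with a variance floor.

    Returns (statistic, df, p).  When both samples are degenerate (zero
    variance) and the means are equal, the statistic is 0 and p = 1.
    """
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1 = max(x.var(ddof=1), VARIANCE_FLOOR)
    v2 = max(y.var(ddof=1), VARIANCE_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m2 - m1) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(max(p, np.finfo(float).tiny), 1.0))


def per_timepoint_de(
    matrix: TimeCourseMatrix,
    fdr_alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Test every feature at every non-baseline time against baseline.

    Welch t on log2(value + pseudocount) within each group; BH across
    features per (group, time).  Features with < 2 non-missing replicates
    on either side get NA statistics (not a run failure).  Returns one
    row per (feature, group, time) with columns ``effect`` (mean log2
    difference vs baseline), ``statistic``, ``df``, ``p``, ``q`` and
    ``called`` (q < fdr_alpha).
    """
    if not (0 < fdr_alpha < 1):
        raise ValueError(f"fdr_alpha must be in (0, 1), got {fdr_alpha}")
    logs = np.log2(matrix.values + pseudocount)
    out = []
    for group in matrix.samples.frame["group"].unique():
        times = matrix.samples.times(group)
        t0 = times[0]
        X = logs[matrix.samples.samples_at(group, t0)].to_numpy(dtype=float)
        for t in times[1:]:
            Y = logs[matrix.samples.samples_at(group, t)].to_numpy(dtype=float)
            frame = _welch_stratum(X, Y, logs.index, group, float(t))
            ok = frame["p"].notna()
            frame["q"] = np.nan
            if ok.any():
                frame.loc[ok, "q"] = bh_adjust(frame.loc[ok, "p"].to_numpy())
            frame["called"] = frame["q"] < fdr_alpha
            out.append(frame)
    return pd.concat(out, ignore_index=True)


def _welch_stratum(X, Y, index, group, time) -> pd.DataFrame:
    """Vectorized Welch tests of Y vs X per feature (rows), missing-aware."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof on tiny slices
        n1 = np.isfinite(X).sum(axis=1)
        n2 = np.isfinite(Y).sum(axis=1)
        m1, m2 = np.nanmean(X, axis=1), np.nanmean(Y, axis=1)
        v1 = np.maximum(np.nanvar(X, axis=1, ddof=1), VARIANCE_FLOOR)
        v2 = np.maximum(np.nanvar(Y, axis=1, ddof=1), VARIANCE_FLOOR)
        se2 = v1 / n1 + v2 / n2
        tstat = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = np.clip(2.0 * stats.t.sf(np.abs(tstat), df),
                    np.finfo(float).tiny, 1.0)
    bad = (n1 < 2) | (n2 < 2)
    degenerate = ~bad & (tstat == 0.0)
    p = np.where(degenerate, 1.0, p)
    for arr in (tstat, df, p):
        arr[bad] = np.nan
    effect = m2 - m1
    effect[bad] = np.nan
    return pd.DataFrame(
        {"feature_id": index, "group": group, "time": time,
         "effect": effect, "statistic": tstat, "df": df, "p": p}
    )


# ---------------------------------------------------------------------------
# Temporal-profile clustering


def _roman(n: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
                (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
                (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label per feature plus per-cluster mean profiles.

    ``labels`` maps the group-A feature id to a roman-numeral label;
    ``mean_profiles`` is indexed by (label, group) with one column per
    time point.
    """

    labels: pd.Series
    mean_profiles: pd.DataFrame
    k: int


def _as_curves(profiles) -> pd.DataFrame:
    if isinstance(profiles, NormalizedProfiles):
        return profiles.curves
    return profiles


def cluster_profiles(
    profiles_a,
    profiles_b,
    ortholog_map: OrthologMap,
    k: int = 4,
) -> ClusterAssignment:
    """Hierarchical (Ward) clustering of paired temporal profiles.

    Each mapped pair contributes the vector [curve_A || curve_B],
    z-scored per feature across its 2T entries (constant vectors map to
    all-zeros); Euclidean distance, Ward linkage, tree cut into ``k``
    groups.  Labels I..k are assigned by decreasing cluster size, ties by
    the lexicographically smallest member id, so the output is
    deterministic on identical input.
    """
    curves_a = _as_curves(profiles_a)
    curves_b = _as_curves(profiles_b)
    feats = []
    vecs = []
    for fa, fb in ortholog_map.pairs.itertuples(index=False):
        if fa in curves_a.index and fb in curves_b.index:
            feats.append(fa)
            vecs.append(
                np.concatenate([curves_a.loc[fa].to_numpy(),
                                curves_b.loc[fb].to_numpy()])
            )
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(feats):
        raise ValueError(f"k={k} exceeds the {len(feats)} complete mapped features")
    X = np.vstack(vecs)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if k == len(feats):
        raw = np.arange(1, k + 1)
    else:
        raw = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    raw_labels = pd.Series(raw, index=feats)

    # relabel by decreasing size; ties by smallest member id
    order = sorted(
        raw_labels.unique(),
        key=lambda c: (-int((raw_labels == c).sum()),
                       min(raw_labels.index[raw_labels == c])),
    )
    rename = {c: _roman(i + 1) for i, c in enumerate(order)}
    labels = raw_labels.map(rename).rename("cluster")

    times = list(curves_a.columns)
    b_of_a = ortholog_map.a_to_b
    mean_rows = {}
    for c in order:
        lab = rename[c]
        members = labels.index[labels == lab]
        mean_rows[(lab, "A")] = curves_a.loc[members].mean(axis=0).to_numpy()
        mean_rows[(lab, "B")] = curves_b.loc[[b_of_a[f] for f in members]].mean(axis=0).to_numpy()
    mean_profiles = pd.DataFrame.from_dict(mean_rows, orient="index", columns=times)
    mean_profiles.index = pd.MultiIndex.from_tuples(
        mean_profiles.index, names=["cluster", "group"]
    )
    return ClusterAssignment(labels=labels, mean_profiles=mean_profiles, k=k)


# ---------------------------------------------------------------------------
# Cross-layer overlap


@dataclass(frozen=True)
class OverlapResult:
    """Features called in both layers at one (group, time)."""

    group: str
    time: float
    n_rna: int
    n_protein: int
    n_overlap: int
    pairs: pd.DataFrame  # feature_a, feature_b for overlapping mapped features

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_rna, self.n_protein):
            raise ValueError("overlap exceeds a layer's call count")


def _called_set(de: pd.DataFrame, group: str, time: float) -> set[str]:
    sub = de[(de["group"] == group) & (de["time"] == float(time))]
    if sub.empty:
        raise SchemaError(f"(group={group!r}, time={time}) absent from DE table")
    return set(sub.loc[sub["called"].fillna(False), "feature_id"])


def cross_layer_overlap(
    rna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    ortholog_map: OrthologMap,
    group: str,
    time: float,
) -> OverlapResult:
    """Intersect RNA and protein call sets within one group at one time.

    Both layers of one group share a feature namespace; the overlap is a
    plain set intersection, and overlapping features are reported as
    ortholog pairs (group-A namespace first) where the map covers them.
    """
    rna_called = _called_set(rna_de, group, time)
    prot_called = _called_set(protein_de, group, time)
    overlap = rna_called & prot_called

    a_to_b = ortholog_map.a_to_b
    b_to_a = ortholog_map.b_to_a
    pair_rows = []
    for feat in sorted(overlap):
        if feat in a_to_b:
            pair_rows.append({"feature_a": feat, "feature_b": a_to_b[feat]})
        elif feat in b_to_a:
            pair_rows.append({"feature_a": b_to_a[feat], "feature_b": feat})
    return OverlapResult(
        group=group,
        time=float(time),
        n_rna=len(rna_called),
        n_protein=len(prot_called),
        n_overlap=len(overlap),
        pairs=pd.DataFrame(pair_rows, columns=["feature_a", "feature_b"]),
    )
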