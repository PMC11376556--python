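"""Replicate aggregation, baseline-anchored log2-ratio normalization, QC.

Every temporal curve is expressed relative to its own group's baseline:
``r_g(t) = log2(mean abundance at t / mean abundance at the minimum time
point)``, so the log2 ratio is 0 at the first time point by construction.
This anchoring removes static abundance offsets between the two groups so
that the divergence score compares response *shapes*, not expression
levels.

Replicates are aggregated on the raw scale (arithmetic mean by default,
median available) before the ratio.  RNA gets a pseudocount before the
ratio; protein intensities of 0 mean "not quantified", so features with a
zero or missing mean are flagged incomplete and excluded from scoring
rather than imputed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SchemaError, TimeCourseMatrix

__all__ = [
    "NormalizedProfiles",
    "QCReport",
    "normalize_to_baseline",
    "replicate_correlation_qc",
    "rna_protein_correlation",
]


@dataclass(frozen=True)
class NormalizedProfiles:
    """Per-feature baseline-anchored log2-ratio curves for one group.

    ``curves`` holds complete features only (finite everywhere, exactly 0
    at baseline); ``excluded`` records incomplete features with a reason.
    """

    group: str
    times: np.ndarray           # strictly increasing; times[0] is baseline
    curves: pd.DataFrame        # feature x time
    excluded: pd.DataFrame      # columns: feature_id, reason

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise SchemaError("time grid must be strictly increasing")
        if len(self.curves) and not np.allclose(self.curves.iloc[:, 0], 0.0, atol=0.0):
            raise SchemaError("log2 ratio at baseline must be exactly 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.curves.index)


def _aggregate(matrix: TimeCourseMatrix, aggregate: str) -> pd.DataFrame:
    """Per-(feature, time) aggregate over non-missing replicates."""
    group = matrix.group
    times = matrix.samples.times(group)
    cols = {}
    for t in times:
        sub = matrix.values[matrix.samples.samples_at(group, t)]
        agg = sub.mean(axis=1) if aggregate == "mean" else sub.median(axis=1)
        cols[float(t)] = agg  # NaN where every replicate is missing
    return pd.DataFrame(cols)


def normalize_to_baseline(
    matrix: TimeCourseMatrix,
    pseudocount: float = 0.0,
    aggregate: str = "mean",
) -> NormalizedProfiles:
    """Collapse replicates and anchor each curve at 0 at the baseline time.

    ``pseudocount`` is added to the aggregated value before the ratio
    (use the configured RNA pseudocount for counts; 0 for intensities).
    Features whose ratio is non-finite anywhere — e.g. a zero protein
    baseline, or a time point with all replicates missing — are excluded
    and reported, not imputed.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    group = matrix.group
    times = matrix.samples.times(group)
    if len(times) == 0:
        raise SchemaError(f"no samples for group {group!r}")
    for t in times:
        if not matrix.samples.samples_at(group, t):
            raise SchemaError(f"no replicates at (group={group!r}, time={t})")

    means = _aggregate(matrix, aggregate) + pseudocount
    baseline = means.iloc[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        curves = np.log2(means.div(baseline, axis=0))

    finite = np.isfinite(curves).all(axis=1)
    reasons = []
    for feat in curves.index[~finite]:
        if not np.isfinite(baseline.loc[feat]) or baseline.loc[feat] == 0:
            reason = "zero or missing baseline"
        elif means.loc[feat].isna().any():
            reason = "all replicates missing at a time point"
        else:
            reason = "zero abundance at a non-baseline time point"
        reasons.append({"feature_id": feat, "reason": reason})

    kept = curves.loc[finite].copy()
    kept.iloc[:, 0] = 0.0  # exact anchor (guards against -0.0 / rounding)
    return NormalizedProfiles(
        group=group,
        times=times,
        curves=kept,
        excluded=pd.DataFrame(reasons, columns=["feature_id", "reason"]),
    )


@dataclass(frozen=True)
class QCReport:
    """Replicate-reproducibility correlations.

    ``pairs``: one row per within-(group, time) sample pair with its
    Pearson r; ``summary``: the minimum r per (group, time).
    """

    pairs: pd.DataFrame    # group, time, sample_i, sample_j, r
    summary: pd.DataFrame  # group, time, min_r, n_pairs


def replicate_correlation_qc(
    matrix: TimeCourseMatrix,
    pseudocount: float = 1.0,
    log: bool = True,
) -> QCReport:
    """Pairwise Pearson correlation between replicates at each (group, time).

    Computed across features on ``log2(value + pseudocount)`` by default
    (``log=False`` gives raw-scale correlations).  A sample with zero
    variance across features yields ``NA`` for its pairs.
    """
    vals = matrix.values
    data = np.log2(vals + pseudocount) if log else vals
    rows = []
    any_pair = False
    for group in matrix.samples.frame["group"].unique():
        for t in matrix.samples.times(group):
            samples = matrix.samples.samples_at(group, t)
            for si, sj in itertools.combinations(samples, 2):
                any_pair = True
                x = data[si].to_numpy(dtype=float)
                y = data[sj].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() >= 2 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                else:
                    r = np.nan
                rows.append(
                    {"group": group, "time": float(t),
                     "sample_i": si, "sample_j": sj, "r": r}
                )
    if not any_pair:
        raise SchemaError("no (group, time) stratum has >= 2 replicates")
    pairs = pd.DataFrame(rows)
    summary = (
        pairs.groupby(["group", "time"], as_index=False)
        .agg(min_r=("r", "min"), n_pairs=("r", "size"))
    )
    return QCReport(pairs=pairs, summary=summary)


def rna_protein_correlation(
    rna: NormalizedProfiles,
    protein: NormalizedProfiles,
    min_features: int = 3,
) -> pd.DataFrame:
    """Per-timepoint Pearson r between RNA and protein log2 ratios.

    Both profile sets must be for the same group (same feature
    namespace); features are joined by id.  Returns one row per
    non-baseline time with columns ``time, r, n_features``; times with
    fewer than ``min_features`` joint features get ``NA`` and a warning.
    """
    if rna.group != protein.group:
        raise SchemaError(
            f"layers are from different groups: {rna.group!r} vs {protein.group!r}"
        )
    if not np.array_equal(rna.times, protein.times):
        raise SchemaError("RNA and protein profiles are on different time grids")
    common = rna.curves.index.intersection(protein.curves.index)
    rows = []
    for j, t in enumerate(rna.times):
        if j == 0:
            continue  # baseline column is identically 0 in both layers
        n = len(common)
        if n < min_features:
            warnings.warn(
                f"time {t}: only {n} joint features (<{min_features}); r set to NA"
            )
            rows.append({"time": float(t), "r": np.nan, "n_features": n})
            continue
        x = rna.curves.loc[common].iloc[:, j].to_numpy()
        y = protein.curves.loc[common].iloc[:, j].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"time": float(t), "r": r, "n_features": n})
    return pd.DataFrame(rows, columns=["time", "r", "n_features"])
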