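"""Domain types and readers/writers for every external format the pipeline touches.

All tabular I/O is tab-separated UTF-8 with a header row and a decimal
point; missing values are encoded as the literal ``NA``.  Feature
identifiers are case-sensitive opaque strings — no symbol normalization is
attempted, cross-group reconciliation goes through the ortholog map only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ParseError",
    "ConfigError",
    "SampleSheet",
    "TimeCourseMatrix",
    "OrthologMap",
    "GeneSetCollection",
    "AnalysisConfig",
    "read_sample_sheet",
    "read_matrix",
    "write_table",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gmt",
    "load_config",
]

NA_REP = "NA"


class SchemaError(ValueError):
    """A table's shape or column set violates its contract."""


class ParseError(ValueError):
    """A file's content cannot be interpreted in its declared dialect."""


class ConfigError(ValueError):
    """A configuration value is out of bounds."""


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample annotations: group, time (hours) and replicate.

    The full design must contain exactly two groups, each with a baseline
    (its minimum time point).  Views restricted to a subset of samples
    (e.g. the columns of a single-group matrix) may carry one group.
    """

    frame: pd.DataFrame  # columns: sample_id, group, time, replicate

    REQUIRED = ("sample_id", "group", "time", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise SchemaError(f"duplicate sample ids: {dups}")
        if (df["time"].astype(float) < 0).any():
            raise SchemaError("negative time values in sample sheet")
        if (df["replicate"].astype(int) < 1).any():
            raise SchemaError("replicate numbers must be positive integers")
        if df["group"].nunique() > 2:
            raise SchemaError(
                f"more than two groups: {sorted(df['group'].unique())}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, require_both_groups: bool = True) -> "SampleSheet":
        sheet = cls(frame.reset_index(drop=True).copy())
        if require_both_groups and sheet.frame["group"].nunique() != 2:
            raise SchemaError(
                "sample sheet must contain exactly two groups, got "
                f"{sorted(sheet.frame['group'].unique())}"
            )
        return sheet

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def baseline_time(self, group: str) -> float:
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise SchemaError(f"group {group!r} absent from sample sheet")
        return float(sub["time"].min())

    def times(self, group: str) -> np.ndarray:
        sub = self.frame[self.frame["group"] == group]
        return np.array(sorted(sub["time"].astype(float).unique()))

    def samples_at(self, group: str, time: float) -> list[str]:
        sub = self.frame[
            (self.frame["group"] == group)
            & (self.frame["time"].astype(float) == float(time))
        ]
        return list(sub["sample_id"])

    def restrict(self, sample_ids: Iterable[str]) -> "SampleSheet":
        wanted = list(sample_ids)
        unknown = set(wanted) - set(self.frame["sample_id"])
        if unknown:
            raise SchemaError(f"unknown sample ids: {sorted(unknown)}")
        sub = self.frame.set_index("sample_id").loc[wanted].reset_index()
        return SampleSheet(sub)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV (sample_id, group, time, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleSheet.from_frame(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TimeCourseMatrix


@dataclass
class TimeCourseMatrix:
    """One layer's feature-by-sample abundances with sample annotations.

    ``values`` rows are features, columns are samples, reordered to the
    sheet order.  Counts and intensities are non-negative; missing values
    (NA) are permitted and tracked per feature rather than imputed.
    """

    layer: str  # "rna" | "protein"
    values: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.layer not in ("rna", "protein"):
            raise SchemaError(f"unknown layer {self.layer!r}")
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise SchemaError(f"duplicate feature ids: {dups}")
        cols = list(self.values.columns)
        sheet_ids = self.samples.sample_ids
        extra = [c for c in cols if c not in set(sheet_ids)]
        if extra:
            raise SchemaError(
                f"matrix columns absent from the sample sheet: {extra}"
            )
        missing = [s for s in sheet_ids if s not in set(cols)]
        if missing:
            raise SchemaError(f"sample sheet rows absent from matrix: {missing}")
        # canonical column order = sheet order
        self.values = self.values[sheet_ids].astype(float)
        neg = self.values.lt(0)
        if neg.any().any():
            r, c = next(
                (f, s) for f in self.values.index for s in self.values.columns
                if neg.at[f, s]
            )
            raise ValueError(
                f"negative abundance at feature {r!r}, sample {c!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group(self) -> str:
        """The single group this matrix covers; error if ambiguous."""
        groups = self.samples.frame["group"].unique()
        if len(groups) != 1:
            raise SchemaError(
                f"matrix spans groups {sorted(groups)}; one group expected here"
            )
        return str(groups[0])

    def features_with_missing(self) -> list[str]:
        mask = self.values.isna().any(axis=1)
        return list(self.values.index[mask])


def read_matrix(path: str | Path, sheet: SampleSheet, layer: str) -> TimeCourseMatrix:
    """Read a feature-by-sample TSV into a validated :class:`TimeCourseMatrix`.

    The first column holds feature ids; remaining column names must each
    appear in ``sheet``.  Columns are reordered to sheet order.  ``NA`` is
    the only missing-value token.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False,
    )
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in set(sheet.sample_ids)]
    if unknown:
        raise SchemaError(
            f"matrix {path} has columns not in the sample sheet: {unknown}"
        )
    sub_sheet = sheet.restrict([s for s in sheet.sample_ids if s in set(df.columns)])
    return TimeCourseMatrix(layer=layer, values=df, samples=sub_sheet)


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = True) -> None:
    """Write a TSV at full float precision (shortest round-trip repr)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA_REP)


def write_matrix(matrix: TimeCourseMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    write_table(out, path)


# ---------------------------------------------------------------------------
# OrthologMap


@dataclass(frozen=True)
class OrthologMap:
    """Strictly one-to-one pairing between two feature namespaces."""

    pairs: pd.DataFrame  # columns: feature_a, feature_b
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.pairs
        if list(df.columns) != ["feature_a", "feature_b"]:
            raise SchemaError("ortholog map needs columns feature_a, feature_b")
        if df["feature_a"].duplicated().any() or df["feature_b"].duplicated().any():
            raise SchemaError("ortholog map is not one-to-one after validation")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["feature_a"], self.pairs["feature_b"]))

    @property
    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["feature_b"], self.pairs["feature_a"]))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        df = pd.DataFrame(list(pairs), columns=["feature_a", "feature_b"])
        return _validate_one_to_one(df)


def _validate_one_to_one(df: pd.DataFrame) -> OrthologMap:
    """Drop every row whose id participates in a many-to-many relation."""
    dup_a = df["feature_a"].duplicated(keep=False)
    dup_b = df["feature_b"].duplicated(keep=False)
    keep = ~(dup_a | dup_b)
    kept = df.loc[keep].reset_index(drop=True)
    return OrthologMap(pairs=kept, n_dropped=int((~keep).sum()))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a 2-column TSV of ortholog pairs, enforcing one-to-one.

    Rows whose id on either side occurs more than once are dropped and
    counted in ``n_dropped``.  An empty map after filtering is an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise SchemaError(
            f"ortholog map {path} must have exactly 2 columns, got {df.shape[1]}"
        )
    df.columns = ["feature_a", "feature_b"]
    omap = _validate_one_to_one(df)
    if len(omap) == 0:
        raise ParseError(
            f"ortholog map {path} is empty after one-to-one filtering "
            f"({omap.n_dropped} rows dropped)"
        )
    return omap


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: set_name TAB description TAB member1 TAB member2 ..."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, desc, *members = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# AnalysisConfig


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level thresholds; every pipeline constant lives here."""

    percentile_q: float = 75.0
    fdr_alpha: float = 0.05
    n_clusters: int = 4
    pseudocount_rna: float = 1.0
    seed: int = 42
    include_baseline_in_shape: bool = True
    area_method: str = "crossing"  # or "trapezoid_abs"
    aggregate: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not (0 < self.percentile_q <= 100):
            raise ConfigError(f"percentile_q must be in (0, 100], got {self.percentile_q}")
        if not (0 < self.fdr_alpha < 1):
            raise ConfigError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be positive, got {self.n_clusters}")
        if self.pseudocount_rna <= 0:
            raise ConfigError(f"pseudocount_rna must be positive, got {self.pseudocount_rna}")
        if self.area_method not in ("crossing", "trapezoid_abs"):
            raise ConfigError(f"unknown area_method {self.area_method!r}")
        if self.aggregate not in ("mean", "median"):
            raise ConfigError(f"unknown aggregate {self.aggregate!r}")


def load_config(path: str | Path) -> tuple[AnalysisConfig, dict]:
    """Load a YAML run config.

    Returns the validated :class:`AnalysisConfig` (from the ``analysis``
    section) and the full raw document (the ``synthetic`` section, if any,
    is interpreted by :mod:`tcdiv.synthetic`).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("analysis", {})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
    return AnalysisConfig(**section), raw
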