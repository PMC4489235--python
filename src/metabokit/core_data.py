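"""Concentration-table handling: read, validate, impute, filter, normalize, subset.

Every downstream analysis consumes a :class:`DataTable` produced here.  All
processing steps append a structured descriptor to ``DataTable.log`` so that a
processed table can be reproduced bit-for-bit from the raw table with
:func:`replay`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Minimum number of samples required per group level.
MIN_GROUP_SIZE = 3

#: Cell contents treated as missing values (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}

#: Constant total used by sum normalization.  Any positive constant yields
#: identical downstream statistics after scaling; 1000 keeps values readable.
SUM_NORM_CONSTANT = 1000.0

ROW_METHODS = ("none", "sum", "median")
TRANSFORMS = ("none", "log10", "cube_root")
SCALINGS = ("none", "auto", "pareto", "range")


class DataTableError(ValueError):
    """Raised for malformed inputs or contract violations on tables."""


@dataclass
class NormalizationSpec:
    """Three-stage normalization: per-sample row method, value transform,
    per-feature column scaling, applied in that order."""

    row_method: str = "none"
    transform: str = "none"
    scaling: str = "none"

    def __post_init__(self) -> None:
        if self.row_method not in ROW_METHODS:
            raise DataTableError(f"row_method must be one of {ROW_METHODS}")
        if self.transform not in TRANSFORMS:
            raise DataTableError(f"transform must be one of {TRANSFORMS}")
        if self.scaling not in SCALINGS:
            raise DataTableError(f"scaling must be one of {SCALINGS}")


@dataclass
class DataTable:
    """Numeric sample-by-feature concentration matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame with samples in rows and features in columns; ``NaN``
        encodes missing values before imputation.
    group
        Categorical group label per sample (index-aligned with ``values``).
    factor2
        Optional second factor (e.g. time point) per sample.
    log
        Ordered list of processing-step descriptors (dicts with an ``op``
        key plus that step's parameters).
    non_numeric
        Cells whose raw content was neither numeric nor a missing token,
        recorded as ``(sample_id, feature_id, raw_text)``.
    """

    values: pd.DataFrame
    group: pd.Series
    factor2: pd.Series | None = None
    log: list = field(default_factory=list)
    non_numeric: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataTableError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise DataTableError("duplicate feature ids")
        self.group = self.group.reindex(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def group_levels(self) -> list:
        return sorted(self.group.dropna().unique().tolist())

    def copy(self) -> "DataTable":
        return DataTable(
            values=self.values.copy(),
            group=self.group.copy(),
            factor2=None if self.factor2 is None else self.factor2.copy(),
            log=list(self.log),
            non_numeric=list(self.non_numeric),
        )

    def with_values(self, values: pd.DataFrame, log_entry: dict) -> "DataTable":
        """Return a copy carrying new values and one appended log entry."""
        out = self.copy()
        out.values = values
        out.log.append(log_entry)
        return out

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "Label", self.group.values)
        if self.factor2 is not None:
            out.insert(1, "Time", self.factor2.values)
        out.to_csv(path, index_label="Sample")


@dataclass
class IntegrityReport:
    n_samples: int
    n_features: int
    n_missing: int
    offending_cells: list
    group_counts: dict
    passed: bool

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "n_missing": self.n_missing,
            "offending_cells": [list(c) for c in self.offending_cells],
            "group_counts": dict(self.group_counts),
            "passed": bool(self.passed),
        }


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_table(path, orientation: str = "rows", has_factor2: bool = False) -> DataTable:
    """Read a CSV/TSV concentration table into a :class:`DataTable`.

    ``orientation='rows'`` expects samples in rows with a ``Label`` column
    (and optionally a ``Time`` column); ``orientation='columns'`` expects the
    transposed layout (samples in columns, a ``Label`` row).  The returned
    table always has samples in rows.  Non-numeric cells other than the
    missing tokens are recorded in ``non_numeric``, not silently coerced.
    """
    if orientation not in ("rows", "columns"):
        raise DataTableError("orientation must be 'rows' or 'columns'")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    sep = _sniff_delimiter(text)
    raw = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    if orientation == "columns":
        raw = raw.T
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise DataTableError("duplicate sample or feature ids in input")

    label_col = next((c for c in raw.columns if c.strip().lower() == "label"), None)
    if label_col is None:
        raise DataTableError("no 'Label' row/column found")
    group = raw[label_col].astype(str).str.strip()
    meta_cols = [label_col]

    factor2 = None
    if has_factor2:
        time_col = next((c for c in raw.columns if c.strip().lower() == "time"), None)
        if time_col is None:
            raise DataTableError("has_factor2=True but no 'Time' row/column found")
        factor2 = raw[time_col].astype(str).str.strip()
        meta_cols.append(time_col)

    data = raw.drop(columns=meta_cols)
    data.index.name = None
    data.columns.name = None
    values = pd.DataFrame(np.nan, index=data.index, columns=data.columns)
    non_numeric = []
    for col in data.columns:
        cell = data[col].astype(str).str.strip()
        num = pd.to_numeric(cell, errors="coerce")
        values[col] = num.astype(float)
        bad = num.isna() & ~cell.str.lower().isin(MISSING_TOKENS)
        for sid in data.index[bad]:
            non_numeric.append((sid, col, data.at[sid, col]))
    dt = DataTable(values=values, group=group, factor2=factor2,
                   non_numeric=non_numeric)
    dt.log.append({"op": "read_table", "orientation": orientation,
                   "has_factor2": bool(has_factor2)})
    return dt


# ---------------------------------------------------------------------------
# Integrity
# ---------------------------------------------------------------------------

def check_integrity(dt: DataTable, min_group_size: int = MIN_GROUP_SIZE) -> IntegrityReport:
    """Validate a loaded table; never raises, always returns a report.

    The check fails when any group has fewer than ``min_group_size`` samples,
    when a feature is entirely missing, or when non-numeric cells exist.
    """
    offending = []
    for sid, fid, raw in dt.non_numeric:
        offending.append((sid, fid, f"non-numeric value {raw!r}"))
    all_missing = dt.values.columns[dt.values.isna().all(axis=0)]
    for fid in all_missing:
        offending.append(("*", fid, "feature entirely missing"))
    counts = dt.group.value_counts().to_dict()
    groups_ok = len(counts) >= 2 and all(c >= min_group_size for c in counts.values())
    passed = groups_ok and not offending
    return IntegrityReport(
        n_samples=dt.n_samples,
        n_features=dt.n_features,
        n_missing=int(dt.values.isna().sum().sum()),
        offending_cells=offending,
        group_counts=counts,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing(dt: DataTable, method: str = "half_min", k: int = 10) -> DataTable:
    """Replace missing values; default replaces with half the feature minimum.

    ``half_min`` is the long-standing default for left-censored metabolomics
    data: a value below the detection limit is represented by half of the
    smallest positive observed concentration of that feature.  ``knn``
    averages the feature over the ``k`` nearest samples by Euclidean distance
    across co-observed features.
    """
    if method not in ("half_min", "mean", "median", "knn"):
        raise DataTableError(f"unknown imputation method {method!r}")
    vals = dt.values.copy()
    warnings = []
    if vals.isna().any().any():
        if method == "half_min":
            pos = vals.where(vals > 0)
            global_half = pos.min().min() / 2.0 if pos.notna().any().any() else np.nan
            for col in vals.columns:
                if not vals[col].isna().any():
                    continue
                col_pos = pos[col].min()
                if pd.isna(col_pos):
                    fill = global_half
                    warnings.append(
                        f"feature {col!r} has no positive observed value; "
                        "used global half-minimum")
                else:
                    fill = col_pos / 2.0
                vals[col] = vals[col].fillna(fill)
        elif method == "mean":
            vals = vals.fillna(vals.mean(axis=0))
        elif method == "median":
            vals = vals.fillna(vals.median(axis=0))
        else:  # knn
            vals = _knn_impute(vals, k=min(k, dt.n_samples - 1))
    entry = {"op": "impute_missing", "method": method, "k": int(k)}
    if warnings:
        entry["warnings"] = warnings
    return dt.with_values(vals, entry)


def _knn_impute(values: pd.DataFrame, k: int) -> pd.DataFrame:
    """KNN over samples: distance on co-observed features, mean of the k
    nearest samples that observed the feature; feature-mean fallback."""
    x = values.to_numpy(dtype=float)
    n = x.shape[0]
    out = x.copy()
    col_means = np.nanmean(x, axis=0)
    for i in range(n):
        miss = np.isnan(x[i])
        if not miss.any():
            continue
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not shared.any():
                continue
            # mean squared difference keeps distances comparable across
            # pairs with different numbers of co-observed features
            dists[j] = np.sqrt(np.mean((x[i, shared] - x[j, shared]) ** 2))
        order = np.argsort(dists, kind="stable")
        for fidx in np.where(miss)[0]:
            donors = [j for j in order if np.isfinite(dists[j])
                      and not np.isnan(x[j, fidx])][:k]
            if donors:
                out[i, fidx] = np.mean(x[donors, fidx])
            else:
                out[i, fidx] = col_means[fidx]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

#: Fraction of identical values above which a feature counts as near-constant.
NEAR_CONSTANT_FRACTION = 0.95


def filter_features(dt: DataTable, method: str = "iqr",
                    drop_fraction: float = 0.0) -> DataTable:
    """Drop low-information features by a dispersion statistic.

    Removes the ``floor(drop_fraction * n_features)`` features with the
    smallest dispersion (``iqr``, ``sd`` or ``mad``); ``near_constant``
    instead drops features identical in more than 95% of samples.  Ties are
    broken by feature id so the result is stable.
    """
    if not 0 <= drop_fraction < 1:
        raise DataTableError("drop_fraction must be in [0, 1)")
    vals = dt.values
    if method == "near_constant":
        frac_modal = vals.apply(
            lambda c: c.value_counts(dropna=False).iloc[0] / len(c), axis=0)
        keep = frac_modal[frac_modal <= NEAR_CONSTANT_FRACTION].index
    elif method in ("iqr", "sd", "mad"):
        if method == "iqr":
            disp = vals.quantile(0.75) - vals.quantile(0.25)
        elif method == "sd":
            disp = vals.std(ddof=1)
        else:
            med = vals.median()
            disp = (vals - med).abs().median()
        n_drop = int(np.floor(drop_fraction * dt.n_features))
        order = sorted(vals.columns, key=lambda c: (disp[c], str(c)))
        keep = [c for c in vals.columns if c not in set(order[:n_drop])]
    else:
        raise DataTableError(f"unknown filter method {method!r}")
    if len(keep) == 0:
        raise DataTableError("filtering would remove all features")
    out = dt.copy()
    out.values = vals[list(keep)]
    out.log.append({"op": "filter_features", "method": method,
                    "drop_fraction": float(drop_fraction)})
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(dt: DataTable, spec: NormalizationSpec) -> DataTable:
    """Apply row normalization, transform, then column scaling.

    Zeros (or negatives rounded to zero) before a log transform are offset by
    half the smallest positive matrix value rather than failing; zero-variance
    features under auto/pareto/range scaling are left centered.  Both events
    are recorded in the log.
    """
    vals = dt.values.copy()
    notes = []

    if spec.row_method == "sum":
        totals = vals.sum(axis=1)
        vals = vals.div(totals, axis=0) * SUM_NORM_CONSTANT
    elif spec.row_method == "median":
        vals = vals.div(vals.median(axis=1), axis=0)

    if spec.transform == "log10":
        arr = vals.to_numpy(dtype=float)
        pos = arr[arr > 0]
        if pos.size == 0:
            raise DataTableError("log10 transform requires positive values")
        if (arr <= 0).any():
            offset = pos.min() / 2.0
            arr = np.where(arr <= 0, arr + offset, arr)
            notes.append(f"log10 zero-offset {offset!r} applied")
            if (arr <= 0).any():
                raise DataTableError("negative values remain after log offset")
        vals = pd.DataFrame(np.log10(arr), index=vals.index, columns=vals.columns)
    elif spec.transform == "cube_root":
        vals = pd.DataFrame(np.cbrt(vals.to_numpy(dtype=float)),
                            index=vals.index, columns=vals.columns)

    if spec.scaling != "none":
        centered = vals - vals.mean(axis=0)
        sd = vals.std(ddof=1)
        if spec.scaling == "auto":
            denom = sd
        elif spec.scaling == "pareto":
            denom = np.sqrt(sd)
        else:  # range
            denom = vals.max(axis=0) - vals.min(axis=0)
        zero = denom == 0
        if zero.any():
            notes.append("zero-variance features left centered: "
                         + ", ".join(map(str, denom.index[zero])))
        denom = denom.mask(zero, 1.0)
        vals = centered / denom

    entry = {"op": "normalize", "row_method": spec.row_method,
             "transform": spec.transform, "scaling": spec.scaling}
    if notes:
        entry["notes"] = notes
    return dt.with_values(vals, entry)


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def exclude(dt: DataTable, samples=(), features=(), groups=()) -> DataTable:
    """Remove named samples, features, or (for multi-group data) groups.

    Group exclusion is only permitted when the table has more than two group
    levels.  The operation refuses to leave fewer than two groups or any
    group smaller than the minimum group size.
    """
    samples, features, groups = list(samples), list(features), list(groups)
    missing = [s for s in samples if s not in dt.values.index]
    missing += [f for f in features if f not in dt.values.columns]
    missing += [g for g in groups if g not in dt.group_levels()]
    if missing:
        raise DataTableError(f"unknown ids/labels: {missing}")
    if groups and len(dt.group_levels()) <= 2:
        raise DataTableError("group exclusion is only available for multi-group data")

    keep_samples = [s for s in dt.values.index
                    if s not in set(samples) and dt.group[s] not in set(groups)]
    keep_features = [f for f in dt.values.columns if f not in set(features)]
    new_group = dt.group.loc[keep_samples]
    counts = new_group.value_counts()
    if len(counts) < 2:
        raise DataTableError("exclusion would leave fewer than 2 groups")
    if (counts < MIN_GROUP_SIZE).any():
        small = counts[counts < MIN_GROUP_SIZE].index.tolist()
        raise DataTableError(f"exclusion would leave groups below minimum size: {small}")

    out = DataTable(
        values=dt.values.loc[keep_samples, keep_features],
        group=new_group,
        factor2=None if dt.factor2 is None else dt.factor2.loc[keep_samples],
        log=list(dt.log),
        non_numeric=[c for c in dt.non_numeric
                     if c[0] in set(keep_samples) and c[1] in set(keep_features)],
    )
    out.log.append({"op": "exclude", "samples": samples,
                    "features": features, "groups": groups})
    return out


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

def replay(raw: DataTable, log: list) -> DataTable:
    """Re-apply logged processing steps to a raw table.

    Applying the full log of a processed table to the corresponding raw table
    reproduces the processed table bit-for-bit.
    """
    dt = raw
    for entry in log:
        op = entry["op"]
        if op in ("read_table", "fixture"):
            continue  # provenance entries, not transformations
        if op == "impute_missing":
            dt = impute_missing(dt, method=entry["method"], k=entry["k"])
        elif op == "filter_features":
            dt = filter_features(dt, method=entry["method"],
                                 drop_fraction=entry["drop_fraction"])
        elif op == "normalize":
            dt = normalize(dt, NormalizationSpec(entry["row_method"],
                                                 entry["transform"],
                                                 entry["scaling"]))
        elif op == "exclude":
            dt = exclude(dt, samples=entry["samples"],
                         features=entry["features"], groups=entry["groups"])
        else:
            raise DataTableError(f"cannot replay unknown op {op!r}")
    return dt
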