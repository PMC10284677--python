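"""The master table: joined per-sample metadata and feature measurements.

Both analysis drivers consume a single object holding, per sample: the
individual (donor) it came from, its time value, any covariate columns, and
the feature matrix of one declared data type (count, proportion, binary,
ordinal or continuous).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DATA_TYPES = ("count", "proportion", "binary", "ordinal", "continuous")


@dataclass
class MasterTable:
    """Joined sample metadata + feature matrix keyed by sample ID.

    Parameters
    ----------
    data : DataFrame indexed by sample ID containing the individual column,
        the time column, covariate columns, and feature columns.
    individual_col, time_col : column names of the donor label and the time
        variable.
    feature_cols : ordered feature column names.
    data_type : declared type of every feature column.
    covariate_types : mapping covariate -> "categorical" | "continuous";
        unlisted covariates are inferred (non-numeric -> categorical).
    """

    data: pd.DataFrame
    individual_col: str
    time_col: str
    feature_cols: list
    data_type: str
    covariate_types: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_cols = list(self.feature_cols)
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def covariate_cols(self):
        reserved = {self.individual_col, self.time_col, *self.feature_cols}
        return [c for c in self.data.columns if c not in reserved]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_cols]

    @property
    def individuals(self) -> pd.Series:
        return self.data[self.individual_col]

    @property
    def time(self) -> pd.Series:
        return self.data[self.time_col]

    def covariate_type(self, name) -> str:
        if name in self.covariate_types:
            return self.covariate_types[name]
        return "continuous" if pd.api.types.is_numeric_dtype(self.data[name]) \
            else "categorical"

    def time_levels(self):
        """Sorted unique time values, the ordered levels of disc mode."""
        return np.sort(self.data[self.time_col].unique())

    # -- validation --------------------------------------------------------
    def validate(self):
        df = self.data
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        for col in (self.individual_col, self.time_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        missing = [c for c in self.feature_cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        if len(set(self.feature_cols)) != len(self.feature_cols):
            raise ValueError("feature names must be unique")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if not pd.api.types.is_numeric_dtype(df[self.time_col]):
            raise ValueError("time column must be numeric")
        pair = df[[self.individual_col, self.time_col]]
        if pair.duplicated().any():
            raise ValueError("duplicate (individual, time) pairs")
        if self.individual_col in self.covariate_cols or \
                self.time_col in self.covariate_cols:
            raise ValueError("covariates may not duplicate the time or "
                             "individual columns")
        self._check_feature_values()

    def _check_feature_values(self):
        feats = self.data[self.feature_cols]
        for name in self.feature_cols:
            v = feats[name].to_numpy()
            if not np.issubdtype(np.asarray(v).dtype, np.number):
                raise ValueError(f"feature {name!r} is non-numeric")
            if np.any(~np.isfinite(np.asarray(v, dtype=float))):
                raise ValueError(f"feature {name!r} contains non-finite values")
            if self.data_type == "count":
                if np.any(v < 0) or np.any(v != np.round(v)):
                    raise ValueError(
                        f"feature {name!r} violates data_type=count "
                        "(values must be non-negative integers)")
            elif self.data_type == "proportion":
                if np.any(v < 0) or np.any(v > 1):
                    raise ValueError(
                        f"feature {name!r} violates data_type=proportion "
                        "(values must lie in [0, 1])")
            elif self.data_type == "binary":
                if not np.all(np.isin(v, (0, 1))):
                    raise ValueError(
                        f"feature {name!r} violates data_type=binary")
            elif self.data_type == "ordinal":
                if np.any(v != np.round(v)):
                    raise ValueError(
                        f"feature {name!r} violates data_type=ordinal "
                        "(values must be integers)")


def _drop_single_timepoint(df, individual_col, time_col):
    counts = df.groupby(individual_col)[time_col].nunique()
    keep = counts[counts >= 2].index
    dropped = counts[counts < 2].index.tolist()
    if dropped:
        msg = (f"dropping {len(dropped)} individual(s) with < 2 time points: "
               f"{dropped}")
        warnings.warn(msg)
        logger.warning(msg)
    return df[df[individual_col].isin(keep)]


def make_master_table(metadata: pd.DataFrame, features: pd.DataFrame,
                      individual_col: str, time_col: str, data_type: str,
                      covariate_types: dict | None = None) -> MasterTable:
    """Inner-join metadata and feature tables on sample ID.

    Both inputs must be indexed by sample ID; the feature table's samples must
    be a subset of the metadata's. Individuals observed at fewer than two
    distinct time values are dropped with a warning.
    """
    if metadata.index.has_duplicates:
        raise ValueError("metadata has duplicate sample IDs")
    if features.index.has_duplicates:
        raise ValueError("feature table has duplicate sample IDs")
    extra = features.index.difference(metadata.index)
    if len(extra):
        raise ValueError(f"feature-table samples missing from metadata: "
                         f"{extra.tolist()}")
    joined = metadata.join(features, how="inner")
    joined = _drop_single_timepoint(joined, individual_col, time_col)
    return MasterTable(joined, individual_col, time_col,
                       list(features.columns), data_type,
                       covariate_types or {})


def write_master_table(table: MasterTable, path, sep="\t"):
    """Write the joined table as delimited text, sample IDs in the first column."""
    table.data.to_csv(path, sep=sep, index_label="sample_id")


def read_master_table(path, individual_col, time_col, data_type,
                      feature_cols=None, covariate_types=None,
                      sep=None) -> MasterTable:
    """Read a master table from TSV/CSV.

    If ``feature_cols`` is omitted, every numeric column other than the
    individual and time columns is treated as a feature (i.e. no covariates).
    The delimiter is inferred from the filename unless ``sep`` is given.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in (individual_col, time_col):
        if col not in df.columns:
            raise ValueError(f"input file is missing column {col!r}")
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c not in (individual_col, time_col)
                        and pd.api.types.is_numeric_dtype(df[c])]
    missing = [c for c in feature_cols if c not in df.columns]
    if missing:
        raise ValueError(f"input file is missing feature columns: {missing}")
    for name in feature_cols:
        if not pd.api.types.is_numeric_dtype(df[name]):
            bad = df[name][pd.to_numeric(df[name], errors="coerce").isna()]
            raise ValueError(
                f"unparseable numeric cell(s) in column {name!r}, "
                f"row(s) {bad.index.tolist()}")
    df = _drop_single_timepoint(df, individual_col, time_col)
    return MasterTable(df, individual_col, time_col, list(feature_cols),
                       data_type, covariate_types or {})


__all__ = ["MasterTable", "make_master_table", "read_master_table",
           "write_master_table", "DATA_TYPES"]
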