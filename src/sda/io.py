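"""Reading feature tables and covariates, and running tests table-wide.

Abundance tables are features x samples (first column feature_id, header
of sample ids); covariate tables are one row per sample.  Both are plain
TSV/CSV with the delimiter inferred from the file extension.  Zeros are
literal ``0`` values — the model treats them as data, and missing
measurements are not supported.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .baselines import TwoGroupFeature, two_part_t, two_part_wilcoxon
from .core import DesignMatrix, FeatureVector, fit_feature, lrt_test
from .multiplicity import storey_qvalues

__all__ = ["read_abundance", "read_covariates", "run_test", "run_baselines",
           "write_results", "read_results"]

logger = logging.getLogger("sda")

RESULT_COLUMNS = ["feature_id", "mode", "gamma0_hat", "gamma_hat_q", "beta_hat_q",
                  "h", "lrt", "df", "pvalue", "qvalue", "flags"]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_abundance(path) -> pd.DataFrame:
    """Read and validate a features x samples abundance table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty abundance table")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric cell at feature {bad[0]!r}, sample {col!r}")
        df[col] = numeric
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(f"{path}: negative abundance at feature {df.index[g]!r}, "
                         f"sample {df.columns[s]!r}")
    df.index.name = "feature_id"
    return df


def read_covariates(path, test_var: str, sample_order=None) -> DesignMatrix:
    """Read a per-sample covariate table into a design matrix.

    Categorical columns are one-hot encoded with the first sorted level as
    the reference; a binary categorical test variable therefore becomes a
    single 0/1 column (beta is the log fold change of the second sorted
    level over the first).  Rows are reordered to ``sample_order`` when
    given; samples missing from either table are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if test_var not in df.columns:
        raise ValueError(f"{path}: test variable {test_var!r} not found "
                         f"(columns: {list(df.columns)})")
    if sample_order is not None:
        sample_order = [str(s) for s in sample_order]
        missing = sorted(set(sample_order) - set(df.index))
        if missing:
            raise ValueError(f"{path}: samples missing from covariates: {missing[:5]}")
        extra = sorted(set(df.index) - set(sample_order))
        if extra:
            raise ValueError(f"{path}: covariate samples absent from abundance: {extra[:5]}")
        df = df.loc[sample_order]

    columns = []
    names = []
    test_name = None
    for col in df.columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            columns.append(series.to_numpy(dtype=float))
            names.append(col)
            if col == test_var:
                test_name = col
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"{path}: covariate {col!r} is constant")
            if col == test_var and len(levels) > 2:
                raise ValueError(f"{path}: test variable {col!r} has {len(levels)} levels; "
                                 "only binary test variables are supported")
            for level in levels[1:]:
                columns.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{col}[{level}]")
                if col == test_var:
                    test_name = names[-1]
    X = np.column_stack(columns)
    test_index = names.index(test_name if test_name is not None else test_var)
    if np.ptp(X[:, test_index]) == 0:
        raise ValueError(f"{path}: test covariate {test_var!r} is constant across samples")
    return DesignMatrix(X=X, test_index=test_index,
                        sample_ids=list(df.index), covariate_names=names)


def run_test(abundance: pd.DataFrame, design: DesignMatrix,
             bandwidth_scale: float = 1.144) -> pd.DataFrame:
    """Run the two-part semi-parametric LRT on every feature of a table.

    Per-feature failures are logged and recorded as ``skipped`` rows rather
    than aborting the run; q-values are computed over the non-missing
    p-values only.  Deterministic given inputs and options.
    """
    if abundance.shape[1] != design.n_samples:
        raise ValueError("abundance and covariates have mismatched sample counts")
    rows = []
    n_failed = 0
    for feature_id, values in abundance.iterrows():
        try:
            feature = FeatureVector(feature_id=str(feature_id),
                                    y=values.to_numpy(dtype=float))
            res = lrt_test(fit_feature(feature, design), design)
        except Exception as exc:  # noqa: BLE001 - per-feature isolation
            n_failed += 1
            logger.warning("feature %s failed: %s", feature_id, exc)
            rows.append({"feature_id": str(feature_id), "mode": "skipped",
                         "gamma0_hat": np.nan, "gamma_hat_q": np.nan,
                         "beta_hat_q": np.nan, "h": np.nan, "lrt": np.nan,
                         "df": 0, "pvalue": np.nan, "flags": f"error:{exc}"})
            continue
        rows.append({"feature_id": res.feature_id, "mode": res.mode,
                     "gamma0_hat": res.gamma0_hat, "gamma_hat_q": res.gamma_hat_q,
                     "beta_hat_q": res.beta_hat_q, "h": res.h, "lrt": res.lrt,
                     "df": res.df, "pvalue": res.pvalue,
                     "flags": ";".join(res.flags)})
    table = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "qvalue"])
    if table["pvalue"].notna().sum() == 0:
        raise ValueError("no testable features in the input")
    table["qvalue"] = storey_qvalues(table["pvalue"].to_numpy())
    table = table[RESULT_COLUMNS]
    n_sep = table["flags"].str.contains("separated").sum()
    logger.info("tested %d features (%d skipped/failed, %d separated zero parts)",
                len(table), int((table["mode"] == "skipped").sum()), int(n_sep))
    return table


def run_baselines(abundance: pd.DataFrame, design: DesignMatrix,
                  methods=("2t", "2w")) -> pd.DataFrame:
    """Run the two-part t and/or Wilcoxon baselines on every feature.

    Requires a binary (0/1) test covariate; rows with value 0 form group 0.
    """
    x = design.X[:, design.test_index]
    levels = np.unique(x)
    if levels.size != 2:
        raise ValueError("baselines require a binary test covariate")
    mask1 = x == levels[1]
    rows = []
    runners = {"2t": two_part_t, "2w": two_part_wilcoxon}
    unknown = set(methods) - set(runners)
    if unknown:
        raise ValueError(f"unknown baseline methods: {sorted(unknown)}")
    for feature_id, values in abundance.iterrows():
        y = values.to_numpy(dtype=float)
        feat = TwoGroupFeature(y0=y[~mask1], y1=y[mask1])
        row = {"feature_id": str(feature_id)}
        for name in methods:
            res = runners[name](feat)
            row[f"{name}_x2"] = res.x2
            row[f"{name}_df"] = res.df
            row[f"{name}_pvalue"] = res.pvalue
        rows.append(row)
    table = pd.DataFrame(rows)
    for name in methods:
        table[f"{name}_qvalue"] = storey_qvalues(table[f"{name}_pvalue"].to_numpy())
    return table


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV/CSV; numeric fields round-trip to full
    double precision."""
    path = Path(path)
    table.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path))
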