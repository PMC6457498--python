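"""Tidy tabular containers exchanged between pipeline stages.

Two tables travel through the pipeline, both as tidy :class:`pandas.DataFrame`
objects with columns ``subject_id, tract, metric, value``:

* **ROI metric table** — per-subject, per-tract mean of a scalar diffusion
  metric (FA dimensionless, MD/AD/RD in mm^2/s).
* **Z-score table** — the same layout after normative standardisation;
  ``value`` holds the Z-score.

Missing entries are explicit ``NaN`` rows, never silently dropped: a tract
whose ROI mean could not be computed (too few skeleton voxels, degenerate
control SD, noisy fit) keeps its row.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .tracts import JHU_TRACTS, METRICS

TABLE_COLUMNS = ("subject_id", "tract", "metric", "value")


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check tidy-table structure and return the frame unchanged."""
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"table missing required columns: {sorted(missing)}")
    if df.duplicated(subset=["subject_id", "tract", "metric"]).any():
        raise ValueError("duplicate (subject_id, tract, metric) cells")
    present = df["value"].dropna()
    if not np.isfinite(present.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values present; use NaN for missing")
    return df


def make_table(values: np.ndarray, subjects, tracts, metric: str) -> pd.DataFrame:
    """Build a tidy table from a (n_subjects, n_tracts) array for one metric."""
    values = np.asarray(values, dtype=float)
    n_s, n_t = values.shape
    if n_s != len(subjects) or n_t != len(tracts):
        raise ValueError("array shape does not match subject/tract labels")
    return pd.DataFrame(
        {
            "subject_id": np.repeat(list(subjects), n_t),
            "tract": np.tile(list(tracts), n_s),
            "metric": metric,
            "value": values.ravel(),
        }
    )


def to_wide(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot one metric to a tract x subject frame (rows ordered as in input)."""
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise KeyError(f"metric {metric!r} not present")
    tract_order = sub["tract"].drop_duplicates().tolist()
    wide = sub.pivot(index="tract", columns="subject_id", values="value")
    return wide.reindex(tract_order)


def bivariate_array(
    df: pd.DataFrame, metrics: tuple[str, str] = ("FA", "MD")
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack two metrics into a (n_tracts, n_subjects, 2) array.

    Returns ``(x, tract_names, subject_ids)``; missing cells are NaN.
    """
    wides = [to_wide(df, m) for m in metrics]
    if not wides[0].index.equals(wides[1].index) or not wides[0].columns.equals(
        wides[1].columns
    ):
        common_t = wides[0].index.intersection(wides[1].index)
        common_s = wides[0].columns.intersection(wides[1].columns)
        wides = [w.loc[common_t, common_s] for w in wides]
    x = np.stack([w.to_numpy(dtype=float) for w in wides], axis=-1)
    return x, list(wides[0].index), list(wides[0].columns)


# ---------------------------------------------------------------------------
# file IO


def read_table_csv(path) -> pd.DataFrame:
    # leading '#' lines carry run provenance (seed, config hash)
    return validate_table(pd.read_csv(path, comment="#"))


def write_table_csv(df: pd.DataFrame, path) -> None:
    validate_table(df).to_csv(path, index=False)


def write_xlsx(df: pd.DataFrame, path, missing_token: str = "X") -> None:
    """Write one sheet per metric: rows = tracts, columns = subjects.

    Missing cells are written as the literal token (default ``"X"``), the
    convention used in deposited Z-score workbooks.
    """
    validate_table(df)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for metric in df["metric"].drop_duplicates():
            wide = to_wide(df, metric)
            wide.astype(object).where(wide.notna(), missing_token).to_excel(
                xl, sheet_name=metric
            )


def read_xlsx(path, missing_token: str = "X") -> pd.DataFrame:
    """Read a one-sheet-per-metric workbook back into a tidy table."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    frames = []
    for metric, wide in sheets.items():
        wide = wide.apply(pd.to_numeric, errors="coerce")
        long = wide.reset_index().melt(
            id_vars=wide.index.name or "tract",
            var_name="subject_id",
            value_name="value",
        )
        long.columns = ["tract", "subject_id", "value"]
        long["metric"] = metric
        frames.append(long[list(TABLE_COLUMNS)])
    return validate_table(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# bundled in-study fixture


def _patient6_frame() -> pd.DataFrame:
    with resources.files("tractmix.data").joinpath("patient6_zscores.csv").open() as fh:
        return pd.read_csv(fh)


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Return the bundled single-patient Z-score table.

    The package ships the published per-tract Z-scores of one locked-in
    syndrome patient ("patient 6") over the 48 atlas tracts, as a ready-made
    real-data fixture.  ``name`` selects the metric pair:
    ``"patient6_FA_MD"`` or ``"patient6_AD_RD"``.
    """
    pairs = {"patient6_FA_MD": ("FA", "MD"), "patient6_AD_RD": ("AD", "RD")}
    if name not in pairs:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(pairs)}")
    raw = _patient6_frame()
    frames = [
        make_table(raw[m].to_numpy()[None, :], ["patient6"], raw["tract"], m)
        for m in pairs[name]
    ]
    return validate_table(pd.concat(frames, ignore_index=True))


def load_patient6() -> pd.DataFrame:
    """All four metrics (FA, MD, AD, RD) of the bundled patient fixture."""
    raw = _patient6_frame()
    frames = [
        make_table(raw[m].to_numpy()[None, :], ["patient6"], raw["tract"], m)
        for m in METRICS
    ]
    return validate_table(pd.concat(frames, ignore_index=True))
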