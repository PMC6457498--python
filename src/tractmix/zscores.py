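"""Normative Z-scoring of patient ROI metrics against a control cohort.

Each patient value is standardised cell-wise (per tract, per metric):

    Z = (patient value - control mean) / control SD

with the sample SD (n-1 denominator).  |Z| > 1.96 is the conventional
single-subject abnormality flag (strict inequality).  Cells whose control SD
is zero are degenerate and propagate as missing rather than +/-inf.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import tables

ABNORMAL_THRESHOLD = 1.96


def control_reference(controls: pd.DataFrame) -> pd.DataFrame:
    """Per-(tract, metric) control mean, sample SD and n.

    Cells with SD == 0 are flagged ``degenerate``; any cell with fewer than
    two non-missing control values raises (SD undefined).
    """
    tables.validate_table(controls)
    grouped = controls.groupby(["tract", "metric"], sort=False)["value"]
    ref = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (ref["n"] < 2).any():
        bad = ref.loc[ref["n"] < 2, ["tract", "metric"]].to_records(index=False)
        raise ValueError(f"fewer than 2 control values for cells: {list(bad)[:5]}")
    ref["degenerate"] = ref["sd"] == 0
    return ref


class NormativeZScorer(TransformerMixin, BaseEstimator):
    """Transformer: fit on a control ROI-metric table, transform patients.

    Parameters
    ----------
    strict : bool
        Require every (tract, metric) cell of the patient table to exist in
        the control reference (raise listing offenders).  Default True.

    Attributes
    ----------
    reference_ : DataFrame
        Columns ``tract, metric, mean, sd, n, degenerate``.
    """

    def __init__(self, strict: bool = True):
        self.strict = strict

    def fit(self, X: pd.DataFrame, y=None):
        self.reference_ = control_reference(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise RuntimeError("NormativeZScorer must be fitted on controls first")
        tables.validate_table(X)
        merged = X.merge(self.reference_, on=["tract", "metric"], how="left")
        unmatched = merged["mean"].isna() & merged["value"].notna()
        if unmatched.any():
            offenders = sorted(merged.loc[unmatched, "tract"].unique())
            if self.strict:
                raise KeyError(f"patient cells without control reference: {offenders}")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (merged["value"] - merged["mean"]) / merged["sd"]
        z = z.where(~merged["degenerate"].fillna(True).astype(bool), np.nan)
        out = merged[["subject_id", "tract", "metric"]].copy()
        out["value"] = z
        return tables.validate_table(out)


def compute_zscores(patients: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Functional form of :class:`NormativeZScorer` taking a prebuilt reference."""
    scorer = NormativeZScorer()
    scorer.reference_ = reference
    return scorer.transform(patients)


def flag_abnormal(zscores: pd.DataFrame, threshold: float = ABNORMAL_THRESHOLD) -> pd.DataFrame:
    """Boolean table: True where |Z| strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = zscores.copy()
    out["abnormal"] = zscores["value"].abs() > threshold
    out.loc[zscores["value"].isna(), "abnormal"] = False
    return out[["subject_id", "tract", "metric", "value", "abnormal"]]


def rank_table(zscores: pd.DataFrame, patient: str, metric: str) -> pd.DataFrame:
    """Tracts of one patient and metric ordered most-negative Z first.

    Missing entries are listed last.  Mirrors the published per-patient
    ranked tables (columns: tract, Z).
    """
    sub = zscores[(zscores["subject_id"] == patient) & (zscores["metric"] == metric)]
    if sub.empty:
        raise KeyError(f"no rows for patient {patient!r}, metric {metric!r}")
    ranked = sub.sort_values("value", ascending=True, na_position="last", kind="mergesort")
    return ranked[["tract", "value"]].rename(columns={"value": "Z"}).reset_index(drop=True)
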