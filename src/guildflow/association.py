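"""Per-feature multivariable linear models with covariate adjustment.

MaAsLin-style screen: for each (transformed) feature, ordinary least
squares of abundance on treatment group plus food and water intake;
Benjamini-Hochberg correction across features, separately per model term;
records flagged significant at q below the chosen threshold (default
0.25, the conventional screening cutoff for this kind of analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, SampleInfo, samples_to_frame

__all__ = ["AssociationRecord", "fit_feature_lm", "bh_adjust", "run_association", "association_frame"]


@dataclass
class AssociationRecord:
    feature: str
    term: str
    coefficient: float
    se: float
    t: float
    p: float
    q: float
    direction: str  # "positive" | "negative"
    significant: bool


def association_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _find_collinear(X: pd.DataFrame) -> list[str]:
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    return [
        c
        for c in X.columns
        if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == full_rank
    ]


def build_design(
    metadata: pd.DataFrame,
    treatment_col: str = "group",
    covariates: Sequence[str] = ("food", "water"),
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Intercept + treatment dummies (reference level dropped) + covariates."""
    groups = metadata[treatment_col].astype(str)
    levels = list(pd.unique(groups))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among groups {levels}")
    X = pd.DataFrame({"Intercept": np.ones(len(metadata))}, index=metadata.index)
    for lv in levels:
        if lv != reference:
            X[f"{treatment_col}[{lv}]"] = (groups == lv).astype(float)
    for cov in covariates:
        if metadata[cov].isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        X[cov] = metadata[cov].astype(float)
    return X


def fit_feature_lm(y: Sequence[float], design: pd.DataFrame) -> pd.DataFrame:
    """OLS of one feature on the design; per-term coefficient, SE, t, p."""
    y = np.asarray(y, dtype=float)
    X = design
    if len(y) != len(X):
        raise ValueError("response and design have different lengths")
    if len(y) <= X.shape[1]:
        raise ValueError("need more samples than design columns")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_find_collinear(X)}")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_association(
    features: AbundanceTable,
    metadata: Union[Sequence[SampleInfo], pd.DataFrame],
    q_threshold: float = 0.25,
    day: Optional[int] = None,
    treatment_col: str = "group",
    covariates: Sequence[str] = ("food", "water"),
    reference: Optional[str] = None,
) -> list[AssociationRecord]:
    """Fit every feature, BH-correct per term, and flag q < threshold.

    ``day`` restricts the analysis to one sampling day (default: the last
    day present in the metadata, the study's endpoint convention).
    Zero-variance features are dropped with a warning.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else samples_to_frame(metadata)
    missing = set(features.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
    meta = meta.loc[features.sample_ids]
    if day is None:
        day = int(meta["day"].max())
    keep = meta["day"] == day
    if not keep.any():
        raise ValueError(f"no samples at day {day}")
    meta = meta[keep]
    table = features.select_samples(list(meta.index))

    design = build_design(meta, treatment_col=treatment_col, covariates=covariates, reference=reference)

    fits: dict[str, pd.DataFrame] = {}
    for j, fid in enumerate(table.feature_ids):
        y = table.values[:, j]
        if np.ptp(y) == 0:
            warnings.warn(f"feature {fid!r} has zero variance at day {day}; skipped", stacklevel=2)
            continue
        fits[fid] = fit_feature_lm(y, design)

    if not fits:
        return []

    terms = [c for c in design.columns if c != "Intercept"]
    records: list[AssociationRecord] = []
    feature_order = [f for f in table.feature_ids if f in fits]
    for term in terms:
        ps = np.array([fits[f].loc[term, "p"] for f in feature_order])
        qs = bh_adjust(ps)
        for f, q in zip(feature_order, qs):
            row = fits[f].loc[term]
            records.append(
                AssociationRecord(
                    feature=f,
                    term=term,
                    coefficient=float(row["coefficient"]),
                    se=float(row["se"]),
                    t=float(row["t"]),
                    p=float(row["p"]),
                    q=float(q),
                    direction="positive" if row["coefficient"] >= 0 else "negative",
                    significant=bool(q < q_threshold),
                )
            )
    return records
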