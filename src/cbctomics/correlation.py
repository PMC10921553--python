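"""Per-feature Pearson concordance between paired pCT and CBCT feature tables.

For each radiomic feature, the Pearson correlation coefficient R is computed
across the paired cohort (population moments; the sample/population choice
cancels in R).  A feature is deemed interchangeable between modalities when
R strictly exceeds the selection threshold (default 0.9).  Features with
zero variance in either table have an undefined R: they are reported as
missing and never selected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

__all__ = [
    "SENTINEL_FEATURES",
    "ConcordanceReport",
    "pearson",
    "correlate_tables",
    "select_interchangeable",
]

#: Features reported in the literature as prognostic for rectal cancer
#: staging/therapy response; flagged in reports when present.
SENTINEL_FEATURES = (
    "original_firstorder_Energy",
    "wavelet-HLH_glrlm_GrayLevelNonUniformity",
    "original_glrlm_GrayLevelNonUniformity",
)


def pearson(x, y) -> float:
    """Pearson R = cov(x, y) / (sigma_x * sigma_y) with population moments.

    Returns NaN (missing) when either argument has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).mean())
    sy = np.sqrt((yc**2).mean())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc * yc).mean() / (sx * sy))


@dataclass
class ConcordanceReport:
    """Per-feature concordance plus the interchangeable selection."""

    table: pd.DataFrame  # columns: feature, n, r, p_value, degenerate, selected
    threshold: float

    @property
    def interchangeable(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "feature"])

    @property
    def degenerate(self) -> list[str]:
        return list(self.table.loc[self.table["degenerate"], "feature"])

    @property
    def sentinels(self) -> pd.DataFrame:
        return self.table[self.table["feature"].isin(SENTINEL_FEATURES)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


def correlate_tables(
    t_pct: FeatureTable, t_cbct: FeatureTable, threshold: float = 0.9
) -> ConcordanceReport:
    """One Pearson R per feature across an order-aligned paired cohort.

    Rows are sorted by descending R; degenerate (zero-variance) features are
    reported with a missing R rather than dropped.  A two-sided p-value is
    annotated per feature for reference; it plays no role in selection.
    """
    if t_pct.case_ids != t_cbct.case_ids:
        raise ValueError("case ids differ between the paired tables")
    if t_pct.feature_names != t_cbct.feature_names:
        a = set(t_pct.feature_names)
        b = set(t_cbct.feature_names)
        if a != b:
            raise ValueError(f"feature sets differ, e.g. {sorted(a ^ b)[:4]}")
        raise ValueError("feature name order differs between the paired tables")
    n = t_pct.n_cases
    rows = []
    for k, name in enumerate(t_pct.feature_names):
        x = t_pct.values[:, k]
        y = t_cbct.values[:, k]
        r = pearson(x, y)
        degenerate = bool(np.isnan(r))
        if degenerate:
            p_val = np.nan
        else:
            rr = min(max(r, -1.0), 1.0)
            if abs(rr) == 1.0:
                p_val = 0.0
            else:
                t_stat = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
                p_val = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
        rows.append(
            {
                "feature": name,
                "n": n,
                "r": r,
                "p_value": p_val,
                "degenerate": degenerate,
                "selected": (not degenerate) and r > threshold,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "r", ascending=False, na_position="last", kind="mergesort"
    )
    return ConcordanceReport(table=table.reset_index(drop=True), threshold=threshold)


def select_interchangeable(report: ConcordanceReport, threshold: float = 0.9):
    """Features with R strictly above the threshold (missing R excluded).

    Returns ``(selected names, flagged sentinel subset)``.
    """
    t = report.table
    sel = t.loc[~t["degenerate"] & (t["r"] > threshold), "feature"]
    selected = list(sel)
    flagged = [f for f in SENTINEL_FEATURES if f in selected]
    return selected, flagged
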