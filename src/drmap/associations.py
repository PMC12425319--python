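"""Socioeconomic gradients and health-system correlations.

Districts are ranked by a covariate (e.g. female mean years of schooling)
and split into five near-equal groups; the expected-count-weighted mean RR
per quintile summarises the gradient. The relative index of inequality is
reported as the ratio of the top-quintile to the bottom-quintile mean RR
(a regression-based variant on the midpoint scale is available separately).
Province-level correlations with health-system indicators use Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError


@dataclass(frozen=True)
class QuintileSummary:
    """Per-quintile covariate mean, expected-weighted mean RR and size."""

    year: int
    covariate: str
    mean_covariate: np.ndarray   # (5,)
    mean_rr: np.ndarray          # (5,) expected-weighted
    district_count: np.ndarray   # (5,)
    assignment: dict[str, int]   # district -> quintile (1..5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quintile": np.arange(1, 6),
            "year": self.year,
            "covariate": self.covariate,
            "mean_covariate": self.mean_covariate,
            "mean_rr": self.mean_rr,
            "district_count": self.district_count,
        })


def quintile_assignment(district_ids: Sequence[str],
                        covariate: np.ndarray) -> np.ndarray:
    """Quintile index (1..5) per district; ties broken by district ID.

    Districts are sorted by (covariate, ID) and cut into 5 groups whose
    sizes differ by at most one; quintile 1 holds the lowest values.
    """
    n = len(district_ids)
    if n < 5:
        raise DataError("need at least 5 districts for quintiles")
    order = sorted(range(n), key=lambda i: (covariate[i], district_ids[i]))
    q = np.empty(n, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(np.array(order), 5), start=1):
        q[chunk] = g
    return q


def quintile_rr(rr: np.ndarray, expected: np.ndarray, covariate: np.ndarray,
                district_ids: Sequence[str], year: int,
                covariate_name: str = "yos") -> QuintileSummary:
    """Expected-weighted mean RR by covariate quintile for one year."""
    rr = np.asarray(rr, dtype=float)
    expected = np.asarray(expected, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    q = quintile_assignment(district_ids, covariate)
    mean_cov = np.empty(5)
    mean_rr = np.empty(5)
    count = np.empty(5, dtype=np.int64)
    for g in range(1, 6):
        sel = q == g
        mean_cov[g - 1] = covariate[sel].mean()
        mean_rr[g - 1] = np.sum(expected[sel] * rr[sel]) / np.sum(expected[sel])
        count[g - 1] = sel.sum()
    return QuintileSummary(year=year, covariate=covariate_name,
                           mean_covariate=mean_cov, mean_rr=mean_rr,
                           district_count=count,
                           assignment=dict(zip(district_ids, q.tolist())))


def relative_index_of_inequality(q: QuintileSummary) -> float:
    """Extreme-quintile ratio: top-quintile mean RR over bottom-quintile."""
    if q.mean_rr[0] <= 0:
        raise DataError("bottom-quintile mean RR must be > 0")
    return float(q.mean_rr[4] / q.mean_rr[0])


def regression_rii(q: QuintileSummary) -> float:
    """Regression-based RII variant on the cumulative-rank midpoint scale.

    Fits a weighted least-squares line of quintile mean RR on the quintile
    midpoints of the cumulative district-share distribution and returns the
    ratio of the fitted values at rank 1 and rank 0. Offered for
    completeness; the extreme-quintile ratio above is the default summary.
    """
    w = q.district_count.astype(float)
    shares = w / w.sum()
    upper = np.cumsum(shares)
    mid = upper - shares / 2
    X = np.column_stack([np.ones(5), mid])
    W = np.diag(w)
    coef, *_ = np.linalg.lstsq(W @ X, W @ q.mean_rr, rcond=None)
    bottom, top = coef[0], coef[0] + coef[1]
    if bottom <= 0:
        raise DataError("regression RII undefined: fitted bottom value <= 0")
    return float(top / bottom)


def pearson(x: np.ndarray, y: np.ndarray,
            alpha: float = 0.05) -> tuple[float, float, bool]:
    """Pearson correlation with a two-sided p-value and significance flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(p < alpha)


def health_system_correlations(table: pd.DataFrame, rr_column: str = "rr",
                               ) -> pd.DataFrame:
    """Correlate each health-system indicator with province-level RR.

    ``table`` is one row per province with indicator columns plus
    ``rr_column``; only complete cases enter each correlation.
    """
    rows = []
    for col in table.columns:
        if col in (rr_column, "province"):
            continue
        sub = table[[col, rr_column]].dropna()
        r, p, sig = pearson(sub[col].to_numpy(), sub[rr_column].to_numpy())
        rows.append({"indicator": col, "n": len(sub), "r": r, "p": p,
                     "significant": sig})
    return pd.DataFrame(rows)


def province_rr(district_rr: np.ndarray, expected: np.ndarray,
                province_of: Mapping[str, str],
                district_ids: Sequence[str]) -> dict[str, float]:
    """Expected-weighted mean district RR per province."""
    out: dict[str, list] = {}
    for i, d in enumerate(district_ids):
        out.setdefault(province_of[d], []).append(i)
    return {prov: float(np.sum(expected[idx] * district_rr[idx])
                        / np.sum(expected[idx]))
            for prov, idx in ((p, np.array(v)) for p, v in out.items())}
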