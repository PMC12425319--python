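"""Posterior summaries: district RRs, national RR and exceedance probabilities.

The national relative risk for a year is the expected-count-weighted mean of
the district RRs within each posterior draw,
``sum_i E(i,t) lambda(i,t) / sum_i E(i,t)`` — the plug-in analogue of total
observed over total expected. Exceedance probabilities compare district and
national draws iteration by iteration (strict inequality), so the reported
probability is the proportion of aligned draws in which the district's RR
lies above the national RR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DataError, PanelData
from .st_model import PosteriorSamples


@dataclass(frozen=True)
class RRSummary:
    """Posterior mean and central 95% credible interval per district-year."""

    district_ids: tuple[str, ...]
    years: tuple[int, ...]
    mean: np.ndarray   # (n, T)
    lo: np.ndarray     # 2.5th percentile
    hi: np.ndarray     # 97.5th percentile

    def to_frame(self) -> pd.DataFrame:
        n, T = self.mean.shape
        return pd.DataFrame({
            "district_id": np.repeat(self.district_ids, T),
            "year": np.tile(self.years, n),
            "mean": self.mean.ravel(),
            "lo": self.lo.ravel(),
            "hi": self.hi.ravel(),
        })


@dataclass(frozen=True)
class ExceedanceTable:
    """P(district RR > national RR) per district-year."""

    district_ids: tuple[str, ...]
    years: tuple[int, ...]
    probability: np.ndarray  # (n, T) in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        n, T = self.probability.shape
        return pd.DataFrame({
            "district_id": np.repeat(self.district_ids, T),
            "year": np.tile(self.years, n),
            "probability": self.probability.ravel(),
        })


def national_rr(samples: PosteriorSamples, panel: PanelData,
                weights: str = "expected") -> np.ndarray:
    """Per-draw national RR for every year: (n_draws, n_years).

    ``weights="expected"`` (default) uses E(i,t); ``weights="uniform"``
    averages districts equally.
    """
    lam = samples.lambda_draws()
    if weights == "expected":
        w = panel.E
    elif weights == "uniform":
        w = np.ones_like(panel.E)
    else:
        raise DataError(f"unknown weighting {weights!r}")
    wsum = w.sum(axis=0)
    if np.any(wsum <= 0):
        raise DataError("weights sum to zero for some year")
    return np.einsum("dit,it->dt", lam, w) / wsum[None, :]


def exceedance(district_draws: np.ndarray,
               national_draws: np.ndarray) -> float:
    """Proportion of aligned draws with district RR strictly above national."""
    district_draws = np.asarray(district_draws)
    national_draws = np.asarray(national_draws)
    if district_draws.shape != national_draws.shape:
        raise DataError("draw vectors must be aligned and equally long")
    return float(np.mean(district_draws > national_draws))


def exceedance_table(samples: PosteriorSamples, panel: PanelData,
                     weights: str = "expected") -> ExceedanceTable:
    """Exceedance probabilities for every district-year at once."""
    lam = samples.lambda_draws()
    nat = national_rr(samples, panel, weights=weights)   # (d, T)
    prob = np.mean(lam > nat[:, None, :], axis=0)
    return ExceedanceTable(district_ids=samples.district_ids,
                           years=samples.years, probability=prob)


def summarise(draws: np.ndarray, district_ids=None, years=None) -> RRSummary:
    """Mean and 2.5th/97.5th empirical percentiles over the draw axis.

    Percentiles use linear interpolation between order statistics (numpy's
    default rule). ``draws`` is (n_draws, ...) — typically (n_draws, n, T).
    """
    draws = np.asarray(draws)
    if draws.shape[0] < 2:
        raise DataError("need at least 2 draws to summarise")
    mean = draws.mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    if district_ids is None:
        district_ids = tuple(str(i) for i in range(mean.shape[0])) \
            if mean.ndim else ("0",)
    if years is None:
        years = tuple(range(mean.shape[1])) if mean.ndim > 1 else (0,)
    return RRSummary(district_ids=tuple(district_ids), years=tuple(years),
                     mean=mean, lo=lo, hi=hi)


def rr_summary(samples: PosteriorSamples) -> RRSummary:
    """Posterior RR summary per district-year from fitted samples."""
    return summarise(samples.lambda_draws(),
                     district_ids=samples.district_ids, years=samples.years)
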