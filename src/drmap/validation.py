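"""Cross-validation and MCMC diagnostics.

Validation follows a hold-out design: a fraction of the observed
district-year cells (default 10%) is masked, the model is refitted on the
rest, and the held-out SMRs (Y/E) are compared with the posterior RR
predictions at those cells. Reported per year: median relative error, median
absolute relative error, median error, median absolute error, and the
percentage of held-out SMRs covered by the predicted 95% credible interval.
A Bayesian rank statistic (a per-draw Wilcoxon signed-rank analogue; the
declared contract of this package) tests whether predicted-minus-observed
differences centre on zero.

Convergence diagnostics: split-chain potential scale reduction factor
(R-hat) and the Deviance Information Criterion, DIC = Dbar + pD with
pD = Dbar - D(posterior mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata

from .core_data import DataError, PanelData
from .st_model import PosteriorSamples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeldOutCells:
    """Indices and values of the held-out (district, year) cells."""

    district_idx: np.ndarray   # (m,)
    year_idx: np.ndarray       # (m,)
    district_ids: tuple[str, ...]
    years: np.ndarray          # (m,) calendar years
    Y: np.ndarray              # (m,) held-out counts
    E: np.ndarray              # (m,) expected counts

    @property
    def smr(self) -> np.ndarray:
        return self.Y / self.E


@dataclass(frozen=True)
class ValidationReport:
    """Held-out error metrics per year plus overall rank-test result."""

    per_year: dict[int, dict[str, float]]
    n_cells: int
    n_excluded_relative: int
    rank_interval: tuple[float, float] | None = None
    rank_includes_zero: bool | None = None

    def to_dict(self) -> dict:
        return {
            "per_year": {str(y): v for y, v in self.per_year.items()},
            "n_cells": self.n_cells,
            "n_excluded_relative": self.n_excluded_relative,
            "rank_interval": list(self.rank_interval)
            if self.rank_interval is not None else None,
            "rank_includes_zero": self.rank_includes_zero,
        }


@dataclass(frozen=True)
class DiagnosticsReport:
    """Per-parameter R-hat and DIC components."""

    rhat: dict[str, float]
    dbar: float
    d_hat: float
    p_d: float
    dic: float

    def to_dict(self) -> dict:
        return {"rhat": dict(self.rhat), "dbar": self.dbar,
                "d_hat": self.d_hat, "p_d": self.p_d, "dic": self.dic}


# ---------------------------------------------------------------------------
# Hold-out split
# ---------------------------------------------------------------------------

def holdout_split(panel: PanelData, fraction: float = 0.1,
                  seed: int = 0) -> tuple[PanelData, HeldOutCells]:
    """Withhold a uniform sample of observed cells without replacement.

    The number held out is ``round(fraction * n_observed)``. The returned
    training panel is the input with those cells masked.
    """
    if not (0 < fraction < 1):
        raise DataError("fraction must be in (0, 1)")
    obs = np.argwhere(panel.observed_mask)
    n_obs = len(obs)
    n_hold = int(round(fraction * n_obs))
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_obs, size=n_hold, replace=False)
    cells = obs[np.sort(pick)]

    mask = panel.observed_mask.copy()
    mask[cells[:, 0], cells[:, 1]] = False
    for j in range(panel.n_years):
        if panel.observed_mask[:, j].any() and not mask[:, j].any():
            logger.warning("holdout removed all observed data for year %s",
                           panel.years[j])

    held = HeldOutCells(
        district_idx=cells[:, 0],
        year_idx=cells[:, 1],
        district_ids=tuple(panel.district_ids[i] for i in cells[:, 0]),
        years=np.array([panel.years[j] for j in cells[:, 1]]),
        Y=panel.Y[cells[:, 0], cells[:, 1]].astype(float),
        E=panel.E[cells[:, 0], cells[:, 1]].astype(float),
    )
    return panel.with_mask(mask), held


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def cv_metrics(heldout_Y: np.ndarray, heldout_E: np.ndarray,
               pred_mean: np.ndarray, pred_lo: np.ndarray,
               pred_hi: np.ndarray, years: Sequence[int]) -> ValidationReport:
    """Held-out error metrics against observed SMRs, grouped by year.

    Relative errors are undefined where the held-out count is zero; such
    cells are excluded from the relative-error medians (the exclusion count
    is reported) but kept in the absolute-error and coverage summaries.
    """
    heldout_Y = np.asarray(heldout_Y, dtype=float)
    heldout_E = np.asarray(heldout_E, dtype=float)
    years = np.asarray(years)
    if not (len(heldout_Y) == len(heldout_E) == len(pred_mean) == len(years)):
        raise DataError("held-out arrays must be aligned")
    smr = heldout_Y / heldout_E
    err = np.asarray(pred_mean) - smr
    nonzero = heldout_Y > 0
    n_excluded = int(np.sum(~nonzero))
    if n_excluded:
        logger.info("excluded %d zero-count cells from relative metrics",
                    n_excluded)
    covered = (smr >= np.asarray(pred_lo)) & (smr <= np.asarray(pred_hi))

    per_year: dict[int, dict[str, float]] = {}
    for y in sorted(set(int(v) for v in years)):
        sel = years == y
        rel_sel = sel & nonzero
        rel = err[rel_sel] / smr[rel_sel]
        per_year[y] = {
            "median_relative_error": float(np.median(rel)) if rel.size else float("nan"),
            "median_absolute_relative_error":
                float(np.median(np.abs(rel))) if rel.size else float("nan"),
            "median_error": float(np.median(err[sel])),
            "median_absolute_error": float(np.median(np.abs(err[sel]))),
            "coverage_pct": float(100.0 * covered[sel].mean()),
            "n_cells": int(sel.sum()),
        }
    return ValidationReport(per_year=per_year, n_cells=len(smr),
                            n_excluded_relative=n_excluded)


def bayesian_rank_test(heldout_smr: np.ndarray,
                       predicted_samples: np.ndarray,
                       interval: float = 95.0) -> tuple[tuple[float, float], bool]:
    """Per-draw signed-rank statistic of predicted minus observed.

    For each posterior draw, differences between the predicted RRs and the
    held-out SMRs are ranked by magnitude (average ranks on ties) and the
    mean signed rank is computed; zero differences contribute zero. Returns
    the central ``interval``% range of the statistic across draws and
    whether it contains zero.
    """
    obs = np.asarray(heldout_smr, dtype=float)
    pred = np.atleast_2d(np.asarray(predicted_samples, dtype=float))
    if pred.shape[1] != len(obs):
        raise DataError("predicted draws and observations misaligned")
    if len(obs) < 1:
        raise DataError("need at least one held-out cell")
    diff = pred - obs[None, :]
    ranks = rankdata(np.abs(diff), axis=1)
    stat = np.mean(np.sign(diff) * ranks, axis=1)
    half = (100.0 - interval) / 2
    lo, hi = np.percentile(stat, [half, 100.0 - half])
    return (float(lo), float(hi)), bool(lo <= 0.0 <= hi)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def rhat(chains: Sequence[np.ndarray] | np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is halved (a trailing odd draw is dropped), then
    ``sqrt((W(n-1)/n + B/n) / W)`` is computed over the 2c half-chains,
    where W is the mean within-chain variance and B the between-chain
    variance of the half-chain means. Splitting makes the statistic
    sensitive to within-chain trends.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise DataError("need at least 2 chains")
    n_full = min(len(c) for c in chains)
    if any(len(c) != n_full for c in chains):
        raise DataError("chains must have equal lengths")
    half = n_full // 2
    if half < 2:
        raise DataError("chains too short to split")
    splits = []
    for c in chains:
        splits.append(c[:half])
        splits.append(c[half:2 * half])
    arr = np.stack(splits)                   # (2c, half)
    n = half
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    means = arr.mean(axis=1)
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        logger.warning("zero within-chain variance; reporting R-hat = 1")
        return 1.0
    return float(np.sqrt((W * (n - 1) / n + B / n) / W))


def _deviance_per_draw(samples: PosteriorSamples,
                       panel: PanelData) -> tuple[np.ndarray, float]:
    m = panel.observed_mask
    y = panel.Y[m].astype(float)
    logE = np.log(panel.E[m])
    const = float(np.sum(gammaln(y + 1.0)))
    eta = samples.log_lambda[:, m]           # (n_draws, n_obs)
    log_mu = logE[None, :] + eta
    ll = np.sum(y[None, :] * log_mu - np.exp(log_mu), axis=1) - const
    dev = -2.0 * ll
    bad = ~np.isfinite(dev)
    if bad.any():
        raise DataError(f"non-finite deviance at draw {int(np.argmax(bad))}")
    # Plug-in deviance at the posterior mean of the linear predictor (the
    # predictor is linear in all parameters, so this is the deviance at the
    # posterior mean of the parameters).
    eta_bar = eta.mean(axis=0)
    log_mu_bar = logE + eta_bar
    d_hat = -2.0 * (float(np.sum(y * log_mu_bar - np.exp(log_mu_bar))) - const)
    return dev, d_hat


def dic(samples: PosteriorSamples, panel: PanelData) -> DiagnosticsReport:
    """DIC = Dbar + pD, with pD = Dbar - D(posterior mean)."""
    dev, d_hat = _deviance_per_draw(samples, panel)
    dbar = float(dev.mean())
    p_d = dbar - d_hat
    return DiagnosticsReport(rhat={}, dbar=dbar, d_hat=d_hat, p_d=p_d,
                             dic=dbar + p_d)


def diagnostics(samples: PosteriorSamples,
                panel: PanelData) -> DiagnosticsReport:
    """Per-parameter split R-hat plus DIC for a fitted model."""
    rh = {}
    for name, draws in samples.parameter_draws().items():
        per_chain = samples.split_by_chain(draws)
        rh[name] = rhat(per_chain)
    base = dic(samples, panel)
    return DiagnosticsReport(rhat=rh, dbar=base.dbar, d_hat=base.d_hat,
                             p_d=base.p_d, dic=base.dic)
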