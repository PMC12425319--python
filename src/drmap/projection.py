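"""Per-posterior-draw linear projection of district RRs beyond the data years.

For every district and every retained posterior draw, an ordinary
least-squares line ``RR = b0 + b1 * year`` is fitted to that draw's RR
trajectory over the fit years, and evaluated at the requested future years.
Running the projection per draw propagates the full posterior uncertainty of
the spatiotemporal model into the projections. Projection is on the RR scale
(not log), so extrapolated values can go negative; they are floored at a
configurable minimum and the number of floored cells is logged.

The year covariate is centred at the midpoint of the fit years for numerical
conditioning; the reported intercept is re-expressed at year zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import DataError
from .posterior import RRSummary, summarise
from .st_model import PosteriorSamples

logger = logging.getLogger(__name__)

DEFAULT_RR_FLOOR = 1e-6


@dataclass(frozen=True)
class ProjectionSamples:
    """OLS coefficients and projected RRs per district and draw."""

    district_ids: tuple[str, ...]
    fit_years: tuple[int, ...]
    future_years: tuple[int, ...]
    b0: np.ndarray            # (n_draws, n) intercept at year 0
    b1: np.ndarray            # (n_draws, n) slope, RR per year
    projected: np.ndarray     # (n_draws, n, n_future)
    n_floored: int

    def summary(self) -> RRSummary:
        return summarise(self.projected, district_ids=self.district_ids,
                         years=self.future_years)


def fit_projection(samples: PosteriorSamples,
                   fit_years: Sequence[int] | None = None,
                   future_years: Sequence[int] = (),
                   floor: float = DEFAULT_RR_FLOOR) -> ProjectionSamples:
    """Fit one OLS line per (district, draw) and project it forward.

    All fit years with a posterior RR are usable — including years without
    data, where the model interpolates the risk surface.
    """
    if fit_years is None:
        fit_years = samples.years
    fit_years = tuple(int(y) for y in fit_years)
    future_years = tuple(int(y) for y in future_years)
    if len(fit_years) < 2:
        raise DataError("need at least 2 fit years")
    if len(set(fit_years)) < 2:
        raise DataError("fit years are degenerate (all equal)")
    if set(future_years) & set(fit_years):
        raise DataError("future years must be disjoint from fit years")
    missing = set(fit_years) - set(samples.years)
    if missing:
        raise DataError(f"fit years without posterior RRs: {sorted(missing)}")

    cols = [samples.years.index(y) for y in fit_years]
    lam = samples.lambda_draws()[:, :, cols]          # (d, n, Tf)

    x = np.array(fit_years, dtype=float)
    xc = x - x.mean()                                  # centred years
    sxx = float(xc @ xc)
    b1 = np.einsum("dnt,t->dn", lam, xc) / sxx
    mean_lam = lam.mean(axis=2)
    b0 = mean_lam - b1 * x.mean()                      # intercept at year 0

    xf = np.array(future_years, dtype=float)
    projected = b0[:, :, None] + b1[:, :, None] * xf[None, None, :]
    n_floored = int(np.sum(projected < floor))
    if n_floored:
        logger.info("floored %d projected RR cells at %g", n_floored, floor)
    projected = np.maximum(projected, floor)

    return ProjectionSamples(district_ids=samples.district_ids,
                             fit_years=fit_years, future_years=future_years,
                             b0=b0, b1=b1, projected=projected,
                             n_floored=n_floored)


def fitted_values(proj: ProjectionSamples,
                  years: Sequence[int] | None = None) -> np.ndarray:
    """Evaluate the fitted lines at given years (default: the fit years)."""
    if years is None:
        years = proj.fit_years
    x = np.array(list(years), dtype=float)
    return proj.b0[:, :, None] + proj.b1[:, :, None] * x[None, None, :]
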