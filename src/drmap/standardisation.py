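"""Indirect age standardisation: expected counts and SMRs.

Expected counts apply reference age-specific incidence rates to each
district's female age structure: ``E_i = sum_age rate(age) * pop(i, age)``.
The standardised morbidity ratio is then ``SMR(i,t) = Y(i,t) / E(i,t)``,
defined only at observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AgePopulationTable, DataError, PanelData, ReferenceRates


@dataclass(frozen=True)
class SMRTable:
    """Observed, expected and SMR per observed district-year."""

    district_ids: tuple[str, ...]
    years: tuple[int, ...]
    observed: np.ndarray       # (n, T) int
    expected: np.ndarray       # (n, T) float
    smr: np.ndarray            # (n, T) float, NaN where unobserved
    observed_mask: np.ndarray  # (n, T) bool

    def to_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(self.observed_mask)
        return pd.DataFrame({
            "district_id": [self.district_ids[k] for k in i],
            "year": [self.years[k] for k in j],
            "observed": self.observed[i, j],
            "expected": self.expected[i, j],
            "smr": self.smr[i, j],
        })


def compute_expected(pop: AgePopulationTable,
                     rates: ReferenceRates) -> np.ndarray:
    """Expected counts per district from reference rates and age structure.

    Returns a (n_districts,) array. A district whose population is all zero
    gets E = 0, which is invalid for modelling; callers must check.
    """
    rate_by_group = dict(zip(rates.age_groups, rates.rates))
    missing = [g for g in pop.age_groups if g not in rate_by_group]
    if missing:
        raise DataError(f"age groups without a reference rate: {missing}")
    r = np.array([rate_by_group[g] for g in pop.age_groups])
    return pop.population @ r


def compute_smr(panel: PanelData) -> SMRTable:
    """SMR = Y/E at observed cells; NaN elsewhere."""
    if np.any(panel.E[panel.observed_mask] <= 0):
        raise DataError("E must be > 0 at all observed cells")
    smr = np.full(panel.E.shape, np.nan)
    m = panel.observed_mask
    smr[m] = panel.Y[m] / panel.E[m]
    return SMRTable(district_ids=panel.district_ids, years=panel.years,
                    observed=panel.Y.copy(), expected=panel.E.copy(),
                    smr=smr, observed_mask=m.copy())
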