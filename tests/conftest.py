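import numpy as np
import pytest

from drmap.core_data import PanelData, make_district_graph


@pytest.fixture
def square_graph():
    """4-cycle: A-B-D-C-A."""
    return make_district_graph(
        ["A", "B", "C", "D"],
        [("A", "B"), ("B", "D"), ("D", "C"), ("C", "A")])


def build_panel(Y, E=None, covariates=None, mask=None, years=None):
    """Small helper to assemble a PanelData from plain arrays."""
    Y = np.asarray(Y, dtype=np.int64)
    n, T = Y.shape
    if E is None:
        E = np.ones((n, T))
    if years is None:
        years = tuple(range(2000, 2000 + T))
    if mask is None:
        mask = np.ones((n, T), dtype=bool)
    district_ids = tuple(f"d{i:02d}" for i in range(n))
    covs = {c: np.zeros((n, T)) for c in ("yos", "urb", "comp", "wi")}
    if covariates:
        covs.update({k: np.asarray(v, dtype=float) for k, v in covariates.items()})
    return PanelData(district_ids=district_ids, years=years, Y=Y,
                     E=np.asarray(E, dtype=float), covariates=covs,
                     observed_mask=np.asarray(mask, dtype=bool))


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(42)
    n, T = 5, 4
    E = rng.uniform(5, 20, size=(n, T))
    Y = rng.poisson(E)
    return build_panel(Y, E=E)
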