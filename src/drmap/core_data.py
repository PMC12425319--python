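"""Domain types, file readers/writers and run configuration.

The pipeline works on district-year panels: observed case counts ``Y(i, t)``,
expected counts ``E(i, t)`` from indirect age standardisation, district-year
covariates, and a district adjacency graph that defines the spatial
neighbourhood structure. Everything downstream (standardisation, the
spatiotemporal model, posterior summaries, projection, validation,
association analyses) consumes these containers.

File formats are deliberately plain text:

* ``counts.csv``: ``district_id,year,cases`` — one row per *observed*
  district-year; a missing row means the cell is unobserved.
* ``covariates.csv``: ``district_id,year,yos,urb,comp,wi`` — complete grid,
  no gaps allowed.
* ``expected.csv``: ``district_id,year,expected``.
* ``population.csv``: ``district_id,age_group,female_population``.
* ``reference_rates.csv``: ``age_group,rate``.
* ``adjacency.txt``: ``district_id_a,district_id_b`` per line.

District order is canonical: lexicographic by ID, fixed at load time; every
array in the package uses this order.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

COVARIATE_NAMES = ("yos", "urb", "comp", "wi")
DEFAULT_COVARIATE_SELECTION = ("yos", "urb", "comp")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# DistrictGraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistrictGraph:
    """Symmetric district adjacency with a fixed (lexicographic) node order.

    Isolated districts are permitted; self-loops are not. ``edges`` stores
    each undirected edge once as a sorted ID pair.
    """

    district_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        known = set(self.district_ids)
        if len(known) != len(self.district_ids):
            raise DataError("duplicate district IDs")
        for a, b in self.edges:
            if a == b:
                raise DataError(f"self-loop on district {a!r}")
            if a not in known or b not in known:
                raise DataError(f"edge ({a!r}, {b!r}) names unknown district")

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.district_ids)}

    @property
    def neighbor_counts(self) -> np.ndarray:
        """Integer degree per district, in canonical order."""
        deg = np.zeros(self.n_districts, dtype=np.int64)
        idx = self.index
        for a, b in self.edges:
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        return deg

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency lists as integer index arrays, canonical order."""
        idx = self.index
        nbrs: list[list[int]] = [[] for _ in self.district_ids]
        for a, b in self.edges:
            ia, ib = idx[a], idx[b]
            nbrs[ia].append(ib)
            nbrs[ib].append(ia)
        return [np.array(sorted(v), dtype=np.int64) for v in nbrs]

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as two parallel index arrays (each edge once, i < j)."""
        idx = self.index
        pairs = sorted((min(idx[a], idx[b]), max(idx[a], idx[b]))
                       for a, b in self.edges)
        if not pairs:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        i, j = zip(*pairs)
        return np.array(i, dtype=np.int64), np.array(j, dtype=np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.district_ids)
        g.add_edges_from(self.edges)
        return g

    def coloring(self) -> np.ndarray:
        """Greedy proper coloring (per-district color index).

        Districts of one color are never adjacent, so their ICAR full
        conditionals are mutually independent and can be updated in one
        vectorised sweep.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        return np.array([colors[d] for d in self.district_ids], dtype=np.int64)

    def icar_rank(self) -> int:
        """Rank of the ICAR precision matrix restricted to connected districts.

        Equals (number of non-isolated districts) minus (number of connected
        components among them); used in the conjugate Gibbs update of the
        spatial precision.
        """
        g = self.to_networkx()
        g.remove_nodes_from([d for d in self.district_ids if g.degree[d] == 0])
        if g.number_of_nodes() == 0:
            return 0
        return g.number_of_nodes() - nx.number_connected_components(g)


def make_district_graph(district_ids: Iterable[str],
                        edges: Iterable[tuple[str, str]]) -> DistrictGraph:
    """Build a graph with canonical ID order and deduplicated edges."""
    ids = tuple(sorted(district_ids))
    canon = frozenset(tuple(sorted(e)) for e in edges)
    return DistrictGraph(district_ids=ids, edges=canon)


# ---------------------------------------------------------------------------
# PanelData and friends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelData:
    """District-year incidence panel.

    ``Y`` holds counts only where ``observed_mask`` is true (zero elsewhere,
    by convention; masked entries are never read). ``E`` must be strictly
    positive everywhere — the model interpolates risk at unobserved cells,
    which still needs an exposure. Covariates are complete (no missing
    values), one (n_districts, n_years) array per named column.
    """

    district_ids: tuple[str, ...]
    years: tuple[int, ...]
    Y: np.ndarray                  # (n, T) int64
    E: np.ndarray                  # (n, T) float64, > 0
    covariates: dict[str, np.ndarray]   # name -> (n, T) float64
    observed_mask: np.ndarray      # (n, T) bool

    def __post_init__(self) -> None:
        n, T = len(self.district_ids), len(self.years)
        if list(self.years) != sorted(set(self.years)):
            raise DataError("years must be strictly increasing")
        for name, arr in [("Y", self.Y), ("E", self.E),
                          ("observed_mask", self.observed_mask),
                          *self.covariates.items()]:
            if arr.shape != (n, T):
                raise DataError(f"{name} has shape {arr.shape}, expected {(n, T)}")
        if np.any(self.Y[self.observed_mask] < 0):
            raise DataError("negative counts")
        if np.any(~np.isfinite(self.E)) or np.any(self.E <= 0):
            raise DataError("E must be positive and finite everywhere")
        for name, arr in self.covariates.items():
            if np.any(~np.isfinite(arr)):
                raise DataError(f"covariate {name!r} contains non-finite values")

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def covariate_matrix(self, selection: Sequence[str]) -> np.ndarray:
        """Stack selected covariates into (k, n, T)."""
        missing = [c for c in selection if c not in self.covariates]
        if missing:
            raise DataError(f"unknown covariates: {missing}")
        return np.stack([self.covariates[c] for c in selection])

    def with_mask(self, mask: np.ndarray) -> "PanelData":
        """Return a copy with a different observed mask (Y zeroed outside)."""
        mask = np.asarray(mask, dtype=bool)
        Y = np.where(mask, self.Y, 0)
        return replace(self, Y=Y, observed_mask=mask)


@dataclass(frozen=True)
class AgePopulationTable:
    """Female population by district and age group (long format)."""

    district_ids: tuple[str, ...]
    age_groups: tuple[str, ...]
    population: np.ndarray  # (n_districts, n_age_groups), >= 0

    def __post_init__(self) -> None:
        shape = (len(self.district_ids), len(self.age_groups))
        if self.population.shape != shape:
            raise DataError(f"population shape {self.population.shape} != {shape}")
        if np.any(self.population < 0):
            raise DataError("negative population")


@dataclass(frozen=True)
class ReferenceRates:
    """Reference age-specific incidence rates (per person-year)."""

    age_groups: tuple[str, ...]
    rates: np.ndarray  # (n_age_groups,), in (0, 1)

    def __post_init__(self) -> None:
        if len(self.age_groups) != len(self.rates):
            raise DataError("one rate per age group required")
        if np.any((self.rates <= 0) | (self.rates >= 1)):
            raise DataError("rates must lie in (0, 1)")


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (conventional disease-mapping defaults).

    Intercept and covariate effects get diffuse normals; precisions get
    Gamma(shape, rate) priors.
    """

    coef_variance: float = 1000.0
    tau_shape: float = 0.5
    tau_rate: float = 0.0005


@dataclass(frozen=True)
class RunConfig:
    """Sampler and pipeline configuration.

    Defaults reproduce the reference analysis protocol: 2 chains of 15,000
    iterations, the first 5,000 discarded as burn-in, no thinning — 20,000
    retained draws in total.
    """

    n_chains: int = 2
    iterations_per_chain: int = 15000
    burn_in: int = 5000
    thin: int = 1
    seed: int = 0
    covariate_selection: tuple[str, ...] = DEFAULT_COVARIATE_SELECTION
    priors: PriorSpec = field(default_factory=PriorSpec)
    projection_years: tuple[int, ...] = ()
    # Effects included in the linear predictor; the full model uses all four.
    components: tuple[str, ...] = ("spatial", "unstructured", "temporal", "residual")
    # Optional fixed values for precisions (name -> value); fixed precisions
    # are not sampled. Names: tau_u, tau_v, tau_x, tau_eps.
    fixed_precisions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations_per_chain):
            raise DataError("burn_in must satisfy 0 <= burn_in < iterations_per_chain")
        if self.thin < 1:
            raise DataError("thin must be >= 1")
        unknown = set(self.covariate_selection) - set(COVARIATE_NAMES)
        if unknown:
            raise DataError(f"unknown covariates in selection: {sorted(unknown)}")
        unknown = set(self.components) - {"spatial", "unstructured", "temporal", "residual"}
        if unknown:
            raise DataError(f"unknown components: {sorted(unknown)}")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations_per_chain - self.burn_in) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "iterations_per_chain": self.iterations_per_chain,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "covariate_selection": list(self.covariate_selection),
            "priors": {
                "coef_variance": self.priors.coef_variance,
                "tau_shape": self.priors.tau_shape,
                "tau_rate": self.priors.tau_rate,
            },
            "projection_years": list(self.projection_years),
            "components": list(self.components),
            "fixed_precisions": dict(self.fixed_precisions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        priors = d.pop("priors", {})
        return cls(
            n_chains=d.get("n_chains", 2),
            iterations_per_chain=d.get("iterations_per_chain", 15000),
            burn_in=d.get("burn_in", 5000),
            thin=d.get("thin", 1),
            seed=d.get("seed", 0),
            covariate_selection=tuple(d.get("covariate_selection",
                                            DEFAULT_COVARIATE_SELECTION)),
            priors=PriorSpec(**priors) if priors else PriorSpec(),
            projection_years=tuple(d.get("projection_years", ())),
            components=tuple(d.get("components",
                                   ("spatial", "unstructured", "temporal", "residual"))),
            fixed_precisions=dict(d.get("fixed_precisions", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip",
                     dtype={"district_id": str, "age_group": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def read_panel(counts_path: str | Path, covariates_path: str | Path,
               expected_path: str | Path) -> PanelData:
    """Assemble a :class:`PanelData` from the three CSV inputs.

    The covariate file defines the full (district, year) grid; the observed
    mask is false exactly where the counts file has no row for that cell.
    """
    cov = _read_csv(covariates_path, ["district_id", "year"] + list(COVARIATE_NAMES))
    counts = _read_csv(counts_path, ["district_id", "year", "cases"])
    exp = _read_csv(expected_path, ["district_id", "year", "expected"])

    if cov.duplicated(["district_id", "year"]).any():
        raise DataError("duplicate (district, year) rows in covariates")
    if counts.duplicated(["district_id", "year"]).any():
        dup = counts[counts.duplicated(["district_id", "year"])].iloc[0]
        raise DataError(f"duplicate count row for ({dup.district_id}, {dup.year})")
    if (counts["cases"] < 0).any():
        raise DataError("negative counts in counts file")

    district_ids = tuple(sorted(cov["district_id"].unique()))
    years = tuple(int(y) for y in sorted(cov["year"].unique()))
    n, T = len(district_ids), len(years)
    d_idx = {d: i for i, d in enumerate(district_ids)}
    y_idx = {y: j for j, y in enumerate(years)}

    covariates = {}
    for name in COVARIATE_NAMES:
        arr = np.full((n, T), np.nan)
        arr[cov["district_id"].map(d_idx), cov["year"].map(y_idx)] = cov[name]
        bad = np.argwhere(~np.isfinite(arr))
        if len(bad):
            i, j = bad[0]
            raise DataError(
                f"covariate {name!r} missing at ({district_ids[i]}, {years[j]})")
        covariates[name] = arr

    E = np.full((n, T), np.nan)
    exp_d = exp["district_id"].map(d_idx)
    if exp_d.isna().any():
        raise DataError("expected file names unknown district")
    E[exp_d, exp["year"].map(y_idx)] = exp["expected"]
    if np.any(~np.isfinite(E)):
        i, j = np.argwhere(~np.isfinite(E))[0]
        raise DataError(f"expected count missing at ({district_ids[i]}, {years[j]})")

    Y = np.zeros((n, T), dtype=np.int64)
    mask = np.zeros((n, T), dtype=bool)
    for d, y, c in counts[["district_id", "year", "cases"]].itertuples(index=False):
        if d not in d_idx:
            raise DataError(f"counts file names unknown district {d!r}")
        if y not in y_idx:
            raise DataError(f"counts file names unknown year {y}")
        Y[d_idx[d], y_idx[y]] = int(c)
        mask[d_idx[d], y_idx[y]] = True

    return PanelData(district_ids=district_ids, years=years, Y=Y, E=E,
                     covariates=covariates, observed_mask=mask)


def read_adjacency(edge_list_path: str | Path,
                   district_ids: Iterable[str]) -> DistrictGraph:
    """Read a two-column edge list; duplicates and reversals are merged."""
    ids = tuple(sorted(district_ids))
    known = set(ids)
    edges: set[tuple[str, str]] = set()
    with open(edge_list_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise DataError(f"{edge_list_path}:{lineno}: expected two columns")
            a, b = parts
            if a == b:
                raise DataError(f"{edge_list_path}:{lineno}: self-loop on {a!r}")
            if a not in known or b not in known:
                raise DataError(f"{edge_list_path}:{lineno}: unknown district")
            edges.add((min(a, b), max(a, b)))
    return DistrictGraph(district_ids=ids, edges=frozenset(edges))


def read_population(path: str | Path) -> AgePopulationTable:
    df = _read_csv(path, ["district_id", "age_group", "female_population"])
    districts = tuple(sorted(df["district_id"].unique()))
    # Age-group order follows first appearance, identical across districts.
    age_groups = tuple(df["age_group"].unique())
    per_district = df.groupby("district_id")["age_group"].apply(tuple)
    for d, groups in per_district.items():
        if set(groups) != set(age_groups):
            raise DataError(f"district {d!r} has mismatched age groups")
    pivot = df.pivot(index="district_id", columns="age_group",
                     values="female_population")
    pop = pivot.loc[list(districts), list(age_groups)].to_numpy(dtype=float)
    return AgePopulationTable(district_ids=districts, age_groups=age_groups,
                              population=pop)


def read_reference_rates(path: str | Path) -> ReferenceRates:
    df = _read_csv(path, ["age_group", "rate"])
    if df["age_group"].duplicated().any():
        raise DataError("duplicate age group in reference rates")
    return ReferenceRates(age_groups=tuple(df["age_group"]),
                          rates=df["rate"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Writers (canonical form: lexicographic districts, ascending years)
# ---------------------------------------------------------------------------

def _metadata_header(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    items = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# drmap {items}\n"


def write_panel(panel: PanelData, counts_path: str | Path,
                covariates_path: str | Path, expected_path: str | Path,
                meta: Mapping[str, object] | None = None) -> None:
    """Write a panel back to the three canonical CSV files."""
    header = _metadata_header(meta)
    n, T = panel.n_districts, panel.n_years

    rows = []
    for i in range(n):
        for j in range(T):
            if panel.observed_mask[i, j]:
                rows.append((panel.district_ids[i], panel.years[j],
                             int(panel.Y[i, j])))
    _write_csv(counts_path, header, "district_id,year,cases",
               (f"{d},{y},{c}" for d, y, c in rows))

    cov_lines = (
        f"{panel.district_ids[i]},{panel.years[j]},"
        + ",".join(repr(float(panel.covariates[c][i, j])) for c in COVARIATE_NAMES)
        for i in range(n) for j in range(T)
    )
    _write_csv(covariates_path, header,
               "district_id,year," + ",".join(COVARIATE_NAMES), cov_lines)

    exp_lines = (
        f"{panel.district_ids[i]},{panel.years[j]},{float(panel.E[i, j])!r}"
        for i in range(n) for j in range(T)
    )
    _write_csv(expected_path, header, "district_id,year,expected", exp_lines)


def write_adjacency(graph: DistrictGraph, path: str | Path,
                    meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        for a, b in sorted(graph.edges):
            fh.write(f"{a},{b}\n")


def write_population(pop: AgePopulationTable, path: str | Path) -> None:
    lines = (
        f"{pop.district_ids[i]},{pop.age_groups[j]},{float(pop.population[i, j])!r}"
        for i in range(len(pop.district_ids))
        for j in range(len(pop.age_groups))
    )
    _write_csv(path, "", "district_id,age_group,female_population", lines)


def write_reference_rates(rates: ReferenceRates, path: str | Path) -> None:
    lines = (f"{g},{float(r)!r}" for g, r in zip(rates.age_groups, rates.rates))
    _write_csv(path, "", "age_group,rate", lines)


def _write_csv(path: str | Path, header: str, columns: str,
               lines: Iterable[str]) -> None:
    buf = io.StringIO()
    buf.write(header)
    buf.write(columns + "\n")
    for line in lines:
        buf.write(line + "\n")
    Path(path).write_text(buf.getvalue())
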