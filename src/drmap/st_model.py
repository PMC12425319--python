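"""Bayesian Poisson spatiotemporal model and its MCMC sampler.

The model for district ``i`` and year ``t``::

    Y(i,t) ~ Poisson(E(i,t) * lambda(i,t))
    log lambda(i,t) = alpha + beta' x(i,t) + U_i + V_i + X_t + eps(i,t)

with

* ``U``   — spatially structured effect, intrinsic CAR (ICAR) prior: each
  district's effect is normal around the mean of its neighbours' effects with
  precision ``tau_u * degree``; identified by a sum-to-zero constraint,
  re-imposed by recentring after every sweep. Isolated districts carry
  ``U_i = 0``; their spatial variation is absorbed by ``V_i``.
* ``V``   — unstructured iid Normal(0, 1/tau_v) district effect,
* ``X_t`` — exchangeable iid Normal(0, 1/tau_x) year effect (no random walk),
* ``eps`` — iid Normal(0, 1/tau_eps) space-time residual (the saturated
  interaction term).

Priors: alpha and each beta ~ Normal(0, 1000); every precision ~
Gamma(0.5, rate=0.0005) — conventional disease-mapping defaults, all
overridable through :class:`~drmap.core_data.RunConfig`.

Sampling is Metropolis-within-Gibbs:

* conjugate Gibbs draws for the precisions,
* random-walk Metropolis for alpha, the betas, U, V, X_t and eps.

Element-wise updates (V, X_t, eps) are vectorised because their full
conditionals are mutually independent given the rest. U is updated one graph
color at a time: districts sharing a color are never adjacent, so their ICAR
full conditionals are also conditionally independent and each color class
can be proposed and accepted in a single vectorised step. eps at unobserved
cells (the likelihood carries no information there) is drawn directly from
its prior — its exact full conditional.

Proposal standard deviations adapt during burn-in only (Robbins–Monro
towards 0.44 acceptance) and are frozen afterwards to preserve detailed
balance. Covariates are centred and scaled to unit SD before fitting; the
transform is recorded so effects can be reported on the original scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .core_data import DataError, DistrictGraph, PanelData, RunConfig

logger = logging.getLogger(__name__)

_TAU_NAMES = ("tau_u", "tau_v", "tau_x", "tau_eps")


@dataclass
class ModelState:
    """One point in parameter space (natural, unstandardised covariate scale
    unless stated otherwise by the caller)."""

    alpha: float
    beta: np.ndarray          # (k,)
    U: np.ndarray             # (n,)
    V: np.ndarray             # (n,)
    X_t: np.ndarray           # (T,)
    eps: np.ndarray           # (n, T)
    tau_u: float = 1.0
    tau_v: float = 1.0
    tau_x: float = 1.0
    tau_eps: float = 1.0

    def __post_init__(self) -> None:
        for name in _TAU_NAMES:
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, pooled across chains (tagged by ``chain_id``).

    ``log_lambda`` holds the linear predictor per draw, from which the
    relative risk ``lambda = exp(log_lambda)`` derives. Betas are stored on
    the standardised covariate scale; ``covariate_transform`` maps them back.
    """

    district_ids: tuple[str, ...]
    years: tuple[int, ...]
    beta_names: tuple[str, ...]
    chain_id: np.ndarray              # (n_draws,)
    alpha: np.ndarray                 # (n_draws,) standardised scale
    beta: np.ndarray                  # (n_draws, k) standardised scale
    tau: dict[str, np.ndarray]        # name -> (n_draws,)
    U: np.ndarray                     # (n_draws, n)
    log_lambda: np.ndarray            # (n_draws, n, T)
    covariate_transform: dict[str, tuple[float, float]]  # name -> (mean, sd)
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    config: RunConfig | None = None

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def lambda_draws(self) -> np.ndarray:
        """(n_draws, n_districts, n_years) relative-risk draws."""
        return np.exp(self.log_lambda)

    def beta_original_scale(self) -> np.ndarray:
        """Covariate effects per unit of the raw covariate."""
        sds = np.array([self.covariate_transform[c][1] for c in self.beta_names])
        return self.beta / sds

    def alpha_original_scale(self) -> np.ndarray:
        """Intercept at raw covariate value zero."""
        out = self.alpha.copy()
        for j, c in enumerate(self.beta_names):
            m, s = self.covariate_transform[c]
            out -= self.beta[:, j] * m / s
        return out

    def parameter_draws(self) -> dict[str, np.ndarray]:
        """Scalar parameter draws keyed by name (for diagnostics)."""
        out = {"alpha": self.alpha}
        for j, c in enumerate(self.beta_names):
            out[f"beta_{c}"] = self.beta[:, j]
        out.update(self.tau)
        return out

    def split_by_chain(self, draws: np.ndarray) -> list[np.ndarray]:
        return [draws[self.chain_id == c] for c in np.unique(self.chain_id)]


# ---------------------------------------------------------------------------
# Persistence: compressed columnar draws + JSON manifest
# ---------------------------------------------------------------------------

def save_samples(samples: PosteriorSamples, path) -> None:
    """Write draws to ``<path>`` (.npz) and a ``<path>.manifest.json``."""
    import json
    from pathlib import Path
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez_compressed(
        path, chain_id=samples.chain_id, alpha=samples.alpha,
        beta=samples.beta, U=samples.U, log_lambda=samples.log_lambda,
        **{name: samples.tau[name] for name in _TAU_NAMES})
    manifest = {
        "district_ids": list(samples.district_ids),
        "years": [int(y) for y in samples.years],
        "beta_names": list(samples.beta_names),
        "covariate_transform": {k: list(v) for k, v
                                in samples.covariate_transform.items()},
        "acceptance_rates": samples.acceptance_rates,
        "config": samples.config.to_dict() if samples.config else None,
        "config_hash": samples.config.config_hash() if samples.config else None,
        "n_draws": samples.n_draws,
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def load_samples(path) -> PosteriorSamples:
    import json
    from pathlib import Path
    from .core_data import RunConfig as _RC
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    manifest = json.loads(Path(str(path) + ".manifest.json").read_text())
    cfg = (_RC.from_dict(manifest["config"])
           if manifest.get("config") else None)
    return PosteriorSamples(
        district_ids=tuple(manifest["district_ids"]),
        years=tuple(manifest["years"]),
        beta_names=tuple(manifest["beta_names"]),
        chain_id=arrays["chain_id"], alpha=arrays["alpha"],
        beta=arrays["beta"],
        tau={name: arrays[name] for name in _TAU_NAMES},
        U=arrays["U"], log_lambda=arrays["log_lambda"],
        covariate_transform={k: tuple(v) for k, v
                             in manifest["covariate_transform"].items()},
        acceptance_rates=manifest.get("acceptance_rates", {}),
        config=cfg)


# ---------------------------------------------------------------------------
# Likelihood and ICAR conditional
# ---------------------------------------------------------------------------

def linear_predictor(state: ModelState, panel: PanelData,
                     covariate_selection: Sequence[str],
                     transform: Mapping[str, tuple[float, float]] | None = None,
                     ) -> np.ndarray:
    """log lambda(i, t) for a given state; covariates optionally standardised."""
    eta = np.full((panel.n_districts, panel.n_years), state.alpha)
    for j, name in enumerate(covariate_selection):
        x = panel.covariates[name]
        if transform is not None:
            m, s = transform[name]
            x = (x - m) / s
        eta = eta + state.beta[j] * x
    eta = eta + state.U[:, None] + state.V[:, None]
    eta = eta + state.X_t[None, :] + state.eps
    return eta


def log_likelihood(state: ModelState, panel: PanelData,
                   covariate_selection: Sequence[str] = (),
                   transform: Mapping[str, tuple[float, float]] | None = None,
                   ) -> float:
    """Poisson log likelihood over observed cells; masked cells contribute 0.

    ``sum_obs [ Y log(E lambda) - E lambda - log Y! ]``.
    """
    eta = linear_predictor(state, panel, covariate_selection, transform)
    bad = ~np.isfinite(eta)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-finite linear predictor at "
            f"({panel.district_ids[i]}, {panel.years[j]})")
    m = panel.observed_mask
    log_mu = np.log(panel.E[m]) + eta[m]
    y = panel.Y[m]
    return float(np.sum(y * log_mu - np.exp(log_mu) - gammaln(y + 1.0)))


def icar_conditional(U: np.ndarray, graph: DistrictGraph, tau_u: float,
                     district: str) -> tuple[float, float]:
    """Full-conditional (mean, precision) of one district's spatial effect.

    Intrinsic CAR: mean is the average of the neighbours' effects and the
    precision is ``tau_u * degree``. Isolated districts have no conditional
    (their effect is pinned to zero by design) and raise an error.
    """
    i = graph.index[district]
    nbrs = graph.neighbors()[i]
    if len(nbrs) == 0:
        raise DataError(f"district {district!r} is isolated; U_i is fixed at 0")
    return float(np.mean(U[nbrs])), float(tau_u * len(nbrs))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _adjacency_matrix(graph: DistrictGraph) -> sp.csr_matrix:
    n = graph.n_districts
    ei, ej = graph.edge_index_arrays()
    data = np.ones(2 * len(ei))
    rows = np.concatenate([ei, ej])
    cols = np.concatenate([ej, ei])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


class _Adapter:
    """Robbins–Monro adaptation of a log proposal scale during burn-in."""

    def __init__(self, initial_sd: float, target: float = 0.44):
        self.log_sd = math.log(initial_sd)
        self.target = target
        self.t = 0
        self.accepted = 0.0
        self.proposed = 0

    @property
    def sd(self) -> float:
        return math.exp(self.log_sd)

    def update(self, acc_rate: float, adapting: bool) -> None:
        self.t += 1
        if adapting:
            self.log_sd += self.t ** -0.6 * (acc_rate - self.target)
            self.log_sd = min(max(self.log_sd, -15.0), 5.0)
        else:
            self.accepted += acc_rate
            self.proposed += 1

    @property
    def post_adaptation_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else float("nan")


def fit(panel: PanelData, graph: DistrictGraph, config: RunConfig,
        chain_seeds: Sequence[int] | None = None) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains and pool retained draws.

    Chain ``c`` is seeded ``config.seed + c`` unless explicit ``chain_seeds``
    are given. Returns draws of alpha, betas (standardised scale), the
    precisions, U and the full log-relative-risk surface.
    """
    if tuple(panel.district_ids) != tuple(graph.district_ids):
        raise DataError("panel and graph districts are not aligned")
    if chain_seeds is None:
        chain_seeds = [config.seed + c for c in range(config.n_chains)]
    if len(chain_seeds) != config.n_chains:
        raise DataError("need one seed per chain")

    selection = tuple(config.covariate_selection)
    transform: dict[str, tuple[float, float]] = {}
    Z = []
    for name in selection:
        x = panel.covariates[name]
        m, s = float(x.mean()), float(x.std())
        if s < 1e-12:
            raise DataError(f"covariate {name!r} is constant; cannot standardise")
        transform[name] = (m, s)
        Z.append((x - m) / s)

    chains = [_run_chain(panel, graph, config, Z, int(seed), chain_id=c)
              for c, seed in enumerate(chain_seeds)]

    pooled = {k: np.concatenate([ch[k] for ch in chains]) for k in chains[0]
              if k not in ("acceptance",)}
    acc = {f"chain{c}:{k}": v for c, ch in enumerate(chains)
           for k, v in ch["acceptance"].items()}
    for name, rate in acc.items():
        if not (0.05 <= rate <= 0.95):
            logger.warning("acceptance rate for %s outside [0.05, 0.95]: %.3f",
                           name, rate)

    return PosteriorSamples(
        district_ids=panel.district_ids,
        years=panel.years,
        beta_names=selection,
        chain_id=pooled["chain_id"],
        alpha=pooled["alpha"],
        beta=pooled["beta"],
        tau={name: pooled[name] for name in _TAU_NAMES},
        U=pooled["U"],
        log_lambda=pooled["log_lambda"],
        covariate_transform=transform,
        acceptance_rates=acc,
        config=config,
    )


def _run_chain(panel: PanelData, graph: DistrictGraph, config: RunConfig,
               Z: list[np.ndarray], seed: int, chain_id: int) -> dict:
    rng = np.random.default_rng(seed)
    n, T = panel.n_districts, panel.n_years
    k = len(Z)
    priors = config.priors
    coef_prec = 1.0 / priors.coef_variance

    use_spatial = "spatial" in config.components
    use_unstruct = "unstructured" in config.components
    use_temporal = "temporal" in config.components
    use_residual = "residual" in config.components

    M = panel.observed_mask
    Mf = M.astype(float)
    Ymask = np.where(M, panel.Y, 0).astype(float)
    E = panel.E
    sumY = float(Ymask.sum())
    rowY = Ymask.sum(axis=1)          # per district over observed years
    colY = Ymask.sum(axis=0)          # per year over observed districts
    zY = [float((Ymask * z).sum()) for z in Z]

    A = _adjacency_matrix(graph)
    degree = graph.neighbor_counts.astype(float)
    free = degree > 0
    colors = graph.coloring()
    color_groups = [np.where(free & (colors == c))[0]
                    for c in range(int(colors.max()) + 1 if n else 0)]
    color_groups = [g for g in color_groups if len(g)]
    icar_rank = graph.icar_rank()
    ei, ej = graph.edge_index_arrays()

    fixed = dict(config.fixed_precisions)

    # Moment-based initial intercept keeps the first likelihood finite even
    # for very sparse panels.
    sumE_obs = float((E * Mf).sum())
    alpha = math.log(max(sumY, 0.5) / sumE_obs) if sumE_obs > 0 else 0.0
    beta = np.zeros(k)
    U = np.zeros(n)
    V = np.zeros(n)
    Xt = np.zeros(T)
    eps = np.zeros((n, T))
    tau = {name: float(fixed.get(name, 1.0)) for name in _TAU_NAMES}

    eta = np.full((n, T), alpha)
    for j in range(k):
        eta += beta[j] * Z[j]
    mu = E * np.exp(eta)
    if not np.all(np.isfinite(mu)):
        raise DataError("non-finite likelihood at initial state")

    # Decomposition of each standardised covariate into a district profile
    # (absorbed by U), a year profile (absorbed by X_t) and a residual.
    # Used by the translation moves below to break the posterior correlation
    # between the fixed effects and the random-effect surfaces.
    z_row, z_col, z_res = [], [], []
    for z in Z:
        r = z.mean(axis=1)
        r = np.where(free, r, 0.0)
        if free.any():
            r = r - np.where(free, r[free].mean(), 0.0) * free
        c = z.mean(axis=0)
        res = z - r[:, None] - c[None, :]
        z_row.append(r)
        z_col.append(c)
        z_res.append(res)

    adapters = {"alpha": _Adapter(0.1)}
    for j in range(k):
        adapters[f"beta{j}"] = _Adapter(0.1)
    if use_spatial and icar_rank > 0:
        adapters["U"] = _Adapter(0.3)
    if use_unstruct:
        adapters["V"] = _Adapter(0.3)
    if use_temporal:
        adapters["X"] = _Adapter(0.3)
    if use_residual:
        adapters["eps"] = _Adapter(0.5)
    if use_spatial and use_unstruct and color_groups:
        adapters["swap_UV"] = _Adapter(0.2)
    if use_temporal:
        adapters["shift_alpha_X"] = _Adapter(0.2)
    if use_unstruct:
        adapters["shift_alpha_V"] = _Adapter(0.2)
    for j in range(k):
        adapters[f"shift_beta{j}"] = _Adapter(0.2)
        if use_residual:
            adapters[f"shift_beta_eps{j}"] = _Adapter(0.05)
        if use_residual and use_spatial and use_temporal:
            adapters[f"shift_beta_full{j}"] = _Adapter(0.2)
        if use_residual and use_unstruct and use_temporal:
            adapters[f"shift_beta_fullV{j}"] = _Adapter(0.2)

    n_ret = config.retained_per_chain
    out = {
        "chain_id": np.full(n_ret, chain_id, dtype=np.int64),
        "alpha": np.empty(n_ret),
        "beta": np.empty((n_ret, k)),
        "U": np.empty((n_ret, n)),
        "log_lambda": np.empty((n_ret, n, T)),
        **{name: np.empty(n_ret) for name in _TAU_NAMES},
    }

    ret = 0
    for it in range(config.iterations_per_chain):
        adapting = it < config.burn_in

        # --- alpha: scalar random walk; a shift d moves every eta by d.
        ad = adapters["alpha"]
        d = rng.normal(0.0, ad.sd)
        S = float((mu * Mf).sum())
        dll = d * sumY - (math.expm1(d)) * S
        dlp = -coef_prec / 2 * ((alpha + d) ** 2 - alpha ** 2)
        if math.log(rng.random()) < dll + dlp:
            alpha += d
            eta += d
            mu *= math.exp(d)
            ad.update(1.0, adapting)
        else:
            ad.update(0.0, adapting)

        # --- betas: scalar random walks on the standardised scale.
        for j in range(k):
            ad = adapters[f"beta{j}"]
            d = rng.normal(0.0, ad.sd)
            grow = np.exp(d * Z[j])
            dll = d * zY[j] - float((mu * Mf * (grow - 1.0)).sum())
            dlp = -coef_prec / 2 * ((beta[j] + d) ** 2 - beta[j] ** 2)
            if math.log(rng.random()) < dll + dlp:
                beta[j] += d
                eta += d * Z[j]
                mu *= grow
                ad.update(1.0, adapting)
            else:
                ad.update(0.0, adapting)

        # --- U: one color class at a time (same-color districts are
        # non-adjacent, hence conditionally independent under ICAR).
        if use_spatial and color_groups:
            ad = adapters["U"]
            acc_sum, acc_n = 0.0, 0
            for g in color_groups:
                d = rng.normal(0.0, ad.sd, size=len(g))
                row_mu = (mu * Mf)[g].sum(axis=1)
                dll = d * rowY[g] - np.expm1(d) * row_mu
                nbr_sum = A @ U
                dlp = -tau["tau_u"] / 2 * (
                    degree[g] * ((U[g] + d) ** 2 - U[g] ** 2)
                    - 2 * d * nbr_sum[g])
                accept = np.log(rng.random(len(g))) < dll + dlp
                step = np.where(accept, d, 0.0)
                U[g] += step
                eta[g] += step[:, None]
                mu[g] *= np.exp(step)[:, None]
                acc_sum += accept.sum()
                acc_n += len(g)
            # Sum-to-zero recentring over connected districts (isolated stay
            # at 0); the intercept re-absorbs the level over iterations.
            mshift = U[free].mean()
            U[free] -= mshift
            eta[free] -= mshift
            mu[free] *= math.exp(-mshift)
            ad.update(acc_sum / acc_n, adapting)

        # --- V: element-wise vectorised random walk.
        if use_unstruct:
            ad = adapters["V"]
            d = rng.normal(0.0, ad.sd, size=n)
            row_mu = (mu * Mf).sum(axis=1)
            dll = d * rowY - np.expm1(d) * row_mu
            dlp = -tau["tau_v"] / 2 * ((V + d) ** 2 - V ** 2)
            accept = np.log(rng.random(n)) < dll + dlp
            step = np.where(accept, d, 0.0)
            V += step
            eta += step[:, None]
            mu *= np.exp(step)[:, None]
            ad.update(accept.mean(), adapting)

        # --- X_t: element-wise per year.
        if use_temporal:
            ad = adapters["X"]
            d = rng.normal(0.0, ad.sd, size=T)
            col_mu = (mu * Mf).sum(axis=0)
            dll = d * colY - np.expm1(d) * col_mu
            dlp = -tau["tau_x"] / 2 * ((Xt + d) ** 2 - Xt ** 2)
            accept = np.log(rng.random(T)) < dll + dlp
            step = np.where(accept, d, 0.0)
            Xt += step
            eta += step[None, :]
            mu *= np.exp(step)[None, :]
            ad.update(accept.mean(), adapting)

        # --- eps: element-wise over cells; prior Gibbs draw at unobserved
        # cells (exact full conditional there).
        if use_residual:
            ad = adapters["eps"]
            d = rng.normal(0.0, ad.sd, size=(n, T))
            dll = d * Ymask - mu * Mf * np.expm1(d)
            dlp = -tau["tau_eps"] / 2 * ((eps + d) ** 2 - eps ** 2)
            accept = (np.log(rng.random((n, T))) < dll + dlp) & M
            step = np.where(accept, d, 0.0)
            fresh = rng.normal(0.0, tau["tau_eps"] ** -0.5, size=(n, T))
            step = np.where(M, step, fresh - eps)
            eps += step
            eta += step
            mu *= np.exp(step)
            ad.update(accept[M].mean() if M.any() else 0.0, adapting)

        # --- translation moves. The linear predictor is invariant (or
        # nearly so) under these joint shifts, so they cost only prior
        # ratios yet break the posterior correlations that make alpha and
        # the betas mix slowly against the random-effect levels.

        # U_i <-> V_i exchange (eta exactly invariant): reallocates the
        # convolution between its structured and unstructured halves, the
        # classic weak direction of BYM-type models.
        if use_spatial and use_unstruct and color_groups:
            ad = adapters["swap_UV"]
            acc_sum, acc_n = 0.0, 0
            for g in color_groups:
                w = rng.normal(0.0, ad.sd, size=len(g))
                nbr_sum = A @ U
                dlp = (-tau["tau_u"] / 2 * (degree[g] * ((U[g] + w) ** 2
                                                         - U[g] ** 2)
                                            - 2 * w * nbr_sum[g])
                       - tau["tau_v"] / 2 * ((V[g] - w) ** 2 - V[g] ** 2))
                accept = np.log(rng.random(len(g))) < dlp
                step = np.where(accept, w, 0.0)
                U[g] += step
                V[g] -= step
                acc_sum += accept.sum()
                acc_n += len(g)
            mshift = U[free].mean()
            U[free] -= mshift
            V[free] += mshift
            ad.update(acc_sum / acc_n, adapting)

        # alpha <-> level of X_t (eta exactly invariant).
        if use_temporal:
            ad = adapters["shift_alpha_X"]
            d = rng.normal(0.0, ad.sd)
            dlp = (-coef_prec / 2 * ((alpha + d) ** 2 - alpha ** 2)
                   - tau["tau_x"] / 2 * float(np.sum((Xt - d) ** 2 - Xt ** 2)))
            if math.log(rng.random()) < dlp:
                alpha += d
                Xt -= d
                ad.update(1.0, adapting)
            else:
                ad.update(0.0, adapting)

        # alpha <-> level of V (eta exactly invariant).
        if use_unstruct:
            ad = adapters["shift_alpha_V"]
            d = rng.normal(0.0, ad.sd)
            dlp = (-coef_prec / 2 * ((alpha + d) ** 2 - alpha ** 2)
                   - tau["tau_v"] / 2 * float(np.sum((V - d) ** 2 - V ** 2)))
            if math.log(rng.random()) < dlp:
                alpha += d
                V -= d
                ad.update(1.0, adapting)
            else:
                ad.update(0.0, adapting)

        # beta_j <-> (U district profile, X_t year profile): only the
        # non-separable residual of the covariate touches the likelihood.
        for j in range(k):
            ad = adapters[f"shift_beta{j}"]
            d = rng.normal(0.0, ad.sd)
            grow = np.exp(d * z_res[j])
            dll = d * float((Ymask * z_res[j]).sum()) \
                - float((mu * Mf * (grow - 1.0)).sum())
            dlp = -coef_prec / 2 * ((beta[j] + d) ** 2 - beta[j] ** 2)
            if use_spatial and free.any():
                dU = U[ei] - U[ej]
                dr = z_row[j][ei] - z_row[j][ej]
                dlp += -tau["tau_u"] / 2 * float(
                    np.sum((dU - d * dr) ** 2 - dU ** 2))
            else:
                # No spatial field to absorb the district profile; let V
                # take it instead.
                dlp += -tau["tau_v"] / 2 * float(
                    np.sum((V - d * z_row[j]) ** 2 - V ** 2)) \
                    if use_unstruct else -np.inf if np.any(z_row[j]) else 0.0
            if use_temporal:
                dlp += -tau["tau_x"] / 2 * float(
                    np.sum((Xt - d * z_col[j]) ** 2 - Xt ** 2))
            elif np.any(z_col[j]):
                dlp += -np.inf
            if math.log(rng.random()) < dll + dlp:
                beta[j] += d
                if use_spatial and free.any():
                    U -= d * z_row[j]
                elif use_unstruct:
                    V -= d * z_row[j]
                if use_temporal:
                    Xt -= d * z_col[j]
                eta += d * z_res[j]
                mu *= grow
                ad.update(1.0, adapting)
            else:
                ad.update(0.0, adapting)

        # beta_j <-> eps surface (eta exactly invariant): lets the fixed
        # effect move against the residual field at prior-only cost.
        if use_residual:
            for j in range(k):
                ad = adapters[f"shift_beta_eps{j}"]
                d = rng.normal(0.0, ad.sd)
                z = Z[j]
                dlp = (-coef_prec / 2 * ((beta[j] + d) ** 2 - beta[j] ** 2)
                       - tau["tau_eps"] / 2 * float(
                           np.sum((eps - d * z) ** 2 - eps ** 2)))
                if math.log(rng.random()) < dlp:
                    beta[j] += d
                    eps -= d * z
                    ad.update(1.0, adapting)
                else:
                    ad.update(0.0, adapting)

        # beta_j <-> (U, X_t, eps) jointly (eta exactly invariant): the
        # district profile of the covariate goes to U, the year profile to
        # X_t and the non-separable remainder to eps, so the move is
        # likelihood-free along the complete covariate direction.
        if use_residual and use_spatial and use_temporal:
            for j in range(k):
                ad = adapters[f"shift_beta_full{j}"]
                d = rng.normal(0.0, ad.sd)
                dU = U[ei] - U[ej]
                dr = z_row[j][ei] - z_row[j][ej]
                dlp = (-coef_prec / 2 * ((beta[j] + d) ** 2 - beta[j] ** 2)
                       - tau["tau_u"] / 2 * float(
                           np.sum((dU - d * dr) ** 2 - dU ** 2))
                       - tau["tau_x"] / 2 * float(
                           np.sum((Xt - d * z_col[j]) ** 2 - Xt ** 2))
                       - tau["tau_eps"] / 2 * float(
                           np.sum((eps - d * z_res[j]) ** 2 - eps ** 2)))
                if math.log(rng.random()) < dlp:
                    beta[j] += d
                    U -= d * z_row[j]
                    Xt -= d * z_col[j]
                    eps -= d * z_res[j]
                    ad.update(1.0, adapting)
                else:
                    ad.update(0.0, adapting)

        # Same joint move with V absorbing the district profile — effective
        # when the spatial field has collapsed and V carries the structure.
        if use_residual and use_unstruct and use_temporal:
            for j in range(k):
                ad = adapters[f"shift_beta_fullV{j}"]
                d = rng.normal(0.0, ad.sd)
                dlp = (-coef_prec / 2 * ((beta[j] + d) ** 2 - beta[j] ** 2)
                       - tau["tau_v"] / 2 * float(
                           np.sum((V - d * z_row[j]) ** 2 - V ** 2))
                       - tau["tau_x"] / 2 * float(
                           np.sum((Xt - d * z_col[j]) ** 2 - Xt ** 2))
                       - tau["tau_eps"] / 2 * float(
                           np.sum((eps - d * z_res[j]) ** 2 - eps ** 2)))
                if math.log(rng.random()) < dlp:
                    beta[j] += d
                    V -= d * z_row[j]
                    Xt -= d * z_col[j]
                    eps -= d * z_res[j]
                    ad.update(1.0, adapting)
                else:
                    ad.update(0.0, adapting)

        # --- precisions: conjugate gamma Gibbs (skipped when fixed).
        a, b = priors.tau_shape, priors.tau_rate
        if use_spatial and "tau_u" not in fixed and icar_rank > 0:
            ss = float(((U[ei] - U[ej]) ** 2).sum())
            tau["tau_u"] = rng.gamma(a + icar_rank / 2, 1.0 / (b + ss / 2))
        if use_unstruct and "tau_v" not in fixed:
            tau["tau_v"] = rng.gamma(a + n / 2, 1.0 / (b + float(V @ V) / 2))
        if use_temporal and "tau_x" not in fixed:
            tau["tau_x"] = rng.gamma(a + T / 2, 1.0 / (b + float(Xt @ Xt) / 2))
        if use_residual and "tau_eps" not in fixed:
            tau["tau_eps"] = rng.gamma(a + n * T / 2,
                                       1.0 / (b + float((eps * eps).sum()) / 2))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["alpha"][ret] = alpha
            out["beta"][ret] = beta
            out["U"][ret] = U
            out["log_lambda"][ret] = eta
            for name in _TAU_NAMES:
                out[name][ret] = tau[name]
            ret += 1

    assert ret == n_ret
    out["acceptance"] = {name: ad.post_adaptation_rate
                         for name, ad in adapters.items()}
    return out
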