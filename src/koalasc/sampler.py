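"""Metropolis-within-Gibbs sampler for the SC model.

Update scheme per iteration: exact Gibbs sweep over the inclusion flags z,
exact conjugate draw for psi, per-individual random-walk moves for the
activity centres (uniform redraw for excluded individuals), and log-scale
Metropolis for lambda0 and sigma. Proposal scales adapt during a declared
adaptive phase and are frozen afterwards. Multiple chains run from distinct
seeds; convergence is judged with the Gelman-Rubin potential scale reduction
factor (values below 1.1 taken as converged).

The study-scale settings are M = 500 augmented individuals and three chains
of 50,000 iterations with 10,000 burn-in after a 1,000-iteration adaptive
phase, unthinned; :meth:`MCMCConfig.desk` gives the reduced desk-scale
configuration used throughout the test-suite experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _kernels
from .containers import DetectorArray, NightlyCounts
from .model import LatentState, PriorSpec, StateSpace

__all__ = [
    "MCMCConfig",
    "Snapshots",
    "PosteriorDraws",
    "update_z",
    "update_s",
    "update_scalars",
    "run_chains",
    "gelman_rubin",
    "summarize",
]

MONITORED = ("N", "D", "lambda0", "sigma", "psi")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings. Defaults are the study-scale settings."""

    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 10_000
    n_adapt: int = 1_000
    thin: int = 1
    M: int = 500
    seeds: tuple[int, ...] = (101, 202, 303)
    step_s: float = 200.0      # metres, activity-centre random walk
    step_lambda0: float = 0.5  # log-scale
    step_sigma: float = 0.2    # log-scale
    snapshot_every: int = 10   # retained iterations between z/s snapshots

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.n_adapt > self.n_burnin:
            raise ValueError("adaptive phase must end before burn-in does")
        if self.thin < 1 or self.M < 1:
            raise ValueError("thin and M must be >= 1")
        if len(self.seeds) != self.n_chains:
            raise ValueError("need one seed per chain")
        if len(set(self.seeds)) != self.n_chains:
            raise ValueError("chain seeds must be distinct")

    @classmethod
    def desk(cls, seed: int = 1, **overrides) -> "MCMCConfig":
        """Reduced desk-scale settings (M=150, 3 x 5,000, burn 1,000)."""
        seeds = tuple(int(s) for s in seed_sequence(seed, overrides.get("n_chains", 3)))
        kw = dict(
            n_chains=3, n_iter=5_000, n_burnin=1_000, n_adapt=1_000,
            thin=1, M=150, seeds=seeds,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        return d


def seed_sequence(base_seed: int, n: int) -> np.ndarray:
    """n distinct deterministic 31-bit chain seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 1)).astype(np.int64) + 1


@dataclass
class Snapshots:
    """Retained (z, s) states for density-surface mapping, pooled over chains."""

    chain: np.ndarray      # (S,)
    iteration: np.ndarray  # (S,)
    x: np.ndarray          # (S, M)
    y: np.ndarray          # (S, M)
    z: np.ndarray          # (S, M) 0/1

    @property
    def n_snapshots(self) -> int:
        return self.chain.shape[0]

    def to_frame(self) -> pd.DataFrame:
        S, M = self.x.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(self.chain, M),
                "iteration": np.repeat(self.iteration, M),
                "individual": np.tile(np.arange(M), S),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "z": self.z.ravel().astype(int),
            }
        )


@dataclass
class PosteriorDraws:
    """Monitored chains: params maps name -> (n_chains, n_retained) array."""

    params: dict[str, np.ndarray]
    snapshots: Snapshots
    area_ha: float
    M: int
    accept_rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    final_steps: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, iteration, parameter, value)."""
        rows = []
        for name, arr in self.params.items():
            nc, nk = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(1, nc + 1), nk),
                        "iteration": np.tile(np.arange(nk), nc),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _sufficient_stats(counts: NightlyCounts) -> tuple[np.ndarray, np.ndarray]:
    n_j = counts.detector_totals().astype(float)
    k_j = counts.effective_nights().astype(float)
    return n_j, k_j


def _sigma_prior_args(priors: PriorSpec) -> tuple[int, float, float]:
    if priors.sigma_dist == "uniform":
        return _kernels.SIGMA_UNIFORM, priors.sigma_lo, priors.sigma_hi
    return _kernels.SIGMA_GAMMA, priors.sigma_shape, priors.sigma_rate


def _state_arrays(state: LatentState, array: DetectorArray):
    R = np.empty((state.M, array.n_detectors))
    T = np.empty(array.n_detectors)
    _kernels.compute_R(state.sx, state.sy, array.x, array.y, state.sigma, R)
    _kernels.compute_T(state.z, R, T)
    return R, T


def update_z(
    state: LatentState,
    counts: NightlyCounts,
    array: DetectorArray,
    seed: int | None = None,
) -> LatentState:
    """Gibbs sweep over inclusion flags from their exact Bernoulli conditionals."""
    if seed is not None:
        _kernels.set_seed(seed)
    new = state.copy()
    n_j, k_j = _sufficient_stats(counts)
    R, T = _state_arrays(new, array)
    _kernels.update_z(new.z, R, T, new.lambda0, new.psi, n_j, k_j)
    return new


def update_s(
    state: LatentState,
    counts: NightlyCounts,
    array: DetectorArray,
    state_space: StateSpace,
    step: float,
    seed: int | None = None,
) -> LatentState:
    """Random-walk activity-centre moves (uniform redraw where z=0)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if seed is not None:
        _kernels.set_seed(seed)
    new = state.copy()
    n_j, k_j = _sufficient_stats(counts)
    R, T = _state_arrays(new, array)
    _kernels.update_s(
        new.z, new.sx, new.sy, R, T, new.lambda0, n_j, k_j,
        array.x, array.y, new.sigma,
        state_space.xmin, state_space.xmax, state_space.ymin, state_space.ymax,
        step,
    )
    return new


def update_scalars(
    state: LatentState,
    counts: NightlyCounts,
    array: DetectorArray,
    priors: PriorSpec,
    step_lambda0: float = 0.3,
    step_sigma: float = 0.15,
    seed: int | None = None,
) -> LatentState:
    """lambda0 and sigma log-scale Metropolis; psi exact conjugate beta draw."""
    if seed is not None:
        _kernels.set_seed(seed)
    new = state.copy()
    n_j, k_j = _sufficient_stats(counts)
    R, T = _state_arrays(new, array)
    lam, _ = _kernels.update_lambda0(
        new.lambda0, T, n_j, k_j, priors.lambda0_lo, priors.lambda0_hi, step_lambda0
    )
    new.lambda0 = float(lam)
    kind, p1, p2 = _sigma_prior_args(priors)
    r_buf = np.empty_like(R)
    t_buf = np.empty_like(T)
    sig, _ = _kernels.update_sigma(
        new.sigma, new.z, new.sx, new.sy, R, T, new.lambda0, n_j, k_j,
        array.x, array.y, kind, p1, p2, step_sigma, r_buf, t_buf,
    )
    new.sigma = float(sig)
    new.psi = float(_kernels.update_psi(new.z, priors.psi_a, priors.psi_b))
    return new


def _init_values(counts: NightlyCounts, priors: PriorSpec) -> tuple[float, float]:
    n_j, k_j = _sufficient_stats(counts)
    mean_count = n_j.sum() / max(k_j.sum(), 1.0)
    lam0 = float(np.clip(mean_count, 0.05, 0.99 * priors.lambda0_hi))
    lam0 = max(lam0, priors.lambda0_lo + 1e-6)
    sigma0 = float(priors.sigma_mean)
    if priors.sigma_dist == "uniform" and not (
        priors.sigma_lo < sigma0 < priors.sigma_hi
    ):
        sigma0 = 0.5 * (priors.sigma_lo + priors.sigma_hi)
    return lam0, sigma0


def run_chains(
    counts: NightlyCounts,
    array: DetectorArray,
    state_space: StateSpace,
    priors: PriorSpec,
    config: MCMCConfig,
) -> PosteriorDraws:
    """Run all chains and collect monitored draws and z/s snapshots.

    Raises on an all-masked count matrix; warns when the posterior for N
    piles up at the augmentation ceiling M (M set too small).
    """
    if counts.n_detectors != array.n_detectors:
        raise ValueError("counts and array disagree on the number of detectors")
    n_j, k_j = _sufficient_stats(counts)
    if k_j.sum() == 0:
        raise ValueError("all detector-nights are masked; nothing to fit")
    lam0, sigma0 = _init_values(counts, priors)
    kind, p1, p2 = _sigma_prior_args(priors)
    per_chain = []
    snaps = []
    acc = []
    steps = []
    for c in range(config.n_chains):
        draws, snap_iter, sx, sy, sz, fsteps, arates = _kernels.run_chain(
            int(config.seeds[c]), array.x, array.y, n_j, k_j, config.M,
            state_space.xmin, state_space.xmax,
            state_space.ymin, state_space.ymax,
            priors.lambda0_lo, priors.lambda0_hi, priors.psi_a, priors.psi_b,
            kind, p1, p2,
            config.n_iter, config.n_burnin, config.n_adapt, config.thin,
            config.snapshot_every,
            lam0, sigma0,
            config.step_s, config.step_lambda0, config.step_sigma,
        )
        per_chain.append(draws)
        snaps.append((np.full(snap_iter.shape[0], c + 1), snap_iter, sx, sy, sz))
        acc.append(arates)
        steps.append(fsteps)
    stacked = np.stack(per_chain)  # (chains, kept, 4)
    params = {
        "N": stacked[:, :, 0],
        "D": stacked[:, :, 0] / state_space.area_ha,
        "lambda0": stacked[:, :, 1],
        "sigma": stacked[:, :, 2],
        "psi": stacked[:, :, 3],
    }
    snapshots = Snapshots(
        chain=np.concatenate([s[0] for s in snaps]),
        iteration=np.concatenate([s[1] for s in snaps]),
        x=np.concatenate([s[2] for s in snaps]),
        y=np.concatenate([s[3] for s in snaps]),
        z=np.concatenate([s[4] for s in snaps]),
    )
    out = PosteriorDraws(
        params=params,
        snapshots=snapshots,
        area_ha=state_space.area_ha,
        M=config.M,
        accept_rates=np.stack(acc),
        final_steps=np.stack(steps),
    )
    at_ceiling = (params["N"] >= config.M - 1).mean()
    if at_ceiling > 0.01:
        warnings.warn(
            f"posterior for N piles at the augmentation ceiling M={config.M} "
            f"({100 * at_ceiling:.1f}% of draws at M-1 or M); increase M",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray]) -> pd.Series:
    """Potential scale reduction factor per monitored parameter.

    Classic between/within-chain variance form: with m chains of length n,
    W = mean within-chain variance, B/n = variance of chain means, and
    R-hat = sqrt(((n-1)/n + (B/n)/W)). Zero within-chain variance makes the
    statistic undefined and is reported as NaN.
    """
    params = draws.params if isinstance(draws, PosteriorDraws) else draws
    out = {}
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains")
        n = arr.shape[1]
        if n < 2:
            raise ValueError("gelman_rubin needs >= 2 retained iterations")
        w = arr.var(axis=1, ddof=1).mean()
        b_over_n = arr.mean(axis=1).var(ddof=1)
        if w == 0.0:
            out[name] = np.nan
            continue
        var_plus = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(var_plus / w))
    return pd.Series(out, name="rhat")


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and central 50% credible interval, pooled across chains.

    Density D is in males per hectare. Percentiles use the default linear
    interpolation rule.
    """
    if isinstance(draws, PosteriorDraws) and draws.n_retained == 0:
        raise ValueError("no retained draws to summarise")
    rows = []
    for name, arr in draws.params.items():
        pooled = np.asarray(arr, dtype=float).ravel()
        rows.append(
            {
                "parameter": name,
                "mean": pooled.mean(),
                "q25": np.percentile(pooled, 25),
                "q75": np.percentile(pooled, 75),
                "q2.5": np.percentile(pooled, 2.5),
                "q97.5": np.percentile(pooled, 97.5),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
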