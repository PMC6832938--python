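"""Generic MCMC engine: adaptive Metropolis-within-Gibbs and posterior summaries.

The sampler updates one scalar unknown at a time with a normal random walk,
sweeping over all unknowns once per iteration.  Proposal scales are adapted
during burn-in towards the ~0.44 acceptance rate that is optimal for scalar
random-walk Metropolis, then frozen so the post-burn-in chain is a genuine
Markov chain.  Chains are vectorised: a single sweep proposes for every
chain simultaneously, so the target log density must accept a state matrix
of shape ``(n_chains, n_params)`` and return one log density per chain.

Transformations (log scales for positive parameters, bounds) are the
responsibility of the model that builds the log density; the engine is
agnostic and operates on the unconstrained vector it is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "sample_posterior",
    "summarize_draws",
    "split_rhat",
]

TARGET_ACCEPTANCE = 0.44  # optimal for one-dimensional random-walk Metropolis


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_iter`` draws per chain are retained after ``n_burn`` burn-in sweeps;
    ``thin`` keeps every thin-th sweep.  Defaults are desk-scale for the
    low-dimensional ISE models (a few seconds to ~2 minutes) with healthy
    effective sample sizes.
    """

    n_chains: int = 4
    n_iter: int = 10_000
    n_burn: int = 5_000
    thin: int = 1
    seed: int = 1

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for R-hat diagnostics")
        if self.n_iter < 1000:
            raise ValueError("n_iter must be >= 1000 for stable interval estimates")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_burn < 0:
            raise ValueError("n_burn must be >= 0")


class PosteriorDraws:
    """Retained MCMC draws for all model unknowns across chains.

    Access a single quantity with ``draws["b[1]"]`` -> array of shape
    ``(n_chains, n_iter)``.  Derived quantities (deterministic transforms
    computed per draw, e.g. the log LOD) can be attached with
    :meth:`add_derived`.
    """

    def __init__(self, names: Sequence[str], array: np.ndarray,
                 acceptance: dict[str, float] | None = None):
        array = np.asarray(array, dtype=float)
        if array.ndim != 3 or array.shape[2] != len(names):
            raise ValueError("array must have shape (n_chains, n_iter, n_params)")
        if not np.all(np.isfinite(array)):
            raise ValueError("posterior draws must be finite")
        self._names = list(names)
        self._array = array
        self._index = {n: i for i, n in enumerate(self._names)}
        self.acceptance = acceptance or {}
        self.warnings: list[str] = []

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def n_chains(self) -> int:
        return self._array.shape[0]

    @property
    def n_iter(self) -> int:
        return self._array.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        return self._array[:, :, self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def add_derived(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self._array.shape[:2]:
            raise ValueError("derived values must have shape (n_chains, n_iter)")
        if not np.all(np.isfinite(values)):
            raise ValueError("derived draws must be finite")
        self._array = np.concatenate([self._array, values[:, :, None]], axis=2)
        self._index[name] = len(self._names)
        self._names.append(name)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with chain and iteration columns (CSV-friendly)."""
        c, n, p = self._array.shape
        frame = pd.DataFrame(
            self._array.reshape(c * n, p), columns=self._names
        )
        frame.insert(0, "iteration", np.tile(np.arange(1, n + 1), c))
        frame.insert(0, "chain", np.repeat(np.arange(1, c + 1), n))
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_posterior(
    log_density: Callable[[np.ndarray], np.ndarray],
    initial: np.ndarray,
    names: Sequence[str],
    config: MCMCConfig = MCMCConfig(),
    initial_scales: np.ndarray | float = 0.1,
) -> PosteriorDraws:
    """Draw from ``log_density`` by adaptive Metropolis-within-Gibbs.

    Parameters
    ----------
    log_density
        Vectorised target: maps a state matrix ``(n_chains, n_params)`` to
        per-chain log densities ``(n_chains,)``.  May return ``-inf``
        outside the support.
    initial
        Start states, shape ``(n_chains, n_params)``; the log density must
        be finite at every one.
    names
        Parameter names, in column order.
    initial_scales
        Starting random-walk standard deviations (scalar or per-parameter).

    Proposal scales adapt per chain and parameter during burn-in with a
    Robbins-Monro step towards 44% acceptance and are frozen afterwards.
    Fully reproducible from ``config.seed``.  A split-chain R-hat above
    1.05 on any retained quantity attaches a warning to the result.
    """
    initial = np.atleast_2d(np.asarray(initial, dtype=float))
    n_chains, n_params = initial.shape
    if n_chains != config.n_chains:
        raise ValueError(
            f"initial has {n_chains} chains but config.n_chains={config.n_chains}"
        )
    if len(names) != n_params:
        raise ValueError("names length must match the parameter dimension")

    logp = np.asarray(log_density(initial), dtype=float)
    if logp.shape != (n_chains,):
        raise ValueError("log_density must return one value per chain")
    if not np.all(np.isfinite(logp)):
        bad = [i for i in range(n_chains) if not np.isfinite(logp[i])]
        raise ValueError(f"log density not finite at initial state of chain(s) {bad}")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    log_scale = np.full((n_chains, n_params), 0.0) + np.log(
        np.broadcast_to(np.asarray(initial_scales, dtype=float), (n_params,))
    )

    state = initial.copy()
    total_sweeps = config.n_burn + config.n_iter * config.thin
    kept = np.empty((n_chains, config.n_iter, n_params))
    accept_count = np.zeros(n_params)
    accept_total = 0
    keep_i = 0
    for sweep in range(total_sweeps):
        adapting = sweep < config.n_burn
        if adapting:
            # Robbins-Monro gain; decays so scales settle before freezing
            gain = (sweep + 1) ** -0.6
        for p in range(n_params):
            prop = state.copy()
            prop[:, p] += np.exp(log_scale[:, p]) * rng.standard_normal(n_chains)
            logp_prop = np.asarray(log_density(prop), dtype=float)
            accept = np.log(rng.random(n_chains)) < logp_prop - logp
            state[accept, p] = prop[accept, p]
            logp[accept] = logp_prop[accept]
            if adapting:
                log_scale[:, p] += gain * (accept.astype(float) - TARGET_ACCEPTANCE)
            else:
                accept_count[p] += accept.sum()
                accept_total += n_chains
        if not adapting and (sweep - config.n_burn + 1) % config.thin == 0:
            kept[:, keep_i, :] = state
            keep_i += 1
    assert keep_i == config.n_iter

    acceptance = {
        name: accept_count[p] * n_params / max(accept_total, 1)
        for p, name in enumerate(names)
    }
    draws = PosteriorDraws(names, kept, acceptance)
    for name in names:
        r = split_rhat(draws[name])
        if r > 1.05:
            msg = f"R-hat = {r:.3f} > 1.05 for {name}: chains may not have converged"
            draws.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return draws


# ---------------------------------------------------------------------------
# diagnostics and summaries

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin R-hat).

    Each chain is split in half, and the classic between/within variance
    ratio is computed over the 2*n_chains half-chains.  Degenerate
    (constant) draws have no mixing information and report 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return 1.0
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size (via arviz); total draws if degenerate."""
    chains = np.asarray(chains, dtype=float)
    if np.allclose(chains, chains.flat[0]):
        return float(chains.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(az.convert_to_dataset(chains)).x)
    return ess


@dataclass(frozen=True)
class PosteriorSummary:
    """Equal-tailed interval summary of one posterior quantity.

    The point estimate is the posterior median; the 50% interval
    (25th-75th percentiles) is nested inside the 95% interval
    (2.5th-97.5th percentiles) by construction.
    """

    name: str
    median: float
    lower95: float
    upper95: float
    lower50: float
    upper50: float
    ess: float
    rhat: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "median": self.median,
            "lower95": self.lower95,
            "upper95": self.upper95,
            "lower50": self.lower50,
            "upper50": self.upper50,
            "ess": self.ess,
            "rhat": self.rhat,
        }


def summarize_draws(draws: PosteriorDraws, names: Sequence[str] | None = None
                    ) -> dict[str, PosteriorSummary]:
    """Posterior medians, 50%/95% equal-tailed intervals, ESS and R-hat."""
    names = list(names) if names is not None else draws.names
    out = {}
    for name in names:
        x = draws[name]
        if x.size < 100:
            raise ValueError(f"need >= 100 retained draws to summarise {name}")
        flat = x.ravel()
        q = np.percentile(flat, [2.5, 25.0, 50.0, 75.0, 97.5])
        out[name] = PosteriorSummary(
            name=name,
            median=float(q[2]),
            lower95=float(q[0]),
            upper95=float(q[4]),
            lower50=float(q[1]),
            upper50=float(q[3]),
            ess=effective_sample_size(x),
            rhat=split_rhat(x),
        )
    return out


def summary_frame(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    """Tabular view of a summary dict, one row per quantity."""
    return pd.DataFrame([s.as_dict() for s in summaries.values()]).set_index("name")
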