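"""Priors, initial values and the joint Bayesian ISE model.

The model couples, for each sensor ``i``, the Nikolskii-Eisenman response
parameters (a_i, b_i, c_i, sigma_i) to the calibration observations, and,
when experimental data are present, the unknown sample activities
``log10x_j`` to the experimental observations through the same response
curves.  Sensors share nothing except the sample activities, so redundant
arrays pool information about each sample while noisy sensors are
down-weighted automatically through their own sigma_i.

Prior forms (weakly informative, scale-aware):

* a_i   ~ Normal(median calibration emf, 1000^2)      -- diffuse baseline
* b_i   ~ Normal(theoretical Nernst slope, (|slope|/2)^2)
* log10 c_i ~ Uniform over the calibration activity range widened by
  [-5, +1] decades
* sigma_i ~ Half-Normal(scale 25 mV)
* log10 x_j ~ Uniform over the calibration range widened by [-3, +1]

Sampling coordinates are ``a``, ``b`` (identity), ``log10 c`` and
``log sigma`` (positive parameters on log scales) and ``log10 x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import ISEDataset, Mode
from .response import (
    BelowBlankError,
    ModelContext,
    SensorParams,
    invert_basic,
    sa_initial_estimate,
    theoretical_slope,
)
from .sampling import MCMCConfig, PosteriorDraws, sample_posterior

__all__ = ["PriorSpec", "default_priors", "initial_values", "JointIseModel"]

_LOG_SIGMA_BOUND = 23.0  # hard support bound to keep exp() finite
_SIGMA_FLOOR = 0.1  # mV; floor for the OLS residual-SD initialiser


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly-informative default priors."""

    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    log10c_low: float
    log10c_high: float
    sigma_high: float
    log10x_low: float
    log10x_high: float

    def __post_init__(self):
        if self.a_sd <= 0 or self.b_sd <= 0 or self.sigma_high <= 0:
            raise ValueError("prior scales must be > 0")
        if self.log10c_low >= self.log10c_high:
            raise ValueError("log10c bounds must be an increasing pair")
        if self.log10x_low >= self.log10x_high:
            raise ValueError("log10x bounds must be an increasing pair")


def default_priors(dataset: ISEDataset, ctx: ModelContext) -> PriorSpec:
    """Data- and context-derived default priors (identical form per sensor)."""
    cal = dataset.calibration_frame()
    b_mean = theoretical_slope(ctx)
    lo, hi = cal.log10x.min(), cal.log10x.max()
    return PriorSpec(
        a_mean=float(cal.emf.median()),
        a_sd=1000.0,
        b_mean=b_mean,
        b_sd=abs(b_mean) / 2.0,
        log10c_low=float(lo - 5.0),
        log10c_high=float(hi + 1.0),
        sigma_high=25.0,
        log10x_low=float(lo - 3.0),
        log10x_high=float(hi + 1.0),
    )


def _nernstian_ols(log10x: np.ndarray, emf: np.ndarray):
    """OLS of emf on log10x over the top half of the calibration points.

    The highest-activity half of the curve is the Nernstian-region proxy;
    ceil rule, e.g. 7 points -> the 4 highest activities.  Falls back to
    all points if the top half is degenerate; errors if the whole design
    sits at a single activity.
    """
    order = np.argsort(log10x)
    k = math.ceil(len(log10x) / 2)
    top = order[-k:]
    xs, ys = log10x[top], emf[top]
    if np.unique(xs).size < 2:
        xs, ys = log10x, emf
    if np.unique(xs).size < 2:
        raise ValueError(
            "degenerate calibration design: all points at one log10x"
        )
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (intercept + slope * xs)
    sigma = max(float(np.std(resid)), _SIGMA_FLOOR)
    return float(intercept), float(slope), sigma


def initial_values(dataset: ISEDataset, ctx: ModelContext, chain_index: int = 0,
                   seed: int = 1, priors: PriorSpec | None = None) -> dict[str, float]:
    """Starting values for one chain, as a mapping of natural-scale names.

    Per sensor, a line fitted through the Nernstian (top) half of the
    calibration gives initial ``a`` and ``b``; ``c`` starts at the lowest
    calibration activity and ``sigma`` at the residual SD of that line
    (floored at 0.1 mV).  Unknown activities start at the classical inverse
    (Basic) or classical standard-addition (SA) estimate.  Chains beyond
    the first are jittered deterministically from ``seed`` so starts are
    overdispersed.
    """
    priors = priors or default_priors(dataset, ctx)
    cal = dataset.calibration_frame()
    out: dict[str, float] = {}
    params0: dict[int, SensorParams] = {}
    for i, grp in cal.groupby("ISEID"):
        a0, b0, s0 = _nernstian_ols(grp.log10x.to_numpy(), grp.emf.to_numpy())
        c0 = 10.0 ** float(grp.log10x.min())
        i = int(i)
        out[f"a[{i}]"] = a0
        out[f"b[{i}]"] = b0
        out[f"c[{i}]"] = c0
        out[f"sigma[{i}]"] = s0
        params0[i] = SensorParams(a0, b0, c0, s0)

    mid = float((priors.log10x_low + priors.log10x_high) / 2.0)
    if dataset.mode is not Mode.CALIBRATION_ONLY:
        per_sample: dict[int, list[float]] = {j: [] for j in dataset.sample_ids()}
        for rec in dataset.experimental:
            p = params0[rec.ise_id]
            if dataset.mode is Mode.BASIC:
                try:
                    est = invert_basic(p, rec.emf)
                except BelowBlankError:
                    est = None
            else:
                est = sa_initial_estimate(
                    p.b, rec.emf1, rec.emf2, rec.v_s, rec.v_add, rec.conc_add
                )
            if est is not None and est > 0:
                per_sample[rec.sample_id].append(math.log10(est))
        for j, vals in per_sample.items():
            start = float(np.mean(vals)) if vals else mid
            out[f"log10x[{j}]"] = float(
                np.clip(start, priors.log10x_low + 0.05, priors.log10x_high - 0.05)
            )

    if chain_index > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(chain_index)]))
        for key in list(out):
            if key.startswith("a["):
                out[key] += rng.normal(0.0, 2.0)
            elif key.startswith("b["):
                out[key] *= math.exp(rng.normal(0.0, 0.05))
            elif key.startswith("c["):
                out[key] *= 10.0 ** rng.normal(0.0, 0.3)
            elif key.startswith("sigma["):
                out[key] *= math.exp(rng.normal(0.0, 0.3))
            elif key.startswith("log10x["):
                out[key] = float(
                    np.clip(out[key] + rng.normal(0.0, 0.2),
                            priors.log10x_low + 0.05, priors.log10x_high - 0.05)
                )
    # keep c inside its uniform support
    for key in list(out):
        if key.startswith("c["):
            lo = 10.0 ** (priors.log10c_low + 0.05)
            hi = 10.0 ** (priors.log10c_high - 0.05)
            out[key] = float(np.clip(out[key], lo, hi))
    return out


def _profile_center(log10x: np.ndarray, emf: np.ndarray, priors: PriorSpec) -> float:
    """Centering constant for one sensor: mean effective covariate.

    Profiles c over a coarse grid, fitting emf ~ log10(x + c) by OLS at
    each value, and returns mean(log10(x + c_best)).  Used only to choose
    sampling coordinates; the posterior itself is unaffected.
    """
    x = 10.0 ** log10x
    best = (np.inf, float(np.mean(log10x)))
    for log10c in np.arange(priors.log10c_low, priors.log10c_high + 1e-9, 0.25):
        t = np.log10(x + 10.0 ** log10c)
        if np.ptp(t) < 1e-8:
            continue
        slope, intercept = np.polyfit(t, emf, 1)
        rss = float(np.sum((emf - intercept - slope * t) ** 2))
        if rss < best[0]:
            best = (rss, float(np.mean(t)))
    return best[1]


class JointIseModel:
    """Joint posterior over sensor parameters and (optionally) activities.

    Builds the vectorised log density consumed by
    :func:`isebayes.sampling.sample_posterior` and converts raw sampling
    coordinates back to natural-scale draws.
    """

    def __init__(self, dataset: ISEDataset, ctx: ModelContext,
                 priors: PriorSpec | None = None):
        self.dataset = dataset
        self.ctx = ctx
        self.priors = priors or default_priors(dataset, ctx)
        self.n_ise = dataset.n_ise
        self.sample_ids = dataset.sample_ids() if dataset.mode is not Mode.CALIBRATION_ONLY else []

        cal = dataset.calibration_frame()
        self._cal_ise = cal.ISEID.to_numpy(int) - 1
        self._cal_x = 10.0 ** cal.log10x.to_numpy(float)
        self._cal_y = cal.emf.to_numpy(float)
        # Sampling uses a centered intercept a' = a + b * m_i with
        # m_i = mean(log10(x + c_hat_i)) from a coarse profile fit of c:
        # the baseline a lives several decades outside the data range, so
        # in raw coordinates (a, b, c) are nearly collinear and scalar
        # updates barely move.  m_i is a fixed constant per run.
        self._center = np.array([
            _profile_center(grp.log10x.to_numpy(float), grp.emf.to_numpy(float),
                            self.priors)
            for _, grp in cal.groupby("ISEID")
        ])

        self.mode = dataset.mode
        if self.mode is not Mode.CALIBRATION_ONLY:
            exp = dataset.experimental_frame()
            sample_pos = {j: k for k, j in enumerate(self.sample_ids)}
            self._exp_ise = exp.ISEID.to_numpy(int) - 1
            self._exp_sample = exp.SampleID.map(sample_pos).to_numpy(int)
            if self.mode is Mode.BASIC:
                self._exp_y = exp.emf.to_numpy(float)
            else:
                self._exp_y1 = exp.emf1.to_numpy(float)
                self._exp_y2 = exp.emf2.to_numpy(float)
                self._v_s = exp["V.s"].to_numpy(float)
                self._v_add = exp["V.add"].to_numpy(float)
                self._conc_add = exp["conc.add"].to_numpy(float)

        s = self.n_ise
        self._ia = np.arange(0, s)
        self._ib = np.arange(s, 2 * s)
        self._ic = np.arange(2 * s, 3 * s)
        self._isig = np.arange(3 * s, 4 * s)
        self._ix = np.arange(4 * s, 4 * s + len(self.sample_ids))
        self.n_params = 4 * s + len(self.sample_ids)

    # -- names -------------------------------------------------------------
    @property
    def raw_names(self) -> list[str]:
        ids = range(1, self.n_ise + 1)
        return (
            [f"a_centered[{i}]" for i in ids]
            + [f"b[{i}]" for i in ids]
            + [f"log10c[{i}]" for i in ids]
            + [f"log_sigma[{i}]" for i in ids]
            + [f"log10x[{j}]" for j in self.sample_ids]
        )

    @property
    def natural_names(self) -> list[str]:
        ids = range(1, self.n_ise + 1)
        return (
            [f"a[{i}]" for i in ids]
            + [f"b[{i}]" for i in ids]
            + [f"c[{i}]" for i in ids]
            + [f"sigma[{i}]" for i in ids]
            + [f"log10x[{j}]" for j in self.sample_ids]
        )

    # -- density -----------------------------------------------------------
    def log_density(self, state: np.ndarray) -> np.ndarray:
        """Log posterior density (up to a constant), vectorised over chains."""
        state = np.atleast_2d(state)
        pr = self.priors
        b = state[:, self._ib]
        a = state[:, self._ia] - b * self._center[None, :]
        log10c = state[:, self._ic]
        log_sig = state[:, self._isig]

        inside = (
            np.all((log10c >= pr.log10c_low) & (log10c <= pr.log10c_high), axis=1)
            & np.all(np.abs(log_sig) < _LOG_SIGMA_BOUND, axis=1)
        )
        if self._ix.size:
            log10x = state[:, self._ix]
            inside &= np.all(
                (log10x >= pr.log10x_low) & (log10x <= pr.log10x_high), axis=1
            )

        c = 10.0 ** np.clip(log10c, -300.0, 300.0)
        sigma = np.exp(np.clip(log_sig, -_LOG_SIGMA_BOUND, _LOG_SIGMA_BOUND))

        lp = -0.5 * np.sum(((a - pr.a_mean) / pr.a_sd) ** 2, axis=1)
        lp -= 0.5 * np.sum(((b - pr.b_mean) / pr.b_sd) ** 2, axis=1)
        # half-normal on sigma, with the log-scale Jacobian
        lp += np.sum(-0.5 * (sigma / pr.sigma_high) ** 2 + log_sig, axis=1)

        mu = a[:, self._cal_ise] + b[:, self._cal_ise] * np.log10(
            self._cal_x[None, :] + c[:, self._cal_ise]
        )
        s_obs = sigma[:, self._cal_ise]
        lp += np.sum(-0.5 * ((self._cal_y - mu) / s_obs) ** 2 - np.log(s_obs), axis=1)

        if self.mode is Mode.BASIC:
            x = 10.0 ** log10x
            xs = x[:, self._exp_sample]
            mu_e = a[:, self._exp_ise] + b[:, self._exp_ise] * np.log10(
                xs + c[:, self._exp_ise]
            )
            s_e = sigma[:, self._exp_ise]
            lp += np.sum(-0.5 * ((self._exp_y - mu_e) / s_e) ** 2 - np.log(s_e), axis=1)
        elif self.mode is Mode.STANDARD_ADDITION:
            x = 10.0 ** log10x
            xs = x[:, self._exp_sample]
            ce = c[:, self._exp_ise]
            ae = a[:, self._exp_ise]
            be = b[:, self._exp_ise]
            s_e = sigma[:, self._exp_ise]
            mu1 = ae + be * np.log10(xs + ce)
            mixed = (xs * self._v_s + self._conc_add * self._v_add) / (
                self._v_s + self._v_add
            )
            mu2 = ae + be * np.log10(mixed + ce)
            lp += np.sum(-0.5 * ((self._exp_y1 - mu1) / s_e) ** 2 - np.log(s_e), axis=1)
            lp += np.sum(-0.5 * ((self._exp_y2 - mu2) / s_e) ** 2 - np.log(s_e), axis=1)

        return np.where(inside, lp, -np.inf)

    # -- initial states and scales ------------------------------------------
    def initial_matrix(self, config: MCMCConfig) -> np.ndarray:
        rows = []
        for k in range(config.n_chains):
            vals = initial_values(self.dataset, self.ctx, chain_index=k,
                                  seed=config.seed, priors=self.priors)
            row = np.empty(self.n_params)
            ids = range(1, self.n_ise + 1)
            row[self._ib] = [vals[f"b[{i}]"] for i in ids]
            row[self._ia] = [
                vals[f"a[{i}]"] + vals[f"b[{i}]"] * self._center[i - 1] for i in ids
            ]
            row[self._ic] = [math.log10(vals[f"c[{i}]"]) for i in ids]
            row[self._isig] = [math.log(vals[f"sigma[{i}]"]) for i in ids]
            row[self._ix] = [vals[f"log10x[{j}]"] for j in self.sample_ids]
            rows.append(row)
        return np.array(rows)

    def initial_scales(self) -> np.ndarray:
        scales = np.empty(self.n_params)
        scales[self._ia] = 1.0
        scales[self._ib] = 0.5
        scales[self._ic] = 0.2
        scales[self._isig] = 0.2
        scales[self._ix] = 0.1
        return scales

    # -- sampling ------------------------------------------------------------
    def sample(self, config: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
        """Run the sampler and return draws on natural scales.

        Raw log-scale coordinates for c and sigma are transformed back per
        draw; diagnostics (R-hat warnings, acceptance rates) carry over.
        """
        raw = sample_posterior(
            self.log_density,
            self.initial_matrix(config),
            self.raw_names,
            config,
            initial_scales=self.initial_scales(),
        )
        arr = np.stack([raw[name] for name in self.raw_names], axis=2)
        arr[:, :, self._ia] -= arr[:, :, self._ib] * self._center[None, None, :]
        arr[:, :, self._ic] = 10.0 ** arr[:, :, self._ic]
        arr[:, :, self._isig] = np.exp(arr[:, :, self._isig])
        nat = PosteriorDraws(self.natural_names, arr, raw.acceptance)
        nat.warnings = [
            w.replace("a_centered", "a").replace("log10c", "c").replace("log_sigma", "sigma")
            for w in raw.warnings
        ]
        return nat
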