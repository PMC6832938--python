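"""Model/Results interface for characterising ISEs and quantifying samples.

Two model classes mirror the two analysis tasks:

* :class:`CalibrationModel` -- calibration data only; ``fit()`` estimates
  each sensor's response parameters (a, b, c, sigma) and the posterior of
  its limit of detection LOD_{alpha,beta}.
* :class:`ActivityModel` -- calibration plus experimental data (Basic or
  Standard Addition); ``fit()`` samples the joint posterior of all sensor
  parameters and all unknown sample activities, pooling the array.

Both return Results objects carrying the posterior draws, equal-tailed
50%/95% credible intervals, convergence diagnostics, a ``summary()`` text
report and plotting helpers.  The functional wrappers
:func:`characterize_array` and :func:`quantify_samples` are one-liners over
these classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ISEDataset, Mode
from .inference import JointIseModel, PriorSpec
from .response import DetectionSpec, ModelContext, SensorParams
from .sampling import (
    MCMCConfig,
    PosteriorDraws,
    PosteriorSummary,
    summarize_draws,
    summary_frame,
)

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "ActivityModel",
    "ActivityResults",
    "characterize_array",
    "quantify_samples",
]


def _fmt(v: float) -> str:
    """3-significant-figure scientific notation, e.g. 2.95e+01."""
    return f"{v:.2e}"


class CalibrationModel:
    """Bayesian characterisation of one or more ISEs from calibration data.

    Parameters
    ----------
    dataset
        A validated dataset (experimental records, if any, are ignored:
        characterisation uses calibration data only).
    ctx
        Primary-ion valence and temperature; sets the Nernstian prior on
        the slope.
    priors
        Optional override of the default weakly-informative priors.
    """

    def __init__(self, dataset: ISEDataset, ctx: ModelContext,
                 priors: PriorSpec | None = None):
        if dataset.mode is not Mode.CALIBRATION_ONLY:
            dataset = ISEDataset(dataset.calibration, (), Mode.CALIBRATION_ONLY)
        self.dataset = dataset
        self.ctx = ctx
        self._joint = JointIseModel(dataset, ctx, priors)
        self.priors = self._joint.priors

    def fit(self, detection: DetectionSpec = DetectionSpec(),
            config: MCMCConfig = MCMCConfig()) -> "CalibrationResults":
        """Sample the posterior and derive each sensor's log10 LOD per draw."""
        draws = self._joint.sample(config)
        k = stats.norm.ppf(1 - detection.alpha) + stats.norm.ppf(1 - detection.beta)
        for i in range(1, self.dataset.n_ise + 1):
            lod = draws[f"c[{i}]"] * (
                10.0 ** (k * draws[f"sigma[{i}]"] / np.abs(draws[f"b[{i}]"])) - 1.0
            )
            draws.add_derived(f"logLOD[{i}]", np.log10(lod))
        summaries = summarize_draws(draws)
        return CalibrationResults(self.dataset, self.ctx, detection, draws, summaries)


class CalibrationResults:
    """Posterior summaries of sensor parameters and detection limits."""

    def __init__(self, dataset, ctx, detection, draws: PosteriorDraws,
                 summaries: dict[str, PosteriorSummary]):
        self.dataset = dataset
        self.ctx = ctx
        self.detection = detection
        self.draws = draws
        self.summaries = summaries
        self.warnings = list(draws.warnings)

    @property
    def n_ise(self) -> int:
        return self.dataset.n_ise

    def params(self, ise_id: int) -> SensorParams:
        """Posterior-median response parameters of one sensor."""
        s = self.summaries
        return SensorParams(
            a=s[f"a[{ise_id}]"].median,
            b=s[f"b[{ise_id}]"].median,
            c=s[f"c[{ise_id}]"].median,
            sigma=s[f"sigma[{ise_id}]"].median,
        )

    def lod(self, ise_id: int) -> PosteriorSummary:
        """Posterior summary of log10 LOD_{alpha,beta} for one sensor."""
        return self.summaries[f"logLOD[{ise_id}]"]

    def parameter_table(self) -> pd.DataFrame:
        return summary_frame(self.summaries)

    def summary(self) -> str:
        """Print-style report: per-sensor parameter table plus the log LOD line."""
        lines = [
            "Non-linear parameter estimates and 95% CIs for",
            "  y = a + b log(x + c)",
            "",
        ]
        for i in range(1, self.n_ise + 1):
            lines.append(f"ISE #{i}:")
            lines.append(f"  {'Parameter':<10}{'estimate':>10}{'Lower limit':>14}{'Upper limit':>14}")
            for name in ("a", "b", "c", "sigma"):
                s = self.summaries[f"{name}[{i}]"]
                lines.append(
                    f"  {name:<10}{_fmt(s.median):>10}{_fmt(s.lower95):>14}{_fmt(s.upper95):>14}"
                )
            lod = self.lod(i)
            lines.append(
                f"  Estimated log LOD{{alpha={self.detection.alpha:g}, "
                f"beta={self.detection.beta:g}}} (95% CI): "
                f"{lod.median:.2f} ({lod.lower95:.2f}, {lod.upper95:.2f})"
            )
            lines.append("")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines).rstrip() + "\n"

    def plot(self, path=None):
        """Histograms of each sensor's parameter and log-LOD posteriors."""
        from . import plotting

        return plotting.plot_characterisation(self, path)

    def __str__(self) -> str:
        return self.summary()


class ActivityModel:
    """Joint Bayesian quantification of unknown samples over a sensor array.

    Calibration and experimental data enter one posterior, so calibration
    uncertainty propagates into the activity estimates, and every sensor
    measuring a sample contributes with weight set by its own noise level.
    """

    def __init__(self, dataset: ISEDataset, ctx: ModelContext,
                 priors: PriorSpec | None = None):
        if dataset.mode is Mode.CALIBRATION_ONLY:
            raise ValueError(
                "dataset has no experimental data; use CalibrationModel "
                "(describe) to characterise sensors"
            )
        self.dataset = dataset
        self.ctx = ctx
        self._joint = JointIseModel(dataset, ctx, priors)
        self.priors = self._joint.priors

    def fit(self, config: MCMCConfig = MCMCConfig()) -> "ActivityResults":
        draws = self._joint.sample(config)
        summaries = summarize_draws(draws)
        return ActivityResults(self.dataset, self.ctx, draws, summaries)


class ActivityResults:
    """Posterior log10 activities per sample, pooled across the array."""

    def __init__(self, dataset, ctx, draws: PosteriorDraws,
                 summaries: dict[str, PosteriorSummary]):
        self.dataset = dataset
        self.ctx = ctx
        self.mode = dataset.mode
        self.draws = draws
        self.summaries = summaries
        self.warnings = list(draws.warnings)

    @property
    def sample_ids(self) -> list[int]:
        return self.dataset.sample_ids()

    def activity(self, sample_id: int) -> PosteriorSummary:
        return self.summaries[f"log10x[{sample_id}]"]

    def activities(self) -> pd.DataFrame:
        """One row per sample: median log10 activity with 50%/95% intervals."""
        rows = [self.activity(j).as_dict() | {"SampleID": j} for j in self.sample_ids]
        return pd.DataFrame(rows).set_index("SampleID").drop(columns="name")

    def sensor_table(self) -> pd.DataFrame:
        names = [
            f"{p}[{i}]"
            for i in range(1, self.dataset.n_ise + 1)
            for p in ("a", "b", "c", "sigma")
        ]
        return summary_frame({n: self.summaries[n] for n in names})

    def summary(self) -> str:
        label = "Standard Addition" if self.mode is Mode.STANDARD_ADDITION else "Basic"
        lines = [
            f"Estimated sample activities ({label} format, "
            f"{self.dataset.n_ise} ISEs, {self.dataset.n_sample} samples)",
            "",
            f"  {'Sample':<8}{'log10x':>9}{'2.5%':>9}{'25%':>9}{'75%':>9}{'97.5%':>9}",
        ]
        for j in self.sample_ids:
            s = self.activity(j)
            lines.append(
                f"  {j:<8}{s.median:>9.2f}{s.lower95:>9.2f}{s.lower50:>9.2f}"
                f"{s.upper50:>9.2f}{s.upper95:>9.2f}"
            )
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"

    def plot(self, path=None, ylab="log10 activity", ylim=None, color="steelblue"):
        """Interval plot: thin 95% bars, thick 50% bars, a dash at the median."""
        from . import plotting

        return plotting.plot_activities(self, path, ylab=ylab, ylim=ylim, color=color)

    def __str__(self) -> str:
        return self.summary()


def characterize_array(dataset: ISEDataset, ctx: ModelContext,
                       detection: DetectionSpec = DetectionSpec(),
                       config: MCMCConfig = MCMCConfig(),
                       priors: PriorSpec | None = None) -> CalibrationResults:
    """Fit per-sensor response parameters and LOD posteriors (describe step)."""
    return CalibrationModel(dataset, ctx, priors).fit(detection, config)


def quantify_samples(dataset: ISEDataset, ctx: ModelContext,
                     config: MCMCConfig = MCMCConfig(),
                     priors: PriorSpec | None = None) -> ActivityResults:
    """Fit the joint model and return posterior sample activities (analyse step)."""
    return ActivityModel(dataset, ctx, priors).fit(config)
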