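"""Deterministic mathematics of the Nikolskii-Eisenman response curve.

An ion-selective electrode (ISE) converts the activity ``x`` of its primary
ion into a potential (emf, in mV).  The empirical Nikolskii-Eisenman
parameterisation used throughout this package is

    emf = a + b * log10(x + c) + error,    error ~ Normal(0, sigma)

where ``a`` is a baseline potential, ``b`` the response slope in mV/decade
(theoretically the Nernst slope set by the ion's valence and temperature),
``c`` an empirical interference parameter that sets the flat, blank-like
region of the curve at low activity, and ``sigma`` the emf noise standard
deviation.  Everything in this module is a pure function of these
parameters; no randomness and no I/O.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SensorParams",
    "ModelContext",
    "DetectionSpec",
    "GAS_CONSTANT",
    "FARADAY_CONSTANT",
    "emf_expected",
    "theoretical_slope",
    "lod_plugin",
    "invert_basic",
    "mixed_activity",
    "sa_initial_estimate",
    "BelowBlankError",
]

#: Molar gas constant R, J mol^-1 K^-1 (CODATA).
GAS_CONSTANT = 8.31446
#: Faraday constant F, C mol^-1 (CODATA).
FARADAY_CONSTANT = 96485.33


class BelowBlankError(ValueError):
    """Raised when an emf lies below the blank plateau and cannot be inverted."""


@dataclass(frozen=True)
class SensorParams:
    """Response parameters of one ISE.

    Parameters
    ----------
    a : float
        Baseline emf (mV).
    b : float
        Slope (mV/decade); nonzero, sign follows the primary ion's valence.
    c : float
        Interference parameter (activity, molar scale); >= 0.  Sets the
        low-activity plateau where the sensor cannot distinguish a blank.
    sigma : float
        Standard deviation of the emf noise (mV); > 0.
    """

    a: float
    b: float
    c: float
    sigma: float

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("slope b must be nonzero")
        if self.c < 0:
            raise ValueError(f"interference parameter c must be >= 0, got {self.c}")
        if self.sigma <= 0:
            raise ValueError(f"noise sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ModelContext:
    """Physical context of a measurement: primary-ion valence and temperature.

    ``z`` is the signed charge of the primary ion (e.g. 2 for Pb2+, -1 for
    Cl-); it sets the sign and theoretical magnitude of the Nernst slope.
    """

    z: int
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("valence z must be a nonzero integer")


@dataclass(frozen=True)
class DetectionSpec:
    """False-positive (alpha) and false-negative (beta) rates for the LOD.

    Defaults alpha = beta = 0.05, the IUPAC-style convention.
    """

    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")


def emf_expected(params: SensorParams, x):
    """Expected emf (mV) at activity ``x`` (x = 0 is the blank).

    Vectorised over ``x``.  Raises a domain error if x + c <= 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activity x must be >= 0")
    arg = x + params.c
    if np.any(arg <= 0):
        raise ValueError("x + c must be > 0 (blank with c = 0 has no defined emf)")
    out = params.a + params.b * np.log10(arg)
    return float(out) if out.ndim == 0 else out


def theoretical_slope(ctx: ModelContext) -> float:
    """Theoretical Nernst slope in mV/decade for the given valence and temperature.

    slope = 1000 * ln(10) * R * T / (z * F) with T in kelvin; 59.16 mV/decade
    for a monovalent cation at 25 C, half that for a divalent one.  The sign
    follows the sign of z.
    """
    t_kelvin = ctx.temperature_c + 273.15
    return 1000.0 * math.log(10.0) * GAS_CONSTANT * t_kelvin / (ctx.z * FARADAY_CONSTANT)


def lod_plugin(params: SensorParams, spec: DetectionSpec = DetectionSpec()) -> float:
    """Plug-in limit of detection LOD_{alpha,beta} on the activity scale.

    The LOD is the smallest activity that a one-sided decision against a
    blank detects with false-positive rate alpha and false-negative rate
    beta.  With normal noise the decision threshold is

        y_crit = emf_expected(blank) + sign(b) * z_{1-alpha} * sigma

    and solving the beta condition at x = LOD gives the closed form

        LOD = c * (10 ** ((z_{1-alpha} + z_{1-beta}) * sigma / |b|) - 1).

    Vectorised internally; accepts scalar params.  c = 0 yields LOD = 0 (no
    interference floor -- a warning is emitted because a real sensor always
    has one).
    """
    if params.c == 0:
        warnings.warn(
            "c = 0: no interference floor, plug-in LOD is 0", stacklevel=2
        )
    k = stats.norm.ppf(1 - spec.alpha) + stats.norm.ppf(1 - spec.beta)
    return params.c * (10.0 ** (k * params.sigma / abs(params.b)) - 1.0)


def detection_threshold(params: SensorParams, spec: DetectionSpec = DetectionSpec()) -> float:
    """Critical emf for deciding 'analyte present' against a blank.

    False-positive rate is alpha at x = 0 and false-negative rate is beta at
    x = lod_plugin(params, spec); this pair of properties defines the LOD.
    """
    blank = emf_expected(params, 0.0)
    sign = 1.0 if params.b > 0 else -1.0
    return blank + sign * stats.norm.ppf(1 - spec.alpha) * params.sigma


def invert_basic(params: SensorParams, y):
    """Activity whose expected emf equals ``y``: the exact algebraic inverse.

    x = 10 ** ((y - a) / b) - c.  An emf below the blank plateau (x < 0)
    cannot correspond to any activity and raises :class:`BelowBlankError`.
    """
    y = np.asarray(y, dtype=float)
    x = 10.0 ** ((y - params.a) / params.b) - params.c
    if np.any(x < 0):
        raise BelowBlankError(
            "emf below the blank plateau: no nonnegative activity matches it"
        )
    return float(x) if x.ndim == 0 else x


def mixed_activity(x, v_s: float, v_add: float, conc_add: float):
    """Activity after adding an aliquot: (x*v_s + conc_add*v_add) / (v_s + v_add).

    ``v_s`` is the original sample volume, ``v_add`` and ``conc_add`` the
    volume and activity of the standard-addition aliquot (any consistent
    volume unit).
    """
    if v_s <= 0:
        raise ValueError(f"sample volume v_s must be > 0, got {v_s}")
    if v_add < 0:
        raise ValueError(f"aliquot volume v_add must be >= 0, got {v_add}")
    x = np.asarray(x, dtype=float)
    out = (x * v_s + conc_add * v_add) / (v_s + v_add)
    return float(out) if out.ndim == 0 else out


def sa_initial_estimate(b: float, emf1: float, emf2: float, v_s: float,
                        v_add: float, conc_add: float) -> float:
    """Classical standard-addition estimate of the sample activity.

    Solves the two-measurement system assuming c = 0 (pure Nernstian
    response):

        x = conc_add * v_add / ((v_s + v_add) * 10**(delta/b) - v_s),
        delta = emf2 - emf1.

    Exact when c = 0; used only to initialise MCMC chains.  Returns None
    when noise drives the denominator nonpositive (caller falls back to a
    mid-calibration start).
    """
    if b == 0:
        raise ValueError("slope b must be nonzero")
    delta = emf2 - emf1
    denom = (v_s + v_add) * 10.0 ** (delta / b) - v_s
    if denom <= 0:
        return None
    return conc_add * v_add / denom
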