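"""Synthetic ISE datasets from known response parameters.

Simulated emf values follow the response model exactly: the expected curve
plus independent Normal(0, sigma) noise per reading.  The default
lead-like scenario emulates a realistic environmental deployment -- an
array of three Pb2+ (z = 2) solid-contact ISEs at 21 C with near-Nernstian
slopes (~29.2 mV/decade), interference floors near 2e-6 and 1-2 mV noise,
calibrated over seven decade-spaced activities (log10 x = -9..-3, leaving
the top three points in the Nernstian region) and measuring 17 samples
with activities spread log-uniformly over [-6.5, -3.5] by standard
addition.  Drift, hysteresis and liquid-junction effects are not
simulated.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .data import (
    BasicSampleRecord,
    CalibrationRecord,
    ISEDataset,
    Mode,
    StandardAdditionRecord,
    build_dataset,
)
from .response import ModelContext, SensorParams, emf_expected, mixed_activity

__all__ = [
    "simulate_calibration",
    "simulate_basic",
    "simulate_standard_addition",
    "lead_like_sensors",
    "lead_like_example",
    "DEFAULT_DESIGN",
]

#: Seven decade-spaced calibration activities spanning the full response curve.
DEFAULT_DESIGN = tuple(float(v) for v in range(-9, -2))


def _as_param_map(params) -> dict[int, SensorParams]:
    if isinstance(params, SensorParams):
        return {1: params}
    if isinstance(params, Mapping):
        return {int(k): v for k, v in params.items()}
    return {i + 1: p for i, p in enumerate(params)}


def _as_activity_map(activities) -> dict[int, float]:
    if isinstance(activities, Mapping):
        return {int(k): float(v) for k, v in activities.items()}
    return {j + 1: float(v) for j, v in enumerate(activities)}


def simulate_calibration(params, design: Sequence[float] = DEFAULT_DESIGN,
                         seed: int = 0) -> list[CalibrationRecord]:
    """Noisy calibration readings for each sensor at each design activity.

    ``design`` lists log10 activities; replicates are allowed.  Reproducible
    from ``seed``; the design itself never depends on the seed.
    """
    design = list(design)
    if not design:
        raise ValueError("calibration design must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA1]))
    records = []
    for i, p in sorted(_as_param_map(params).items()):
        for lx in design:
            mu = emf_expected(p, 10.0 ** lx)
            records.append(
                CalibrationRecord(i, float(lx), float(mu + rng.normal(0.0, p.sigma)))
            )
    return records


def simulate_basic(params, activities, seed: int = 0) -> list[BasicSampleRecord]:
    """One noisy Basic-format reading per (sensor, sample)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA51C]))
    records = []
    for i, p in sorted(_as_param_map(params).items()):
        for j, x in sorted(_as_activity_map(activities).items()):
            mu = emf_expected(p, x)
            records.append(
                BasicSampleRecord(i, j, float(mu + rng.normal(0.0, p.sigma)))
            )
    return records


def simulate_standard_addition(params, activities, v_s: float, v_add: float,
                               conc_add: float, seed: int = 0
                               ) -> list[StandardAdditionRecord]:
    """Standard-addition readings: emf before and after spiking each sample.

    The two readings carry independent noise.  ``v_add`` must be positive
    (standard addition requires an actual addition).
    """
    if v_s <= 0:
        raise ValueError(f"sample volume v_s must be > 0, got {v_s}")
    if v_add <= 0:
        raise ValueError(f"standard addition requires v_add > 0, got {v_add}")
    if conc_add <= 0:
        raise ValueError(f"aliquot activity conc.add must be > 0, got {conc_add}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A]))
    records = []
    for i, p in sorted(_as_param_map(params).items()):
        for j, x in sorted(_as_activity_map(activities).items()):
            mu1 = emf_expected(p, x)
            mu2 = emf_expected(p, mixed_activity(x, v_s, v_add, conc_add))
            records.append(
                StandardAdditionRecord(
                    i, j,
                    float(mu1 + rng.normal(0.0, p.sigma)),
                    float(mu2 + rng.normal(0.0, p.sigma)),
                    float(v_s), float(v_add), float(conc_add),
                )
            )
    return records


def lead_like_sensors() -> dict[int, SensorParams]:
    """Three lead-array-like sensors: near-Nernstian, c ~ 2e-6, 1-2 mV noise."""
    return {
        1: SensorParams(a=176.0, b=29.5, c=2.18e-6, sigma=1.42),
        2: SensorParams(a=158.0, b=29.0, c=1.5e-6, sigma=1.0),
        3: SensorParams(a=190.0, b=28.8, c=3.0e-6, sigma=2.0),
    }


def lead_like_example(seed: int = 0, mode: Mode = Mode.STANDARD_ADDITION,
                      n_sample: int = 17):
    """Full lead-like synthetic study: dataset, true parameters, true activities.

    Returns ``(dataset, params, activities)`` where ``activities`` maps
    sample id to true activity.  Sample activities are drawn log-uniformly
    on [-6.5, -3.5]; standard addition spikes 1 volume unit of 1.1e-3
    aliquot into 10 units of sample.
    """
    params = lead_like_sensors()
    ctx = ModelContext(z=2, temperature_c=21.0)  # noqa: F841  (documents the scenario)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1EAD]))
    log10x = rng.uniform(-6.5, -3.5, size=n_sample)
    activities = {j + 1: float(10.0 ** v) for j, v in enumerate(log10x)}
    cal = simulate_calibration(params, DEFAULT_DESIGN, seed=seed)
    if mode is Mode.CALIBRATION_ONLY:
        return build_dataset(cal, [], mode), params, {}
    if mode is Mode.BASIC:
        exp = simulate_basic(params, activities, seed=seed)
    else:
        exp = simulate_standard_addition(
            params, activities, v_s=10.0, v_add=1.0, conc_add=1.1e-3, seed=seed
        )
    return build_dataset(cal, exp, mode), params, activities
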