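"""Small frequentist utilities used alongside the Bayesian models."""

from __future__ import annotations

from scipy import stats

__all__ = ["t_multiplier"]


def t_multiplier(df: int, level: float = 0.95) -> float:
    """Two-sided Student-t multiplier for a confidence interval.

    The contrast between few and many residual degrees of freedom is what
    makes nonlinear fits on the full calibration so much tighter than
    linear fits restricted to the Nernstian subset: t(df=1) = 12.7 versus
    t(df=6) = 2.4 at 95%.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(stats.t.ppf(1 - (1 - level) / 2, df))
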