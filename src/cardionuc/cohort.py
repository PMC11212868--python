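"""Synthetic (enrichment, aspect-ratio) cohorts.

Draws nuclear aspect ratio as a continuous two-segment linear function of
perinuclear microtubule enrichment plus Gaussian noise — the biphasic
relationship used to characterise how the perinuclear MT cage restricts
nuclear elongation (negative slope below a deflection point, flat above it).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_from

#: defaults are the fitted population relationship: deflection point at
#: MT-cage enrichment 1.9 with lower-segment slope -2.1 AR per enrichment
#: unit and a flat upper segment.
FITTED_BREAKPOINT = 1.9
FITTED_SLOPE_BELOW = -2.1
FITTED_SLOPE_ABOVE = 0.0


@dataclass
class CohortSpec:
    """Parameters of the biphasic aspect-ratio-versus-enrichment cohort."""

    n_points: int = 300
    breakpoint: float = FITTED_BREAKPOINT
    slope_below: float = FITTED_SLOPE_BELOW
    slope_above: float = FITTED_SLOPE_ABOVE
    ar_at_breakpoint: float = 2.5
    enrichment_range: tuple = (1.0, 3.5)
    noise_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.enrichment_range
        if not lo < self.breakpoint < hi:
            raise ValueError("enrichment_range must span the breakpoint")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def piecewise_mean(x, breakpoint, slope_below, slope_above, ar_at_breakpoint):
    """Continuous two-segment line evaluated at x."""
    x = np.asarray(x, dtype=float)
    d = x - breakpoint
    return ar_at_breakpoint + np.where(d < 0, slope_below * d, slope_above * d)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Table of (enrichment, aspect_ratio); bit-reproducible for a fixed seed."""
    spec.validate()
    rng = rng_from(spec.seed, "cohort")
    lo, hi = spec.enrichment_range
    x = rng.uniform(lo, hi, spec.n_points)
    y = piecewise_mean(x, spec.breakpoint, spec.slope_below,
                       spec.slope_above, spec.ar_at_breakpoint)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n_points)
    return pd.DataFrame({"enrichment": x, "aspect_ratio": y})
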