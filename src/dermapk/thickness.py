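"""SC thickness estimation from TEWL measured during tape-stripping.

Transepidermal water loss (TEWL) across a partially stripped SC is, to a good
approximation, inversely proportional to the remaining barrier thickness:

    TEWL(x) = Kw / (H - x)

where ``x`` is the cumulative depth of SC already removed and ``H`` the total
SC thickness.  Plotting 1/TEWL against ``x`` is therefore linear, and the
x-intercept — where the barrier resistance extrapolates to zero — is ``H``.
The thickness obtained this way is what the diffusion model uses as ``L``.

Stripping is continued until TEWL reaches a threshold (100 g m^-2 h^-1 by
convention) indicating that essentially all of the SC has been removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .units import mass_per_area_to_depth_um

__all__ = [
    "TEWLSeries",
    "ThicknessEstimate",
    "ThicknessEstimationError",
    "mass_to_depth",
    "estimate_thickness",
    "stripping_endpoint_reached",
]

#: conventional TEWL endpoint (g m^-2 h^-1) indicating full SC removal
TEWL_ENDPOINT = 100.0
#: readings below this multiple of the pre-stripping baseline are dominated by
#: the intact-barrier signal and are excluded from the inverse-TEWL fit
BASELINE_EXCLUSION_FACTOR = 2.0


class ThicknessEstimationError(RuntimeError):
    """Raised when a TEWL series cannot support a thickness estimate."""


@dataclass
class TEWLSeries:
    """TEWL readings paired with cumulative SC depth removed.

    ``depth_removed[i]`` is the cumulative depth (um) of SC removed before the
    i-th reading; the first entry must be 0 (pre-stripping) and the sequence
    non-decreasing.  ``baseline`` is the pre-stripping TEWL.
    """

    depth_removed: np.ndarray
    tewl: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        self.depth_removed = np.asarray(self.depth_removed, dtype=float)
        self.tewl = np.asarray(self.tewl, dtype=float)
        if self.depth_removed.size == 0:
            raise ValueError("TEWL series is empty")
        if self.depth_removed.size != self.tewl.size:
            raise ValueError("depth_removed and tewl must have equal length")
        if self.depth_removed[0] != 0.0:
            raise ValueError("depth_removed must start at 0 (pre-stripping reading)")
        if np.any(np.diff(self.depth_removed) < 0):
            raise ValueError("depth_removed must be non-decreasing")
        if np.any(self.tewl <= 0):
            raise ValueError("TEWL readings must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline TEWL must be positive")


@dataclass
class ThicknessEstimate:
    """Result of the inverse-TEWL extrapolation."""

    H: float            # SC thickness, um
    se: float           # standard error of H, um
    n_used: int         # readings entering the fit
    slope: float        # d(1/TEWL)/dx, (g m^-2 h^-1)^-1 um^-1
    intercept: float    # 1/TEWL at x = 0 (fitted)
    excluded: int = field(default=0)  # baseline-dominated readings dropped


def mass_to_depth(mass_ug_per_cm2: float, sc_density_g_cm3: float = 1.0) -> float:
    """Depth of SC (um) corresponding to a removed areal mass.

    The default density of 1.0 g/cm^3 is the standard assumption for hydrated
    SC; 100 ug/cm^2 then corresponds to 1 um.
    """
    return mass_per_area_to_depth_um(mass_ug_per_cm2, sc_density_g_cm3)


def estimate_thickness(series: TEWLSeries, min_points: int = 3) -> ThicknessEstimate:
    """Estimate total SC thickness H by inverse-TEWL extrapolation.

    Ordinary least squares of 1/TEWL on cumulative depth removed; H is the
    x-intercept, where the extrapolated barrier resistance vanishes.  Readings
    below ``BASELINE_EXCLUSION_FACTOR * baseline`` are excluded: early in the
    stripping the flux is still controlled by the nearly intact barrier and
    those points carry no thickness information, only noise.

    The standard error of H = -intercept/slope is propagated from the OLS
    coefficient covariance by the delta method.
    """
    usable = series.tewl >= BASELINE_EXCLUSION_FACTOR * series.baseline
    n_used = int(usable.sum())
    if n_used < min_points:
        raise ThicknessEstimationError(
            f"only {n_used} readings above {BASELINE_EXCLUSION_FACTOR}x baseline; "
            f"at least {min_points} required for the inverse-TEWL fit"
        )
    x = series.depth_removed[usable]
    y = 1.0 / series.tewl[usable]
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    if slope >= 0:
        raise ThicknessEstimationError(
            "non-negative slope of 1/TEWL vs depth removed: TEWL is not rising "
            "with stripping, so no thickness extrapolation is possible"
        )
    H = -intercept / slope
    # delta method: H = -a/b, grad = (-1/b, a/b^2)
    grad = np.array([-1.0 / slope, intercept / slope**2])
    var = float(grad @ res.cov_params() @ grad)
    return ThicknessEstimate(
        H=float(H),
        se=float(np.sqrt(max(var, 0.0))),
        n_used=n_used,
        slope=float(slope),
        intercept=float(intercept),
        excluded=int((~usable).sum()),
    )


def stripping_endpoint_reached(
    series: TEWLSeries, threshold: float = TEWL_ENDPOINT
) -> bool:
    """Whether the final TEWL reading has reached the removal endpoint.

    The criterion is inclusive: a final reading exactly at the threshold
    counts as reached.
    """
    return bool(series.tewl[-1] >= threshold)
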