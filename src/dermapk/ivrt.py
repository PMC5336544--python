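"""In vitro release testing (IVRT): cumulative release curves and sqrt-t kinetics.

A Franz diffusion cell holds the formulation on an artificial membrane above a
stirred receptor chamber.  Receptor samples withdrawn at each time point are
replaced with fresh medium, so the measured concentration under-reports the
cumulative release; the mass balance

    Q_n = ( C_n * V_receptor + sum_{i<n} C_i * V_sample,i ) / area

restores the cumulative amount released per unit membrane area.

Diffusion-controlled release from a semisolid follows Higuchi kinetics,
Q(t) = k * sqrt(t); the release rate k (ug cm^-2 h^-1/2) is estimated by OLS
of Q on sqrt(t).  Release of different formulations is compared by one-way
ANOVA with Bonferroni-corrected pairwise t-tests, within and across membranes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ReleaseCurve",
    "HiguchiFit",
    "cumulative_from_samples",
    "higuchi_fit",
    "compare_release",
]

#: Franz-cell defaults: receptor volume (mL) and membrane area (cm^2)
DEFAULT_RECEPTOR_VOLUME_ML = 7.4
DEFAULT_AREA_CM2 = 2.0
#: significance level for release comparisons
ALPHA = 0.05
#: early samples before this time (h) may be excluded as burst release
BURST_CUTOFF_H = 0.25


@dataclass
class ReleaseCurve:
    """Cumulative drug released per unit area as a function of time."""

    times: np.ndarray          # h, strictly increasing
    cumulative: np.ndarray     # ug/cm^2
    formulation_id: str = ""
    membrane_id: str = ""
    area: float = DEFAULT_AREA_CM2
    receptor_volume: float = DEFAULT_RECEPTOR_VOLUME_ML
    censored: np.ndarray | None = None  # True where reading was below quantitation

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.times.size != self.cumulative.size:
            raise ValueError("times and cumulative must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.cumulative) < 0):
            warnings.warn(
                "cumulative release is not monotone non-decreasing "
                "(measurement noise?)",
                stacklevel=2,
            )


@dataclass
class HiguchiFit:
    """OLS fit of cumulative release on sqrt(time)."""

    slope: float          # ug cm^-2 h^-1/2
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int
    detected: bool = field(default=True)  # False -> no measurable release


def cumulative_from_samples(
    times,
    concs,
    sample_volumes,
    receptor_volume: float = DEFAULT_RECEPTOR_VOLUME_ML,
    area: float = DEFAULT_AREA_CM2,
    *,
    replacement_correction: bool = True,
    formulation_id: str = "",
    membrane_id: str = "",
) -> ReleaseCurve:
    """Build a ReleaseCurve from sampled receptor concentrations.

    ``concs`` (ug/mL) and ``sample_volumes`` (mL) are per time point; each
    withdrawal is assumed replaced by fresh medium.  With
    ``replacement_correction=False`` the naive Q_n = C_n * V / area is
    returned (for data already corrected upstream).
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    vols = np.asarray(sample_volumes, dtype=float)
    if not (times.size == concs.size == vols.size):
        raise ValueError("times, concs and sample_volumes must have equal length")
    if receptor_volume <= 0 or area <= 0:
        raise ValueError("receptor volume and area must be positive")
    if np.any(vols < 0) or np.any(vols > receptor_volume):
        raise ValueError("sample volumes must lie in [0, receptor_volume]")
    if replacement_correction:
        withdrawn = np.concatenate([[0.0], np.cumsum(concs * vols)[:-1]])
        q = (concs * receptor_volume + withdrawn) / area
    else:
        q = concs * receptor_volume / area
    return ReleaseCurve(
        times=times,
        cumulative=q,
        formulation_id=formulation_id,
        membrane_id=membrane_id,
        area=area,
        receptor_volume=receptor_volume,
    )


def higuchi_fit(
    curve: ReleaseCurve,
    *,
    exclude_burst: bool = False,
    burst_cutoff: float = BURST_CUTOFF_H,
) -> HiguchiFit:
    """Fit Q = intercept + k * sqrt(t) by ordinary least squares.

    ``exclude_burst`` drops points with t < ``burst_cutoff`` (initial burst
    release is not diffusion-controlled).  A curve with no measurable release
    at any time (all zeros) is reported with ``detected=False`` rather than
    fitted.
    """
    mask = curve.times >= (burst_cutoff if exclude_burst else -np.inf)
    t = curve.times[mask]
    q = curve.cumulative[mask]
    if t.size < 3:
        raise ValueError(f"at least 3 points required for the sqrt-t fit, got {t.size}")
    if np.all(curve.cumulative == 0):
        return HiguchiFit(
            slope=np.nan, slope_se=np.nan, intercept=np.nan, intercept_se=np.nan,
            r_squared=np.nan, n=int(t.size), detected=False,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-q curves
        res = sm.OLS(q, sm.add_constant(np.sqrt(t))).fit()
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
    intercept, slope = res.params
    se = res.bse
    return HiguchiFit(
        slope=float(slope),
        slope_se=float(se[1]),
        intercept=float(intercept),
        intercept_se=float(se[0]),
        r_squared=r2,
        n=int(t.size),
    )


def _anova_p(groups: list[np.ndarray]) -> float:
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups of >= 2 values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values identical: no evidence of difference
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


def _pairwise_bonferroni(named: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    pairs = list(itertools.combinations(sorted(named), 2))
    out = {}
    for a, b in pairs:
        if np.ptp(np.concatenate([named[a], named[b]])) == 0:
            p = 1.0
        else:
            _, p = stats.ttest_ind(named[a], named[b])
        out[(a, b)] = min(1.0, float(p) * len(pairs))
    return out


def compare_release(
    data: pd.DataFrame,
    value_col: str = "q6h",
    *,
    alpha: float = ALPHA,
) -> dict:
    """Compare 6-h cumulative release across formulations and membranes.

    ``data`` must have columns ``formulation_id``, ``membrane_id`` and
    ``value_col`` (one row per cell).  Returns a nested report:

    - ``within_membrane``: per membrane, one-way ANOVA p across formulations
      plus Bonferroni-adjusted pairwise t-tests;
    - ``between_membrane``: one-way ANOVA p across membranes (cells pooled
      over formulations) plus adjusted pairwise tests;

    with ``significant`` flags at ``alpha``.
    """
    required = {"formulation_id", "membrane_id", value_col}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    report: dict = {"within_membrane": {}, "alpha": alpha}
    for membrane, sub in data.groupby("membrane_id"):
        named = {
            str(f): g[value_col].to_numpy()
            for f, g in sub.groupby("formulation_id")
        }
        if len(named) < 2:  # a single formulation: nothing to compare
            report["within_membrane"][str(membrane)] = {
                "anova_p": None,
                "significant": False,
                "pairwise_p": {},
            }
            continue
        p = _anova_p(list(named.values()))
        report["within_membrane"][str(membrane)] = {
            "anova_p": p,
            "significant": p < alpha,
            "pairwise_p": _pairwise_bonferroni(named),
        }
    named_m = {
        str(m): g[value_col].to_numpy() for m, g in data.groupby("membrane_id")
    }
    if len(named_m) >= 2:
        p = _anova_p(list(named_m.values()))
        report["between_membrane"] = {
            "anova_p": p,
            "significant": p < alpha,
            "pairwise_p": _pairwise_bonferroni(named_m),
        }
    return report
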