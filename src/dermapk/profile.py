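"""Tape-strip records -> concentration-depth profiles -> diffusion-parameter fits.

A tape-stripping experiment removes the SC layer by layer; each strip (or pool
of strips assayed together) yields the drug amount recovered from a known slab
of SC.  Dividing by the slab volume gives a depth-resolved concentration
profile, which is fitted to the Fickian uptake model of
:mod:`dermapk.diffusion` to recover the partition coefficient K and the
diffusivity parameter D/L^2.

The fit compares observed slab concentrations with the model's *interval
averages* (slab amount / slab volume), not with point evaluations at slab
midpoints: deep strips are commonly pooled in groups of up to four and span a
wide depth range over which the profile is strongly curved, so midpoint
evaluation biases D/L^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diffusion import (
    DiffusionParams,
    average_slab_concentration,
    derive_kp_jss_tlag,
    total_uptake,
)
from .thickness import mass_to_depth
from .units import um_to_cm

__all__ = [
    "TapeStripRecord",
    "StripProfile",
    "ProfileError",
    "FitError",
    "ProfileFit",
    "build_profile",
    "fit_profile",
    "observed_total",
    "summarize_replicates",
]

#: multi-start grid for the least-squares fit (log-spaced)
K_GRID = np.logspace(-2, 2, 5)
DL2_GRID = np.logspace(-4, 1, 5)
#: log-space parameter bounds for the local optimiser
LOG_BOUNDS = (np.log([1e-6, 1e-8]), np.log([1e6, 1e4]))
#: local optimisations are started from this many best grid points
N_LOCAL_STARTS = 5
#: the fit is flagged steady-state when the slowest series mode has decayed
#: below this factor — the exposure time then carries no diffusivity
#: information and DL2 is unidentifiable
STEADY_STATE_DECAY = 1e-8


class ProfileError(ValueError):
    """Raised when tape-strip records cannot form a valid profile."""


class FitError(RuntimeError):
    """Raised when the diffusion-model fit cannot be performed."""


@dataclass(frozen=True)
class TapeStripRecord:
    """A single adhesive tape strip.

    ``pool_id`` marks strips that were extracted and assayed together (deep
    strips are typically pooled in groups of up to 4 for assay sensitivity);
    pooled strips must be consecutive.  For pooled strips
    ``drug_ug_per_cm2`` carries the pool total on the first strip of the pool
    and 0 on the others, or equivalently any split — only the pool sum is used.
    """

    strip_index: int
    mass_ug_per_cm2: float
    drug_ug_per_cm2: float
    pool_id: str | None = None

    def __post_init__(self) -> None:
        if self.mass_ug_per_cm2 < 0:
            raise ValueError(f"strip {self.strip_index}: negative SC mass")
        if self.drug_ug_per_cm2 < 0:
            raise ValueError(f"strip {self.strip_index}: negative drug amount")


@dataclass
class StripProfile:
    """Concentration-vs-relative-depth profile from one replicate.

    ``intervals`` are half-open relative-depth slabs [x1, x2) in [0, 1]
    (x = 0 at the surface); ``concentrations`` the per-volume drug levels in
    each slab (ug/cm^3).
    """

    intervals: list[tuple[float, float]]
    concentrations: np.ndarray
    t_exposure: float
    Cveh: float
    L: float  # um

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.intervals) != self.concentrations.size:
            raise ValueError("intervals and concentrations length mismatch")
        prev = 0.0
        for x1, x2 in self.intervals:
            if not (0.0 <= x1 < x2 <= 1.0 + 1e-12):
                raise ValueError(f"invalid interval [{x1}, {x2}]")
            if x1 < prev - 1e-12:
                raise ValueError("intervals overlap or are out of order")
            prev = x2


@dataclass
class ProfileFit:
    """Fitted diffusion parameters with asymptotic uncertainties."""

    params: DiffusionParams              # K, DL2 point estimates + derived kp/Jss/tlag
    K_se: float
    DL2_se: float
    K_ci90: tuple[float, float]
    DL2_ci90: tuple[float, float]
    objective: float                     # residual sum of squares
    steady_state: bool                   # True -> DL2 unidentifiable (profile fully relaxed)
    n_intervals: int


def _merge_pools(records: list[TapeStripRecord]) -> list[tuple[float, float]]:
    """Collapse pooled strips into (mass, drug) tuples, in stripping order."""
    merged: list[tuple[float, float]] = []
    i = 0
    while i < len(records):
        rec = records[i]
        if rec.pool_id is None or rec.pool_id == "":
            merged.append((rec.mass_ug_per_cm2, rec.drug_ug_per_cm2))
            i += 1
            continue
        j = i
        mass = drug = 0.0
        while j < len(records) and records[j].pool_id == rec.pool_id:
            if records[j].strip_index != rec.strip_index + (j - i):
                raise ProfileError(
                    f"pool {rec.pool_id!r}: pooled strips must be consecutive"
                )
            mass += records[j].mass_ug_per_cm2
            drug += records[j].drug_ug_per_cm2
            j += 1
        merged.append((mass, drug))
        i = j
    return merged


def build_profile(
    records: list[TapeStripRecord],
    L: float,
    t_exposure: float,
    Cveh: float,
    *,
    density_g_cm3: float = 1.0,
    discard_first_n: int = 0,
) -> StripProfile:
    """Convert one replicate's tape-strip records into a StripProfile.

    Cumulative removed SC mass is converted to depth (``mass_to_depth``),
    pooled strips are merged into single slabs, and depths are normalised by
    the SC thickness ``L``.  ``discard_first_n`` drops the first strips from
    the profile (their depth still offsets the remaining slabs) — a guard
    against residual surface formulation when the skin was not swabbed.

    Raises
    ------
    ProfileError
        If strip indices are not contiguous from 1, or the total mass-derived
        depth exceeds 1.2 * L (suggesting a wrong L or density).
    """
    if not records:
        raise ProfileError("no tape-strip records supplied")
    if t_exposure <= 0:
        raise ProfileError(f"t_exposure must be positive, got {t_exposure}")
    recs = sorted(records, key=lambda r: r.strip_index)
    indices = [r.strip_index for r in recs]
    if indices != list(range(1, len(recs) + 1)):
        raise ProfileError(
            f"strip indices must be contiguous starting at 1, got {indices}"
        )

    merged = _merge_pools(recs)
    # zero-mass slabs cannot carry a concentration; fold their drug into the
    # next slab (or the previous one for a trailing strip)
    cleaned: list[tuple[float, float]] = []
    carry = 0.0
    for mass, drug in merged:
        if mass == 0.0:
            warnings.warn(
                "zero-mass strip inside profile; merging its drug with the "
                "neighbouring slab",
                stacklevel=2,
            )
            carry += drug
            continue
        cleaned.append((mass, drug + carry))
        carry = 0.0
    if carry and cleaned:
        mass, drug = cleaned[-1]
        cleaned[-1] = (mass, drug + carry)
    if not cleaned:
        raise ProfileError("all strips have zero mass")

    depths = np.array([mass_to_depth(m, density_g_cm3) for m, _ in cleaned])
    bounds = np.concatenate([[0.0], np.cumsum(depths)])  # um
    if bounds[-1] > 1.2 * L:
        raise ProfileError(
            f"cumulative mass-derived depth {bounds[-1]:.2f} um exceeds "
            f"1.2 * L = {1.2 * L:.2f} um; check the thickness L or SC density"
        )

    intervals: list[tuple[float, float]] = []
    concs: list[float] = []
    for k, (mass, drug) in enumerate(cleaned):
        if k < discard_first_n:
            continue
        x1, x2 = bounds[k] / L, bounds[k + 1] / L
        if x1 >= 1.0:
            continue  # slab entirely beyond the nominal SC thickness
        x2 = min(x2, 1.0)
        width_cm = um_to_cm((x2 - x1) * L)
        intervals.append((x1, x2))
        concs.append(drug / width_cm)
    return StripProfile(
        intervals=intervals,
        concentrations=np.asarray(concs),
        t_exposure=t_exposure,
        Cveh=Cveh,
        L=L,
    )


def _model_concentrations(
    profile: StripProfile, K: float, DL2: float
) -> np.ndarray:
    params = DiffusionParams(K=K, DL2=DL2, Cveh=profile.Cveh, L=profile.L)
    return np.array(
        [
            average_slab_concentration(params, x1, x2, profile.t_exposure)
            for x1, x2 in profile.intervals
        ]
    )


def fit_profile(
    profile: StripProfile,
    *,
    weighting: str = "linear",
    n_local_starts: int = N_LOCAL_STARTS,
    seed: int | None = None,
) -> ProfileFit:
    """Fit the Fickian uptake model to a strip profile by least squares.

    Residuals are observed minus model *interval-average* concentrations
    (``weighting='linear'``, the default) or their logs
    (``weighting='log'``, which down-weights the drug-rich surface slabs).
    Parameters are optimised in log space — both K and DL2 are positive and
    can span orders of magnitude — with a multi-start strategy: the objective
    is evaluated on a 5x5 log-spaced (K, DL2) grid and local trust-region
    least squares is run from the best ``n_local_starts`` grid points, keeping
    the lowest final objective.

    90% confidence intervals come from the asymptotic covariance of the
    log-parameters (t quantile, n - 2 degrees of freedom).

    A profile measured after the SC has fully relaxed to its steady-state
    linear shape carries no information about DL2; such fits are flagged
    ``steady_state=True`` and their DL2 (a lower bound at best) should not be
    interpreted.
    """
    obs = profile.concentrations
    if len(profile.intervals) < 4 or np.count_nonzero(obs > 0) < 4:
        raise FitError(
            "at least 4 slabs with positive concentration are required to fit "
            "K and DL2"
        )
    if np.all(obs == 0):
        raise FitError("all slab concentrations are zero; nothing to fit")
    if weighting not in ("linear", "log"):
        raise ValueError(f"unknown weighting {weighting!r}")

    floor = max(obs[obs > 0].min() * 1e-6, 1e-300)

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = _model_concentrations(profile, math.exp(theta[0]), math.exp(theta[1]))
        if weighting == "log":
            return np.log(np.maximum(model, floor)) - np.log(np.maximum(obs, floor))
        return model - obs

    # grid scan, then local refinement from the best starts
    starts = [
        (lk, ld)
        for lk in np.log(K_GRID)
        for ld in np.log(DL2_GRID)
    ]
    sse = [float(np.sum(residuals(np.array(s)) ** 2)) for s in starts]
    order = np.argsort(sse)[: max(1, n_local_starts)]

    best = None
    attempts: list[tuple[tuple[float, float], float]] = []
    for idx in order:
        theta0 = np.array(starts[idx])
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=LOG_BOUNDS, method="trf", xtol=1e-12
            )
        except Exception:  # singular Jacobian etc.; try the next start
            continue
        attempts.append((tuple(np.exp(theta0)), float(res.cost)))
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(
            f"diffusion-model fit failed to converge from every start; "
            f"grid starts and objectives tried: {attempts}"
        )

    K_hat, DL2_hat = np.exp(best.x)
    m = obs.size
    dof = max(m - 2, 1)
    rss = float(2 * best.cost)
    # asymptotic covariance of the log-parameters
    J = best.jac
    try:
        cov_log = rss / dof * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(2, np.nan)
    tq = stats.t.ppf(0.95, dof)
    K_se = K_hat * se_log[0]
    DL2_se = DL2_hat * se_log[1]
    # an unidentifiable parameter (huge log-SE) yields an infinite bound
    with np.errstate(over="ignore"):
        K_ci = (
            float(K_hat * np.exp(-tq * se_log[0])),
            float(K_hat * np.exp(tq * se_log[0])),
        )
        DL2_ci = (
            float(DL2_hat * np.exp(-tq * se_log[1])),
            float(DL2_hat * np.exp(tq * se_log[1])),
        )

    steady = math.exp(-math.pi**2 * DL2_hat * profile.t_exposure) < STEADY_STATE_DECAY
    params = derive_kp_jss_tlag(
        DiffusionParams(K=K_hat, DL2=DL2_hat, Cveh=profile.Cveh, L=profile.L)
    )
    return ProfileFit(
        params=params,
        K_se=float(K_se),
        DL2_se=float(DL2_se),
        K_ci90=K_ci,
        DL2_ci90=DL2_ci,
        objective=rss,
        steady_state=bool(steady),
        n_intervals=m,
    )


def observed_total(profile: StripProfile) -> float:
    """Total drug recovered from the profiled SC (ug/cm^2): sum of slab amounts."""
    widths_cm = np.array([um_to_cm((x2 - x1) * profile.L) for x1, x2 in profile.intervals])
    return float(np.sum(profile.concentrations * widths_cm))


def summarize_replicates(
    fits: list[ProfileFit],
    profiles: list[StripProfile],
    t_uptake: float = 6.0,
) -> pd.DataFrame:
    """Group summary (mean, SD, n) of K, DL2, kp, Jss and Q at ``t_uptake``.

    ``Q_model`` is the model prediction ``total_uptake(fit, t_uptake)`` for
    each replicate's fitted parameters; ``Q_observed`` is the direct sum of
    the replicate's slab amounts.  Both are reported — agreement between them
    is a useful model-adequacy check.
    """
    if len(fits) < 2:
        raise ValueError("at least 2 replicate fits are required for a summary")
    if len(fits) != len(profiles):
        raise ValueError("fits and profiles length mismatch")
    rows = {
        "K": [f.params.K for f in fits],
        "DL2": [f.params.DL2 for f in fits],
        "kp": [f.params.kp for f in fits],
        "Jss": [f.params.Jss for f in fits],
        "Q_model": [total_uptake(f.params, t_uptake) for f in fits],
        "Q_observed": [observed_total(p) for p in profiles],
    }
    out = pd.DataFrame(
        {
            "mean": {k: float(np.mean(v)) for k, v in rows.items()},
            "sd": {k: float(np.std(v, ddof=1)) for k, v in rows.items()},
            "n": {k: len(v) for k, v in rows.items()},
        }
    )
    out.index.name = "parameter"
    return out
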