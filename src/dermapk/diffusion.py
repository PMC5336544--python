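"""Fickian drug uptake into the stratum corneum (SC) from a constant-activity vehicle.

The SC is treated as a homogeneous membrane of thickness ``L`` that is initially
drug-free.  At ``t = 0`` a vehicle of constant drug concentration ``Cveh`` is
applied to the surface (``x = 0``), establishing and maintaining the interface
concentration ``K * Cveh`` (``K`` is the SC-vehicle partition coefficient); the
inner face (``x = L``) is a perfect sink.  The concentration inside the SC is
then the classical series solution of Fick's second law,

    C(x, t) = K * Cveh * [ (1 - x/L)
              - (2/pi) * sum_{n>=1} sin(n*pi*x/L)/n * exp(-(D/L^2) n^2 pi^2 t) ]

where ``D/L^2`` (``DL2`` in code, units 1/h) is the apparent diffusivity of the
drug divided by the SC thickness squared.  ``DL2`` and ``K`` are the two shape
parameters recoverable from a single concentration-depth profile; combined with
an independent thickness estimate they yield the permeability coefficient
``kp = K * DL2 * L``, the steady-state flux ``Jss = kp * Cveh`` and the
diffusion lag time ``tlag = 1 / (6 * DL2)``.

Everything here is closed-form: point concentrations, term-by-term integrated
amounts in a depth slab (what a tape-strip or a pool of strips physically
removes), and the total amount taken up by the whole SC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .units import um_to_cm

__all__ = [
    "DiffusionParams",
    "concentration_profile",
    "slab_amount",
    "average_slab_concentration",
    "total_uptake",
    "derive_kp_jss_tlag",
]

#: relative tail bound (fraction of the surface concentration K*Cveh) used to
#: truncate the Fourier series adaptively
SERIES_REL_TOL = 1e-8
#: minimum number of series terms (convergence is slow near t = 0)
SERIES_MIN_TERMS = 50
#: hard cap on series terms; beyond this the neglected penetration depth is
#: far below any physically resolvable scale
SERIES_MAX_TERMS = 200_000


@dataclass(frozen=True)
class DiffusionParams:
    """Transport parameters of the SC membrane model.

    Parameters
    ----------
    K : float
        SC-vehicle partition coefficient (dimensionless, > 0).
    DL2 : float
        Apparent diffusivity over thickness squared, D/L^2 (1/h, > 0).
    Cveh : float
        Drug concentration in the vehicle (ug/cm^3, >= 0).
    L : float, optional
        SC thickness (um).  Required only for absolute amounts, kp and Jss;
        typically estimated from a TEWL series (:mod:`dermapk.thickness`).
    kp, Jss, tlag : float, optional
        Derived quantities (cm/h, ug cm^-2 h^-1, h); filled by
        :func:`derive_kp_jss_tlag`.
    """

    K: float
    DL2: float
    Cveh: float
    L: float | None = None
    kp: float | None = None
    Jss: float | None = None
    tlag: float | None = None

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if not self.DL2 > 0:
            raise ValueError(f"DL2 must be positive, got {self.DL2}")
        if self.Cveh < 0:
            raise ValueError(f"Cveh must be non-negative, got {self.Cveh}")
        if self.L is not None and not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")

    @property
    def L_cm(self) -> float:
        """Thickness in cm (raises if L is unset)."""
        self._require_L()
        return um_to_cm(self.L)  # type: ignore[arg-type]

    def _require_L(self) -> None:
        if self.L is None:
            raise ValueError(
                "SC thickness L is not set; estimate it from a TEWL series "
                "(dermapk.thickness.estimate_thickness) or supply L explicitly"
            )


def _n_terms(a: float, n_terms: int | None) -> int:
    """Number of series terms for decay rate ``a = DL2 * pi^2 * t``.

    The tail of the series is dominated by ``exp(-a n^2)``; we keep terms until
    the first neglected term is below SERIES_REL_TOL of the surface value.
    """
    if n_terms is not None:
        if n_terms < 1:
            raise ValueError(f"n_terms must be >= 1, got {n_terms}")
        return int(n_terms)
    if a <= 0:
        return SERIES_MIN_TERMS
    n = int(math.ceil(math.sqrt(math.log(1.0 / SERIES_REL_TOL) / a))) + 2
    return min(max(n, SERIES_MIN_TERMS), SERIES_MAX_TERMS)


def _series_sum(x: np.ndarray, a: float, n_max: int) -> np.ndarray:
    """sum_{n=1..n_max} sin(n pi x)/n * exp(-a n^2), chunked over n."""
    out = np.zeros_like(x, dtype=float)
    chunk = 20_000
    for start in range(1, n_max + 1, chunk):
        n = np.arange(start, min(start + chunk, n_max + 1), dtype=float)
        decay = np.exp(-a * n**2)
        if not decay.any():
            break
        out += (np.sin(np.outer(x, n * np.pi)) / n * decay).sum(axis=1)
    return out


def concentration_profile(
    params: DiffusionParams,
    x_rel: float | Sequence[float] | np.ndarray,
    t: float,
    n_terms: int | None = None,
) -> np.ndarray:
    """Drug concentration C(x, t) at relative depths ``x_rel = x/L``.

    Parameters
    ----------
    params : DiffusionParams
        Transport parameters (L not required: the profile shape depends only
        on K, DL2 and Cveh).
    x_rel : array-like
        Relative depths in [0, 1]; 0 is the SC surface, 1 the inner face.
    t : float
        Exposure time (h), >= 0.
    n_terms : int, optional
        Series truncation override; by default chosen adaptively so the
        neglected tail is below ``1e-8 * K * Cveh``.

    Returns
    -------
    numpy.ndarray
        Concentrations in ug/cm^3, clamped at 0 (truncated Fourier series can
        undershoot slightly near sharp fronts; negative concentrations are
        unphysical).
    """
    x = np.atleast_1d(np.asarray(x_rel, dtype=float))
    if t < 0:
        raise ValueError(f"exposure time must be non-negative, got {t}")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("relative depths must lie in [0, 1]")
    surface = params.K * params.Cveh
    if t == 0:
        # initial condition: drug-free SC; the surface node carries the
        # (discontinuous) boundary value
        return np.where(x == 0.0, surface, 0.0)
    a = params.DL2 * math.pi**2 * t
    series = _series_sum(x, a, _n_terms(a, n_terms))
    c = surface * ((1.0 - x) - (2.0 / math.pi) * series)
    return np.clip(c, 0.0, None)


def slab_amount(
    params: DiffusionParams,
    x1_rel: float,
    x2_rel: float,
    t: float,
    n_terms: int | None = None,
) -> float:
    """Drug amount per unit area (ug/cm^2) held in the depth slab [x1, x2].

    Integrates the concentration series term by term in closed form:

        A = K*Cveh*L * [ (x2-x1) - (x2^2-x1^2)/2
            + (2/pi^2) sum_n (cos(n pi x2) - cos(n pi x1))/n^2 exp(-a n^2) ]

    with ``a = DL2 * pi^2 * t`` and L in cm.  This is what a tape-strip (or a
    pool of strips) spanning that slab removes.
    """
    if not (0.0 <= x1_rel < x2_rel <= 1.0):
        raise ValueError(
            f"slab bounds must satisfy 0 <= x1 < x2 <= 1, got [{x1_rel}, {x2_rel}]"
        )
    if t < 0:
        raise ValueError(f"exposure time must be non-negative, got {t}")
    params._require_L()
    if t == 0:
        return 0.0
    a = params.DL2 * math.pi**2 * t
    n_max = _n_terms(a, n_terms)
    n = np.arange(1.0, n_max + 1.0)
    decay = np.exp(-a * n**2)
    series = np.sum(
        (np.cos(n * math.pi * x2_rel) - np.cos(n * math.pi * x1_rel)) / n**2 * decay
    )
    bracket = (
        (x2_rel - x1_rel)
        - (x2_rel**2 - x1_rel**2) / 2.0
        + (2.0 / math.pi**2) * series
    )
    amount = params.K * params.Cveh * params.L_cm * bracket
    return max(amount, 0.0)


def average_slab_concentration(
    params: DiffusionParams, x1_rel: float, x2_rel: float, t: float
) -> float:
    """Depth-averaged concentration (ug/cm^3) over the slab [x1, x2].

    This — not the point value at the slab midpoint — is what a tape-strip
    assay measures once the removed drug is normalised by the removed SC
    volume, and is the model quantity fitted against strip data.
    """
    width_cm = (x2_rel - x1_rel) * params.L_cm
    return slab_amount(params, x1_rel, x2_rel, t) / width_cm


def total_uptake(params: DiffusionParams, t: float, n_terms: int | None = None) -> float:
    """Total drug amount Q(t) per unit area in the whole SC (ug/cm^2).

    Closed form (slab integral over [0, 1]; only odd terms survive):

        Q(t) = K*Cveh*L * [ 1/2 - (4/pi^2) sum_{n odd} exp(-a n^2) / n^2 ]

    Q(0) = 0 and Q(inf) = K*Cveh*L/2, the area under the steady-state linear
    profile.
    """
    return slab_amount(params, 0.0, 1.0, t, n_terms=n_terms)


def derive_kp_jss_tlag(params: DiffusionParams) -> DiffusionParams:
    """Fill the derived transport metrics kp, Jss and tlag.

    kp = K * DL2 * L (L in cm) is the steady-state permeability coefficient of
    the SC, Jss = kp * Cveh the steady-state flux, and tlag = 1/(6 * DL2) the
    classical diffusion lag time.
    """
    kp = params.K * params.DL2 * params.L_cm
    return replace(
        params,
        kp=kp,
        Jss=kp * params.Cveh,
        tlag=1.0 / (6.0 * params.DL2),
    )
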