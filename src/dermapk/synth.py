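"""Synthetic tape-stripping, TEWL and IVRT experiments with known ground truth.

Every generator simulates the laboratory protocol the analysis modules assume,
so each pipeline stage can be exercised against data whose generating
parameters are known exactly:

- tape-strip cohorts: per-replicate transport parameters drawn log-normally
  around the cohort truth, strip masses drawn log-normally, drug per strip
  assigned from the closed-form slab amounts of the diffusion model, deep
  strips pooled in groups of up to 4, multiplicative log-normal assay noise;
- concurrent TEWL series following the inverse-remaining-thickness law, with
  stripping stopped at the conventional >= 100 g m^-2 h^-1 endpoint;
- a clearance arm in which SC totals either persist (ex-vivo-like behaviour,
  no microcirculation to clear the drug) or decay first-order
  (in-vivo-like);
- Franz-cell release curves following sqrt-t kinetics, emitted as raw sampled
  receptor concentrations so the withdrawal/replacement bookkeeping
  round-trips exactly.

Noise model: multiplicative log-normal for drug amounts (positive, skewed,
asymmetric intervals — the shape such assays exhibit), additive Gaussian for
TEWL readings and receptor concentrations.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, slab_amount, total_uptake
from .ivrt import DEFAULT_AREA_CM2, DEFAULT_RECEPTOR_VOLUME_ML, ReleaseCurve
from .profile import TapeStripRecord
from .thickness import TEWL_ENDPOINT, TEWLSeries, mass_to_depth

__all__ = [
    "CohortSpec",
    "ReplicateData",
    "CohortData",
    "PRESETS",
    "preset",
    "generate_tape_strip_cohort",
    "generate_clearance_arm",
    "generate_release_curves",
    "sc_totals",
]

#: hard cap on strips per replicate (protocol sanity)
MAX_STRIPS = 60


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic tape-stripping cohort.

    ``between_replicate_cv`` is the log-normal coefficient of variation of the
    replicate-level K and DL2 around the cohort truth (median-preserving);
    ``assay_cv`` the multiplicative (mean-preserving) log-normal CV applied to
    each assayed drug amount.  ``tewl_kw`` defaults to ``baseline * L`` so the
    pre-stripping reading of the inverse-thickness law equals the baseline.
    """

    true_params: DiffusionParams          # must carry L (um)
    n_replicates: int = 6
    t_exposure: float = 6.0               # h
    between_replicate_cv: float = 0.40
    strip_mass_mean: float = 75.0         # ug/cm^2
    strip_mass_cv: float = 0.30
    pool_after: int = 8                   # strips beyond this index are pooled
    pool_size: int = 4
    assay_cv: float = 0.10
    tewl_baseline: float = 7.0            # g m^-2 h^-1
    tewl_kw: float | None = None          # g m^-2 h^-1 * um
    tewl_noise_frac: float = 0.05
    tewl_endpoint: float = TEWL_ENDPOINT
    density_g_cm3: float = 1.0
    label: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_params.L is None:
            raise ValueError("true_params must carry the SC thickness L")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("between_replicate_cv", "strip_mass_cv", "assay_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def kw(self) -> float:
        return self.tewl_kw if self.tewl_kw is not None else self.tewl_baseline * self.true_params.L


@dataclass
class ReplicateData:
    """One virtual skin sample: its strips, TEWL series and true parameters."""

    replicate_id: str
    records: list[TapeStripRecord]
    tewl: TEWLSeries
    K: float
    DL2: float
    clean_amounts: np.ndarray = field(repr=False)  # pre-assay-noise drug per strip


@dataclass
class CohortData:
    spec: CohortSpec
    replicates: list[ReplicateData]

    def truth(self) -> pd.DataFrame:
        """Ground-truth parameter table for recovery tests."""
        p = self.spec.true_params
        return pd.DataFrame(
            {
                "replicate_id": [r.replicate_id for r in self.replicates],
                "K": [r.K for r in self.replicates],
                "DL2": [r.DL2 for r in self.replicates],
                "Q_true": [
                    total_uptake(
                        replace(p, K=r.K, DL2=r.DL2), self.spec.t_exposure
                    )
                    for r in self.replicates
                ],
            }
        )


def _lognormal_factor(rng: np.random.Generator, cv: float, mean_preserving: bool) -> float:
    """Multiplicative log-normal factor with the given CV.

    ``mean_preserving=True`` gives E[factor] = 1 (noise); otherwise the median
    is 1 (between-replicate parameter spread around the cohort truth).
    """
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    shift = -0.5 * sigma**2 if mean_preserving else 0.0
    return float(np.exp(rng.normal(shift, sigma)))


def _generate_replicate(
    spec: CohortSpec, rng: np.random.Generator, replicate_id: str
) -> ReplicateData:
    p = spec.true_params
    K_i = p.K * _lognormal_factor(rng, spec.between_replicate_cv, mean_preserving=False)
    DL2_i = p.DL2 * _lognormal_factor(rng, spec.between_replicate_cv, mean_preserving=False)
    params_i = replace(p, K=K_i, DL2=DL2_i)
    H = p.L
    kw = spec.kw

    depths: list[float] = []      # per-strip depth increments, um
    masses: list[float] = []
    tewl_depths: list[float] = [0.0]
    tewl_readings: list[float] = []
    x = 0.0
    while True:
        remaining = H - x
        true_tewl = kw / remaining if remaining > 1e-6 else 1e6
        reading = max(
            true_tewl + rng.normal(0.0, spec.tewl_noise_frac * true_tewl), 0.1
        )
        tewl_readings.append(reading)
        if reading >= spec.tewl_endpoint and depths:
            break
        if len(depths) >= MAX_STRIPS or remaining <= 1e-6:
            break
        mass = spec.strip_mass_mean * _lognormal_factor(
            rng, spec.strip_mass_cv, mean_preserving=True
        )
        dx = min(mass_to_depth(mass, spec.density_g_cm3), remaining)
        masses.append(dx * spec.density_g_cm3 * 100.0)  # actual removed mass
        depths.append(dx)
        x += dx
        tewl_depths.append(x)

    n_strips = len(depths)
    if n_strips < 4:
        raise ValueError(
            f"replicate {replicate_id}: only {n_strips} strips generated before "
            "the TEWL endpoint; spec is inconsistent with the protocol"
        )

    bounds = np.concatenate([[0.0], np.cumsum(depths)]) / H
    clean = np.array(
        [
            slab_amount(params_i, bounds[k], min(bounds[k + 1], 1.0), spec.t_exposure)
            if bounds[k] < 1.0
            else 0.0
            for k in range(n_strips)
        ]
    )
    noisy = clean * np.array(
        [_lognormal_factor(rng, spec.assay_cv, mean_preserving=True) for _ in range(n_strips)]
    )

    records = []
    for k in range(n_strips):
        idx = k + 1
        pool_id = None
        if idx > spec.pool_after:
            pool_id = f"P{(idx - spec.pool_after - 1) // spec.pool_size + 1}"
        records.append(
            TapeStripRecord(
                strip_index=idx,
                mass_ug_per_cm2=float(masses[k]),
                drug_ug_per_cm2=float(noisy[k]),
                pool_id=pool_id,
            )
        )
    tewl = TEWLSeries(
        depth_removed=np.array(tewl_depths),
        tewl=np.array(tewl_readings),
        baseline=spec.tewl_baseline,
    )
    return ReplicateData(
        replicate_id=replicate_id,
        records=records,
        tewl=tewl,
        K=K_i,
        DL2=DL2_i,
        clean_amounts=clean,
    )


def generate_tape_strip_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a full tape-stripping cohort (uptake phase).

    Deterministic for a given spec: the RNG is seeded from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    reps = [
        _generate_replicate(spec, rng, f"{spec.label}-r{i + 1}")
        for i in range(spec.n_replicates)
    ]
    return CohortData(spec=spec, replicates=reps)


def generate_clearance_arm(
    cohort: CohortData,
    *,
    clearance_mode: str = "none",
    k_clear: float = 0.0,
    t_clear: float = 17.0,
    seed: int | None = None,
) -> CohortData:
    """Simulate re-stripping the same cohort after a clearance interval.

    ``clearance_mode='none'`` leaves the SC load unchanged up to fresh assay
    noise (the ex-vivo outcome: without a microcirculation the drug stays
    put); ``'first-order'`` scales each replicate's amounts by
    ``exp(-k_clear * t_clear)`` (in-vivo-like elimination).
    """
    if clearance_mode not in ("none", "first-order"):
        raise ValueError(f"unknown clearance_mode {clearance_mode!r}")
    if k_clear < 0:
        raise ValueError(f"k_clear must be non-negative, got {k_clear}")
    factor = math.exp(-k_clear * t_clear) if clearance_mode == "first-order" else 1.0
    rng = np.random.default_rng(cohort.spec.seed + 1 if seed is None else seed)
    reps = []
    for r in cohort.replicates:
        scaled = r.clean_amounts * factor
        noisy = scaled * np.array(
            [
                _lognormal_factor(rng, cohort.spec.assay_cv, mean_preserving=True)
                for _ in range(scaled.size)
            ]
        )
        records = [
            replace(rec, drug_ug_per_cm2=float(noisy[k])) for k, rec in enumerate(r.records)
        ]
        reps.append(
            ReplicateData(
                replicate_id=r.replicate_id,
                records=records,
                tewl=r.tewl,
                K=r.K,
                DL2=r.DL2,
                clean_amounts=scaled,
            )
        )
    return CohortData(spec=cohort.spec, replicates=reps)


def generate_release_curves(
    true_slope: float,
    times,
    *,
    noise_sd: float = 0.0,
    n_cells: int = 1,
    seed: int | None = None,
    receptor_volume: float = DEFAULT_RECEPTOR_VOLUME_ML,
    area: float = DEFAULT_AREA_CM2,
    sample_volume: float = 1.0,
    formulation_id: str = "F",
    membrane_id: str = "M",
) -> tuple[list[ReleaseCurve], pd.DataFrame]:
    """Simulate Franz-cell sampling of sqrt-t release, Q(t) = slope * sqrt(t).

    Gaussian noise (``noise_sd``, ug/cm^2) is added to the cumulative amounts
    and the withdrawal/replacement mass balance is inverted to produce the raw
    receptor concentrations a laboratory would record, so that
    :func:`dermapk.ivrt.cumulative_from_samples` round-trips the generated
    curve exactly.

    Returns the true+noisy curves and a tidy concentration table with columns
    cell_id, formulation_id, membrane_id, time_h, conc_ug_per_ml,
    sample_volume_ml.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    curves: list[ReleaseCurve] = []
    rows: list[dict] = []
    import warnings

    for c in range(n_cells):
        cell_id = f"cell{c + 1}"
        q = true_slope * np.sqrt(times)
        if noise_sd > 0:
            q = q + rng.normal(0.0, noise_sd, size=times.size)
        # invert the replacement bookkeeping: C_n = (Q_n*A - sum_{i<n} C_i*V_i)/V_r
        concs = np.empty_like(q)
        withdrawn = 0.0
        for n in range(times.size):
            concs[n] = (q[n] * area - withdrawn) / receptor_volume
            withdrawn += concs[n] * sample_volume
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noisy curves may be non-monotone
            curves.append(
                ReleaseCurve(
                    times=times,
                    cumulative=q,
                    formulation_id=formulation_id,
                    membrane_id=membrane_id,
                    area=area,
                    receptor_volume=receptor_volume,
                )
            )
        for t, cc in zip(times, concs):
            rows.append(
                {
                    "cell_id": cell_id,
                    "formulation_id": formulation_id,
                    "membrane_id": membrane_id,
                    "time_h": t,
                    "conc_ug_per_ml": cc,
                    "sample_volume_ml": sample_volume,
                }
            )
    return curves, pd.DataFrame(rows)


def sc_totals(cohort: CohortData, product_id: str, phase: str) -> pd.DataFrame:
    """Per-replicate total SC drug amounts, in the BE-module totals schema."""
    return pd.DataFrame(
        {
            "subject_or_cell_id": [r.replicate_id for r in cohort.replicates],
            "product_id": product_id,
            "phase": phase,
            "amount": [
                float(sum(rec.drug_ug_per_cm2 for rec in r.records))
                for r in cohort.replicates
            ],
        }
    )


def _bmv_like(Cveh: float, K: float, n: int, label: str) -> CohortSpec:
    return CohortSpec(
        true_params=DiffusionParams(K=K, DL2=1.0 / 78.0, Cveh=Cveh, L=15.0),
        n_replicates=n,
        label=label,
    )


#: named experiment presets.  Transport magnitudes are anchored to the study
#: conditions the package targets: vehicle concentrations of 9.3 and 1.7 mg/mL
#: for the corticosteroid microemulsion (ME) and triglyceride (MCT) gels
#: (yielding a steady-state-flux ratio of ~8.7 between them), a 1% w/v
#: antifungal cream (~2 ug/cm^2 total SC uptake in 6 h), a 15 um SC, and a
#: diffusion lag time of ~13 h (DL2 = 1/78 h^-1).
PRESETS: dict[str, CohortSpec] = {
    "bmv-me-like": _bmv_like(Cveh=9300.0, K=2.0, n=6, label="bmv-me-like"),
    "bmv-mct-like": _bmv_like(Cveh=1700.0, K=1.25, n=6, label="bmv-mct-like"),
    "en-like": CohortSpec(
        true_params=DiffusionParams(K=0.43, DL2=1.0 / 78.0, Cveh=10_000.0, L=15.0),
        n_replicates=14,
        label="en-like",
    ),
}


def preset(name: str, *, seed: int = 0, **overrides) -> CohortSpec:
    """A named CohortSpec with optional field overrides and a seed."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
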