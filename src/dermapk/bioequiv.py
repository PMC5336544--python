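"""Average-bioequivalence assessment of topical products from SC drug totals.

The endpoint is the total drug amount recovered from the SC of each replicate,
measured immediately after the application period ("uptake" phase) and after a
subsequent drug-free interval ("clearance" phase).  When uptake and clearance
totals are statistically indistinguishable, the phases are pooled into a
combined sample per product, and the test/reference ratio of combined means is
assessed against the conventional average-BE limits 0.8-1.25: the product is
declared equivalent when the whole 90% confidence interval of the ratio lies
inside the limits.  The looser criterion — the point estimate alone falling
inside the limits — is reported separately and never conflated with the CI
verdict.

Because SC amounts are positive and right-skewed (log-normal-like, with
markedly asymmetric confidence intervals), the default CI is a seeded
percentile bootstrap; a t-interval on log-transformed values is offered as an
alternative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateTotal",
    "PhaseSummary",
    "CombinedSummary",
    "BEResult",
    "BE_LIMITS",
    "totals_to_frame",
    "phase_summary",
    "combined_metric",
    "combined_mean_from_phase_means",
    "be_ratio",
    "assess_bioequivalence",
    "compare_groups",
]

#: conventional average-bioequivalence limits on the test/reference ratio
BE_LIMITS = (0.8, 1.25)
#: default number of bootstrap resamples for percentile CIs
N_BOOT = 10_000
#: two-sided confidence level for BE intervals
CONFIDENCE = 0.90
ALPHA = 0.05


@dataclass(frozen=True)
class ReplicateTotal:
    """Total SC drug amount for one replicate, product and phase."""

    subject_or_cell_id: str
    product_id: str
    phase: str  # "uptake" | "clearance"
    amount: float  # ug/cm^2

    def __post_init__(self) -> None:
        if self.phase not in ("uptake", "clearance"):
            raise ValueError(f"phase must be 'uptake' or 'clearance', got {self.phase!r}")
        if self.amount < 0:
            raise ValueError(f"amount must be non-negative, got {self.amount}")


@dataclass
class PhaseSummary:
    product_id: str
    phase: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    method: str  # "bootstrap" | "log-t"


@dataclass
class CombinedSummary:
    product_id: str
    n: int                      # pooled observations (uptake + clearance)
    combined_mean: float
    uptake_mean: float
    clearance_mean: float
    pooled: np.ndarray = field(repr=False)  # pooled sample, retained for CIs


@dataclass
class BEResult:
    test_id: str
    reference_id: str
    ratio: float
    ci_low: float
    ci_high: float
    limits: tuple[float, float]
    scale: str                  # "raw" | "log"
    verdict: str                # "equivalent" | "not-equivalent" | "inconclusive"
    point_within_limits: bool
    method: str


def totals_to_frame(totals: list[ReplicateTotal]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_or_cell_id": [t.subject_or_cell_id for t in totals],
            "product_id": [t.product_id for t in totals],
            "phase": [t.phase for t in totals],
            "amount": [t.amount for t in totals],
        }
    )


def _as_frame(totals) -> pd.DataFrame:
    if isinstance(totals, pd.DataFrame):
        missing = {"product_id", "phase", "amount"} - set(totals.columns)
        if missing:
            raise ValueError(f"totals frame missing columns: {sorted(missing)}")
        return totals
    return totals_to_frame(list(totals))


def _bootstrap_mean_ci(
    x: np.ndarray, seed: int | None, n_boot: int, conf: float
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - conf) / 2, (1 + conf) / 2])
    return float(lo), float(hi)


def _log_t_ci(x: np.ndarray, conf: float) -> tuple[float, float]:
    if np.any(x <= 0):
        raise ValueError("log-t interval requires strictly positive amounts")
    logs = np.log(x)
    m, s = logs.mean(), logs.std(ddof=1)
    half = stats.t.ppf((1 + conf) / 2, x.size - 1) * s / np.sqrt(x.size)
    return float(np.exp(m - half)), float(np.exp(m + half))


def phase_summary(
    totals,
    product_id: str,
    phase: str,
    *,
    method: str = "bootstrap",
    seed: int | None = None,
    n_boot: int = N_BOOT,
    confidence: float = CONFIDENCE,
) -> PhaseSummary:
    """Arithmetic mean and 90% CI of one product's SC totals in one phase.

    ``method='log-t'`` gives the back-transformed t-interval on log amounts
    (asymmetric, centred on the geometric mean — the natural interval for
    log-normal data); ``method='bootstrap'`` a seeded percentile bootstrap of
    the arithmetic mean.
    """
    df = _as_frame(totals)
    x = df.loc[
        (df["product_id"] == product_id) & (df["phase"] == phase), "amount"
    ].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(
            f"at least 3 replicates required for {product_id}/{phase}, got {x.size}"
        )
    if method == "bootstrap":
        lo, hi = _bootstrap_mean_ci(x, seed, n_boot, confidence)
    elif method == "log-t":
        lo, hi = _log_t_ci(x, confidence)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return PhaseSummary(
        product_id=product_id,
        phase=phase,
        n=int(x.size),
        mean=float(x.mean()),
        ci_low=lo,
        ci_high=hi,
        method=method,
    )


def combined_metric(totals, product_id: str) -> CombinedSummary:
    """Pool one product's uptake and clearance totals into a combined sample.

    The combined mean is the mean of all pooled observations; with equal
    per-phase n this equals (uptake mean + clearance mean) / 2, i.e. the two
    phases weighted equally.
    """
    df = _as_frame(totals)
    sub = df[df["product_id"] == product_id]
    phases = {p: g["amount"].to_numpy(dtype=float) for p, g in sub.groupby("phase")}
    if "uptake" not in phases or "clearance" not in phases:
        raise ValueError(
            f"product {product_id!r} needs both uptake and clearance totals; "
            f"found phases {sorted(phases)}"
        )
    pooled = np.concatenate([phases["uptake"], phases["clearance"]])
    return CombinedSummary(
        product_id=product_id,
        n=int(pooled.size),
        combined_mean=float(pooled.mean()),
        uptake_mean=float(phases["uptake"].mean()),
        clearance_mean=float(phases["clearance"].mean()),
        pooled=pooled,
    )


def combined_mean_from_phase_means(uptake_mean: float, clearance_mean: float) -> float:
    """Equal-weight combined mean from published per-phase means.

    Worked-example helper for summary tables that report only the per-phase
    means (valid as the pooled mean when per-phase n is equal).
    """
    return (uptake_mean + clearance_mean) / 2.0


def _verdict(ci: tuple[float, float], limits: tuple[float, float]) -> str:
    lo, hi = ci
    if limits[0] <= lo and hi <= limits[1]:
        return "equivalent"
    if hi < limits[0] or lo > limits[1]:
        return "not-equivalent"
    return "inconclusive"


def be_ratio(
    test: np.ndarray,
    reference: np.ndarray,
    *,
    scale: str = "raw",
    method: str = "bootstrap",
    seed: int | None = None,
    n_boot: int = N_BOOT,
    limits: tuple[float, float] = BE_LIMITS,
    confidence: float = CONFIDENCE,
    test_id: str = "test",
    reference_id: str = "reference",
) -> BEResult:
    """Test/reference ratio with 90% CI and average-BE verdict.

    ``scale='raw'``: ratio of arithmetic means.  ``scale='log'``:
    back-transformed difference of log-means (a geometric-mean ratio).  The CI
    is a seeded percentile bootstrap over replicates (default) or, with
    ``method='t'`` on the log scale, a Welch t-interval on the difference of
    log-means.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.size < 2 or reference.size < 2:
        raise ValueError("both products need >= 2 combined observations")
    if reference.mean() == 0:
        raise ValueError("reference mean is zero; ratio undefined")
    if scale not in ("raw", "log"):
        raise ValueError(f"unknown scale {scale!r}")

    if scale == "log":
        if np.any(test <= 0) or np.any(reference <= 0):
            raise ValueError("log scale requires strictly positive amounts")
        ratio = float(np.exp(np.log(test).mean() - np.log(reference).mean()))
    else:
        ratio = float(test.mean() / reference.mean())

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        it = rng.integers(0, test.size, size=(n_boot, test.size))
        ir = rng.integers(0, reference.size, size=(n_boot, reference.size))
        if scale == "log":
            stat = np.exp(
                np.log(test)[it].mean(axis=1) - np.log(reference)[ir].mean(axis=1)
            )
        else:
            ref_means = reference[ir].mean(axis=1)
            ref_means = np.where(ref_means == 0, np.nan, ref_means)
            stat = test[it].mean(axis=1) / ref_means
        lo, hi = np.nanquantile(stat, [(1 - confidence) / 2, (1 + confidence) / 2])
    elif method == "t":
        if scale != "log":
            raise ValueError("the t-interval is only defined on the log scale")
        lt, lr = np.log(test), np.log(reference)
        se = np.sqrt(lt.var(ddof=1) / lt.size + lr.var(ddof=1) / lr.size)
        df_w = se**4 / (
            (lt.var(ddof=1) / lt.size) ** 2 / (lt.size - 1)
            + (lr.var(ddof=1) / lr.size) ** 2 / (lr.size - 1)
        ) if se > 0 else lt.size + lr.size - 2
        half = stats.t.ppf((1 + confidence) / 2, df_w) * se
        diff = lt.mean() - lr.mean()
        lo, hi = np.exp(diff - half), np.exp(diff + half)
    else:
        raise ValueError(f"unknown CI method {method!r}")

    # the point estimate must lie inside its own interval (degenerate
    # resampling on tiny or constant samples can nick this)
    lo, hi = float(min(lo, ratio)), float(max(hi, ratio))
    return BEResult(
        test_id=test_id,
        reference_id=reference_id,
        ratio=ratio,
        ci_low=lo,
        ci_high=hi,
        limits=limits,
        scale=scale,
        verdict=_verdict((lo, hi), limits),
        point_within_limits=bool(limits[0] <= ratio <= limits[1]),
        method=method,
    )


def assess_bioequivalence(
    totals,
    test_id: str,
    reference_id: str,
    *,
    scale: str = "raw",
    method: str = "bootstrap",
    seed: int | None = None,
    n_boot: int = N_BOOT,
    limits: tuple[float, float] = BE_LIMITS,
) -> BEResult:
    """Combined [uptake + clearance] BE assessment of test vs reference."""
    test = combined_metric(totals, test_id)
    ref = combined_metric(totals, reference_id)
    return be_ratio(
        test.pooled,
        ref.pooled,
        scale=scale,
        method=method,
        seed=seed,
        n_boot=n_boot,
        limits=limits,
        test_id=test_id,
        reference_id=reference_id,
    )


def _anova_oneway(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


def compare_groups(
    data: pd.DataFrame,
    value_col: str,
    factor: str,
    *,
    factor2: str | None = None,
    design: str = "one-way",
    correction: str = "bonferroni",
    alpha: float = ALPHA,
) -> dict:
    """Standard comparison battery: ANOVA plus Bonferroni pairwise t-tests.

    ``design='one-way'`` runs a one-way ANOVA on ``factor``;
    ``design='two-way'`` an additive-plus-interaction two-way ANOVA on
    ``factor`` and ``factor2`` (type-II sums of squares).  Pairwise two-tailed
    t-tests between the levels of ``factor`` are Bonferroni-adjusted.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    named = {
        str(k): g[value_col].to_numpy(dtype=float) for k, g in data.groupby(factor)
    }
    if len(named) < 2 or any(v.size < 2 for v in named.values()):
        raise ValueError("each factor level needs >= 2 observations and >= 2 levels")
    report: dict = {"design": design, "alpha": alpha}

    if design == "one-way":
        p = _anova_oneway(list(named.values()))
        report["anova_p"] = p
        report["significant"] = p < alpha
    elif design == "two-way":
        if factor2 is None:
            raise ValueError("two-way design requires factor2")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = data.rename(columns={value_col: "y", factor: "f1", factor2: "f2"})
        if np.ptp(df["y"].to_numpy(dtype=float)) == 0:
            report["anova_p"] = {factor: 1.0, factor2: 1.0, "interaction": 1.0}
        else:
            model = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
            tab = anova_lm(model, typ=2)
            report["anova_p"] = {
                factor: float(tab.loc["C(f1)", "PR(>F)"]),
                factor2: float(tab.loc["C(f2)", "PR(>F)"]),
                "interaction": float(tab.loc["C(f1):C(f2)", "PR(>F)"]),
            }
        report["significant"] = {
            k: (v < alpha) for k, v in report["anova_p"].items()
        }
    else:
        raise ValueError(f"unknown design {design!r}")

    pairs = list(itertools.combinations(sorted(named), 2))
    pairwise = {}
    for a, b in pairs:
        if np.ptp(np.concatenate([named[a], named[b]])) == 0:
            p = 1.0
        else:
            _, p = stats.ttest_ind(named[a], named[b])
        pairwise[(a, b)] = min(1.0, float(p) * len(pairs))
    report["pairwise_p"] = pairwise
    return report
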