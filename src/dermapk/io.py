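"""CSV readers/writers, run configuration and pipeline orchestration.

All tables are plain CSV with unit-bearing column names; a header that does
not carry the expected unit suffix aborts the run rather than silently
coercing units.  Reports are CSV tables plus a Markdown summary with a
provenance block (package version, seed, config hash) and are byte-identical
across reruns with the same inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioequiv, ivrt, profile, thickness
from .profile import TapeStripRecord
from .thickness import TEWLSeries

__all__ = [
    "RunConfig",
    "ValidationError",
    "load_config",
    "read_tape_strips",
    "write_tape_strips",
    "read_tewl",
    "write_tewl",
    "read_ivrt",
    "write_ivrt",
    "read_totals",
    "write_totals",
    "run_pipeline",
]

log = logging.getLogger("dermapk")

TAPE_COLUMNS = ["replicate_id", "strip_index", "mass_ug_per_cm2", "drug_ug_per_cm2", "pool_id"]
TEWL_COLUMNS = ["replicate_id", "strip_index", "mass_ug_per_cm2", "tewl_g_m2_h"]
IVRT_COLUMNS = ["cell_id", "formulation_id", "membrane_id", "time_h", "conc_ug_per_ml", "sample_volume_ml"]
TOTALS_COLUMNS = ["subject_or_cell_id", "product_id", "phase", "amount_ug_per_cm2"]


class ValidationError(ValueError):
    """Raised on malformed input tables, with the offending row when known."""


@dataclass
class RunConfig:
    """Persisted configuration of one analysis run (YAML or JSON on disk)."""

    # inputs
    tape_strips: str | None = None
    tewl_file: str | None = None
    ivrt_file: str | None = None
    totals_file: str | None = None
    # formulation / protocol metadata
    t_exposure_h: float = 6.0
    t_clearance_h: float = 17.0
    Cveh_ug_per_cm3: float = 0.0
    L_um: float | None = None
    density_g_cm3: float = 1.0
    receptor_volume_ml: float = ivrt.DEFAULT_RECEPTOR_VOLUME_ML
    area_cm2: float = ivrt.DEFAULT_AREA_CM2
    # analysis options
    discard_first_n: int = 0
    ci_method: str = "bootstrap"
    reference_product: str | None = None
    exclude_burst: bool = False
    seed: int = 0
    outdir: str = "dermapk-out"

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for name in ("tape_strips", "tewl_file", "ivrt_file", "totals_file"):
            p = getattr(self, name)
            if p is not None and not (base / p).exists():
                raise ValidationError(f"config: {name} file not found: {p}")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON (YAML is a superset of JSON)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path}: expected a mapping")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate(Path(path).parent)
    return cfg


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected header {required} "
            "(unit suffixes are mandatory — no silent unit coercion)"
        )


def read_tape_strips(path: str | Path) -> dict[str, list[TapeStripRecord]]:
    """Read tape-strip records grouped by replicate, with per-row validation."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TAPE_COLUMNS[:4], path)
    if "pool_id" not in df.columns:
        df["pool_id"] = None
    out: dict[str, list[TapeStripRecord]] = {}
    for row in df.itertuples():
        line = row.Index + 2  # header + 1-based
        if row.mass_ug_per_cm2 < 0:
            raise ValidationError(f"{path}:{line}: negative SC mass")
        if row.drug_ug_per_cm2 < 0:
            raise ValidationError(f"{path}:{line}: negative drug amount")
        pool = None if pd.isna(row.pool_id) or row.pool_id == "" else str(row.pool_id)
        out.setdefault(str(row.replicate_id), []).append(
            TapeStripRecord(
                strip_index=int(row.strip_index),
                mass_ug_per_cm2=float(row.mass_ug_per_cm2),
                drug_ug_per_cm2=float(row.drug_ug_per_cm2),
                pool_id=pool,
            )
        )
    for rid, recs in out.items():
        seen = [r.strip_index for r in recs]
        if len(set(seen)) != len(seen):
            raise ValidationError(f"{path}: duplicate strip_index in replicate {rid}")
    return out


def write_tape_strips(path: str | Path, records: dict[str, list[TapeStripRecord]]) -> None:
    rows = [
        {
            "replicate_id": rid,
            "strip_index": r.strip_index,
            "mass_ug_per_cm2": r.mass_ug_per_cm2,
            "drug_ug_per_cm2": r.drug_ug_per_cm2,
            "pool_id": r.pool_id if r.pool_id is not None else "",
        }
        for rid, recs in records.items()
        for r in recs
    ]
    pd.DataFrame(rows, columns=TAPE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_tewl(path: str | Path, density_g_cm3: float = 1.0) -> dict[str, TEWLSeries]:
    """Read TEWL series per replicate.

    The row with ``strip_index == 0`` is the pre-stripping baseline; depth
    removed before each subsequent reading is the running sum of strip masses,
    converted via ``mass_to_depth``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TEWL_COLUMNS, path)
    out: dict[str, TEWLSeries] = {}
    for rid, g in df.groupby("replicate_id"):
        g = g.sort_values("strip_index")
        if g["strip_index"].iloc[0] != 0:
            raise ValidationError(
                f"{path}: replicate {rid} lacks the baseline row (strip_index=0)"
            )
        masses = g["mass_ug_per_cm2"].to_numpy(dtype=float)
        depths = np.concatenate(
            [[0.0], np.cumsum([thickness.mass_to_depth(m, density_g_cm3) for m in masses[1:]])]
        )
        out[str(rid)] = TEWLSeries(
            depth_removed=depths,
            tewl=g["tewl_g_m2_h"].to_numpy(dtype=float),
            baseline=float(g["tewl_g_m2_h"].iloc[0]),
        )
    return out


def write_tewl(path: str | Path, series: dict[str, TEWLSeries], density_g_cm3: float = 1.0) -> None:
    rows = []
    for rid, s in series.items():
        increments = np.concatenate([[0.0], np.diff(s.depth_removed)])
        for k, (d, t) in enumerate(zip(increments, s.tewl)):
            rows.append(
                {
                    "replicate_id": rid,
                    "strip_index": k,
                    "mass_ug_per_cm2": d * density_g_cm3 * 100.0,
                    "tewl_g_m2_h": t,
                }
            )
    pd.DataFrame(rows, columns=TEWL_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_ivrt(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, IVRT_COLUMNS, path)
    if (df["sample_volume_ml"] < 0).any():
        bad = df.index[df["sample_volume_ml"] < 0][0] + 2
        raise ValidationError(f"{path}:{bad}: negative sample volume")
    return df


def write_ivrt(path: str | Path, df: pd.DataFrame) -> None:
    df.loc[:, IVRT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_totals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TOTALS_COLUMNS, path)
    bad_phase = ~df["phase"].isin(["uptake", "clearance"])
    if bad_phase.any():
        line = df.index[bad_phase][0] + 2
        raise ValidationError(f"{path}:{line}: phase must be 'uptake' or 'clearance'")
    if (df["amount_ug_per_cm2"] < 0).any():
        line = df.index[df["amount_ug_per_cm2"] < 0][0] + 2
        raise ValidationError(f"{path}:{line}: negative amount")
    return df.rename(columns={"amount_ug_per_cm2": "amount"})


def write_totals(path: str | Path, df: pd.DataFrame) -> None:
    out = df.rename(columns={"amount": "amount_ug_per_cm2"})
    out.loc[:, TOTALS_COLUMNS].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pipelines

def _provenance(cfg: RunConfig) -> str:
    from . import __version__

    return (
        "## Provenance\n\n"
        f"- dermapk version: {__version__}\n"
        f"- seed: {cfg.seed}\n"
        f"- config hash: {cfg.digest()}\n"
    )


def _run_dpk(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.tape_strips is None:
        raise ValidationError("dpk pipeline requires tape_strips input")
    strips = read_tape_strips(cfg.tape_strips)
    L = cfg.L_um
    thick_rows = []
    if L is None:
        if cfg.tewl_file is None:
            raise ValidationError("dpk pipeline needs L_um or a tewl_file")
        series = read_tewl(cfg.tewl_file, cfg.density_g_cm3)
        ests = {rid: thickness.estimate_thickness(s) for rid, s in series.items()}
        thick_rows = [
            {"replicate_id": rid, "H_um": e.H, "se_um": e.se, "n_used": e.n_used}
            for rid, e in ests.items()
        ]
        L = float(np.mean([e.H for e in ests.values()]))
        log.info("thickness from TEWL: L = %.2f um (mean of %d replicates)", L, len(ests))
    fits, profiles, fit_rows = [], [], []
    for rid, recs in sorted(strips.items()):
        prof = profile.build_profile(
            recs,
            L=L,
            t_exposure=cfg.t_exposure_h,
            Cveh=cfg.Cveh_ug_per_cm3,
            density_g_cm3=cfg.density_g_cm3,
            discard_first_n=cfg.discard_first_n,
        )
        fit = profile.fit_profile(prof, seed=cfg.seed)
        fits.append(fit)
        profiles.append(prof)
        fit_rows.append(
            {
                "replicate_id": rid,
                "K": fit.params.K,
                "K_se": fit.K_se,
                "DL2_per_h": fit.params.DL2,
                "DL2_se": fit.DL2_se,
                "kp_cm_per_h": fit.params.kp,
                "Jss_ug_cm2_h": fit.params.Jss,
                "tlag_h": fit.params.tlag,
                "steady_state": fit.steady_state,
                "rss": fit.objective,
            }
        )
    summary = profile.summarize_replicates(fits, profiles, t_uptake=cfg.t_exposure_h)
    pd.DataFrame(fit_rows).to_csv(outdir / "fits.csv", index=False)
    summary.to_csv(outdir / "params_summary.csv")
    if thick_rows:
        pd.DataFrame(thick_rows).to_csv(outdir / "thickness.csv", index=False)
    md = [
        "# Tape-strip diffusion analysis\n",
        f"SC thickness L = {L:.2f} um; exposure {cfg.t_exposure_h} h; "
        f"Cveh = {cfg.Cveh_ug_per_cm3} ug/cm^3\n",
        "## Parameter summary (mean +/- SD)\n",
        summary.to_markdown(),
        "\n",
        _provenance(cfg),
    ]
    (outdir / "report.md").write_text("\n".join(md))
    return {"summary": summary, "fits": fits, "L": L}


def _run_ivrt(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.ivrt_file is None:
        raise ValidationError("ivrt pipeline requires ivrt_file input")
    df = read_ivrt(cfg.ivrt_file)
    rows = []
    for (cell, form, mem), g in df.groupby(["cell_id", "formulation_id", "membrane_id"]):
        g = g.sort_values("time_h")
        curve = ivrt.cumulative_from_samples(
            g["time_h"],
            g["conc_ug_per_ml"],
            g["sample_volume_ml"],
            receptor_volume=cfg.receptor_volume_ml,
            area=cfg.area_cm2,
            formulation_id=str(form),
            membrane_id=str(mem),
        )
        fit = ivrt.higuchi_fit(curve, exclude_burst=cfg.exclude_burst)
        rows.append(
            {
                "cell_id": cell,
                "formulation_id": form,
                "membrane_id": mem,
                "q6h": float(curve.cumulative[-1]),
                "slope_ug_cm2_sqrth": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "detected": fit.detected,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "higuchi_fits.csv", index=False)
    comparison = ivrt.compare_release(table[table["detected"]], "q6h")
    md = [
        "# IVRT analysis\n",
        "## Per-cell sqrt-time fits\n",
        table.to_markdown(index=False),
        "\n## Release comparison\n",
        "```\n" + json.dumps(_jsonable(comparison), indent=2) + "\n```\n",
        _provenance(cfg),
    ]
    (outdir / "report.md").write_text("\n".join(md))
    return {"table": table, "comparison": comparison}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    return obj


def _run_be(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.totals_file is None:
        raise ValidationError("be pipeline requires totals_file input")
    totals = read_totals(cfg.totals_file)
    products = sorted(totals["product_id"].unique())
    reference = cfg.reference_product or products[0]
    if reference not in products:
        raise ValidationError(f"reference product {reference!r} not in data")
    summary_rows = []
    for prod in products:
        for phase in ("uptake", "clearance"):
            s = bioequiv.phase_summary(
                totals, prod, phase, method=cfg.ci_method, seed=cfg.seed
            )
            summary_rows.append(
                {
                    "product_id": prod,
                    "phase": phase,
                    "n": s.n,
                    "mean_ug_per_cm2": s.mean,
                    "ci90_low": s.ci_low,
                    "ci90_high": s.ci_high,
                    "method": s.method,
                }
            )
    phase_table = pd.DataFrame(summary_rows)
    be_rows = []
    for prod in products:
        if prod == reference:
            continue
        res = bioequiv.assess_bioequivalence(
            totals, prod, reference, seed=cfg.seed
        )
        be_rows.append(
            {
                "test": prod,
                "reference": reference,
                "ratio": res.ratio,
                "ci90_low": res.ci_low,
                "ci90_high": res.ci_high,
                "limit_low": res.limits[0],
                "limit_high": res.limits[1],
                "verdict": res.verdict,
                "point_within_limits": res.point_within_limits,
            }
        )
    be_table = pd.DataFrame(be_rows)
    phase_table.to_csv(outdir / "phase_summary.csv", index=False)
    be_table.to_csv(outdir / "be_assessment.csv", index=False)
    md = [
        "# Bioequivalence assessment\n",
        "## Per-phase SC totals (mean, 90% CI)\n",
        phase_table.to_markdown(index=False),
        "\n## Combined [uptake + clearance] test/reference ratios\n",
        be_table.to_markdown(index=False) if not be_table.empty else "(single product)",
        "\n",
        _provenance(cfg),
    ]
    (outdir / "report.md").write_text("\n".join(md))
    return {"phase_table": phase_table, "be_table": be_table}


def run_pipeline(cfg: RunConfig, which: str) -> dict:
    """Run one of the analysis pipelines: 'dpk', 'ivrt' or 'be'.

    Writes CSV tables and a Markdown report into ``cfg.outdir`` and returns
    the in-memory results.  Deterministic for fixed inputs and seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline=%s seed=%d outdir=%s", which, cfg.seed, outdir)
    runners = {"dpk": _run_dpk, "ivrt": _run_ivrt, "be": _run_be}
    if which not in runners:
        raise ValueError(f"unknown pipeline {which!r}; choose from {sorted(runners)}")
    try:
        return runners[which](cfg, outdir)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline {which!r} failed: {exc}; check the input tables and "
            "config against the schemas in dermapk.io"
        ) from exc
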