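"""Full-analysis orchestration: inputs -> unit-level result tables + report.

A single structured YAML config drives the run so that every analysis
constant (water-correction parameters, Simpson variant, L/H control ratio,
reservoir offsets, MCMC settings, rounding) is visible and overridable in
one place.  Outputs are a deterministic function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biometrics as bio
from . import isotopes as iso
from . import quantification as quant
from .chronology import (
    PhaseAssignment,
    PhaseSequenceModel,
    ReservoirCorrection,
    apply_delta_r,
    flag_outliers,
    phase_estimates,
    read_calcurve,
    sample_phase_model,
)

logger = logging.getLogger("shellseasons")

__all__ = ["RunConfig", "load_config", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolved from a YAML file."""

    isotopes_csv: Path | None = None
    fragments_csv: Path | None = None
    biometrics_csv: Path | None = None
    dates_csv: Path | None = None
    atmo_curve: Path | None = None
    marine_curve: Path | None = None
    out_dir: Path = Path("results")

    water_modern_smow: float = 0.90
    water_fairbanks_rate: float = 0.011
    water_meltwater_offset: float = -0.3
    water_meltwater_units: tuple[str, ...] = ()
    water_sea_level_m: dict[str, float] = field(default_factory=dict)
    sst_aggregation: str = "mean-of-extremes"
    sst_smooth_window: int = 5

    simpson_variant: str = "dominance"
    indeterminate_taxon: str = "Patella sp."
    apportion_within: tuple[str, ...] = ()

    lh_control_ratio: float | None = None

    delta_r: dict[str, tuple[float, float]] = field(default_factory=dict)
    phases: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (phase, member units), oldest first
    mcmc_iterations: int = 20_000
    mcmc_burn_in: int = 2_000
    rounding_years: int = 5
    outlier_prior: float = 0.05

    seed: int = 0


def load_config(path) -> RunConfig:
    """Read a run config from YAML (see docs for the schema)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = Path(path).parent

    def p(section, key):
        v = raw.get(section, {}).get(key)
        return None if v is None else base / v

    inputs = raw.get("inputs", {})
    water = raw.get("water", {})
    mcmc = raw.get("mcmc", {})
    cfg = RunConfig(
        isotopes_csv=p("inputs", "isotopes"),
        fragments_csv=p("inputs", "fragments"),
        biometrics_csv=p("inputs", "biometrics"),
        dates_csv=p("inputs", "dates"),
        atmo_curve=p("inputs", "atmo_curve"),
        marine_curve=p("inputs", "marine_curve"),
        out_dir=base / raw.get("out_dir", "results"),
        water_modern_smow=water.get("modern_smow", 0.90),
        water_fairbanks_rate=water.get("fairbanks_rate", 0.011),
        water_meltwater_offset=water.get("meltwater_offset", -0.3),
        water_meltwater_units=tuple(str(u) for u in water.get("meltwater_units", [])),
        water_sea_level_m={str(k): float(v) for k, v in water.get("sea_level_m", {}).items()},
        sst_aggregation=raw.get("sst", {}).get("aggregation", "mean-of-extremes"),
        sst_smooth_window=int(raw.get("sst", {}).get("smooth_window", 5)),
        simpson_variant=raw.get("simpson", {}).get("variant", "dominance"),
        indeterminate_taxon=raw.get("quantification", {}).get(
            "indeterminate_taxon", "Patella sp."
        ),
        apportion_within=tuple(raw.get("quantification", {}).get("apportion_within", [])),
        lh_control_ratio=raw.get("biometrics", {}).get("lh_control"),
        delta_r={
            str(d["species"]): (float(d["delta_r"]), float(d["sigma"]))
            for d in raw.get("delta_r", [])
        },
        phases=tuple(
            (str(ph["name"]), tuple(str(u) for u in ph["members"]))
            for ph in raw.get("phases", [])
        ),
        mcmc_iterations=int(mcmc.get("iterations", 20_000)),
        mcmc_burn_in=int(mcmc.get("burn_in", 2_000)),
        rounding_years=int(mcmc.get("rounding", 5)),
        outlier_prior=float(mcmc.get("outlier_prior", 0.05)),
        seed=int(raw.get("seed", 0)),
    )
    return cfg


_SCHEMAS = {
    "isotopes": ["shell_id", "species", "unit_id", "diameter_mm", "position_mm", "d18o_vpdb"],
    "fragments": ["unit_id", "taxon", "taxon_class", "side", "category", "count"],
    "biometrics": ["unit_id", "species", "length_mm", "height_mm", "width_mm"],
    "dates": ["lab_id", "unit_id", "material", "species", "cra_bp", "sigma"],
}


def validate_inputs(paths: dict[str, Path]) -> dict[str, list[str]]:
    """Schema and invariant checks per input table.

    Returns {"errors": [...], "warnings": [...]} with row-level locations.
    Missing files and columns are errors; protocol deviations (shell
    diameter >= 17 mm, biometric units with n < 30) are warnings.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    for kind, path in paths.items():
        if path is None:
            continue
        if kind not in _SCHEMAS:
            errors.append(f"{kind}: unknown input kind")
            continue
        if not Path(path).exists():
            errors.append(f"{kind}: file not found: {path}")
            continue
        df = pd.read_csv(path)
        missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
        if missing:
            errors.append(f"{kind}: missing columns {missing}")
            continue
        frames[kind] = df

    if "isotopes" in frames:
        df = frames["isotopes"]
        bad = df.index[~np.isfinite(df["d18o_vpdb"])]
        errors += [f"isotopes row {i}: non-finite d18o_vpdb" for i in bad]
        big = df.groupby("shell_id")["diameter_mm"].first()
        for sid, d in big[big >= iso.SMALL_SHELL_DIAMETER_MM].items():
            warnings_.append(f"isotopes: shell {sid} diameter {d} mm >= 17 mm threshold")
    if "fragments" in frames:
        df = frames["fragments"]
        bad = df.index[df["count"] < 0]
        errors += [f"fragments row {i}: negative count" for i in bad]
    if "biometrics" in frames:
        df = frames["biometrics"]
        for col in ("length_mm", "height_mm"):
            bad = df.index[df[col] <= 0]
            errors += [f"biometrics row {i}: non-positive {col}" for i in bad]
        sizes = df.groupby(["unit_id", "species"]).size()
        for (unit, spp), n in sizes[sizes < bio.MIN_SAMPLES_FOR_SELECTION_TEST].items():
            warnings_.append(
                f"biometrics: unit {unit} {spp}: n={n} < "
                f"{bio.MIN_SAMPLES_FOR_SELECTION_TEST}, selection test not evaluated"
            )
    if "dates" in frames:
        df = frames["dates"]
        bad = df.index[(df["sigma"] <= 0) | (df["cra_bp"] <= 0)]
        errors += [f"dates row {i}: non-positive cra_bp or sigma" for i in bad]
    return {"errors": errors, "warnings": warnings_}


def _water_for_unit(cfg: RunConfig, unit_id: str) -> iso.WaterCorrection:
    return iso.WaterCorrection(
        modern_d18o_water_smow=cfg.water_modern_smow,
        fairbanks_rate=cfg.water_fairbanks_rate,
        sea_level_offset_m=cfg.water_sea_level_m.get(unit_id, 0.0),
        meltwater_flag=unit_id in cfg.water_meltwater_units,
        meltwater_offset=cfg.water_meltwater_offset,
    )


def _sst_stage(cfg: RunConfig):
    profiles = iso.read_isotopes_csv(cfg.isotopes_csv)
    sample_rows = []
    by_unit: dict[str, list] = {}
    for prof in profiles:
        water = _water_for_unit(cfg, prof.unit_id)
        series = iso.profile_to_sst(prof, water)
        by_unit.setdefault(prof.unit_id, []).append(series)
        for pos, t, s in zip(series.positions_mm, series.sst_celsius, prof.samples):
            sample_rows.append(
                {"shell_id": prof.shell_id, "unit_id": prof.unit_id,
                 "position_mm": pos, "d18o_vpdb": s.d18o_shell_vpdb, "sst_celsius": t}
            )
    summaries = [
        iso.unit_sst_summary(uid, series_list, method=cfg.sst_aggregation,
                             smooth_window=cfg.sst_smooth_window)
        for uid, series_list in sorted(by_unit.items())
    ]
    unit_df = pd.DataFrame(
        [
            {"unit_id": s.unit_id, "sst_min": s.sst_min, "sst_max": s.sst_max,
             "seasonality": s.seasonality, "n_shells": s.n_shells,
             "aggregation": s.aggregation_method}
            for s in summaries
        ]
    )
    return pd.DataFrame(sample_rows), unit_df


def _chronology_stage(cfg: RunConfig, seed: int):
    atmo = read_calcurve(cfg.atmo_curve, curve_kind="atmospheric")
    marine = read_calcurve(cfg.marine_curve, curve_kind="marine") if cfg.marine_curve else atmo
    df = pd.read_csv(cfg.dates_csv)
    unit_to_phase = {u: name for name, members in cfg.phases for u in members}
    assignments = []
    for row in df.itertuples():
        from .chronology import RadiocarbonDate

        date = RadiocarbonDate(
            lab_id=str(row.lab_id), unit_id=str(row.unit_id), material=str(row.material),
            cra_bp=float(row.cra_bp), sigma=float(row.sigma),
            species="" if pd.isna(row.species) else str(row.species),
        )
        if date.material == "shell":
            if date.species not in cfg.delta_r:
                raise ValueError(f"date {date.lab_id}: no ΔR configured for {date.species!r}")
            dr, drs = cfg.delta_r[date.species]
            date = apply_delta_r(
                date, ReservoirCorrection(species=date.species, delta_r=dr, delta_r_sigma=drs)
            )
            curve = marine
        else:
            curve = atmo
        phase = unit_to_phase.get(date.unit_id)
        if phase is None:
            logger.warning("date %s: unit %s not in any phase, skipped", date.lab_id, date.unit_id)
            continue
        assignments.append(PhaseAssignment(date=date, curve=curve, phase=phase))
    model = PhaseSequenceModel(
        phases=tuple(name for name, _ in cfg.phases),
        dates=tuple(assignments),
        outlier_prior=cfg.outlier_prior,
    )
    samples = sample_phase_model(
        model, n_iter=cfg.mcmc_iterations, burn_in=cfg.mcmc_burn_in, seed=seed
    )
    return phase_estimates(samples, rounding=cfg.rounding_years), flag_outliers(samples)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage and write the result tables.

    Produces (as configured inputs allow) sst_by_sample.csv,
    unit_sst_summary.csv, mni_by_unit.csv, biometrics_summary.csv,
    phase_estimates.csv, date_outliers.csv, and report.json with the seed,
    config hash and input digests.  Idempotent for fixed config + seed.
    """
    paths = {
        "isotopes": cfg.isotopes_csv,
        "fragments": cfg.fragments_csv,
        "biometrics": cfg.biometrics_csv,
        "dates": cfg.dates_csv,
    }
    report = validate_inputs({k: v for k, v in paths.items() if v is not None})
    if report["errors"]:
        raise ValueError("input validation failed:\n" + "\n".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("%s", w)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    if cfg.isotopes_csv:
        sample_df, unit_df = _sst_stage(cfg)
        results["sst_by_sample"] = sample_df
        results["unit_sst_summary"] = unit_df
    if cfg.fragments_csv:
        fragments = quant.read_fragments_csv(cfg.fragments_csv)
        results["mni_by_unit"] = quant.mni_table(
            fragments,
            indeterminate_taxon=cfg.indeterminate_taxon,
            apportion_within=cfg.apportion_within,
        )
        pooled = results["mni_by_unit"].groupby("taxon")["mni"].sum().to_dict()
        results["diversity"] = pd.DataFrame(
            [{
                "scope": "all_units",
                "variant": cfg.simpson_variant,
                "simpson_index": quant.simpson_index(pooled, cfg.simpson_variant),
                "total_mni": int(sum(pooled.values())),
            }]
        )
    if cfg.biometrics_csv:
        measurements = bio.read_biometrics_csv(cfg.biometrics_csv)
        results["biometrics_summary"] = bio.biometrics_summary(
            measurements, lh_control_ratio=cfg.lh_control_ratio
        )
    if cfg.dates_csv and cfg.atmo_curve and cfg.phases:
        estimates, outliers = _chronology_stage(cfg, cfg.seed)
        results["phase_estimates"] = estimates
        results["date_outliers"] = outliers

    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)

    digest = {}
    for kind, path in paths.items():
        if path is not None and Path(path).exists():
            digest[kind] = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
    (out / "report.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "input_digests": digest,
                "outputs": sorted(results),
                "warnings": report["warnings"],
            },
            indent=2,
        )
    )
    return results
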