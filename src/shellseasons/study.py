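"""Assemble a complete synthetic study on disk, ready for the pipeline.

Writes the CSV schemas the analysis modules read (isotopes.csv,
fragments.csv, biometrics.csv, dates.csv), two synthetic calibration curves
(atmospheric and marine, the latter with a reservoir-age offset), and a
run.yaml wiring everything together.  The true scenario parameters are
returned so recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chronology.calibrate import ReservoirCorrection
from .chronology.curves import write_calcurve
from . import synthetic as syn

__all__ = ["StudyTruth", "PHASE_INTERVALS", "DELTA_R", "load_scenario", "generate_study"]

# True deposition intervals (cal BP), oldest first — the chronology the
# phase model should recover.
PHASE_INTERVALS: dict[str, tuple[float, float]] = {
    "108": (8995.0, 8760.0),
    "107": (8550.0, 8330.0),
    "105": (8315.0, 8185.0),
    "112C": (8180.0, 8070.0),
    "101B": (7945.0, 7795.0),
}

# Species-specific local marine reservoir offsets (years, 1 sigma).
DELTA_R = {
    "Patella vulgata": (-114.0, 170.0),
    "Phorcus lineatus": (-257.0, 120.0),
}

MARINE_RESERVOIR_OFFSET = 550.0  # 14C y between marine and atmospheric curves


def load_scenario(path) -> tuple[syn.ClimateScenario, syn.AssemblageScenario,
                                 dict[str, tuple[float, float]] | None]:
    """Read a scenario YAML: climate per unit, species pool, phase intervals.

    Any missing section falls back to the package defaults.  Schema::

        climate:
          units:
            "108": {mean_sst: 16.3, amplitude: 6.9, phase: 0.0,
                    meltwater: true, sea_level_m: -14}
        assemblage:
          species:
            - {name: ..., taxon_class: ..., midpoint: 17.5, slope: -1.5,
               base_weight: 1.0, mean_length_mm: 32, sd_length_mm: 4.5,
               lh_ratio: 1.9}
          unit_total_mni: {"108": 3000}
          pressure: {"108": 0.0}
          indeterminate_fraction: 0.1
        chronology:
          intervals: {"108": [8995, 8760]}   # cal BP, oldest first
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    climate = syn.default_climate_scenario()
    if "climate" in raw:
        climate = syn.ClimateScenario(units={
            str(u): syn.UnitClimate(
                mean_sst=float(c["mean_sst"]), amplitude=float(c["amplitude"]),
                phase=float(c.get("phase", 0.0)),
                meltwater_flag=bool(c.get("meltwater", False)),
                sea_level_offset_m=float(c.get("sea_level_m", 0.0)),
            )
            for u, c in raw["climate"]["units"].items()
        })
    assemblage = syn.default_assemblage_scenario()
    if "assemblage" in raw:
        a = raw["assemblage"]
        species = tuple(
            syn.SpeciesResponse(
                name=str(s["name"]), taxon_class=str(s["taxon_class"]),
                midpoint=float(s["midpoint"]), slope=float(s["slope"]),
                base_weight=float(s.get("base_weight", 1.0)),
                mean_length_mm=float(s.get("mean_length_mm", 30.0)),
                sd_length_mm=float(s.get("sd_length_mm", 5.0)),
                lh_ratio=float(s.get("lh_ratio", 1.9)),
            )
            for s in a.get("species", [])
        ) or assemblage.species
        assemblage = syn.AssemblageScenario(
            species=species,
            unit_total_mni={str(k): int(v) for k, v in a.get(
                "unit_total_mni", {u: 3000 for u in climate.units}).items()},
            pressure={str(k): float(v) for k, v in a.get("pressure", {}).items()},
            indeterminate_fraction=float(a.get("indeterminate_fraction", 0.0)),
        )
    intervals = None
    if "chronology" in raw and "intervals" in raw["chronology"]:
        intervals = {str(u): (float(v[0]), float(v[1]))
                     for u, v in raw["chronology"]["intervals"].items()}
    return climate, assemblage, intervals


@dataclass
class StudyTruth:
    """Ground truth of a generated study."""

    climate: syn.ClimateScenario
    assemblage: syn.AssemblageScenario
    phase_intervals: dict[str, tuple[float, float]]
    true_mni: dict[str, dict[str, int]]
    true_dates: dict[str, list[float]]


def generate_study(
    out_dir,
    seed: int = 0,
    *,
    climate: syn.ClimateScenario | None = None,
    assemblage: syn.AssemblageScenario | None = None,
    n_shells_per_unit: int = 4,
    n_samples_per_shell: int = 45,
    n_dates_per_unit: int = 4,
    date_sigma: float = 30.0,
    mcmc_iterations: int = 8000,
    mcmc_burn_in: int = 1500,
    phase_intervals: dict[str, tuple[float, float]] | None = None,
) -> StudyTruth:
    """Generate and write a full synthetic study; returns the ground truth.

    ``phase_intervals`` maps each unit to its true (older, younger)
    deposition interval in cal BP; units without one are laid out as
    contiguous 150-year phases below 9000 cal BP.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    climate = climate or syn.default_climate_scenario()
    assemblage = assemblage or syn.default_assemblage_scenario()
    if phase_intervals is None:
        if all(u in PHASE_INTERVALS for u in climate.units):
            phase_intervals = {u: PHASE_INTERVALS[u] for u in climate.units}
        else:
            phase_intervals = {
                u: (9000.0 - 200.0 * i, 9000.0 - 200.0 * i - 150.0)
                for i, u in enumerate(climate.units)
            }
    root = np.random.SeedSequence(seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ("shells", "assemblage", "sizes", "curve", "dates"), root.spawn(5)
    )}

    units = list(climate.units)

    # --- isotope profiles ---
    iso_rows = []
    for ui, unit in enumerate(units):
        for k in range(n_shells_per_unit):
            prof = syn.simulate_shell(
                climate, unit, n_samples=n_samples_per_shell,
                seed=sub["shells"] + 97 * ui + k, shell_id=f"MA.{unit}.{k + 1}",
            )
            for s in prof.samples:
                iso_rows.append(
                    {"shell_id": prof.shell_id, "species": prof.species,
                     "unit_id": unit, "diameter_mm": round(prof.diameter_mm, 2),
                     "position_mm": round(s.position_mm, 2),
                     "d18o_vpdb": round(s.d18o_shell_vpdb, 4)}
                )
    pd.DataFrame(iso_rows).to_csv(out / "isotopes.csv", index=False)

    # --- assemblages ---
    frag_rows = []
    true_mni: dict[str, dict[str, int]] = {}
    for ui, unit in enumerate(units):
        counts, truth = syn.simulate_assemblage(
            climate, assemblage, unit, seed=sub["assemblage"] + ui
        )
        true_mni[unit] = truth
        for fc in counts:
            if fc.taxon_class == "bivalve":
                for side, cats in (("L", fc.left), ("R", fc.right)):
                    for cat, n in sorted(cats.items()):
                        frag_rows.append({"unit_id": unit, "taxon": fc.taxon,
                                          "taxon_class": fc.taxon_class, "side": side,
                                          "category": cat, "count": n})
                if fc.unsided:
                    frag_rows.append({"unit_id": unit, "taxon": fc.taxon,
                                      "taxon_class": fc.taxon_class, "side": "NA",
                                      "category": "FRAGMENTS", "count": fc.unsided})
            else:
                for cat, n in sorted(fc.counts.items()):
                    frag_rows.append({"unit_id": unit, "taxon": fc.taxon,
                                      "taxon_class": fc.taxon_class, "side": "NA",
                                      "category": cat, "count": n})
    pd.DataFrame(frag_rows).to_csv(out / "fragments.csv", index=False)

    # --- biometrics ---
    bio_rows = []
    for ui, unit in enumerate(units):
        for si, sp in enumerate(("Patella vulgata", "Patella depressa")):
            ms = syn.simulate_sizes(
                assemblage, unit, n=40, seed=sub["sizes"] + 10 * ui + si, species=sp
            )
            for m in ms:
                bio_rows.append(
                    {"unit_id": unit, "species": m.species,
                     "length_mm": round(m.length_mm, 2), "height_mm": round(m.height_mm, 2),
                     "width_mm": round(m.width_mm, 2)}
                )
    pd.DataFrame(bio_rows).to_csv(out / "biometrics.csv", index=False)

    # --- calibration curves ---
    atmo = syn.simulate_calcurve(seed=sub["curve"], name="synthetic-atmo")
    marine = syn.simulate_calcurve(
        seed=sub["curve"] + 1, offset=400.0 + MARINE_RESERVOIR_OFFSET,
        name="synthetic-marine", curve_kind="marine",
    )
    write_calcurve(atmo, out / "atmo.14c")
    write_calcurve(marine, out / "marine.14c")

    # --- radiocarbon dates: bones on the atmospheric curve, shells marine ---
    rng = np.random.default_rng(sub["dates"])
    date_rows = []
    true_dates: dict[str, list[float]] = {}
    shell_species = ["Patella vulgata", "Phorcus lineatus"]
    for ui, unit in enumerate(units):
        old, young = phase_intervals[unit]
        ages = rng.uniform(young, old, size=n_dates_per_unit)
        true_dates[unit] = [float(a) for a in ages]
        n_shell = n_dates_per_unit // 2
        bone_dates = syn.simulate_dates(
            ages[n_shell:], atmo, sigma=date_sigma, seed=sub["dates"] + 31 * ui,
            unit_ids=[unit] * (n_dates_per_unit - n_shell), material="bone",
            lab_prefix=f"BONE-{unit}",
        )
        for d in bone_dates:
            date_rows.append({"lab_id": d.lab_id, "unit_id": unit, "material": "bone",
                              "species": "", "cra_bp": round(d.cra_bp, 1),
                              "sigma": d.sigma})
        for k in range(n_shell):
            spp = shell_species[k % len(shell_species)]
            dr, _ = DELTA_R[spp]
            d = syn.simulate_dates(
                [ages[k]], marine, sigma=date_sigma, seed=sub["dates"] + 31 * ui + 7 + k,
                reservoir=ReservoirCorrection(species=spp, delta_r=dr, delta_r_sigma=0.0),
                unit_ids=[unit], lab_prefix=f"SHELL-{unit}-{k}",
            )[0]
            date_rows.append({"lab_id": d.lab_id, "unit_id": unit, "material": "shell",
                              "species": spp, "cra_bp": round(d.cra_bp, 1),
                              "sigma": d.sigma})
    pd.DataFrame(date_rows).to_csv(out / "dates.csv", index=False)

    # --- run config ---
    config = {
        "inputs": {
            "isotopes": "isotopes.csv",
            "fragments": "fragments.csv",
            "biometrics": "biometrics.csv",
            "dates": "dates.csv",
            "atmo_curve": "atmo.14c",
            "marine_curve": "marine.14c",
        },
        "out_dir": "results",
        "water": {
            "modern_smow": 0.90,
            "fairbanks_rate": 0.011,
            "meltwater_offset": -0.3,
            "meltwater_units": [u for u, c in climate.units.items() if c.meltwater_flag],
            "sea_level_m": {u: c.sea_level_offset_m for u, c in climate.units.items()},
        },
        "sst": {"aggregation": "mean-of-extremes"},
        "simpson": {"variant": "dominance"},
        "quantification": {
            "indeterminate_taxon": "Patella sp.",
            "apportion_within": ["Patella vulgata", "Patella depressa"],
        },
        "biometrics": {"lh_control": 1.9},
        "delta_r": [
            {"species": spp, "delta_r": dr, "sigma": drs}
            for spp, (dr, drs) in DELTA_R.items()
        ],
        "phases": [{"name": u, "members": [u]} for u in units],
        "mcmc": {"iterations": mcmc_iterations, "burn_in": mcmc_burn_in,
                 "rounding": 5, "outlier_prior": 0.05},
        "seed": seed,
    }
    (out / "run.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    return StudyTruth(
        climate=climate,
        assemblage=assemblage,
        phase_intervals=dict(phase_intervals),
        true_mni=true_mni,
        true_dates=true_dates,
    )
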