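"""Synthetic study generator with known ground truth.

Every analysis stage in this package can be exercised end-to-end on data
whose true parameters are known, so recovery can be checked exactly.  The
generator emulates the statistical structure a shell-midden study assumes:

* a sinusoidal seasonal SST cycle per stratigraphic unit, micro-sampled
  sequentially along a shell growth axis whose growth rate decays with age
  (so equal-distance samples cover increasing spans of time towards the
  apex), with Gaussian measurement noise on delta-18-O;
* mollusc assemblages whose species proportions respond logistically to the
  unit's mean SST (warm- vs cold-adapted taxa), fragmented stochastically
  into the standard recording categories so that the MNI formulas recover
  the simulated individual count exactly when no diagnostic element is lost;
* per-unit shell-size distributions, normal with a harvesting-pressure
  shift, plus an upper-truncation mode that produces the non-normal
  distributions read as size selection;
* a radiocarbon calibration curve (linear trend plus smooth bounded
  wiggles, so the mean stays monotone) and measurements drawn from it with
  species-specific marine reservoir offsets.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .biometrics import ShellMeasurement
from .chronology.calibrate import RadiocarbonDate, ReservoirCorrection
from .chronology.curves import CalibrationCurve
from .isotopes import IsotopeSample, ShellProfile, WaterCorrection, shell_d18o_from_sst, water_d18o
from .quantification import FragmentCounts

__all__ = [
    "UnitClimate",
    "ClimateScenario",
    "SpeciesResponse",
    "AssemblageScenario",
    "simulate_sst",
    "simulate_shell",
    "simulate_assemblage",
    "simulate_sizes",
    "simulate_calcurve",
    "simulate_dates",
    "default_climate_scenario",
    "default_assemblage_scenario",
]

DEFAULT_NOISE_SD_PERMIL = 0.15  # order of the larger instrumental error
DEFAULT_SAMPLES_PER_SHELL = 45
SAMPLE_SPACING_MM = 0.3


@dataclass(frozen=True)
class UnitClimate:
    """Seasonal SST regime and water-correction context of one unit."""

    mean_sst: float
    amplitude: float
    phase: float = 0.0  # fraction of a year; 0 puts the maximum at t = 0
    meltwater_flag: bool = False
    sea_level_offset_m: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def water_correction(self, **kwargs) -> WaterCorrection:
        return WaterCorrection(
            sea_level_offset_m=self.sea_level_offset_m,
            meltwater_flag=self.meltwater_flag,
            **kwargs,
        )


@dataclass(frozen=True)
class ClimateScenario:
    """Per-unit climate regimes, keyed by unit id (oldest first)."""

    units: dict[str, UnitClimate]

    def __getitem__(self, unit_id: str) -> UnitClimate:
        return self.units[unit_id]


@dataclass(frozen=True)
class SpeciesResponse:
    """Logistic thermal response of one species' relative representation.

    The unnormalised weight at mean SST ``T`` is
    ``sigmoid(slope * (T - midpoint))``; a negative slope makes the species
    cold-adapted.  ``base_weight`` scales overall commonness.
    """

    name: str
    taxon_class: str
    midpoint: float  # degC
    slope: float  # per degC; sign encodes warm (+) vs cold (-) adaptation
    base_weight: float = 1.0
    mean_length_mm: float = 30.0
    sd_length_mm: float = 5.0
    lh_ratio: float = 1.9


@dataclass(frozen=True)
class AssemblageScenario:
    """Species pool, per-unit target MNI, and harvesting-pressure model."""

    species: tuple[SpeciesResponse, ...]
    unit_total_mni: dict[str, int]
    pressure: dict[str, float] = field(default_factory=dict)  # per-unit, 0..
    pressure_coefficient_mm: float = 2.0  # mean-size drop per unit pressure
    indeterminate_fraction: float = 0.0  # broken limpets recorded as Patella sp.


def species_weights(scenario: AssemblageScenario, mean_sst: float) -> np.ndarray:
    """Normalised expected species proportions at a given mean SST."""
    w = np.array(
        [
            sp.base_weight / (1.0 + np.exp(-sp.slope * (mean_sst - sp.midpoint)))
            for sp in scenario.species
        ]
    )
    return w / w.sum()


def simulate_sst(scenario: ClimateScenario, unit_id: str) -> Callable[[float], float]:
    """The deterministic seasonal cycle T(t) of a unit; t in years."""
    u = scenario[unit_id]

    def temperature(t):
        return u.mean_sst + u.amplitude * np.cos(2.0 * np.pi * (np.asarray(t) - u.phase))

    return temperature


def _sample_times(n_samples: int, span_years: float, growth_decay: float) -> np.ndarray:
    """Time-before-death of equally spaced distance samples, edge to apex.

    Growth rate decays exponentially with age, so equal distance increments
    towards the apex map to geometrically growing time increments.
    """
    u = np.linspace(0.0, 1.0, n_samples)
    if growth_decay <= 0:
        return span_years * u
    return span_years * (np.exp(growth_decay * u) - 1.0) / (np.exp(growth_decay) - 1.0)


def simulate_shell(
    scenario: ClimateScenario,
    unit_id: str,
    n_samples: int = DEFAULT_SAMPLES_PER_SHELL,
    noise_sd_permil: float = DEFAULT_NOISE_SD_PERMIL,
    seed: int = 0,
    *,
    shell_id: str | None = None,
    species: str = "Phorcus lineatus",
    span_years: float = 1.3,
    growth_decay: float = 1.0,
    water_kwargs: dict | None = None,
) -> ShellProfile:
    """One micro-sampled shell profile from a unit's seasonal cycle.

    Samples sit 0.3 mm apart from the growth edge; the sampled times span
    ``span_years`` of growth (>= 1 year so both seasonal extremes are seen).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if span_years < 1.0:
        raise ValueError("span_years must cover at least one full year")
    rng = np.random.default_rng(seed)
    u = scenario[unit_id]
    temp = simulate_sst(scenario, unit_id)
    t_death = rng.uniform(0.0, 1.0)  # death date within the seasonal cycle
    times = t_death - _sample_times(n_samples, span_years, growth_decay)
    water = u.water_correction(**(water_kwargs or {}))
    d_water = water_d18o(water)
    d18o = shell_d18o_from_sst(temp(times), d_water)
    d18o = np.atleast_1d(d18o) + rng.normal(0.0, noise_sd_permil, size=n_samples)
    positions = SAMPLE_SPACING_MM * np.arange(n_samples)
    samples = tuple(
        IsotopeSample(position_mm=float(p), d18o_shell_vpdb=float(d))
        for p, d in zip(positions, d18o)
    )
    return ShellProfile(
        shell_id=shell_id or f"{unit_id}-s{seed}",
        species=species,
        unit_id=unit_id,
        diameter_mm=float(rng.uniform(12.0, 16.5)),
        samples=samples,
    )


def _fragment_non_spiralled(rng, n: int, loss_free: bool) -> dict[str, int]:
    # each individual leaves exactly one countable element: COMI, FRAI or APIF
    kinds = rng.choice(3, size=n, p=[0.3, 0.4, 0.3])
    counts = {"COMI": int((kinds == 0).sum()), "FRAI": int((kinds == 1).sum()),
              "APIF": int((kinds == 2).sum())}
    if not loss_free:
        counts["FTS"] = int(rng.poisson(0.5 * n))
    return counts


def _fragment_spiralled(rng, n: int, loss_free: bool) -> dict[str, int]:
    # broken individuals always leave their apex, and at most one of the
    # stoma/umbilical fragments, so APIF >= STOF + UMBF never overcounts
    kinds = rng.choice(3, size=n, p=[0.35, 0.35, 0.3])
    counts = {"COMI": int((kinds == 0).sum()), "FRAI": int((kinds == 1).sum())}
    broken = int((kinds == 2).sum())
    counts["APIF"] = broken
    base = rng.choice(3, size=broken, p=[0.4, 0.3, 0.3])  # none / stoma / umbilical
    counts["STOF"] = int((base == 1).sum())
    counts["UMBF"] = int((base == 2).sum())
    if not loss_free:
        counts["FTS"] = int(rng.poisson(0.8 * n))
    return counts


def _fragment_bivalve(rng, n: int, loss_free: bool) -> tuple[dict, dict, int]:
    sides = []
    for _ in range(2):  # left, right valves of the same n individuals
        kinds = rng.choice(4, size=n, p=[0.3, 0.3, 0.2, 0.2])
        side = {
            "COMV": int((kinds == 0).sum()),
            "FRAV": int((kinds == 1).sum()),
            "FCH": int((kinds == 2).sum()),
        }
        broken = int((kinds == 3).sum())  # hinge split: one AHF and one PHF each
        side["AHF"] = broken
        side["PHF"] = broken
        sides.append(side)
    unsided = 0 if loss_free else int(rng.poisson(1.0 * n))
    return sides[0], sides[1], unsided


def simulate_assemblage(
    climate: ClimateScenario,
    scenario: AssemblageScenario,
    unit_id: str,
    seed: int = 0,
    *,
    loss_free: bool = True,
) -> tuple[list[FragmentCounts], dict[str, int]]:
    """Fragment tallies for one unit plus the true per-species MNI.

    Species counts are multinomial with logistic thermal weights at the
    unit's mean SST; each individual is then fragmented into valid recording
    categories.  In the loss-free regime every individual leaves a
    countable diagnostic element and the MNI formulas are exact.
    """
    rng = np.random.default_rng(seed)
    total = scenario.unit_total_mni[unit_id]
    probs = species_weights(scenario, climate[unit_id].mean_sst)
    counts = rng.multinomial(total, probs)
    true_mni = {sp.name: int(c) for sp, c in zip(scenario.species, counts)}

    out: list[FragmentCounts] = []
    indet_frai = 0
    for sp, n in zip(scenario.species, counts):
        n = int(n)
        if sp.taxon_class == "non_spiralled_gastropod":
            if scenario.indeterminate_fraction > 0 and sp.name.startswith("Patella"):
                n_indet = rng.binomial(n, scenario.indeterminate_fraction)
                indet_frai += int(n_indet)
                n -= int(n_indet)
            cats = _fragment_non_spiralled(rng, n, loss_free)
            out.append(FragmentCounts(unit_id=unit_id, taxon=sp.name,
                                      taxon_class=sp.taxon_class, counts=cats))
        elif sp.taxon_class == "spiralled_gastropod":
            cats = _fragment_spiralled(rng, n, loss_free)
            out.append(FragmentCounts(unit_id=unit_id, taxon=sp.name,
                                      taxon_class=sp.taxon_class, counts=cats))
        elif sp.taxon_class == "bivalve":
            left, right, unsided = _fragment_bivalve(rng, n, loss_free)
            out.append(FragmentCounts(unit_id=unit_id, taxon=sp.name,
                                      taxon_class=sp.taxon_class,
                                      left=left, right=right, unsided=unsided))
        else:
            raise ValueError(f"unknown taxon_class {sp.taxon_class!r}")
    if indet_frai > 0:
        out.append(FragmentCounts(unit_id=unit_id, taxon="Patella sp.",
                                  taxon_class="non_spiralled_gastropod",
                                  counts={"FRAI": indet_frai}))
    return out, true_mni


def simulate_sizes(
    scenario: AssemblageScenario,
    unit_id: str,
    n: int,
    seed: int = 0,
    *,
    species: str | None = None,
    truncate_top: bool = False,
) -> list[ShellMeasurement]:
    """Shell measurements for one unit under the size model.

    Lengths are Normal(mean - pressure * coefficient, sd) truncated at
    zero; heights and widths follow allometrically with small noise.  With
    ``truncate_top`` only the upper half of the distribution is kept,
    emulating deliberate selection of large shells.
    """
    rng = np.random.default_rng(seed)
    sp = next(
        (s for s in scenario.species if species is None or s.name == species),
        None,
    )
    if sp is None:
        raise ValueError(f"species {species!r} not in scenario")
    pressure = scenario.pressure.get(unit_id, 0.0)
    mean = sp.mean_length_mm - pressure * scenario.pressure_coefficient_mm
    draw = max(2 * n, 20) if truncate_top else n
    lengths = rng.normal(mean, sp.sd_length_mm, size=draw)
    lengths = lengths[lengths > 1.0]
    if truncate_top:
        lengths = np.sort(lengths)[-n:]
    else:
        lengths = lengths[:n]
    heights = lengths / sp.lh_ratio * np.exp(rng.normal(0.0, 0.05, size=len(lengths)))
    widths = 0.8 * lengths * np.exp(rng.normal(0.0, 0.05, size=len(lengths)))
    return [
        ShellMeasurement(unit_id=unit_id, species=sp.name, length_mm=float(l),
                         height_mm=float(h), width_mm=float(w))
        for l, h, w in zip(lengths, heights, widths)
    ]


def simulate_calcurve(
    span: tuple[float, float] = (6500.0, 11000.0),
    wiggle_amplitude: float = 20.0,
    sigma: float = 15.0,
    seed: int = 0,
    *,
    step: float = 5.0,
    slope: float = 0.95,
    offset: float = 400.0,
    name: str = "synthetic",
    curve_kind: str = "atmospheric",
) -> CalibrationCurve:
    """A synthetic calibration curve: linear trend plus bounded smooth wiggles.

    Wiggle amplitudes are scaled so the mean stays strictly monotone in
    calendar age; zero amplitude gives an exactly linear curve.
    """
    lo, hi = span
    cal = np.arange(lo, hi + 0.5 * step, step)
    mean = offset + slope * cal
    if wiggle_amplitude > 0:
        rng = np.random.default_rng(seed)
        periods = np.array([700.0, 260.0, 110.0])
        amps = wiggle_amplitude * np.array([0.6, 0.3, 0.1])
        # cap the wiggle derivative below the trend slope to keep monotonicity
        max_deriv = float(np.sum(2 * np.pi * amps / periods))
        if max_deriv >= slope:
            amps *= 0.9 * slope / max_deriv
        phases = rng.uniform(0, 2 * np.pi, size=len(periods))
        for a, p, ph in zip(amps, periods, phases):
            mean = mean + a * np.sin(2 * np.pi * cal / p + ph)
    return CalibrationCurve(
        name=name, cal_bp=cal, c14_age=mean,
        sigma=np.full_like(cal, float(sigma)), curve_kind=curve_kind,
    )


def simulate_dates(
    true_cal_ages: Sequence[float],
    curve: CalibrationCurve,
    sigma: float = 30.0,
    seed: int = 0,
    *,
    reservoir: ReservoirCorrection | None = None,
    unit_ids: Sequence[str] | None = None,
    material: str = "bone",
    species: str = "",
    lab_prefix: str = "SYN",
) -> list[RadiocarbonDate]:
    """Measured radiocarbon ages for known calendar ages.

    cra = curve_mean(age) + DeltaR + Gaussian(0, sqrt(sigma^2 + curve_sigma^2));
    the reservoir offset (if any) also tags the species on each date.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(list(true_cal_ages), dtype=float)
    mu = curve.mean_at(ages)
    total_sd = np.sqrt(sigma**2 + curve.sigma_at(ages) ** 2)
    delta_r = reservoir.delta_r if reservoir else 0.0
    if reservoir:
        species = reservoir.species
        material = "shell"
    noise = rng.standard_normal(len(ages)) * total_sd
    cras = mu + delta_r + noise
    out = []
    for i, (age, cra) in enumerate(zip(ages, cras)):
        out.append(
            RadiocarbonDate(
                lab_id=f"{lab_prefix}-{i:03d}",
                unit_id=str(unit_ids[i]) if unit_ids is not None else "",
                material=material,
                cra_bp=float(cra),
                sigma=float(sigma) if sigma > 0 else 1.0,
                species=species,
            )
        )
    return out


def default_climate_scenario() -> ClimateScenario:
    """Five-unit Early Holocene scenario, oldest first.

    Means and amplitudes follow the reconstructed northern Iberian regime:
    a cold, strongly seasonal base of the sequence, warming through the
    middle, a meltwater-cooled pair of units with damped summers, and a
    warm recovery at the top.  Sea-level offsets rise towards the present.
    """
    return ClimateScenario(
        units={
            "108": UnitClimate(mean_sst=16.3, amplitude=6.9, sea_level_offset_m=-14.0),
            "107": UnitClimate(mean_sst=18.0, amplitude=6.5, sea_level_offset_m=-10.0),
            "105": UnitClimate(mean_sst=16.8, amplitude=5.6, sea_level_offset_m=-8.0,
                               meltwater_flag=True),
            "112C": UnitClimate(mean_sst=16.8, amplitude=5.9, sea_level_offset_m=-7.0,
                                meltwater_flag=True),
            "101B": UnitClimate(mean_sst=18.7, amplitude=6.3, sea_level_offset_m=-5.0),
        }
    )


def default_assemblage_scenario() -> AssemblageScenario:
    """Four-taxon pool with realistic thermal contrasts and sizes."""
    species = (
        SpeciesResponse("Patella vulgata", "non_spiralled_gastropod",
                        midpoint=17.5, slope=-1.5, base_weight=1.0,
                        mean_length_mm=32.0, sd_length_mm=4.5, lh_ratio=1.9),
        SpeciesResponse("Patella depressa", "non_spiralled_gastropod",
                        midpoint=17.5, slope=0.8, base_weight=0.15,
                        mean_length_mm=28.0, sd_length_mm=4.0, lh_ratio=2.1),
        SpeciesResponse("Phorcus lineatus", "spiralled_gastropod",
                        midpoint=17.0, slope=1.5, base_weight=1.3,
                        mean_length_mm=22.0, sd_length_mm=3.0, lh_ratio=1.1),
        SpeciesResponse("Mytilus galloprovincialis", "bivalve",
                        midpoint=16.0, slope=-0.3, base_weight=0.03,
                        mean_length_mm=40.0, sd_length_mm=6.0, lh_ratio=2.0),
    )
    return AssemblageScenario(
        species=species,
        unit_total_mni={"108": 3000, "107": 3500, "105": 3200,
                        "112C": 3000, "101B": 2800},
        pressure={"108": 0.0, "107": 0.5, "105": 2.0, "112C": 2.0, "101B": 0.5},
        indeterminate_fraction=0.10,
    )
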