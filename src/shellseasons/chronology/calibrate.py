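"""Single-date radiocarbon calibration and reservoir correction.

A conventional radiocarbon age (CRA) is calibrated against a curve by
evaluating, on a calendar-age grid, the Gaussian likelihood of the measured
CRA given the curve mean and combined uncertainty
(sigma_date^2 + sigma_curve^2), under a uniform calendar prior, and
normalizing to a probability mass function.  Marine shell dates are first
adjusted by a species-specific local reservoir offset ΔR: the corrected age
is (measured - ΔR) and the ΔR uncertainty is added in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .curves import CalibrationCurve

__all__ = [
    "RadiocarbonDate",
    "ReservoirCorrection",
    "PosteriorDensity",
    "apply_delta_r",
    "calibrate",
    "hpd",
]

DEFAULT_HPD_MASS = 0.954  # two-sigma radiocarbon convention


@dataclass(frozen=True)
class RadiocarbonDate:
    """One 14C determination (conventional age BP with one-sigma error)."""

    lab_id: str
    unit_id: str
    material: str  # {"bone", "charcoal", "shell"}
    cra_bp: float
    sigma: float
    species: str = ""

    def __post_init__(self) -> None:
        if self.material not in ("bone", "charcoal", "shell"):
            raise ValueError(f"unknown material {self.material!r}")
        if self.cra_bp <= 0:
            raise ValueError("cra_bp must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ReservoirCorrection:
    """Local marine reservoir offset ΔR ± sigma for one shell species."""

    species: str
    delta_r: float
    delta_r_sigma: float

    def __post_init__(self) -> None:
        if self.delta_r_sigma < 0:
            raise ValueError("delta_r_sigma must be >= 0")


@dataclass(frozen=True)
class PosteriorDensity:
    """Calendar-age posterior on a regular grid (probability masses)."""

    cal_bp: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_bp", np.asarray(self.cal_bp, dtype=float))
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=float))
        if self.cal_bp.shape != self.pmf.shape:
            raise ValueError("grid and masses must align")
        if abs(float(self.pmf.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior masses must sum to 1")
        if np.any(self.pmf < 0):
            raise ValueError("negative probability mass")

    @property
    def mean(self) -> float:
        return float(np.sum(self.cal_bp * self.pmf))

    @property
    def median(self) -> float:
        cdf = np.cumsum(self.pmf)
        return float(np.interp(0.5, cdf, self.cal_bp))


def apply_delta_r(date: RadiocarbonDate, corr: ReservoirCorrection) -> RadiocarbonDate:
    """Reservoir-correct a marine shell date.

    Corrected age = measured - ΔR (equivalently, ΔR is added to the marine
    curve); sigmas combine in quadrature.  The species on the correction
    must match the date's.
    """
    if date.material != "shell":
        raise ValueError(f"date {date.lab_id}: ΔR applies to shell dates only")
    if date.species != corr.species:
        raise ValueError(
            f"date {date.lab_id}: species {date.species!r} does not match "
            f"correction for {corr.species!r}"
        )
    return replace(
        date,
        cra_bp=date.cra_bp - corr.delta_r,
        sigma=math.hypot(date.sigma, corr.delta_r_sigma),
    )


def calibrate(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
) -> PosteriorDensity:
    """Calibrate one date against a curve on a regular calendar grid."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    mu_range = (float(curve.c14_age.min()), float(curve.c14_age.max()))
    slack = 5.0 * (date.sigma + float(curve.sigma.max()))
    if date.cra_bp < mu_range[0] - slack or date.cra_bp > mu_range[1] + slack:
        raise ValueError(
            f"date {date.lab_id} ({date.cra_bp} BP) outside curve coverage "
            f"[{mu_range[0]}, {mu_range[1]}] 14C BP"
        )
    grid = np.arange(curve.cal_min, curve.cal_max + 0.5 * grid_step, grid_step)
    logp = _log_likelihood(date.cra_bp, date.sigma, curve, grid)
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    return PosteriorDensity(cal_bp=grid, pmf=pmf)


def _log_likelihood(cra: float, sigma: float, curve: CalibrationCurve, grid) -> np.ndarray:
    mu = curve.mean_at(grid)
    var = sigma**2 + curve.sigma_at(grid) ** 2
    return -0.5 * (cra - mu) ** 2 / var - 0.5 * np.log(var)


def hpd(post: PosteriorDensity, mass: float = DEFAULT_HPD_MASS) -> list[tuple[float, float]]:
    """Highest-posterior-density interval set at the requested mass.

    Grid points are accumulated in descending density order until the target
    mass is reached, then merged into contiguous intervals (returned as
    (younger, older) cal BP bounds, sorted ascending).
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    order = np.argsort(post.pmf)[::-1]
    cum = np.cumsum(post.pmf[order])
    k = int(np.searchsorted(cum, mass)) + 1
    chosen = np.zeros(len(post.pmf), dtype=bool)
    chosen[order[:k]] = True
    step = float(np.median(np.diff(post.cal_bp))) if len(post.cal_bp) > 1 else 1.0
    intervals: list[tuple[float, float]] = []
    start = None
    prev = None
    for x, inc in zip(post.cal_bp, chosen):
        if inc:
            if start is None:
                start = x
            prev = x
        elif start is not None:
            intervals.append((float(start) - 0.5 * step, float(prev) + 0.5 * step))
            start = None
    if start is not None:
        intervals.append((float(start) - 0.5 * step, float(prev) + 0.5 * step))
    return intervals
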