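"""Radiocarbon calibration curves in the standard 5-column format.

Curve files are comma-separated with '#' comment/header lines and columns
(cal BP, 14C age BP, 14C age error, Delta14C, Delta14C error); only the
first three columns are used.  Curves are linearly interpolated in both the
mean and the one-sigma error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationCurve", "read_calcurve", "write_calcurve"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordered (cal BP, 14C age, sigma) grid; kind is atmospheric or marine."""

    name: str
    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    curve_kind: str = "atmospheric"

    def __post_init__(self) -> None:
        for arr_name in ("cal_bp", "c14_age", "sigma"):
            object.__setattr__(self, arr_name, np.asarray(getattr(self, arr_name), dtype=float))
        if not (len(self.cal_bp) == len(self.c14_age) == len(self.sigma)):
            raise ValueError("curve columns must have equal length")
        if len(self.cal_bp) < 2:
            raise ValueError("curve needs at least two grid points")
        d = np.diff(self.cal_bp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("cal_bp grid must be strictly monotone")
        if np.any(self.sigma <= 0):
            raise ValueError("curve sigma must be positive")
        if self.curve_kind not in ("atmospheric", "marine"):
            raise ValueError(f"unknown curve_kind {self.curve_kind!r}")
        # store ascending in cal BP for interpolation
        if d[0] < 0:
            for arr_name in ("cal_bp", "c14_age", "sigma"):
                object.__setattr__(self, arr_name, getattr(self, arr_name)[::-1].copy())

    @property
    def cal_min(self) -> float:
        return float(self.cal_bp[0])

    @property
    def cal_max(self) -> float:
        return float(self.cal_bp[-1])

    def mean_at(self, cal_bp) -> np.ndarray:
        """Interpolated 14C age at calendar age(s)."""
        return np.interp(cal_bp, self.cal_bp, self.c14_age)

    def sigma_at(self, cal_bp) -> np.ndarray:
        """Interpolated curve one-sigma at calendar age(s)."""
        return np.interp(cal_bp, self.cal_bp, self.sigma)

    def covers(self, cal_bp: float) -> bool:
        return self.cal_min <= cal_bp <= self.cal_max


def read_calcurve(source, name: str = "", curve_kind: str = "atmospheric") -> CalibrationCurve:
    """Parse a 5-column curve file (path or text stream) with '#' comments."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return read_calcurve(fh, name=name or str(source), curve_kind=curve_kind)
    cal, age, sig = [], [], []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 comma-separated columns")
        try:
            cal.append(float(parts[0]))
            age.append(float(parts[1]))
            sig.append(float(parts[2]))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
    if len(cal) < 2:
        raise ValueError("curve file contains fewer than two data lines")
    return CalibrationCurve(
        name=name, cal_bp=np.array(cal), c14_age=np.array(age), sigma=np.array(sig),
        curve_kind=curve_kind,
    )


def write_calcurve(curve: CalibrationCurve, path) -> None:
    """Serialize a curve in the 5-column format (zeros in the last two columns)."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.name} ({curve.curve_kind})\n")
        fh.write("# cal BP, 14C age, error, Delta14C, error\n")
        # conventional files run from old to young
        for c, a, s in zip(curve.cal_bp[::-1], curve.c14_age[::-1], curve.sigma[::-1]):
            fh.write(f"{c:.1f},{a:.1f},{s:.1f},0.0,0.0\n")
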