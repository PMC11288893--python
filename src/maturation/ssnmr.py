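"""Kinetics from time series of 1D NMR spectra.

Cross-polarization (CP) spectra report immobilized material and grow as a
condensate rigidifies; refocused-INEPT spectra report mobile material and
decay only weakly.  Maturation rates are quantified by integrating named
spectral regions, normalizing each series to a reference time point
(typically 48 h) and fitting a straight line in units of 1/day, so that
slopes of different samples (for example suspended-droplet versus bulk
condensed preparations) can be compared as ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Spectrum1D",
    "RegionSet",
    "KineticsSeries",
    "SlopeEstimate",
    "DEFAULT_REGIONS",
    "integrate_region",
    "signal_to_noise",
    "normalize_series",
    "fit_linear_rate",
    "compare_rates",
]


@dataclass
class Spectrum1D:
    """A processed 1D spectrum: ppm axis (stored descending), intensities,
    experiment type ('CP', 'INEPT' or 'H1') and a time stamp in hours."""

    ppm: np.ndarray
    intensity: np.ndarray
    experiment: str = "CP"
    time_stamp: float = 0.0

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be monotone")
        if np.all(d > 0):  # store NMR-conventional descending axis
            self.ppm = self.ppm[::-1]
            self.intensity = self.intensity[::-1]


#: Conventional 13C/1H region windows (ppm); the exact windows used for any
#: given dataset are configurable.
DEFAULT_REGIONS = {
    "carbonyl": (165.0, 182.0),
    "aromatic": (105.0, 140.0),
    "ca": (50.0, 65.0),
    "ca_gly": (42.0, 48.0),
    "cb": (15.0, 40.0),
    "imino": (10.0, 15.0),
}


class RegionSet(dict):
    """Named (ppm_low, ppm_high) windows."""

    def __init__(self, windows=None):
        windows = dict(windows or DEFAULT_REGIONS)
        for label, (lo, hi) in windows.items():
            if not lo < hi:
                raise ValueError(f"region {label!r}: ppm_low must be < ppm_high")
        super().__init__(windows)


@dataclass
class KineticsSeries:
    label: str
    times_days: np.ndarray
    values: np.ndarray
    reference_hours: float

    def __post_init__(self):
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float  # 1/day
    intercept: float
    stderr: float
    r_squared: float


def integrate_region(spec: Spectrum1D, window) -> float:
    """Sign-preserving trapezoidal integral of the spectrum over a ppm window."""
    lo, hi = window
    asc_ppm = spec.ppm[::-1]
    asc_int = spec.intensity[::-1]
    mask = (asc_ppm >= lo) & (asc_ppm <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"window ({lo}, {hi}) ppm does not overlap the spectral axis "
            f"[{asc_ppm.min():g}, {asc_ppm.max():g}]"
        )
    return float(np.trapezoid(asc_int[mask], asc_ppm[mask]))


def signal_to_noise(
    spec: Spectrum1D,
    peak_ppm: float,
    noise_window,
    mode: str = "standard",
    peak_halfwidth: float = 0.5,
) -> float:
    """Peak signal-to-noise.

    ``standard``: peak height / (2 * noise rms), the common spectroscopy
    convention.  ``as_printed``: peak height / noise rms**2, a scale-
    dependent variant some processing software reports; provided because
    published kinetic traces may have used it.
    """
    lo, hi = noise_window
    if lo <= peak_ppm <= hi:
        raise ValueError("noise window must not contain the peak")
    near = np.abs(spec.ppm - peak_ppm) <= peak_halfwidth
    if not near.any():
        raise ValueError(f"no points within {peak_halfwidth} ppm of {peak_ppm}")
    height = float(np.max(spec.intensity[near]))
    nmask = (spec.ppm >= lo) & (spec.ppm <= hi)
    noise = spec.intensity[nmask]
    if noise.size < 2:
        raise ValueError("noise window does not overlap the spectral axis")
    rms = float(np.std(noise - noise.mean(), ddof=1))
    if rms == 0:
        raise ValueError("zero noise estimate in the given window")
    if mode == "standard":
        return height / (2 * rms)
    if mode == "as_printed":
        return height / rms**2
    raise ValueError(f"unknown mode {mode!r}")


def normalize_series(
    values,
    times_hours,
    reference_hours: float = 48.0,
    label: str = "",
    tolerance_hours: float = 1.0,
) -> KineticsSeries:
    """Divide a series by its value at the reference time point (48 h by
    default) and convert times to days."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(times_hours, dtype=float)
    near = np.abs(t - reference_hours) <= tolerance_hours
    if not near.any():
        raise ValueError(
            f"no measurement within {tolerance_hours} h of the reference time "
            f"{reference_hours} h; available times (h): {t.tolist()}"
        )
    ref = values[near][np.argmin(np.abs(t[near] - reference_hours))]
    if ref == 0:
        raise ValueError("reference value is zero; cannot normalize")
    return KineticsSeries(
        label=label,
        times_days=t / 24.0,
        values=values / ref,
        reference_hours=reference_hours,
    )


def fit_linear_rate(series: KineticsSeries) -> SlopeEstimate:
    """Ordinary least squares of normalized value versus time in days."""
    t = series.times_days
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical; slope undefined")
    res = stats.linregress(t, series.values)
    return SlopeEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )


def compare_rates(slopes_a: dict, slopes_b: dict) -> pd.DataFrame:
    """Per-label slope ratios a/b with first-order error propagation.

    ``slopes_a`` and ``slopes_b`` map labels to SlopeEstimate.  Labels with a
    zero denominator slope are flagged and their ratio left as NaN.
    """
    rows = []
    for label in slopes_a:
        if label not in slopes_b:
            continue
        a, b = slopes_a[label], slopes_b[label]
        if b.slope == 0:
            rows.append(
                {"label": label, "ratio": np.nan, "ratio_stderr": np.nan,
                 "flag": "zero denominator"}
            )
            continue
        ratio = a.slope / b.slope
        rel_a2 = (a.stderr / a.slope) ** 2 if a.slope else 0.0
        rel = np.sqrt(rel_a2 + (b.stderr / b.slope) ** 2)
        rows.append(
            {"label": label, "ratio": ratio, "ratio_stderr": abs(ratio) * rel,
             "flag": ""}
        )
    return pd.DataFrame(rows, columns=["label", "ratio", "ratio_stderr", "flag"])
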