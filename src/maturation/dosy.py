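"""Condensed/dilute protein fractions from DOSY gradient-decay data.

Protein inside condensates diffuses at least two orders of magnitude more
slowly than free protein, so a pulsed-field-gradient decay separates the two
pools: at (near-)zero gradient both contribute, at the strongest gradient
only the slow condensed pool survives.  Two estimators are provided — the
endpoint intensity ratio and a constrained two-component Stejskal–Tanner
fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DosyAcquisition",
    "DecayCurve",
    "PhaseFractions",
    "DiffusionFit",
    "stejskal_tanner",
    "endpoint_fractions",
    "fit_two_populations",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_1H = 2.675221e8


@dataclass(frozen=True)
class DosyAcquisition:
    """Pulsed-field-gradient acquisition constants.

    Defaults follow a standard stimulated-echo setup: diffusion time
    ``big_delta`` 0.05 s, gradient pulse ``small_delta`` 10 ms, gradients
    sampled between 2% and 95% of the maximum amplitude ``gmax``.
    """

    big_delta: float = 0.05
    small_delta: float = 0.01
    gamma: float = GAMMA_1H
    gmax: float = 0.5
    gradient_fractions: tuple = ()

    def __post_init__(self):
        if self.small_delta >= self.big_delta:
            raise ValueError("small_delta must be smaller than big_delta")
        gf = np.asarray(self.gradient_fractions, dtype=float)
        if gf.size and (np.any(np.diff(gf) <= 0) or gf.min() < 0 or gf.max() > 1):
            raise ValueError("gradient_fractions must be strictly increasing in [0, 1]")

    @property
    def gradients(self) -> np.ndarray:
        """Absolute gradient strengths in T/m."""
        return np.asarray(self.gradient_fractions, dtype=float) * self.gmax

    def b_per_g2(self) -> float:
        """Diffusion weighting per g^2: gamma^2 delta^2 (Delta - delta/3)."""
        return (
            self.gamma**2
            * self.small_delta**2
            * (self.big_delta - self.small_delta / 3.0)
        )


@dataclass
class DecayCurve:
    """Signal intensity versus absolute gradient strength (T/m)."""

    gradients: np.ndarray
    intensities: np.ndarray
    time_stamp: float = 0.0

    def __post_init__(self):
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.gradients.shape != self.intensities.shape:
            raise ValueError("gradients and intensities must have equal length")


@dataclass(frozen=True)
class PhaseFractions:
    condensed: float
    dilute: float
    method: str

    def __post_init__(self):
        if abs(self.condensed + self.dilute - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class DiffusionFit:
    """Two-component fit result; component 1 is the fast (dilute) pool."""

    A1: float
    A2: float
    D1: float
    D2: float
    residual_norm: float


def stejskal_tanner(g, A: float, D: float, acq: DosyAcquisition):
    """Stejskal–Tanner attenuation A exp(-D gamma^2 g^2 delta^2 (Delta - delta/3))."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient strength must be non-negative")
    return A * np.exp(-D * acq.b_per_g2() * g**2)


def endpoint_fractions(curve: DecayCurve) -> PhaseFractions:
    """Condensed fraction as I(g_max) / I(g_min).

    At the weakest gradient the total protein pool is visible; at the
    strongest gradient only the condensed (slow) pool survives, provided the
    fast pool is fully attenuated and the slow pool is not.
    """
    i_min = float(curve.intensities[np.argmin(curve.gradients)])
    i_max = float(curve.intensities[np.argmax(curve.gradients)])
    if i_min <= 0:
        raise ValueError("reference intensity at minimum gradient is not positive")
    condensed = min(max(i_max / i_min, 0.0), 1.0)
    return PhaseFractions(condensed=condensed, dilute=1 - condensed, method="endpoint")


def _log_linear_D(g2, intens, acq):
    """Slope of ln(I) vs b g^2 -> apparent D (clipped to be non-negative)."""
    keep = intens > 0
    if keep.sum() < 2:
        return 1e-12
    slope = np.polyfit(acq.b_per_g2() * g2[keep], np.log(intens[keep]), 1)[0]
    return max(-slope, 1e-16)


def fit_two_populations(
    curve: DecayCurve, acq: DosyAcquisition, ratio_floor: float = 100.0
) -> tuple[DiffusionFit, PhaseFractions]:
    """Constrained two-component Stejskal–Tanner least squares.

    Model: I(g) = A1 exp(-D1 b g^2) + A2 exp(-D2 b g^2) with D1/D2 >=
    ``ratio_floor`` (fast dilute pool vs slow condensed pool) and
    non-negative amplitudes.  Initial diffusivities come from log-linear
    fits of the head (fast) and tail (slow) of the decay.
    """
    g = curve.gradients
    y = curve.intensities
    if g.size < 6:
        raise ValueError("need at least 6 gradient points for a two-component fit")
    g2 = g**2
    n = g.size
    # head: first third dominated by the fast component on top of the slow
    d_fast0 = _log_linear_D(g2[: max(3, n // 3)], y[: max(3, n // 3)], acq)
    d_slow0 = _log_linear_D(g2[-max(3, n // 3):], y[-max(3, n // 3):], acq)
    d_fast0 = max(d_fast0, ratio_floor * d_slow0 * 1.5, 1e-16)

    i0 = max(float(y.max()), 1e-12)
    tail = max(float(y[-1]), 0.0)
    b = acq.b_per_g2()
    # parameters: A1, A2, D1 and the ratio D1/D2 (floored at ratio_floor)
    x0 = np.array(
        [
            max(i0 - tail, 0.05 * i0),
            max(tail, 0.05 * i0),
            d_fast0,
            max(d_fast0 / d_slow0, ratio_floor * 1.01),
        ]
    )

    def resid(p):
        a1, a2, d1, ratio = p
        return a1 * np.exp(-d1 * b * g2) + a2 * np.exp(-d1 / ratio * b * g2) - y

    def jac(p):
        a1, a2, d1, ratio = p
        e1 = np.exp(-d1 * b * g2)
        e2 = np.exp(-d1 / ratio * b * g2)
        return np.column_stack(
            [
                e1,
                e2,
                -a1 * b * g2 * e1 - a2 * b * g2 / ratio * e2,
                a2 * d1 * b * g2 / ratio**2 * e2,
            ]
        )

    x_scale = np.array([i0, i0, d_fast0, ratio_floor])
    out = least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([0, 0, 1e-16, ratio_floor], np.inf),
        x_scale=x_scale,
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    if not out.success:
        raise RuntimeError(
            f"two-population fit did not converge: {out.message}; "
            f"residual norm {np.linalg.norm(out.fun):.3e}"
        )
    a1, a2, d1, ratio = out.x
    if a1 < 0 or a2 < 0:
        raise RuntimeError("two-population fit produced negative amplitudes")
    fit = DiffusionFit(
        A1=float(a1),
        A2=float(a2),
        D1=float(d1),
        D2=float(d1 / ratio),
        residual_norm=float(np.linalg.norm(out.fun)),
    )
    total = a1 + a2
    if total <= 0:
        raise RuntimeError("two-population fit degenerate: zero total amplitude")
    condensed = a2 / total
    fractions = PhaseFractions(
        condensed=condensed, dilute=1 - condensed, method="biexponential"
    )
    return fit, fractions
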