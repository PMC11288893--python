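"""Seeded synthetic-data generators for every input class of the pipeline.

Each generator emulates the statistical structure of one experiment — CP/
INEPT time series, DOSY gradient decays, core-shell CARS cubes, chemical-
shift observations — and returns the generating parameters as ground truth
so parameter-recovery tests can compute expected estimator outputs without
re-running the generator.  All randomness flows from a single seeded
generator per dataset; identical (seed, config) gives identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dosy import DecayCurve, DosyAcquisition, stejskal_tanner
from .raman import HyperspectralCube
from .shifts import ShiftObservation, load_shift_statistics
from .ssnmr import DEFAULT_REGIONS, Spectrum1D

__all__ = [
    "NmrTimeseriesConfig",
    "DosyConfig",
    "CarsConfig",
    "ShiftSampleConfig",
    "make_nmr_timeseries",
    "make_dosy_decays",
    "make_cars_cube",
    "make_shift_observations",
    "make_model_scenarios",
]


def _lorentzian(x, x0, gamma):
    return gamma**2 / ((x - x0) ** 2 + gamma**2)


# ---------------------------------------------------------------- CP/INEPT

@dataclass
class NmrTimeseriesConfig:
    """CP spectra grow linearly (default slope 0.25/day from an intercept of
    half the 48-h level — immobilized material is already present hours
    after droplet formation); INEPT spectra decay slowly (default
    -0.06/day).  Noise: additive Gaussian plus 10% multiplicative slot-to-
    slot scatter, mirroring the intensity uncertainty between measurement
    slots."""

    seed: int = 0
    times_hours: tuple = (4.0, 12.0, 24.0, 36.0, 48.0)
    cp_slope_per_day: float = 0.25
    cp_intercept: float = 0.5
    inept_slope_per_day: float = -0.06
    inept_intercept: float = 1.0
    noise_sigma: float = 0.0  # additive, in units of single-peak height
    slot_noise: float = 0.0  # multiplicative s.d., e.g. 0.10
    ppm_range: tuple = (0.0, 200.0)
    n_points: int = 4096
    linewidth_ppm: float = 0.6
    regions: dict = field(default_factory=lambda: {
        "carbonyl": (165.0, 182.0),
        "aromatic": (105.0, 140.0),
        "ca": (50.0, 65.0),
        "ca_gly": (42.0, 48.0),
        "cb": (15.0, 40.0),
    })


def make_nmr_timeseries(config: NmrTimeseriesConfig):
    """Synthetic CP and INEPT spectrum series with ground truth.

    Returns ``(spectra, ground_truth)`` where ``spectra`` is a list of
    :class:`~maturation.ssnmr.Spectrum1D` (CP and INEPT at every time
    point) and the ground truth carries the linear amplitude laws.
    """
    if len(config.times_hours) < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(config.seed)
    ppm = np.linspace(config.ppm_range[1], config.ppm_range[0], config.n_points)
    # fixed multiplet positions per region (same across times and experiments)
    pos_rng = np.random.default_rng(config.seed + 1)
    peaks = {
        label: np.sort(pos_rng.uniform(lo + 1, hi - 1, size=3))
        for label, (lo, hi) in config.regions.items()
    }
    spectra = []
    for t_h in config.times_hours:
        t_d = t_h / 24.0
        for exp, slope, intercept in (
            ("CP", config.cp_slope_per_day, config.cp_intercept),
            ("INEPT", config.inept_slope_per_day, config.inept_intercept),
        ):
            amp = intercept + slope * t_d
            if config.slot_noise:
                amp *= 1 + rng.normal(scale=config.slot_noise)
            y = np.zeros_like(ppm)
            for centers in peaks.values():
                for c in centers:
                    y += amp * _lorentzian(ppm, c, config.linewidth_ppm)
            if config.noise_sigma:
                y += rng.normal(scale=config.noise_sigma, size=y.shape)
            spectra.append(Spectrum1D(ppm=ppm, intensity=y, experiment=exp,
                                      time_stamp=t_h))
    truth = {
        "cp_slope_per_day": config.cp_slope_per_day,
        "cp_intercept": config.cp_intercept,
        "inept_slope_per_day": config.inept_slope_per_day,
        "inept_intercept": config.inept_intercept,
        "peak_positions": {k: v.tolist() for k, v in peaks.items()},
        "linewidth_ppm": config.linewidth_ppm,
        "noise_sigma": config.noise_sigma,
        "slot_noise": config.slot_noise,
        "seed": config.seed,
    }
    return spectra, truth


# -------------------------------------------------------------------- DOSY

@dataclass
class DosyConfig:
    """Two-pool Stejskal–Tanner decays.

    The condensed pool diffuses at least 100x more slowly than the dilute
    pool (default ratio 200); gradients span 2-95% of the maximum.  Noise is
    Gaussian with s.d. I(g_min)/snr."""

    seed: int = 0
    condensed_fraction: float = 0.6
    d_fast: float = 1.0e-10  # m^2/s, dilute pool
    ratio: float = 200.0
    snr: float = 100.0
    n_gradients: int = 16
    gmin_fraction: float = 0.02
    gmax_fraction: float = 0.95
    acquisition: DosyAcquisition = field(default_factory=DosyAcquisition)
    n_curves: int = 1

    def __post_init__(self):
        if self.ratio < 100:
            raise ValueError("diffusivity ratio below the 100x floor")


def make_dosy_decays(config: DosyConfig):
    """Synthetic two-component decay curves with ground truth."""
    rng = np.random.default_rng(config.seed)
    fractions = np.linspace(config.gmin_fraction, config.gmax_fraction,
                            config.n_gradients)
    acq = DosyAcquisition(
        big_delta=config.acquisition.big_delta,
        small_delta=config.acquisition.small_delta,
        gamma=config.acquisition.gamma,
        gmax=config.acquisition.gmax,
        gradient_fractions=tuple(fractions),
    )
    g = acq.gradients
    d_slow = config.d_fast / config.ratio
    a_slow = config.condensed_fraction
    a_fast = 1.0 - a_slow
    clean = stejskal_tanner(g, a_fast, config.d_fast, acq) + stejskal_tanner(
        g, a_slow, d_slow, acq
    )
    sigma = clean[0] / config.snr if config.snr else 0.0
    curves = []
    for i in range(config.n_curves):
        y = clean + rng.normal(scale=sigma, size=g.shape) if sigma else clean.copy()
        curves.append(DecayCurve(gradients=g, intensities=y, time_stamp=float(i)))
    truth = {
        "condensed_fraction": a_slow,
        "dilute_fraction": a_fast,
        "d_fast": config.d_fast,
        "d_slow": d_slow,
        "noise_sigma": sigma,
        "seed": config.seed,
    }
    return curves, acq, truth


# -------------------------------------------------------------------- CARS

@dataclass
class CarsConfig:
    """Core-shell droplet on a nonresonant (agarose-like) background.

    Per-pixel raw CARS = |chi_NR + sum of complex Lorentzians|^2; the
    reference is |chi_NR|^2.  Core lines: broad amide I (1655) and tyrosine
    (1618).  Shell (outer ``shell_fraction`` of the radius) adds a narrow
    1665 line and a stronger 1618 line, the matured-surface signature."""

    seed: int = 0
    nx: int = 48
    ny: int = 48
    radius_px: float = 16.0
    shell_fraction: float = 0.15
    wavenumber: tuple = (900.0, 1800.0)
    n_wavenumbers: int = 301
    chi_nr: float = 1.0
    # (center cm^-1, half-width cm^-1, amplitude)
    core_lines: tuple = ((1655.0, 25.0, 0.12), (1618.0, 10.0, 0.04))
    shell_lines: tuple = ((1665.0, 8.0, 0.10), (1618.0, 10.0, 0.04))
    counts: float = 0.0  # photon scale for Poisson noise; 0 = off
    gaussian_sigma: float = 0.0  # additive, relative to reference level

    def __post_init__(self):
        if not 0 < self.shell_fraction < 0.5:
            raise ValueError("shell_fraction must be in (0, 0.5)")


def _chi_resonant(w, lines):
    chi = np.zeros_like(w, dtype=complex)
    for w0, gamma, amp in lines:
        chi += amp * gamma / (w0 - w - 1j * gamma)
    return chi


def make_cars_cube(config: CarsConfig):
    """Synthetic hyperspectral CARS cube with ground-truth masks and lines."""
    rng = np.random.default_rng(config.seed)
    w = np.linspace(*config.wavenumber, config.n_wavenumbers)
    yy, xx = np.mgrid[0 : config.ny, 0 : config.nx]
    cy, cx = (config.ny - 1) / 2.0, (config.nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    droplet = r <= config.radius_px
    shell = droplet & (r >= config.radius_px * (1 - config.shell_fraction))
    core = droplet & ~shell

    chi_core = config.chi_nr + _chi_resonant(w, config.core_lines)
    shell_all = tuple(config.core_lines) + tuple(config.shell_lines)
    chi_shell = config.chi_nr + _chi_resonant(w, shell_all)
    spec_bg = np.full(w.shape, config.chi_nr**2)
    spec_core = np.abs(chi_core) ** 2
    spec_shell = np.abs(chi_shell) ** 2

    cube = np.empty((config.ny, config.nx, w.size))
    cube[...] = spec_bg
    cube[core] = spec_core
    cube[shell] = spec_shell
    if config.counts:
        cube = rng.poisson(cube * config.counts) / config.counts
    if config.gaussian_sigma:
        cube = cube + rng.normal(scale=config.gaussian_sigma * config.chi_nr**2,
                                 size=cube.shape)
    hc = HyperspectralCube(wavenumber=w, intensity=cube,
                           nr_reference=spec_bg.copy())
    truth = {
        "droplet_mask": droplet,
        "shell_mask": shell,
        "core_mask": core,
        "core_lines": config.core_lines,
        "shell_lines": config.shell_lines,
        "shell_fraction": config.shell_fraction,
        "radius_px": config.radius_px,
        "seed": config.seed,
    }
    return hc, truth


# ------------------------------------------------------------------ shifts

@dataclass
class ShiftSampleConfig:
    seed: int = 0
    n_per_class: int = 500
    residue_type: str = "THR"
    classes: tuple = ("helix", "sheet", "coil")
    sd_scale: float = 1.0  # 0 collapses samples onto the class means


def make_shift_observations(config: ShiftSampleConfig, stats=None):
    """Gaussian Ca/Cb samples per secondary-structure class."""
    if stats is None:
        stats = load_shift_statistics()
    rng = np.random.default_rng(config.seed)
    res = config.residue_type.upper()
    obs, labels = [], []
    for c in config.classes:
        st = stats[res][c]
        ca = rng.normal(st.mean_ca, st.sd_ca * config.sd_scale,
                        size=config.n_per_class) if st.mean_ca is not None else None
        cb = rng.normal(st.mean_cb, st.sd_cb * config.sd_scale,
                        size=config.n_per_class) if st.mean_cb is not None else None
        for i in range(config.n_per_class):
            obs.append(
                ShiftObservation(
                    residue_type=res,
                    ca=None if ca is None else float(ca[i]),
                    cb=None if cb is None else float(cb[i]),
                )
            )
            labels.append(c)
    truth = {"labels": labels, "residue_type": res, "seed": config.seed,
             "sd_scale": config.sd_scale}
    return obs, truth


# --------------------------------------------------------------- scenarios

def make_model_scenarios() -> dict:
    """Bundled maturation-model parameter presets.

    ``regimeA``: monomer-solvent repulsion dominates (chi1s=3 > chi2s=2.1,
    k1=0.2/d, k2=0.1/d, phi_tot=0.55) — solvent flows into the droplet as
    aggregates accumulate.  ``regimeB``: aggregate-solvent repulsion
    dominates (chi1s=2.1 < chi2s=3, k1=0.1/d, k2=0.05/d) — solvent is
    expelled.  ``regimeA_high_concentration`` repeats regime A at
    phi_tot=0.8.
    """
    scenarios = {}
    for name in ("regimeA", "regimeB"):
        with resources.files("maturation.data").joinpath(f"{name}.json").open() as fh:
            scenarios[name] = json.load(fh)
    high = dict(scenarios["regimeA"])
    high["phi_tot"] = 0.8
    scenarios["regimeA_high_concentration"] = high
    return scenarios
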