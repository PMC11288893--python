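"""File-format adapters: JSON parameter files, CSV curves/spectra/tables,
HDF5 hyperspectral cubes.  Thin wrappers around pandas/h5py so the analysis
modules stay format-agnostic."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dosy import DecayCurve, DosyAcquisition
from .raman import HyperspectralCube
from .ssnmr import Spectrum1D
from .thermo import InteractionParams, KineticParams, MaturationTrajectory

__all__ = [
    "load_model_params",
    "trajectory_frame",
    "read_decay_curve",
    "read_acquisition",
    "read_spectrum",
    "read_manifest",
    "read_regions",
    "read_cube",
    "write_cube",
]


def load_model_params(path) -> tuple[InteractionParams, KineticParams, np.ndarray]:
    """Read a maturation-model JSON parameter file.

    Keys: chi12, chi1s, chi2s, v1, v2, vs, k1_per_day, k2_per_day, phi_tot,
    t_max_days, n_times.
    """
    cfg = json.loads(Path(path).read_text())
    interaction = InteractionParams(
        chi12=cfg.get("chi12", 0.0),
        chi1s=cfg["chi1s"],
        chi2s=cfg["chi2s"],
        v1=cfg.get("v1", 1.0),
        v2=cfg.get("v2", 1.0),
        vs=cfg.get("vs", 1.0),
    )
    kinetic = KineticParams(
        k1=cfg["k1_per_day"], k2=cfg["k2_per_day"], phi_tot=cfg["phi_tot"]
    )
    times = np.linspace(0.0, cfg.get("t_max_days", 20.0), cfg.get("n_times", 81))
    return interaction, kinetic, times


def trajectory_frame(traj: MaturationTrajectory) -> pd.DataFrame:
    rows = []
    for t, a1, a2, eq in zip(traj.times, traj.avg_phi1, traj.avg_phi2,
                             traj.equilibria):
        rows.append(
            {
                "time_days": t,
                "avg_phi1": a1,
                "avg_phi2": a2,
                "phi1_I": eq.dense.phi1,
                "phi2_I": eq.dense.phi2,
                "phis_I": eq.dense.phis,
                "phi1_II": eq.dilute.phi1,
                "phi2_II": eq.dilute.phi2,
                "phis_II": eq.dilute.phis,
                "nu": eq.nu,
                "single_phase": eq.single_phase,
            }
        )
    return pd.DataFrame(rows)


def read_decay_curve(path, acq: DosyAcquisition, time_stamp: float = 0.0) -> DecayCurve:
    """CSV with columns gradient_fraction, intensity (fractions of gmax)."""
    df = pd.read_csv(path)
    return DecayCurve(
        gradients=df["gradient_fraction"].to_numpy() * acq.gmax,
        intensities=df["intensity"].to_numpy(),
        time_stamp=time_stamp,
    )


def read_acquisition(path) -> DosyAcquisition:
    cfg = json.loads(Path(path).read_text())
    return DosyAcquisition(
        big_delta=cfg.get("big_delta_s", 0.05),
        small_delta=cfg.get("small_delta_s", 0.01),
        gamma=cfg.get("gamma", DosyAcquisition.gamma),
        gmax=cfg.get("gmax_T_per_m", 0.5),
        gradient_fractions=tuple(cfg.get("gradient_fractions", ())),
    )


def read_spectrum(path, experiment="CP", time_stamp=0.0) -> Spectrum1D:
    """Two-column CSV (ppm, intensity)."""
    df = pd.read_csv(path)
    return Spectrum1D(
        ppm=df["ppm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        experiment=experiment,
        time_stamp=time_stamp,
    )


def read_manifest(path) -> list[dict]:
    """JSON manifest: list of {file, experiment, time_stamp_hours, sample}."""
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError("manifest must be a JSON list of spectrum entries")
    return entries


def read_regions(path) -> dict:
    """JSON mapping label -> [ppm_low, ppm_high]."""
    raw = json.loads(Path(path).read_text())
    return {label: tuple(window) for label, window in raw.items()}


def read_cube(path) -> HyperspectralCube:
    """HDF5 cube: datasets /wavenumber, /intensity (y,x,w), /nr_reference;
    attribute pixel_size_um."""
    with h5py.File(path, "r") as h5:
        return HyperspectralCube(
            wavenumber=h5["wavenumber"][:],
            intensity=h5["intensity"][:],
            nr_reference=h5["nr_reference"][:],
            pixel_size_um=float(h5.attrs.get("pixel_size_um", 1.0)),
        )


def write_cube(path, cube: HyperspectralCube) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("wavenumber", data=cube.wavenumber)
        h5.create_dataset("intensity", data=cube.intensity)
        h5.create_dataset("nr_reference", data=cube.nr_reference)
        h5.attrs["pixel_size_um"] = cube.pixel_size_um
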