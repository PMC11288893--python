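"""Secondary-structure classification of Ca/Cb chemical shifts and 2D
peak-list back-prediction from assignment tables.

13C Ca and Cb shifts report backbone secondary structure: relative to coil,
helices shift Ca up and Cb down, beta-sheets the opposite.  Observations are
scored against per-residue-type, per-class Gaussian statistics (bundled as
an editable CSV drawn from the published chemical-shift surveys), giving a
posterior over {helix, sheet, coil}.  Assignment tables can be expanded into
the peak lists expected in DARR, NCA and NCO correlation spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SS_CLASSES",
    "ShiftStatistics",
    "ShiftObservation",
    "ClassPosterior",
    "load_shift_statistics",
    "class_posterior",
    "classify_cb_band",
    "predict_correlation_peaks",
]

log = logging.getLogger(__name__)

SS_CLASSES = ("helix", "sheet", "coil")


@dataclass(frozen=True)
class ShiftStatistics:
    residue_type: str
    ss_class: str
    mean_ca: float | None
    sd_ca: float | None
    mean_cb: float | None
    sd_cb: float | None

    def __post_init__(self):
        for sd in (self.sd_ca, self.sd_cb):
            if sd is not None and sd <= 0:
                raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class ShiftObservation:
    residue_type: str
    ca: float | None = None
    cb: float | None = None

    def __post_init__(self):
        if self.ca is None and self.cb is None:
            raise ValueError("at least one of ca, cb must be observed")


@dataclass(frozen=True)
class ClassPosterior:
    probabilities: dict

    def __post_init__(self):
        p = np.array(list(self.probabilities.values()))
        if np.any(p < 0) or abs(p.sum() - 1) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def load_shift_statistics(path=None) -> dict:
    """Load per-(residue, class) Gaussian statistics from CSV.

    Returns ``{residue_type: {ss_class: ShiftStatistics}}``.  With no path,
    the bundled table is used.
    """
    if path is None:
        with resources.files("maturation.data").joinpath("shift_stats.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        res = str(row["residue_type"]).upper()
        stats = ShiftStatistics(
            residue_type=res,
            ss_class=str(row["ss_class"]),
            mean_ca=None if pd.isna(row["mean_ca"]) else float(row["mean_ca"]),
            sd_ca=None if pd.isna(row["sd_ca"]) else float(row["sd_ca"]),
            mean_cb=None if pd.isna(row["mean_cb"]) else float(row["mean_cb"]),
            sd_cb=None if pd.isna(row["sd_cb"]) else float(row["sd_cb"]),
        )
        out.setdefault(res, {})[stats.ss_class] = stats
    return out


def _log_gauss(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd)


def class_posterior(
    obs: ShiftObservation, stats: dict, priors: dict | None = None
) -> ClassPosterior:
    """Posterior over secondary-structure classes for one observation.

    Independent Gaussians per dimension: posterior ~ prior * N(ca) * N(cb),
    with the factor for an unobserved dimension omitted.  ``stats`` is the
    mapping returned by :func:`load_shift_statistics`.
    """
    res = obs.residue_type.upper()
    if res not in stats:
        raise KeyError(f"no chemical-shift statistics for residue type {res!r}")
    by_class = stats[res]
    classes = [c for c in SS_CLASSES if c in by_class]
    if priors is None:
        priors = {c: 1.0 / len(classes) for c in classes}
    logp = {}
    for c in classes:
        st = by_class[c]
        lp = np.log(priors.get(c, 0.0)) if priors.get(c, 0.0) > 0 else -np.inf
        if obs.ca is not None:
            if st.mean_ca is None:
                raise ValueError(f"{res} {c}: no Ca statistics but Ca observed")
            lp += _log_gauss(obs.ca, st.mean_ca, st.sd_ca)
        if obs.cb is not None:
            if st.mean_cb is None:
                raise ValueError(f"{res} {c}: no Cb statistics but Cb observed")
            lp += _log_gauss(obs.cb, st.mean_cb, st.sd_cb)
        logp[c] = lp
    m = max(logp.values())
    w = {c: np.exp(lp - m) for c, lp in logp.items()}
    z = sum(w.values())
    probs = {c: w[c] / z for c in classes}
    # renormalisation guard against accumulated rounding
    s = sum(probs.values())
    probs = {c: p / s for c, p in probs.items()}
    return ClassPosterior(probabilities=probs)


def classify_cb_band(cb: float, residue_type: str, stats: dict):
    """Nearest class by Cb z-score, |cb - mean_cb| / sd_cb.

    Returns ``(ss_class, z_scores, tied)``; ties are broken in the order
    helix < sheet < coil and flagged.
    """
    res = residue_type.upper()
    if res not in stats:
        raise KeyError(f"no chemical-shift statistics for residue type {res!r}")
    z = {}
    for c in SS_CLASSES:
        st = stats[res].get(c)
        if st is None or st.mean_cb is None:
            continue
        z[c] = abs(cb - st.mean_cb) / st.sd_cb
    if not z:
        raise ValueError(f"no Cb statistics available for {res}")
    zmin = min(z.values())
    winners = [c for c in SS_CLASSES if c in z and z[c] == zmin]
    return winners[0], z, len(winners) > 1


_CARBON_SIDE = ("CA", "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2", "CE",
                "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2")


def predict_correlation_peaks(
    table: pd.DataFrame, experiment: str, mixing_ms: float | None = None
) -> pd.DataFrame:
    """Back-predict a 2D peak list from an assignment table.

    ``table`` columns: residue_index, residue_type, atom_name, shift.
    Experiments: ``NCA`` gives N(i)-CA(i); ``NCO`` gives N(i)-C'(i-1);
    ``DARR`` gives all intra-residue carbon-carbon pairs at both symmetric
    positions, plus sequential CA-CA and CA-C' pairs when ``mixing_ms``
    exceeds 50 ms (long-mixing regime).  Residues with missing required
    atoms are skipped; the skipped count is logged.

    Returns a DataFrame (dim1_ppm, dim2_ppm, label) sorted deterministically.
    """
    experiment = experiment.upper()
    if experiment not in ("DARR", "NCA", "NCO"):
        raise ValueError(f"unknown experiment {experiment!r}")
    t = table.copy()
    t["atom_name"] = t["atom_name"].str.upper()
    if t.duplicated(["residue_index", "atom_name"]).any():
        raise ValueError("duplicate (residue_index, atom_name) rows")
    shifts = {
        (int(r.residue_index), r.atom_name): float(r.shift)
        for r in t.itertuples()
    }
    residues = sorted({int(r.residue_index) for r in t.itertuples()})
    restype = {int(r.residue_index): r.residue_type for r in t.itertuples()}

    peaks = []
    skipped = 0

    def lab(i):
        return f"{restype[i]}{i}"

    if experiment == "NCA":
        for i in residues:
            n, ca = shifts.get((i, "N")), shifts.get((i, "CA"))
            if n is None or ca is None:
                skipped += 1
                continue
            peaks.append((n, ca, f"{lab(i)}N-CA"))
    elif experiment == "NCO":
        for i in residues:
            n, co = shifts.get((i, "N")), shifts.get((i - 1, "C"))
            if i - 1 not in restype:
                continue
            if n is None or co is None:
                skipped += 1
                continue
            peaks.append((n, co, f"{lab(i)}N-{lab(i-1)}C"))
    else:  # DARR
        long_mixing = mixing_ms is not None and mixing_ms > 50
        for i in residues:
            carbons = [
                (a, shifts[(i, a)]) for a in _CARBON_SIDE if (i, a) in shifts
            ]
            for k in range(len(carbons)):
                for m in range(k + 1, len(carbons)):
                    (a1, s1), (a2, s2) = carbons[k], carbons[m]
                    peaks.append((s1, s2, f"{lab(i)}{a1}-{a2}"))
                    peaks.append((s2, s1, f"{lab(i)}{a2}-{a1}"))
        if long_mixing:
            for i in residues:
                if i + 1 not in restype:
                    continue
                ca_i, ca_j = shifts.get((i, "CA")), shifts.get((i + 1, "CA"))
                if ca_i is not None and ca_j is not None:
                    peaks.append((ca_i, ca_j, f"{lab(i)}CA-{lab(i+1)}CA"))
                    peaks.append((ca_j, ca_i, f"{lab(i+1)}CA-{lab(i)}CA"))
                co_i = shifts.get((i, "C"))
                if ca_j is not None and co_i is not None:
                    peaks.append((co_i, ca_j, f"{lab(i)}C-{lab(i+1)}CA"))
                    peaks.append((ca_j, co_i, f"{lab(i+1)}CA-{lab(i)}C"))
    if skipped:
        log.info("%s back-prediction skipped %d residues with missing atoms",
                 experiment, skipped)
    df = pd.DataFrame(peaks, columns=["dim1_ppm", "dim2_ppm", "label"])
    return df.sort_values(["label", "dim1_ppm", "dim2_ppm"]).reset_index(drop=True)
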