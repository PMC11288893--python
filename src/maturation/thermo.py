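"""Ternary Flory–Huggins thermodynamics and aggregation kinetics.

The model describes an incompressible ternary mixture of protein monomers
(component 1), protein aggregates (component 2) and solvent (s) with volume
fractions ``phi1 + phi2 + phis = 1``.  Monomers interconvert with aggregates
through a first-order reversible reaction while the mixture stays at phase
equilibrium, which is assumed to be established instantaneously on the
time scale of aggregation.  Energies are in units of kB*T, molecular volumes
in units of a reference volume, and time in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

__all__ = [
    "InteractionParams",
    "Composition",
    "ThermoState",
    "PhaseEquilibrium",
    "KineticParams",
    "MaturationTrajectory",
    "BoundaryCompositionError",
    "CoexistenceError",
    "free_energy_density",
    "thermo_state",
    "solve_coexistence",
    "solve_binary_binodal",
    "brute_force_equilibrium",
    "aggregation_trajectory",
    "simulate_maturation",
]

_PHI_MIN = 1e-12


class BoundaryCompositionError(ValueError):
    """A composition sits on the simplex boundary where chemical potentials
    diverge; clamp the offending volume fraction before calling."""


class CoexistenceError(RuntimeError):
    """The coexistence solver failed to converge; carries final residuals."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class InteractionParams:
    """Flory interaction parameters and molecular volumes."""

    chi12: float = 0.0
    chi1s: float = 0.0
    chi2s: float = 0.0
    v1: float = 1.0
    v2: float = 1.0
    vs: float = 1.0

    def __post_init__(self):
        if min(self.v1, self.v2, self.vs) <= 0:
            raise ValueError("molecular volumes must be positive")
        for chi in (self.chi12, self.chi1s, self.chi2s):
            if not np.isfinite(chi):
                raise ValueError("interaction parameters must be finite")


@dataclass(frozen=True)
class Composition:
    """A point on the ternary composition simplex."""

    phi1: float
    phi2: float
    phis: float

    def __post_init__(self):
        for phi in (self.phi1, self.phi2, self.phis):
            if phi < -1e-12 or phi > 1 + 1e-12:
                raise ValueError(f"volume fraction {phi} outside [0, 1]")
        if abs(self.phi1 + self.phi2 + self.phis - 1.0) > 1e-12:
            raise ValueError("volume fractions must sum to 1")

    @classmethod
    def from_protein(cls, phi1: float, phi2: float) -> "Composition":
        return cls(phi1, phi2, 1.0 - phi1 - phi2)

    def as_array(self) -> np.ndarray:
        return np.array([self.phi1, self.phi2, self.phis])


@dataclass(frozen=True)
class ThermoState:
    """Free energy, chemical potentials and osmotic pressure at a point."""

    f: float
    mu1: float
    mu2: float
    Pi: float


@dataclass(frozen=True)
class PhaseEquilibrium:
    """Coexisting dense (I) / dilute (II) phases with dense volume fraction nu.

    For a single-phase state ``dense == dilute`` equals the average
    composition and ``nu`` is 1.
    """

    dense: Composition
    dilute: Composition
    nu: float
    single_phase: bool

    def average(self) -> Composition:
        avg = self.nu * self.dense.as_array() + (1 - self.nu) * self.dilute.as_array()
        return Composition(*avg)


@dataclass(frozen=True)
class KineticParams:
    """First-order monomer<->aggregate interconversion rates (1/day)."""

    k1: float
    k2: float
    phi_tot: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.phi_tot < 1:
            raise ValueError("phi_tot must lie in (0, 1)")


@dataclass
class MaturationTrajectory:
    """Time course of average compositions and per-time phase equilibria."""

    times: np.ndarray
    avg_phi1: np.ndarray
    avg_phi2: np.ndarray
    equilibria: list = field(default_factory=list)

    def dense_solvent_fraction(self) -> np.ndarray:
        return np.array([eq.dense.phis for eq in self.equilibria])


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy_density(comp: Composition, params: InteractionParams) -> float:
    """Flory–Huggins free-energy density in kB*T per reference volume.

    Boundary fractions are handled through the limit ``phi ln phi -> 0``.
    """
    p1, p2, ps = comp.phi1, comp.phi2, comp.phis
    entropy = (
        _xlogx(p1) / params.v1 + _xlogx(p2) / params.v2 + _xlogx(ps) / params.vs
    )
    mixing = params.chi12 * p1 * p2 + (params.chi1s * p1 + params.chi2s * p2) * ps
    return float(entropy + mixing)


def _f_reduced(p1, p2, params: InteractionParams, clamp=True):
    """f as a function of (phi1, phi2) with phis eliminated; vectorised."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ps = 1.0 - p1 - p2
    if clamp:
        p1c = np.clip(p1, _PHI_MIN, 1 - _PHI_MIN)
        p2c = np.clip(p2, _PHI_MIN, 1 - _PHI_MIN)
        psc = np.clip(ps, _PHI_MIN, 1 - _PHI_MIN)
    else:
        p1c, p2c, psc = p1, p2, ps
    ent = (
        p1 * np.log(p1c) / params.v1
        + p2 * np.log(p2c) / params.v2
        + ps * np.log(psc) / params.vs
    )
    return ent + params.chi12 * p1 * p2 + (params.chi1s * p1 + params.chi2s * p2) * ps


def _partials(p1, p2, params: InteractionParams):
    """(df/dphi1, df/dphi2) of the reduced free energy; vectorised, clamped."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ps = 1.0 - p1 - p2
    p1c = np.clip(p1, _PHI_MIN, 1 - _PHI_MIN)
    p2c = np.clip(p2, _PHI_MIN, 1 - _PHI_MIN)
    psc = np.clip(ps, _PHI_MIN, 1 - _PHI_MIN)
    f1 = (
        (np.log(p1c) + 1) / params.v1
        - (np.log(psc) + 1) / params.vs
        + params.chi12 * p2
        + params.chi1s * (ps - p1)
        - params.chi2s * p2
    )
    f2 = (
        (np.log(p2c) + 1) / params.v2
        - (np.log(psc) + 1) / params.vs
        + params.chi12 * p1
        + params.chi2s * (ps - p2)
        - params.chi1s * p1
    )
    return f1, f2


def _mu_pi(p1, p2, params: InteractionParams):
    f1, f2 = _partials(p1, p2, params)
    f = _f_reduced(p1, p2, params)
    mu1 = params.vs * f1
    mu2 = params.vs * f2
    Pi = -f + p1 * f1 + p2 * f2
    return mu1, mu2, Pi


def thermo_state(comp: Composition, params: InteractionParams) -> ThermoState:
    """Chemical potentials mu_i = vs*df/dphi_i and osmotic pressure
    Pi = -f + phi1*df/dphi1 + phi2*df/dphi2, with f reduced to (phi1, phi2)
    through the incompressibility constraint phis = 1 - phi1 - phi2.
    """
    eps = 1e-10
    if min(comp.phi1, comp.phi2, comp.phis) < eps:
        raise BoundaryCompositionError(
            "chemical potentials diverge at the simplex boundary; "
            "clamp volume fractions away from 0 first"
        )
    mu1, mu2, Pi = _mu_pi(comp.phi1, comp.phi2, params)
    return ThermoState(
        f=free_energy_density(comp, params), mu1=float(mu1), mu2=float(mu2),
        Pi=float(Pi),
    )


def _hessian_pd(p1, p2, params: InteractionParams) -> bool:
    """Local stability of the homogeneous state (reduced-f Hessian PD)."""
    ps = 1.0 - p1 - p2
    f11 = 1 / (params.v1 * p1) + 1 / (params.vs * ps) - 2 * params.chi1s
    f22 = 1 / (params.v2 * p2) + 1 / (params.vs * ps) - 2 * params.chi2s
    f12 = 1 / (params.vs * ps) + params.chi12 - params.chi1s - params.chi2s
    return f11 > 0 and f11 * f22 - f12 * f12 > 0


def solve_binary_binodal(chi: float, v: float = 1.0, vs: float = 1.0):
    """Coexisting protein fractions of the binary protein/solvent mixture.

    For equal molecular volumes the binodal is symmetric about 1/2 and the
    dense branch solves ``ln(phi/(1-phi)) = chi (2 phi - 1)`` by bisection.
    Returns ``(phi_dense, phi_dilute)`` or None when no demixing occurs
    (chi below the critical point, 2 for the symmetric case).
    """
    if v == vs:
        if chi <= 2.0:
            return None
        g = lambda p: np.log(p / (1 - p)) - chi * (2 * p - 1)
        # root strictly above the critical composition 1/2
        lo = 0.5 + 1e-9
        hi = 1 - 1e-12
        if g(lo) * g(hi) > 0:
            return None
        pd = brentq(g, lo, hi, xtol=1e-14)
        return pd, 1 - pd
    # unequal volumes: solve mu and Pi equality in (phi_I, phi_II)
    params = InteractionParams(chi1s=chi, v1=v, vs=vs)

    def res(x):
        m1a, _, pia = _mu_pi(x[0], 0.0, params)
        m1b, _, pib = _mu_pi(x[1], 0.0, params)
        return [m1a - m1b, pia - pib]

    sym = solve_binary_binodal(chi, 1.0, 1.0)
    if sym is None:
        return None
    sol = root(res, x0=list(sym), tol=1e-12)
    if not sol.success or abs(sol.x[0] - sol.x[1]) < 1e-4:
        return None
    pd, pdil = sorted(sol.x, reverse=True)
    return float(pd), float(pdil)


def _pack(dense, dilute, nu):
    return PhaseEquilibrium(
        dense=Composition.from_protein(*dense),
        dilute=Composition.from_protein(*dilute),
        nu=float(nu),
        single_phase=False,
    )


def _single(avg: Composition) -> PhaseEquilibrium:
    return PhaseEquilibrium(dense=avg, dilute=avg, nu=1.0, single_phase=True)


def _residuals(x, avg, params):
    p1I, p2I, p1II, p2II, nu = x
    m1I, m2I, piI = _mu_pi(p1I, p2I, params)
    m1II, m2II, piII = _mu_pi(p1II, p2II, params)
    return np.array(
        [
            m1I - m1II,
            m2I - m2II,
            piI - piII,
            nu * p1I + (1 - nu) * p1II - avg.phi1,
            nu * p2I + (1 - nu) * p2II - avg.phi2,
        ]
    )


def _total_free_energy(eq: PhaseEquilibrium, params: InteractionParams) -> float:
    if eq.single_phase:
        return free_energy_density(eq.dense, params)
    return eq.nu * free_energy_density(eq.dense, params) + (
        1 - eq.nu
    ) * free_energy_density(eq.dilute, params)


def _effective_guess(avg: Composition, params: InteractionParams):
    """Initial tie-line guess from an effective binary mixture.

    Components 1 and 2 are lumped into one protein species whose solvent
    interaction is the composition-weighted chi; exact when chi1s == chi2s
    and chi12 == 0, a serviceable warm start otherwise.
    """
    ptot = avg.phi1 + avg.phi2
    if ptot <= 0:
        return None
    w1 = avg.phi1 / ptot
    chi_eff = w1 * params.chi1s + (1 - w1) * params.chi2s
    sym = solve_binary_binodal(chi_eff)
    if sym is None:
        return None
    pd, pdil = sym
    if not pdil < ptot < pd:
        return None
    nu = (ptot - pdil) / (pd - pdil)
    return np.array([w1 * pd, (1 - w1) * pd, w1 * pdil, (1 - w1) * pdil, nu])


def _coarse_guess(avg: Composition, params: InteractionParams):
    eq = brute_force_equilibrium(avg, params, grid_n=80)
    if eq.single_phase:
        return None
    return np.array(
        [eq.dense.phi1, eq.dense.phi2, eq.dilute.phi1, eq.dilute.phi2, eq.nu]
    )


def solve_coexistence(
    avg: Composition,
    params: InteractionParams,
    guess: PhaseEquilibrium | None = None,
    tol: float = 1e-10,
    max_restarts: int = 5,
) -> PhaseEquilibrium:
    """Solve the two-phase coexistence conditions for an average composition.

    Unknowns are the two phase compositions and the dense-phase volume
    fraction nu; the equations are equality of both chemical potentials and
    of the osmotic pressure between phases, plus the two lever-rule (mass
    balance) constraints that place the average on the tie-line.  Returns a
    single-phase state when no demixed solution with lower total free energy
    exists.
    """
    # Degenerate binary edges are solved by the dedicated binary routine.
    if avg.phi2 < 1e-9 or avg.phi1 < 1e-9:
        on_1 = avg.phi2 < 1e-9
        chi = params.chi1s if on_1 else params.chi2s
        v = params.v1 if on_1 else params.v2
        ptot = avg.phi1 if on_1 else avg.phi2
        sol = solve_binary_binodal(chi, v, params.vs)
        if sol is None or not sol[1] < ptot < sol[0]:
            return _single(avg)
        pd, pdil = sol
        nu = (ptot - pdil) / (pd - pdil)
        if on_1:
            return _pack((pd, 0.0), (pdil, 0.0), nu)
        return _pack((0.0, pd), (0.0, pdil), nu)

    starts = []
    if guess is not None and not guess.single_phase:
        starts.append(
            np.array(
                [
                    guess.dense.phi1,
                    guess.dense.phi2,
                    guess.dilute.phi1,
                    guess.dilute.phi2,
                    guess.nu,
                ]
            )
        )
    eff = _effective_guess(avg, params)
    if eff is not None:
        starts.append(eff)

    rng = np.random.default_rng(0)
    last_residual = None
    tried_coarse = False
    attempt = 0
    while attempt <= max_restarts:
        if attempt < len(starts):
            x0 = starts[attempt]
        elif not tried_coarse:
            tried_coarse = True
            cg = _coarse_guess(avg, params)
            if cg is None:
                break
            starts.append(cg)
            attempt += 1
            continue
        elif starts:
            base = starts[-1]
            x0 = np.clip(base + rng.normal(scale=0.02, size=5), 1e-6, 1 - 1e-6)
        else:
            break
        attempt += 1
        sol = root(_residuals, x0, args=(avg, params), method="hybr",
                   options={"maxfev": 200 * 6, "xtol": 1e-13})
        x = sol.x
        r = _residuals(x, avg, params)
        if np.linalg.norm(r) > tol:
            # polish marginal hybr solutions with Levenberg–Marquardt
            sol = root(_residuals, x, args=(avg, params), method="lm",
                       options={"xtol": 1e-14, "ftol": 1e-15})
            x = sol.x
            r = _residuals(x, avg, params)
        last_residual = r
        if np.linalg.norm(r) > tol:
            continue
        p1I, p2I, p1II, p2II, nu = x
        comps = np.array([p1I, p2I, p1II, p2II])
        if np.any(comps < -1e-12) or not -1e-9 <= nu <= 1 + 1e-9:
            continue
        if p1I + p2I >= 1 or p1II + p2II >= 1:
            continue
        # the identical-phases root always satisfies the equations
        if np.hypot(p1I - p1II, p2I - p2II) < 1e-4:
            continue
        # orient so phase I is the protein-dense phase
        if p1I + p2I < p1II + p2II:
            p1I, p2I, p1II, p2II, nu = p1II, p2II, p1I, p2I, 1 - nu
        eq = _pack((p1I, p2I), (p1II, p2II), np.clip(nu, 0, 1))
        f_two = _total_free_energy(eq, params)
        f_homog = free_energy_density(avg, params)
        if f_two > f_homog + 1e-12:
            continue
        return eq

    if _hessian_pd(avg.phi1, avg.phi2, params):
        return _single(avg)
    if last_residual is not None:
        raise CoexistenceError(
            "coexistence solver did not converge from an unstable average "
            f"composition (residual norm {np.linalg.norm(last_residual):.2e})",
            residuals=last_residual,
        )
    return _single(avg)


def brute_force_equilibrium(
    avg: Composition, params: InteractionParams, grid_n: int = 200
) -> PhaseEquilibrium:
    """Grid-search oracle: minimise total free energy over tie-lines.

    Dense-phase candidates run over a ``grid_n`` x ``grid_n`` composition
    grid; for each candidate and each nu on a grid the dilute composition
    follows from mass balance.  Exhaustive and slow by design — used to
    validate :func:`solve_coexistence`, not for production runs.
    """
    if grid_n < 50:
        raise ValueError("grid_n must be at least 50")
    if grid_n > 2000:
        raise ValueError("grid_n too large; memory guard")
    ax = np.linspace(1e-6, 1 - 1e-6, grid_n)
    P1, P2 = np.meshgrid(ax, ax, indexing="ij")
    valid = P1 + P2 < 1 - 1e-6
    p1 = P1[valid]
    p2 = P2[valid]
    fI = _f_reduced(p1, p2, params)
    f_best = free_energy_density(avg, params)
    best = None
    for nu in np.linspace(1.0 / grid_n, 1 - 1.0 / grid_n, grid_n - 1):
        q1 = (avg.phi1 - nu * p1) / (1 - nu)
        q2 = (avg.phi2 - nu * p2) / (1 - nu)
        ok = (q1 > 1e-9) & (q2 > 1e-9) & (q1 + q2 < 1 - 1e-9)
        if not np.any(ok):
            continue
        ftot = nu * fI[ok] + (1 - nu) * _f_reduced(q1[ok], q2[ok], params)
        i = np.argmin(ftot)
        if ftot[i] < f_best - 1e-12:
            f_best = ftot[i]
            idx = np.flatnonzero(ok)[i]
            best = (p1[idx], p2[idx], q1[idx], q2[idx], nu)
    if best is None:
        return _single(avg)
    p1I, p2I, p1II, p2II, nu = best
    if p1I + p2I < p1II + p2II:
        p1I, p2I, p1II, p2II, nu = p1II, p2II, p1I, p2I, 1 - nu
    if np.hypot(p1I - p1II, p2I - p2II) < 2.0 / grid_n:
        return _single(avg)
    return _pack((p1I, p2I), (p1II, p2II), nu)


def aggregation_trajectory(kin: KineticParams, times) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form average monomer/aggregate fractions of the reversible
    reaction phi1 <-> phi2 started from a fully monomeric solution:

        phi1(t) = phi_tot/(k1+k2) * (k2 + k1 exp(-(k1+k2) t))
        phi2(t) = phi_tot/(k1+k2) * (k1 - k1 exp(-(k1+k2) t))

    Conservation phi1 + phi2 = phi_tot holds exactly; k1 = k2 = 0 yields
    constant series.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    ktot = kin.k1 + kin.k2
    if ktot == 0:
        phi1 = np.full_like(t, kin.phi_tot)
    else:
        decay = np.exp(-ktot * t)
        phi1 = kin.phi_tot / ktot * (kin.k2 + kin.k1 * decay)
    phi2 = kin.phi_tot - phi1
    return phi1, phi2


def simulate_maturation(
    kin: KineticParams, params: InteractionParams, times
) -> MaturationTrajectory:
    """Maturation trajectory: aggregation kinetics with phase equilibrium
    re-solved at every time point (phase separation treated as instantaneous
    relative to aggregation).  Each solve warm-starts from the previous
    time point's tie-line.
    """
    t = np.asarray(times, dtype=float)
    phi1, phi2 = aggregation_trajectory(kin, t)
    equilibria = []
    prev = None
    for i, (a1, a2) in enumerate(zip(phi1, phi2)):
        avg = Composition.from_protein(a1, a2)
        try:
            eq = solve_coexistence(avg, params, guess=prev)
        except CoexistenceError as err:
            raise CoexistenceError(
                f"coexistence solve failed at time index {i} (t={t[i]:g} d): {err}",
                residuals=err.residuals,
            ) from err
        equilibria.append(eq)
        prev = eq
    return MaturationTrajectory(
        times=t, avg_phi1=phi1, avg_phi2=phi2, equilibria=equilibria
    )
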