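"""Forward models of the fluorophore photocycle and their time-integrated emission.

The photocycle is the two-state excitation/relaxation loop S0 <-> S1 driven by
the excitation rate constant ``k1 = sigma_ex * I_ex`` (photons/s per molecule)
and the relaxation rate constant ``k_rel = 1/tau_f`` (s^-1).  Because
excitation and relaxation are many orders of magnitude faster than
photobleaching, a rapid-equilibrium approximation (REA) collapses the kinetics
onto a single slow exponential whose amplitude and observed rate depend on the
photocycle only through the equilibrium constant ``q = k1/k_rel``
(photons/molecule).

Implemented model families:

* singlet-only bleaching (loss ``k2`` from S1): mono-exponential decay with
  observed rate ``k_b = k2*q/(1+q)`` and time-integrated emission (TiEm)
  ``M/k2`` — independent of ``q``, i.e. of illumination and lifetime;
* bleaching with a triplet state (intersystem crossing ``k3``, triplet loss
  ``k4``, triplet relaxation ``k5``): all-state REA again yields a single
  exponential, with TiEm ``M/(k2 + k4*k3/k5)``;
* multi-exponential combinations of such processes, TiEm = sum(A_i * tau_i);
* a time-dependent rate coefficient ``k2(t) = k2p * t^(-b)`` modelling
  consumption of a bleaching agent (e.g. oxygen in lipid droplets), whose
  decay is a stretched exponential and whose TiEm involves the Euler gamma
  function and — unlike the exponential family — depends on ``q``.

All occupancies are in molecules; "fluorescence" is used synonymously with the
excited singlet population S1 (detector and radiative proportionality factors
are deliberately not modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gamma as gamma_fn
from scipy.special import gammainc

from .constants import AVOGADRO, PLANCK_H, SPEED_OF_LIGHT_NM

__all__ = [
    "PhotocycleParams",
    "SingletBleachParams",
    "TripletParams",
    "RateCoeffParams",
    "StateTrajectory",
    "photon_energy",
    "irradiance_to_photon_flux",
    "photon_flux_to_irradiance",
    "cross_section_from_extinction",
    "extinction_from_cross_section",
    "saturation_occupancy",
    "singlet_bleach_decay",
    "observed_bleach_rate",
    "singlet_bleach_integral",
    "tiem_singlet",
    "triplet_ode_solve",
    "triplet_eigenvalues",
    "triplet_rea_decay",
    "triplet_rea_amplitude",
    "triplet_rea_rate",
    "tiem_triplet",
    "multiexp_decay",
    "multiexp_tiem",
    "strexp",
    "strexp_rate_coefficient",
    "ratecoeff_decay",
    "ratecoeff_integral",
    "tiem_ratecoeff",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhotocycleParams:
    """Photocycle S0 <-> S1 without bleaching.

    Exactly one way of specifying the photocycle strength is required:
    ``q`` directly, or the pair ``(k1, k_rel)``, or the photophysical triple
    ``(sigma_ex, i_ex, tau_f)`` with the cross-section in cm^2/molecule, the
    excitation photon flux in photons/(s*cm^2) and the fluorescence lifetime
    in seconds.  Internally everything is reduced to ``q = k1/k_rel``
    (photons/molecule), the only channel through which illumination and
    lifetime enter the REA formulas.
    """

    M: float = 1.0
    q: float | None = None
    k1: float | None = None
    k_rel: float | None = None
    sigma_ex: float | None = None
    i_ex: float | None = None
    tau_f: float | None = None

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError(f"fluorophore count M must be >= 0, got {self.M}")
        q = self.q
        if q is None:
            if self.k1 is not None and self.k_rel is not None:
                if self.k_rel <= 0:
                    raise ValueError("relaxation rate k_rel must be > 0")
                q = self.k1 / self.k_rel
            elif (
                self.sigma_ex is not None
                and self.i_ex is not None
                and self.tau_f is not None
            ):
                # k1 = sigma_ex * I_ex, k_rel = 1/tau_f  =>  q = sigma*I*tau
                q = self.sigma_ex * self.i_ex * self.tau_f
            else:
                raise ValueError(
                    "specify q, or (k1, k_rel), or (sigma_ex, i_ex, tau_f)"
                )
        if q < 0:
            raise ValueError(f"photocycle equilibrium constant q must be >= 0, got {q}")
        object.__setattr__(self, "q", float(q))
        if self.k1 is not None and self.k1 < 0:
            raise ValueError("excitation rate k1 must be >= 0")

    @property
    def q_frac(self) -> float:
        """Equilibrium excited-state fraction q/(1+q) of the non-bleached pool."""
        if np.isinf(self.q):
            return 1.0
        return self.q / (1.0 + self.q)


@dataclass(frozen=True)
class SingletBleachParams:
    """Photocycle plus irreversible loss k2 (s^-1) from the excited singlet.

    The REA requires k1, k_rel >> k2; this is recorded, and violations only
    warn because the closed forms remain well defined.
    """

    base: PhotocycleParams
    k2: float

    def __post_init__(self) -> None:
        if self.k2 < 0:
            raise ValueError(f"intrinsic bleach rate constant k2 must be >= 0, got {self.k2}")
        b = self.base
        if b.k1 is not None and b.k_rel is not None and self.k2 > 0:
            if min(b.k1, b.k_rel) < 100.0 * self.k2:
                warnings.warn(
                    "rapid-equilibrium assumption k1, k_rel >> k2 is questionable "
                    f"(k1={b.k1:g}, k_rel={b.k_rel:g}, k2={self.k2:g})",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class TripletParams:
    """Singlet bleaching extended by a triplet state.

    k3: intersystem crossing S1 -> T (s^-1); k4: intrinsic bleach rate from T
    (s^-1); k5: triplet relaxation T -> S0 (s^-1, > 0).  The triplet yield is
    k3/k5.
    """

    bleach: SingletBleachParams
    k3: float
    k4: float
    k5: float

    def __post_init__(self) -> None:
        for name in ("k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k5 <= 0:
            raise ValueError(f"triplet relaxation rate k5 must be > 0, got {self.k5}")

    @property
    def triplet_yield(self) -> float:
        return self.k3 / self.k5


@dataclass(frozen=True)
class RateCoeffParams:
    """Bleaching with the time-dependent rate coefficient k2(t) = k2p * t^(-b).

    ``k2p`` carries units s^(b-1) so that k2(t) is in s^-1; ``b`` plays the
    role of a stretching parameter (b = 0 recovers the constant-k2 singlet
    model with k2 = k2p).  The closed-form TiEm exists for 0 <= b < 1.
    """

    base: PhotocycleParams
    k2p: float
    b: float

    def __post_init__(self) -> None:
        if self.k2p < 0:
            raise ValueError(f"k2p must be >= 0, got {self.k2p}")
        if not (0.0 <= self.b < 1.0):
            raise ValueError(f"stretching parameter b must satisfy 0 <= b < 1, got {self.b}")


@dataclass(frozen=True)
class StateTrajectory:
    """State occupancies of the three-level system on a time grid."""

    t: np.ndarray
    S0: np.ndarray
    S1: np.ndarray
    T: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        object.__setattr__(self, "t", t)
        if self.T is None:
            object.__setattr__(self, "T", np.zeros_like(t))

    @property
    def total(self) -> np.ndarray:
        return self.S0 + self.S1 + self.T


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------


def photon_energy(lambda_nm: float) -> float:
    """Energy of one photon of wavelength ``lambda_nm`` (nm), in joules.

    E = h*c/lambda with h = 6.626e-34 J·s and c = 3e17 nm/s, e.g.
    320 nm -> 6.211e-19 J.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = PLANCK_H * SPEED_OF_LIGHT_NM / lam
    return out if out.ndim else float(out)


def irradiance_to_photon_flux(irradiance: float, lambda_nm: float) -> float:
    """Convert irradiance (W/cm^2) to photon flux (photons/(s*cm^2)).

    1 W/cm^2 at 320 nm is 1.61e18 photons/(s*cm^2); at 500 nm, 2.515e18.
    """
    irr = np.asarray(irradiance, dtype=float)
    if np.any(irr < 0):
        raise ValueError("irradiance must be >= 0")
    out = irr / photon_energy(lambda_nm)
    return out if out.ndim else float(out)


def photon_flux_to_irradiance(flux: float, lambda_nm: float) -> float:
    """Inverse of :func:`irradiance_to_photon_flux`."""
    fl = np.asarray(flux, dtype=float)
    if np.any(fl < 0):
        raise ValueError("photon flux must be >= 0")
    out = fl * photon_energy(lambda_nm)
    return out if out.ndim else float(out)


def cross_section_from_extinction(epsilon: float) -> float:
    """Absorption cross-section (cm^2/molecule) from a decadic molar
    extinction coefficient (M^-1 cm^-1): sigma = 1000*ln(10)*eps/N_A."""
    if epsilon < 0:
        raise ValueError("extinction coefficient must be >= 0")
    return 1000.0 * np.log(10.0) * epsilon / AVOGADRO


def extinction_from_cross_section(sigma: float) -> float:
    """Inverse of :func:`cross_section_from_extinction`."""
    if sigma < 0:
        raise ValueError("cross-section must be >= 0")
    return sigma * AVOGADRO / (1000.0 * np.log(10.0))


# ---------------------------------------------------------------------------
# Singlet-only photocycle
# ---------------------------------------------------------------------------


def saturation_occupancy(p: PhotocycleParams) -> float:
    """Steady-state excited-singlet population M*q/(1+q) (molecules).

    This is the time-independent part of the non-bleaching photocycle
    solution; as a function of excitation intensity it traces the familiar
    hyperbolic saturation curve, plateauing at M.
    """
    return p.M * p.q_frac


def observed_bleach_rate(p: SingletBleachParams) -> float:
    """Observable (phenomenological) bleach rate constant k_b = k2*q/(1+q).

    Saturates hyperbolically in q: the intrinsic per-excited-molecule loss k2
    is diluted by the fraction of time a surviving molecule spends in S1.
    """
    return p.k2 * p.base.q_frac


def singlet_bleach_decay(p: SingletBleachParams, t) -> np.ndarray:
    """Excited-state population S1(t) under singlet-only bleaching (REA).

    S1(t) = M*q/(1+q) * exp(-k_b*t) with k_b = k2*q/(1+q): the amplitude is
    the saturation occupancy of the non-bleaching photocycle and the decay is
    mono-exponential in the observed rate.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    amp = saturation_occupancy(p.base)
    return amp * np.exp(-observed_bleach_rate(p) * t)


def singlet_bleach_integral(p: SingletBleachParams, t_end: float) -> float:
    """Time integral F of S1(t) over [0, t_end] (molecule*s).

    F(T) = (M/k2) * (1 - exp(-k_b*T)); monotone in T and plateauing at the
    TiEm M/k2 once the pool is fully bleached.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if p.k2 == 0:
        return saturation_occupancy(p.base) * t_end
    kb = observed_bleach_rate(p)
    return (p.base.M / p.k2) * -np.expm1(-kb * t_end)


def tiem_singlet(M: float, k2: float) -> float:
    """Time-integrated emission M/k2 for singlet-only bleaching.

    Independent of q, i.e. of illumination intensity and fluorescence
    lifetime — the basis of shading- and quantum-yield-free probe
    quantification.  A non-bleaching fluorophore (k2 = 0) has infinite TiEm,
    hence the domain error.
    """
    if k2 <= 0:
        raise ValueError("k2 must be > 0 (TiEm diverges for a non-bleaching fluorophore)")
    if M < 0:
        raise ValueError("M must be >= 0")
    return M / k2


# ---------------------------------------------------------------------------
# Triplet-state model
# ---------------------------------------------------------------------------


def _triplet_rate_matrix(p: TripletParams) -> np.ndarray:
    """Full 3x3 rate matrix for (S0, S1, T) of the triplet scheme."""
    b = p.bleach
    base = b.base
    if base.k1 is None or base.k_rel is None:
        raise ValueError("triplet ODE solve requires explicit k1 and k_rel (not just q)")
    k1, km1 = base.k1, base.k_rel
    return np.array(
        [
            [-k1, km1, p.k5],
            [k1, -(km1 + b.k2 + p.k3), 0.0],
            [0.0, p.k3, -(p.k4 + p.k5)],
        ]
    )


def triplet_ode_solve(
    p: TripletParams, t_grid, method: str = "eig"
) -> StateTrajectory:
    """Solve the full three-state system S0 <-> S1 -> T (-> S0) with losses.

    The system is linear and extremely stiff (rate constants span ~1e8 s^-1
    to 1e-2 s^-1), so the default ``method="eig"`` solves it exactly by
    eigendecomposition of the rate matrix, which keeps relative accuracy even
    after the populations have decayed by many orders of magnitude.
    ``method="bdf"`` runs an adaptive implicit integrator (scipy BDF with
    analytic Jacobian) as an independent numerical route.

    Initial condition: S0(0) = M, S1(0) = T(0) = 0.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if t[0] < 0:
        raise ValueError("time must be >= 0")
    A = _triplet_rate_matrix(p)
    M = p.bleach.base.M
    y0 = np.array([M, 0.0, 0.0])

    if method == "eig":
        lam, V = np.linalg.eig(A)
        c = np.linalg.solve(V, y0)
        # y(t) = V @ (c * exp(lam*t)); generically real but guard round-off
        Y = np.real(V @ (c[:, None] * np.exp(np.outer(lam, t))))
    elif method == "bdf":
        sol = solve_ivp(
            lambda _t, y: A @ y,
            (0.0, t[-1]),
            y0,
            method="BDF",
            jac=lambda _t, y: A,
            t_eval=t,
            rtol=1e-9,
            atol=M * 1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"stiff integration failed: {sol.message}")
        Y = sol.y
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(Y)):
        raise RuntimeError("integration produced non-finite state occupancies")
    return StateTrajectory(t=t, S0=Y[0], S1=Y[1], T=Y[2])


def triplet_eigenvalues(p: TripletParams) -> tuple[float, float]:
    """Eigenvalues of the 2x2 Jacobian of the singlet-REA triplet system.

    With the S0/S1 photocycle pre-equilibrated (excited fraction
    qf = q/(1+q)) the slow dynamics in (N = S0+S1, T) has Jacobian

        [[-(k2+k3)*qf,  k5       ],
         [  k3*qf,     -(k4+k5) ]]

    whose eigenvalues are always real (the discriminant is a sum of squares
    plus a non-negative cross term) and strictly negative for positive rates
    (trace < 0, determinant > 0 — the Routh–Hurwitz conditions).
    Returned sorted lambda1 <= lambda2 < 0.
    """
    b = p.bleach
    qf = b.base.q_frac
    a11 = -(b.k2 + p.k3) * qf
    a22 = -(p.k4 + p.k5)
    tr = a11 + a22
    det = a11 * a22 - p.k5 * p.k3 * qf
    disc = tr * tr - 4.0 * det
    root = np.sqrt(max(disc, 0.0))
    # tr < 0: (tr - root)/2 is the large-magnitude root; recover the small
    # one from the product to avoid cancellation when |lam1| >> |lam2|
    lam1 = 0.5 * (tr - root)
    lam2 = det / lam1 if lam1 != 0 else 0.5 * (tr + root)
    return (lam1, lam2)


def triplet_rea_amplitude(p: TripletParams) -> float:
    """Initial S1 amplitude of the all-state REA: M*q/(1 + q + q*k3/k5)."""
    base = p.bleach.base
    q = base.q
    return base.M * q / (1.0 + q + q * p.triplet_yield)


def triplet_rea_rate(p: TripletParams) -> float:
    """Observable bleach rate of the all-state REA.

    k_b = q*(k2 + k3*k4/k5) / (1 + q + q*k3/k5): the singlet and the
    triplet-weighted loss channels, diluted by the equilibrium occupancies of
    all three states.  Saturates hyperbolically in q and grows hyperbolically
    with the triplet yield.
    """
    b = p.bleach
    q = b.base.q
    return q * (b.k2 + p.k3 * p.k4 / p.k5) / (1.0 + q + q * p.triplet_yield)


def triplet_rea_decay(p: TripletParams, t) -> np.ndarray:
    """S1(t) from the rapid-equilibrium treatment of all three states.

    Assumes the electronic states (ns–µs scales) equilibrate long before any
    appreciable bleaching (seconds), giving a single mono-exponential:
    S1(t) = amplitude * exp(-k_b*t) with the amplitude and rate of
    :func:`triplet_rea_amplitude` / :func:`triplet_rea_rate`.  Reduces to
    :func:`singlet_bleach_decay` for k3 = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return triplet_rea_amplitude(p) * np.exp(-triplet_rea_rate(p) * t)


def tiem_triplet(p: TripletParams) -> float:
    """TiEm with triplet bleaching: M / (k2 + k4*k3/k5).

    The triplet loss k4 enters weighted by the triplet equilibrium constant
    k3/k5; the result is again independent of q.  Diverges (domain error)
    when both loss channels vanish.
    """
    b = p.bleach
    k_eff = b.k2 + p.k4 * p.triplet_yield
    if k_eff <= 0:
        raise ValueError("total intrinsic bleach rate is zero; TiEm diverges")
    return b.base.M / k_eff


# ---------------------------------------------------------------------------
# Multi-exponential bleaching
# ---------------------------------------------------------------------------


def multiexp_decay(components: Sequence[tuple[float, float]], t) -> np.ndarray:
    """Sum of exponential decays; ``components`` is a list of (A_i, tau_i)."""
    if len(components) == 0:
        raise ValueError("at least one (amplitude, time constant) component required")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for amp, tau in components:
        if amp < 0 or tau <= 0:
            raise ValueError("amplitudes must be >= 0 and time constants > 0")
        out = out + amp * np.exp(-t / tau)
    return out


def multiexp_tiem(components: Sequence[tuple[float, float]]) -> float:
    """TiEm of a multi-exponential bleach: sum of A_i * tau_i."""
    if len(components) == 0:
        raise ValueError("at least one (amplitude, time constant) component required")
    total = 0.0
    for amp, tau in components:
        if amp < 0 or tau <= 0:
            raise ValueError("amplitudes must be >= 0 and time constants > 0")
        total += amp * tau
    return total


# ---------------------------------------------------------------------------
# Stretched-exponential / rate-coefficient model
# ---------------------------------------------------------------------------


def strexp(t, amplitude: float, tau: float, h_stretch: float) -> np.ndarray:
    """Kohlrausch (stretched-exponential) decay A*exp(-(t/tau)^h).

    ``h_stretch`` is the stretching parameter (named to avoid a clash with
    Planck's constant); h = 1 gives the plain mono-exponential.  For h > 1
    (compressed decay) the rate coefficient grows with time, so the curve
    stays above the matching exponential before t = tau and falls below it
    after; h < 1 behaves the other way around.
    """
    if tau <= 0 or h_stretch <= 0:
        raise ValueError("tau and h_stretch must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return amplitude * np.exp(-((t / tau) ** h_stretch))


def strexp_rate_coefficient(t, tau: float, h_stretch: float) -> np.ndarray:
    """Time-dependent rate coefficient of the stretched exponential.

    k(t) = (h/tau)*(t/tau)^(h-1), so that dn/dt = -k(t)*n reproduces the
    Kohlrausch decay.  For h < 1, k(t) diverges at t = 0 (returned as inf).
    """
    if tau <= 0 or h_stretch <= 0:
        raise ValueError("tau and h_stretch must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    with np.errstate(divide="ignore"):
        out = (h_stretch / tau) * (t / tau) ** (h_stretch - 1.0)
    return out


def ratecoeff_decay(p: RateCoeffParams, t) -> np.ndarray:
    """S1(t) for bleaching with rate coefficient k2(t) = k2p * t^(-b).

    Integrating the REA equation dS1/dt = -(q/(1+q)) * k2(t) * S1 gives

        S1(t) = M*q/(1+q) * exp(- (q/(1+q)) * k2p * t^(1-b) / (1-b)),

    a stretched exponential with exponent 1-b.  b = 0 recovers the
    constant-rate singlet decay exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    qf = p.base.q_frac
    amp = p.base.M * qf
    a = qf * p.k2p / (1.0 - p.b)
    return amp * np.exp(-a * t ** (1.0 - p.b))


def ratecoeff_integral(p: RateCoeffParams, t_end: float) -> float:
    """Integral of :func:`ratecoeff_decay` over [0, t_end] in closed form.

    Expressed via the regularized lower incomplete gamma function; the
    t_end -> inf limit is :func:`tiem_ratecoeff`.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if t_end == 0:
        return 0.0
    full = tiem_ratecoeff(p)
    qf = p.base.q_frac
    beta = 1.0 / (1.0 - p.b)
    a = qf * p.k2p / (1.0 - p.b)
    return full * float(gammainc(beta, a * t_end ** (1.0 - p.b)))


def tiem_ratecoeff(p: RateCoeffParams) -> float:
    """TiEm of the rate-coefficient model (closed form with the gamma function).

    With qf = q/(1+q), beta = 1/(1-b) and a = qf*k2p/(1-b):

        TiEm = M * qf * Gamma(beta + 1) * a^(-beta)

    For b = 0 this is exactly M/k2p for any q; for b > 0 it exceeds M/k2p and
    becomes q-dependent, the excess shrinking as q (illumination) grows.
    """
    if p.k2p <= 0:
        raise ValueError("k2p must be > 0")
    qf = p.base.q_frac
    if qf == 0:
        return 0.0
    beta = 1.0 / (1.0 - p.b)
    a = qf * p.k2p / (1.0 - p.b)
    return p.base.M * qf * float(gamma_fn(beta + 1.0)) * a ** (-beta)
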