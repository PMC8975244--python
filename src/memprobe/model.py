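"""Closed-form membrane fluctuation model.

Static Helfrich undulation spectra, the two relaxation rates of the coupled
height / monolayer-density (Seifert-Langer) dynamics, the out-of-plane
mean-squared angular displacement (MSAD) of a membrane-bound probe, its
long-lag asymptote, bounded diffusion on a sphere, and the narrow-band
covariance model used for cell plasma membranes.

All quantities are strict SI internally (m, s, J, N/m, Pa s, N s/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KBT_ROOM",
    "MembraneParams",
    "WavenumberBand",
    "RelaxationRates",
    "CellCovarianceModel",
    "QuadratureError",
    "renormalized_rigidity",
    "static_height_spectrum",
    "static_angle_spectrum",
    "relaxation_rates",
    "theta_msad_model",
    "theta_msad_asymptote",
    "sphere_msd_model",
    "cell_covariance_model",
]

#: Thermal energy at room temperature (T ~ 295 K), joule.
KBT_ROOM = 4.07e-21


class QuadratureError(RuntimeError):
    """Raised when the adaptive band quadrature fails to converge."""


@dataclass(frozen=True)
class MembraneParams:
    """Physical parameters of a fluctuating bilayer membrane.

    Parameters
    ----------
    kappa_c : float
        Bending rigidity (J).
    sigma : float
        Membrane tension (N/m), >= 0.
    epsilon : float
        Monolayer compressibility modulus (N/m).
    d : float
        Distance from bilayer midplane to the monolayer neutral surface (m).
    b : float
        Intermonolayer friction coefficient (N s/m^3).
    eta : float
        Bulk fluid viscosity (Pa s).
    eta_m : float
        Membrane surface viscosity (Pa s m).
    kBT : float
        Thermal energy (J).
    """

    kappa_c: float
    sigma: float = 0.0
    epsilon: float = 0.1
    d: float = 2e-9
    b: float = 6.9e8
    eta: float = 1e-3
    eta_m: float = 1.2e-9
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        for name in ("kappa_c", "epsilon", "d", "b", "eta", "eta_m", "kBT"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def kappa_tilde(self) -> float:
        """Renormalized rigidity kappa_c + 2*epsilon*d**2 (J)."""
        return self.kappa_c + 2.0 * self.epsilon * self.d**2

    def with_(self, **kwargs) -> "MembraneParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class WavenumberBand:
    """Band of undulation wavenumbers resolvable by a rod of length l on a
    vesicle of radius R: q_min = pi/R, q_max = 2*pi/l."""

    q_min: float
    q_max: float
    R: float = float("nan")
    l: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.q_min < self.q_max):
            raise ValueError("need 0 < q_min < q_max")

    @classmethod
    def from_geometry(cls, R: float, l: float) -> "WavenumberBand":
        if not (R > 0 and 0 < l < 2 * R):
            raise ValueError("need R > 0 and 0 < l < 2R")
        return cls(q_min=np.pi / R, q_max=2 * np.pi / l, R=R, l=l)


@dataclass(frozen=True)
class RelaxationRates:
    """Per-wavenumber relaxation rates of the bilayer.

    ``omega2`` is the branch carrying integrand weight kappa_c/kappa_tilde in
    the MSAD model (the bending rate in the decoupled-monolayer limit);
    ``omega1`` carries the complementary weight 1 - kappa_c/kappa_tilde.
    """

    q: np.ndarray
    omega1: np.ndarray
    omega2: np.ndarray
    weight_fast: float


@dataclass(frozen=True)
class CellCovarianceModel:
    """Single-exponential model for the out-of-plane angle covariance of a
    probe on a corralled plasma membrane, A(tau) = A0 * exp(-omega1*tau) with
    A0 = (kBT / 2 pi kappa_c) * (dq/q)."""

    kappa_c: float
    dq_over_q: float
    omega1: float
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        if not 0 < self.dq_over_q <= 1:
            raise ValueError("dq_over_q must be in (0, 1]")
        if self.kappa_c <= 0 or self.omega1 <= 0 or self.kBT <= 0:
            raise ValueError("kappa_c, omega1, kBT must be positive")

    @property
    def amplitude(self) -> float:
        return self.kBT / (2 * np.pi * self.kappa_c) * self.dq_over_q


def renormalized_rigidity(params: MembraneParams) -> float:
    """Effective short-time rigidity kappa_c + 2*epsilon*d**2 (J)."""
    return params.kappa_tilde


def _check_q(q):
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("wavenumber q must be strictly positive")
    return q


def static_height_spectrum(q, params: MembraneParams):
    """Equal-time height undulation spectrum kBT / (kappa_c q^4 + sigma q^2)."""
    q = _check_q(q)
    return params.kBT / (params.kappa_c * q**4 + params.sigma * q**2)


def static_angle_spectrum(q, params: MembraneParams):
    """Equal-time tilt spectrum q^2 <h_q h_-q> = kBT / (kappa_c q^2 + sigma)."""
    q = _check_q(q)
    return params.kBT / (params.kappa_c * q**2 + params.sigma)


def _two_mode_rates(q, params: MembraneParams, include_monolayer_viscosity: bool):
    """Eigen-rates (lam_plus >= lam_minus) of the height/density relaxation
    matrix at wavenumber(s) q, plus the exact height-autocorrelation
    amplitude carried by lam_plus."""
    kt = params.kappa_tilde
    eps, d, sig = params.epsilon, params.d, params.sigma

    e_hh = kt * q**4 + sig * q**2
    e_hr = -2.0 * eps * d * q**2
    e_rr = 2.0 * eps

    lam_h = 1.0 / (4.0 * params.eta * q)
    visc = 2.0 * params.eta_m * q**2 if include_monolayer_viscosity else 0.0
    lam_r = q**2 / (2.0 * params.b + visc)

    a00 = lam_h * e_hh
    a01 = lam_h * e_hr
    a10 = lam_r * e_hr
    a11 = lam_r * e_rr

    tr = a00 + a11
    det = a00 * a11 - a01 * a10
    disc = np.sqrt(np.maximum(tr**2 - 4.0 * det, 0.0))
    lam_plus = 0.5 * (tr + disc)
    lam_minus = 0.5 * (tr - disc)

    # Equilibrium covariance Sigma = kBT E^{-1}; only ratios enter the
    # height-autocorrelation amplitudes so kBT cancels.
    det_e = e_hh * e_rr - e_hr**2  # = 2 eps (kappa_c q^4 + sigma q^2)
    s00 = e_rr / det_e
    s10 = -e_hr / det_e

    # C_hh(t)/C_hh(0) = a_plus e^{-lam_plus t} + (1 - a_plus) e^{-lam_minus t}
    with np.errstate(invalid="ignore", divide="ignore"):
        a_plus = (lam_minus * s00 - (a00 * s00 + a01 * s10)) / (
            (lam_minus - lam_plus) * s00
        )
    a_plus = np.where(disc > 0, a_plus, 0.5)
    return lam_plus, lam_minus, a_plus


def relaxation_rates(
    q,
    params: MembraneParams,
    include_monolayer_viscosity: bool = True,
) -> RelaxationRates:
    """Eigen-rates of the coupled height/monolayer-density relaxation.

    The bilayer mode at wavenumber q couples the height h_q (damped by the
    bulk fluid, mobility 1/(4 eta q)) to the monolayer density difference
    (damped by intermonolayer friction b and, optionally, monolayer surface
    viscosity, mobility q^2/(2b + 2 eta_m q^2)).  The free energy of the pair
    is quadratic with Hessian

        E = [[kappa_tilde q^4 + sigma q^2, -2 eps d q^2],
             [-2 eps d q^2,                 2 eps       ]]

    and the rate matrix is A = diag(mobilities) @ E.  Branches are labeled by
    matching the exact height-autocorrelation amplitudes of the two-mode
    system to the fixed weights (kappa_c/kappa_tilde on omega2) used in the
    MSAD model, so that omega2 reduces to the classical bulk-damped bending
    rate (kappa_c q^3 + sigma q) / (4 eta) when the monolayer coupling
    vanishes.
    """
    q = _check_q(q)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)

    lam_plus, lam_minus, a_plus = _two_mode_rates(
        q, params, include_monolayer_viscosity
    )
    w = params.kappa_c / params.kappa_tilde
    plus_is_omega2 = np.abs(a_plus - w) <= np.abs((1.0 - a_plus) - w)
    omega2 = np.where(plus_is_omega2, lam_plus, lam_minus)
    omega1 = np.where(plus_is_omega2, lam_minus, lam_plus)

    if scalar:
        omega1, omega2 = float(omega1[0]), float(omega2[0])
        q = float(q[0])
    return RelaxationRates(q=q, omega1=omega1, omega2=omega2, weight_fast=w)


def _label_indicator(q, params, include_monolayer_viscosity):
    """True where the lam_plus branch is omega2 (the kc/kt-weighted rate)."""
    _, _, a_plus = _two_mode_rates(q, params, include_monolayer_viscosity)
    w = params.kappa_c / params.kappa_tilde
    return np.abs(a_plus - w) <= np.abs((1.0 - a_plus) - w)


def _label_flip_points(params, band, include_monolayer_viscosity, n_scan=512):
    """Wavenumbers where the omega1/omega2 branch assignment flips.

    The branch label changes across the avoided crossing of the two
    relaxation branches; the MSAD integrand has a step there and the band
    quadrature must be split at these points."""
    qs = np.geomspace(band.q_min, band.q_max, n_scan + 1)
    ind = _label_indicator(qs, params, include_monolayer_viscosity)
    flips = np.nonzero(ind[:-1] != ind[1:])[0]
    points = []
    for i in flips:
        lo, hi = np.log(qs[i]), np.log(qs[i + 1])
        ind_lo = ind[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if (
                _label_indicator(
                    np.array([np.exp(mid)]), params, include_monolayer_viscosity
                )[0]
                == ind_lo
            ):
                lo = mid
            else:
                hi = mid
        points.append(np.exp(0.5 * (lo + hi)))
    return points


def _segment_nodes(q_lo: float, q_hi: float, n: int):
    """Gauss-Legendre nodes/weights for integration over ln q on a segment."""
    x, w = np.polynomial.legendre.leggauss(n)
    lo, hi = np.log(q_lo), np.log(q_hi)
    lnq = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    return np.exp(lnq), w * 0.5 * (hi - lo)


def _msad_quad(tau, params, band, n, splits, include_monolayer_viscosity=True):
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    edges = [band.q_min, *splits, band.q_max]
    total = np.zeros_like(tau)
    for q_lo, q_hi in zip(edges[:-1], edges[1:]):
        q, w = _segment_nodes(q_lo, q_hi, n)
        rates = relaxation_rates(
            q, params, include_monolayer_viscosity=include_monolayer_viscosity
        )
        wf = rates.weight_fast
        # integrand in ln q: q * [q / (kappa q^2 + sigma)] * bracket(tau, q)
        amp = q**2 / (params.kappa_c * q**2 + params.sigma)
        bracket = (
            1.0
            - wf * np.exp(-np.outer(tau, rates.omega2))
            - (1.0 - wf) * np.exp(-np.outer(tau, rates.omega1))
        )
        total += (bracket * (amp * w)).sum(axis=1)
    return (params.kBT / np.pi) * total


def theta_msad_model(
    tau,
    params: MembraneParams,
    band: WavenumberBand,
    static_offset: float = 0.0,
    rel_tol: float = 1e-8,
    include_monolayer_viscosity: bool = True,
    n_nodes: int | None = None,
):
    """Out-of-plane MSAD of a membrane-bound probe at lag(s) tau (rad^2).

    Evaluates

        (kBT/pi) * Int_{q_min}^{q_max} q dq / (kappa_c q^2 + sigma)
            * [1 - (kc/kt) e^{-omega2 tau} - (1 - kc/kt) e^{-omega1 tau}]
        + static_offset

    by Gauss-Legendre quadrature on a log-q transform with automatic node
    doubling until the relative change is below ``rel_tol``.  The band is
    split where the omega1/omega2 branch labeling flips (the integrand has a
    step there).  Passing ``n_nodes`` skips the adaptive check and uses a
    fixed node count per segment (used inside fitting loops, where ~1e-5
    relative accuracy suffices).
    """
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    if static_offset < 0:
        raise ValueError("static_offset must be >= 0")

    splits = _label_flip_points(params, band, include_monolayer_viscosity)
    if n_nodes is not None:
        out = (
            _msad_quad(
                tau_arr, params, band, n_nodes, splits, include_monolayer_viscosity
            )
            + static_offset
        )
        return float(out[0]) if np.ndim(tau) == 0 else out
    prev = _msad_quad(
        tau_arr, params, band, 64, splits, include_monolayer_viscosity
    )
    for n in (128, 256, 512, 1024):
        cur = _msad_quad(
            tau_arr, params, band, n, splits, include_monolayer_viscosity
        )
        scale = np.maximum(np.abs(cur), np.abs(prev).max() * 1e-12 + 1e-300)
        if np.all(np.abs(cur - prev) <= rel_tol * scale + 1e-30):
            out = cur + static_offset
            return float(out[0]) if np.isscalar(tau) or np.ndim(tau) == 0 else out
        prev = cur
    raise QuadratureError(
        "band quadrature did not converge to rel_tol=%g at 1024 nodes" % rel_tol
    )


def theta_msad_asymptote(params: MembraneParams, band: WavenumberBand) -> float:
    """Long-lag plateau of the out-of-plane MSAD (rad^2), set only by
    rigidity and tension:

        (kBT / 2 pi kappa_c) * ln[(kappa_c q_max^2 + sigma) /
                                  (kappa_c q_min^2 + sigma)]
    """
    kc, sig = params.kappa_c, params.sigma
    return (
        params.kBT
        / (2 * np.pi * kc)
        * np.log((kc * band.q_max**2 + sig) / (kc * band.q_min**2 + sig))
    )


def sphere_msd_model(tau, Dt: float, R: float):
    """Chord-squared MSD of isotropic diffusion on a sphere of radius R.

    <|r(t+tau) - r(t)|^2> = 2 R^2 (1 - exp(-2 Dt tau / R^2)); tends to
    4*Dt*tau for tau << R^2/Dt and saturates at 2 R^2.
    """
    if Dt <= 0 or R <= 0:
        raise ValueError("Dt and R must be positive")
    tau = np.asarray(tau, dtype=float)
    return 2.0 * R**2 * (-np.expm1(-2.0 * Dt * tau / R**2))


def cell_covariance_model(tau, model: CellCovarianceModel):
    """Narrow-band covariance A(tau) = (kBT/2 pi kappa_c)(dq/q) e^{-omega1 tau}."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    return model.amplitude * np.exp(-model.omega1 * tau)
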