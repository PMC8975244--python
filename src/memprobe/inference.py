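"""Model fitting: diffusivities, membrane parameters, mobility inversion,
and the cell covariance analysis.

The membrane-parameter fit minimizes, by weighted least squares over
(log kappa_c, log sigma, log b, log static_offset), the residuals of the
out-of-plane MSAD model on the measured curve plus one residual tying the
model's long-lag asymptote to the variance-derived estimate 2<theta^2>.
Chi-square profiles (others re-optimized) provide Delta-chi2 = 1 intervals
and flag unidentifiable parameters; rod-length uncertainty is propagated by
refitting at l +/- dl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

from .estimators import LagStatistic
from .model import (
    KBT_ROOM,
    MembraneParams,
    WavenumberBand,
    theta_msad_asymptote,
    theta_msad_model,
)

__all__ = [
    "DiffusivityResult",
    "MembraneFitResult",
    "CellFitResult",
    "fit_translational_diffusivity",
    "fit_rotational_diffusivity",
    "sd_rod_drag",
    "invert_mobility",
    "fit_membrane_params",
    "chi2_sensitivity",
    "propagate_qmax_uncertainty",
    "fit_cell_covariance",
    "detect_msd_crossover",
]

EULER_GAMMA = 0.5772156649015329


@dataclass
class DiffusivityResult:
    """Diffusivities, drag coefficients, and the membrane-hydrodynamic
    quantities obtained by inverting them."""

    D_t: float
    D_r: float
    D_t_stderr: float = float("nan")
    D_r_stderr: float = float("nan")
    gamma_t: float = float("nan")
    gamma_r: float = float("nan")
    eta_m: float = float("nan")
    l_eff: float = float("nan")
    l_m: float = float("nan")
    kBT: float = KBT_ROOM
    backend: str = ""
    fit_range: dict = field(default_factory=dict)


@dataclass
class MembraneFitResult:
    kappa_c: float
    sigma: float
    b: float
    static_offset: float
    chi2: float
    intervals: dict = field(default_factory=dict)   # param -> (lo, hi) or one-sided
    profiles: dict = field(default_factory=dict)    # param -> (grid, chi2 values)
    flags: dict = field(default_factory=dict)
    qmax_sensitivity: dict = field(default_factory=dict)
    kBT: float = KBT_ROOM
    meta: dict = field(default_factory=dict)


@dataclass
class CellFitResult:
    omega: float
    omega_stderr: float
    amplitude: float
    amplitude_stderr: float
    kappa_range: tuple[float, float]  # in units of kBT
    dq_over_q_range: tuple[float, float]
    kBT: float = KBT_ROOM
    meta: dict = field(default_factory=dict)


def _weighted_line_through_origin(x, y, sigma):
    """Weighted LS fit y = s*x; returns (s, stderr of s)."""
    w = 1.0 / np.maximum(np.asarray(sigma, float), 1e-300) ** 2
    sxx = np.sum(w * x * x)
    s = np.sum(w * x * y) / sxx
    return s, 1.0 / np.sqrt(sxx)


def fit_translational_diffusivity(
    msd: LagStatistic, R: float | None = None, c: float = 0.01
) -> DiffusivityResult:
    """Short-lag fit of the MSD to 4*Dt*tau.

    On a vesicle the MSD is bounded; only lags with tau < c*R^2/Dt are in
    the linear regime, selected self-consistently (the threshold depends on
    the fitted Dt).  Raises if no lag qualifies.
    """
    lags, vals, err = msd.lags, msd.values, msd.stderr
    sel = np.ones(lags.size, dtype=bool)
    if R is not None:
        D = vals[0] / (4 * lags[0])
        for _ in range(50):
            sel = lags < c * R**2 / D
            if sel.sum() < 1:
                raise ValueError("no MSD lag lies in the short-lag linear regime")
            D_new, _ = _weighted_line_through_origin(
                4 * lags[sel], vals[sel], err[sel]
            )
            if abs(D_new - D) <= 1e-12 + 1e-6 * abs(D):
                D = D_new
                break
            D = D_new
    D, se = _weighted_line_through_origin(4 * lags[sel], vals[sel], err[sel])
    return DiffusivityResult(
        D_t=D, D_r=float("nan"), D_t_stderr=se,
        fit_range={"tau_max": float(lags[sel].max()), "n_lags": int(sel.sum())},
    )


def fit_rotational_diffusivity(
    msad_physical: LagStatistic, slope_flag_threshold: float = 0.9
) -> DiffusivityResult:
    """Short-lag fit of the physical MSAD to 4*Dr*tau.

    Restricted to the shortest decade of available lags; if the local
    log-log slope over that decade falls below ``slope_flag_threshold`` the
    result is flagged subdiffusive.
    """
    lags, vals, err = msad_physical.lags, msad_physical.values, msad_physical.stderr
    sel = lags <= lags[0] * 10
    if sel.sum() < 2:
        sel = np.arange(lags.size) < 2
    D, se = _weighted_line_through_origin(4 * lags[sel], vals[sel], err[sel])
    # local log-slope over the fitted decade
    lx, ly = np.log(lags[sel]), np.log(np.maximum(vals[sel], 1e-300))
    slope = np.polyfit(lx, ly, 1)[0]
    res = DiffusivityResult(
        D_t=float("nan"), D_r=D, D_r_stderr=se,
        fit_range={"tau_max": float(lags[sel].max()), "n_lags": int(sel.sum()),
                   "log_slope": float(slope)},
    )
    if slope < slope_flag_threshold:
        res.fit_range["subdiffusive_flag"] = True
    return res


# ---------------------------------------------------------------------------
# mobility inversion


def sd_rod_drag(eta_m: float, l_eff: float, eta: float) -> tuple[float, float]:
    """Drag coefficients of a rod of effective length l_eff embedded in a
    membrane of surface viscosity eta_m over bulk fluid of viscosity eta,
    in the Saffman-Delbrueck regime (l_eff << l_m = eta_m/eta):

        gamma_t = 4 pi eta_m / [ln(2 l_m / l_eff) - gamma_Euler]
        gamma_r = pi eta_m l_eff^2
    """
    l_m = eta_m / eta
    arg = 2.0 * l_m / l_eff
    if arg <= np.exp(EULER_GAMMA):
        raise ValueError("outside Saffman-Delbrueck regime (l_eff too large)")
    gamma_t = 4 * np.pi * eta_m / (np.log(arg) - EULER_GAMMA)
    gamma_r = np.pi * eta_m * l_eff**2
    return gamma_t, gamma_r


_DRAG_BACKENDS = {"sd_rod": sd_rod_drag}


def invert_mobility(
    D_t: float,
    D_r: float,
    eta: float = 1e-3,
    kBT: float = KBT_ROOM,
    backend: str = "sd_rod",
) -> DiffusivityResult:
    """Solve the membrane-hydrodynamic drag model for (eta_m, l_eff) from
    measured diffusivities.

    gamma_r fixes l_eff as a function of eta_m; the remaining scalar
    equation for gamma_t is solved by bracketing + Brent root finding.
    """
    if D_t <= 0 or D_r <= 0:
        raise ValueError("diffusivities must be positive")
    drag = _DRAG_BACKENDS[backend]
    gt_target, gr_target = kBT / D_t, kBT / D_r

    def l_eff_of(eta_m):
        return np.sqrt(gr_target / (np.pi * eta_m))

    def f(log_eta_m):
        eta_m = np.exp(log_eta_m)
        try:
            gt, _ = drag(eta_m, l_eff_of(eta_m), eta)
        except ValueError:
            return -gt_target  # too far outside regime: force sign
        return gt - gt_target

    # Along the inversion path l_eff ~ eta_m^(-1/2), gamma_t has a minimum
    # where ln(2 l_m/l_eff) - gamma_E = 3/2; the physical (SD-regime) root
    # lies on the increasing branch above it.
    eta_m_floor = (
        np.exp(EULER_GAMMA + 1.5) * eta * np.sqrt(gr_target / np.pi) / 2.0
    ) ** (2.0 / 3.0)
    lo, hi = np.log(max(eta_m_floor, 1e-12)), np.log(1e-5)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            "no root in the physical eta_m range "
            f"[1e-12, 1e-5] Pa s m: f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    log_eta_m = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    eta_m = float(np.exp(log_eta_m))
    l_eff = float(l_eff_of(eta_m))
    return DiffusivityResult(
        D_t=D_t, D_r=D_r, gamma_t=gt_target, gamma_r=gr_target,
        eta_m=eta_m, l_eff=l_eff, l_m=eta_m / eta, kBT=kBT, backend=backend,
    )


# ---------------------------------------------------------------------------
# membrane-parameter fit


class _MembraneFitProblem:
    """Weighted residuals of the MSAD model plus the asymptote constraint,
    over x = log10([kappa_c/kBT, sigma, b, static_offset])."""

    BOUNDS_LO = np.array([np.log10(0.5), -10.0, 6.0, -8.0])
    BOUNDS_HI = np.array([np.log10(500.0), -3.0, 11.0, 0.0])

    def __init__(self, theta_msd, theta_variance, band, fixed, kBT,
                 n_nodes=96, offset_prior=None):
        self.lags = np.asarray(theta_msd.lags, float)
        self.y = np.asarray(theta_msd.values, float)
        self.sy = np.maximum(np.asarray(theta_msd.stderr, float), 1e-300)
        self.var, self.var_sd = theta_variance
        self.band = band
        self.fixed = dict(fixed)
        self.kBT = kBT
        self.n_nodes = n_nodes
        # (value, log10 sd): loose prior anchoring the static noise floor at
        # the known instrument precision; None leaves the offset free
        self.offset_prior = offset_prior

    def params_of(self, x):
        return MembraneParams(
            kappa_c=10 ** x[0] * self.kBT,
            sigma=10 ** x[1],
            b=10 ** x[2],
            epsilon=self.fixed.get("epsilon", 0.1),
            d=self.fixed.get("d", 2e-9),
            eta=self.fixed.get("eta", 1e-3),
            eta_m=self.fixed.get("eta_m", 1.2e-9),
            kBT=self.kBT,
        )

    def residuals(self, x):
        # Measurement noise on MSAD curves is multiplicative, so residuals
        # are taken in log space with weights y/stderr (equal to the linear
        # weighted residual to first order, but unbiased under lognormal
        # scatter).
        p = self.params_of(x)
        offset = 10 ** x[3]
        curve = theta_msad_model(
            self.lags, p, self.band, static_offset=offset, n_nodes=self.n_nodes
        )
        r_curve = np.log(curve / self.y) * (self.y / self.sy)
        asym = theta_msad_asymptote(p, self.band) + offset
        r_asym = np.log(asym / (2.0 * self.var)) * (self.var / self.var_sd)
        res = [r_curve, [r_asym]]
        if self.offset_prior is not None:
            val, log_sd = self.offset_prior
            res.append([(x[3] - np.log10(val)) / log_sd])
        return np.concatenate(res)

    def chi2(self, x):
        return float(np.sum(self.residuals(x) ** 2))

    def fit_from(self, x0, fixed_mask=None, fixed_vals=None):
        """Least-squares fit; optionally freeze a subset of parameters."""
        if fixed_mask is None:
            fun, lo, hi, x0f = self.residuals, self.BOUNDS_LO, self.BOUNDS_HI, x0
        else:
            free = ~fixed_mask

            def fun(xf):
                x = np.array(fixed_vals, float)
                x[free] = xf
                return self.residuals(x)

            lo, hi, x0f = self.BOUNDS_LO[free], self.BOUNDS_HI[free], x0[free]
        sol = least_squares(
            fun, np.clip(x0f, lo, hi), bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
            gtol=1e-10,
        )
        if fixed_mask is None:
            return sol.x, float(2 * sol.cost)
        x = np.array(fixed_vals, float)
        x[~fixed_mask] = sol.x
        return x, float(2 * sol.cost)

    def multistart(self, n_starts=8, seed=0):
        rng = np.random.default_rng(seed)
        # smart start: kappa from the asymptote at sigma -> 0, mid-range b
        asym = max(2.0 * self.var - self.y.min(), 1e-4)
        kc_guess = (
            self.kBT / (2 * np.pi * asym) * np.log(self.band.q_max / self.band.q_min) * 2
        )
        starts = [
            np.array([np.log10(max(kc_guess / self.kBT, 1.0)), -6.0, 8.8,
                      np.log10(max(self.y.min() / 2, 1e-7))])
        ]
        for _ in range(n_starts - 1):
            starts.append(rng.uniform(self.BOUNDS_LO + 0.5, self.BOUNDS_HI - 0.5))
        best = None
        for x0 in starts:
            try:
                x, c2 = self.fit_from(x0)
            except Exception:
                continue
            if best is None or c2 < best[1]:
                best = (x, c2)
        if best is None:
            raise RuntimeError("all multi-start fits failed")
        return best


def fit_membrane_params(
    theta_msd: LagStatistic,
    theta_variance: tuple[float, float],
    band: WavenumberBand,
    fixed: dict | None = None,
    kBT: float = KBT_ROOM,
    n_starts: int = 8,
    seed: int = 0,
    compute_profiles: bool = False,
    offset_prior: tuple[float, float] | None = None,
) -> MembraneFitResult:
    """Simultaneous fit of the out-of-plane MSAD curve and its
    variance-derived asymptote (2<theta^2>) for (kappa_c, sigma, b,
    static_offset).

    ``theta_variance`` is (value, stderr) of <theta^2>; ``fixed`` supplies
    nominal epsilon, d, eta (literature values, not fitted).  Parameters are
    fitted in log space (positivity); multi-start guards against the shallow
    b direction.  ``offset_prior`` = (value, log10-sd) softly anchors the
    static offset at the known instrument noise floor; the offset is poorly
    identified by the curve alone (it is a few percent of the shortest-lag
    signal) and letting it float degrades kappa_c and sigma through their
    mutual correlation.
    """
    prob = _MembraneFitProblem(theta_msd, theta_variance, band, fixed or {},
                               kBT, offset_prior=offset_prior)
    x, chi2 = prob.multistart(n_starts=n_starts, seed=seed)
    result = MembraneFitResult(
        kappa_c=10 ** x[0] * kBT,
        sigma=10 ** x[1],
        b=10 ** x[2],
        static_offset=10 ** x[3],
        chi2=chi2,
        kBT=kBT,
        meta={"x_log10": x.tolist(), "n_starts": n_starts, "seed": seed,
              "n_lags": int(theta_msd.lags.size)},
    )
    if compute_profiles:
        chi2_sensitivity(result, theta_msd, theta_variance, band, fixed, kBT)
    return result


_PARAM_INDEX = {"kappa_c": 0, "sigma": 1, "b": 2, "static_offset": 3}


def chi2_sensitivity(
    fit: MembraneFitResult,
    theta_msd: LagStatistic,
    theta_variance: tuple[float, float],
    band: WavenumberBand,
    fixed: dict | None = None,
    kBT: float = KBT_ROOM,
    half_width_dex: float = 0.6,
    n_scan: int = 13,
) -> dict:
    """1D chi-square profiles per fitted parameter (others re-optimized).

    Delta-chi2 = 1 crossings give 1-sigma intervals; a profile that stays
    below Delta-chi2 = 1 over the scanned range flags the parameter as
    unidentifiable on that side (e.g. tension below the detection floor).
    """
    prob = _MembraneFitProblem(theta_msd, theta_variance, band, fixed or {}, kBT)
    x_hat = np.array(fit.meta["x_log10"], float)
    chi2_min = fit.chi2
    for name, idx in _PARAM_INDEX.items():
        grid = x_hat[idx] + np.linspace(-half_width_dex, half_width_dex, n_scan)
        grid = np.clip(grid, prob.BOUNDS_LO[idx], prob.BOUNDS_HI[idx])
        prof = np.empty(n_scan)
        mask = np.zeros(4, dtype=bool)
        mask[idx] = True
        for i, g in enumerate(grid):
            xv = x_hat.copy()
            xv[idx] = g
            _, prof[i] = prob.fit_from(xv, fixed_mask=mask, fixed_vals=xv)
        fit.profiles[name] = (grid, prof)
        lo, hi = _delta_chi2_interval(grid, prof, chi2_min)
        scale = kBT if name == "kappa_c" else 1.0
        fit.intervals[name] = (
            10 ** lo * scale if np.isfinite(lo) else -np.inf,
            10 ** hi * scale if np.isfinite(hi) else np.inf,
        )
        fit.flags[f"{name}_lower_open"] = not np.isfinite(lo)
        fit.flags[f"{name}_upper_open"] = not np.isfinite(hi)
    return fit.profiles


def _delta_chi2_interval(grid, prof, chi2_min):
    """Delta-chi2 = 1 crossing points around the minimum (log-space)."""
    target = chi2_min + 1.0
    i_min = int(np.argmin(prof))
    lo = -np.inf
    for i in range(i_min, 0, -1):
        if prof[i - 1] >= target:
            # linear interpolation
            f = (target - prof[i]) / (prof[i - 1] - prof[i])
            lo = grid[i] + f * (grid[i - 1] - grid[i])
            break
    hi = np.inf
    for i in range(i_min, len(prof) - 1):
        if prof[i + 1] >= target:
            f = (target - prof[i]) / (prof[i + 1] - prof[i])
            hi = grid[i] + f * (grid[i + 1] - grid[i])
            break
    return lo, hi


def propagate_qmax_uncertainty(
    theta_msd: LagStatistic,
    theta_variance: tuple[float, float],
    R: float,
    l: float,
    dl: float,
    fixed: dict | None = None,
    kBT: float = KBT_ROOM,
    seed: int = 0,
) -> dict:
    """Refit at rod lengths l - dl and l + dl (q_max = 2 pi / l) and report
    the induced shifts of each fitted parameter."""
    if dl < 0:
        raise ValueError("dl must be >= 0")
    out = {}
    fits = {}
    for tag, ll in (("minus", l - dl), ("center", l), ("plus", l + dl)):
        band = WavenumberBand.from_geometry(R, ll)
        fits[tag] = fit_membrane_params(
            theta_msd, theta_variance, band, fixed=fixed, kBT=kBT, seed=seed
        )
    for name in ("kappa_c", "sigma", "b", "static_offset"):
        c = getattr(fits["center"], name)
        out[name] = {
            "center": c,
            "shift_minus": getattr(fits["minus"], name) - c,
            "shift_plus": getattr(fits["plus"], name) - c,
        }
    out["fits"] = fits
    return out


# ---------------------------------------------------------------------------
# cell analysis


def fit_cell_covariance(
    cov: LagStatistic,
    dq_over_q_range: tuple[float, float] = (0.2, 0.9),
    kBT: float = KBT_ROOM,
    tau_max: float = 5e-3,
) -> CellFitResult:
    """Fit A(tau) = A0 exp(-omega tau) to the short-lag out-of-plane angle
    covariance and invert the amplitude for the bending-rigidity range
    kappa_c = (kBT / 2 pi A0) * (dq/q) over the plausible dq/q band."""
    sel = cov.lags <= tau_max
    lags, vals = cov.lags[sel], cov.values[sel]
    err = np.maximum(cov.stderr[sel], 1e-300)
    if lags.size < 3 or np.any(vals <= 0):
        raise ValueError("covariance must be positive over the fitted lag range")

    a0_guess = cov.meta.get("variance", vals[0])
    w_guess = max(-np.polyfit(lags, np.log(vals), 1)[0], 1.0)
    popt, pcov = curve_fit(
        lambda t, a0, w: a0 * np.exp(-w * t),
        lags, vals, p0=[a0_guess, w_guess], sigma=err, absolute_sigma=True,
        maxfev=10000,
    )
    a0, omega = popt
    a0_se, om_se = np.sqrt(np.diag(pcov))
    lo_q, hi_q = dq_over_q_range
    kappa = lambda dq: kBT / (2 * np.pi * a0) * dq / kBT  # in kBT units
    return CellFitResult(
        omega=float(omega), omega_stderr=float(om_se),
        amplitude=float(a0), amplitude_stderr=float(a0_se),
        kappa_range=(float(kappa(lo_q)), float(kappa(hi_q))),
        dq_over_q_range=(lo_q, hi_q),
        kBT=kBT,
        meta={"tau_max": tau_max, "n_lags": int(lags.size)},
    )


def detect_msd_crossover(
    msd: LagStatistic,
    slope_threshold: float = 0.9,
    sustain: int = 3,
    max_rel_se: float = 0.10,
) -> dict:
    """Locate the caged-to-diffusive crossover of a cell MSD.

    Computes a locally smoothed log-log slope and finds the terminal run of
    lags over which the slope stays >= ``slope_threshold`` (the purely
    diffusive regime reached after escape from the corrals; for a purely
    diffusive walk the run extends back to the first lag).  Returns the MSD
    value at the start of that run (the crossover length scale squared) and
    the long-lag diffusivity from a weighted linear fit (with intercept)
    over the run.  If no sustained terminal diffusive regime exists, returns
    ``found=False``.
    """
    # drop the noise-dominated long-lag tail before slope analysis
    rel = msd.stderr / np.maximum(np.abs(msd.values), 1e-300)
    keep = rel <= max_rel_se
    if keep.sum() < sustain + 2:
        keep = np.ones(msd.lags.size, dtype=bool)
    msd = LagStatistic(
        lags=msd.lags[keep], values=msd.values[keep], stderr=msd.stderr[keep],
        n_pairs=msd.n_pairs[keep], kind=msd.kind, meta=msd.meta,
    )
    lx = np.log(msd.lags)
    ly = np.log(np.maximum(msd.values, 1e-300))
    n = lx.size
    if n < sustain + 2:
        raise ValueError("MSD too short for crossover detection")
    # smoothed local slope: centered linear fit over a 5-point window
    half = 2
    slope = np.empty(n)
    for i in range(n):
        s = slice(max(0, i - half), min(n, i + half + 1))
        slope[i] = np.polyfit(lx[s], ly[s], 1)[0]
    below = np.nonzero(slope < slope_threshold)[0]
    idx = 0 if below.size == 0 else int(below[-1]) + 1
    if n - idx < sustain:
        return {"found": False, "crossover_scale": None, "D_t_long": None,
                "reason": "no sustained diffusive regime"}
    sel = np.arange(n) >= idx
    # weighted linear fit MSD = 4 D tau + c beyond the crossover
    w = 1.0 / np.maximum(msd.stderr[sel], 1e-300) ** 2
    A = np.column_stack([msd.lags[sel], np.ones(sel.sum())])
    coef, *_ = np.linalg.lstsq((A * w[:, None] ** 0.5),
                               msd.values[sel] * w**0.5, rcond=None)
    D_long = coef[0] / 4.0
    if D_long <= 0:
        return {"found": False, "crossover_scale": None, "D_t_long": None,
                "reason": "non-positive long-lag slope"}
    return {
        "found": True,
        "crossover_scale": float(msd.values[idx]),
        "crossover_lag": float(msd.lags[idx]),
        "D_t_long": float(D_long),
    }
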