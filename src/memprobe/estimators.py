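"""Kinematic estimators for nanorod tracking data.

Turns raw position/orientation trajectories into lag statistics: MSD, raw
(octant-folded) and physical MSAD, membrane-normal estimation by windowed
plane fits, out-of-plane angle series, and angle covariance.

Lag statistics use overlapping pairs with a block-decorrelated standard
error (pairs separated by less than one lag share data and are not counted
as independent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PositionTrajectory",
    "OrientationTrajectory",
    "NormalSeries",
    "LagStatistic",
    "OctantMap",
    "log_lag_grid",
    "compute_msd",
    "compute_msad_raw",
    "raw_to_physical_msad",
    "estimate_normals",
    "out_of_plane_angles",
    "in_plane_angles",
    "compute_theta_msd",
    "compute_angle_covariance",
    "theta_msd_from_covariance",
]

DEG = np.pi / 180.0


@dataclass
class PositionTrajectory:
    """Timestamped positions; for vesicle recordings the sphere geometry
    (center, radius) is known and z can be reconstructed from it."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    center: tuple[float, float] = (0.0, 0.0)
    R: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.z is None and self.R is not None:
            self.z = self.reconstruct_z()
            self.meta.setdefault("z_derived", True)

    def reconstruct_z(self) -> np.ndarray:
        """Depth on the sphere: z = sqrt(R^2 - (x-xc)^2 - (y-yc)^2)."""
        if self.R is None:
            raise ValueError("sphere radius required to reconstruct z")
        xc, yc = self.center
        r2 = (np.asarray(self.x) - xc) ** 2 + (np.asarray(self.y) - yc) ** 2
        if np.any(r2 > self.R**2 * (1 + 1e-9)):
            raise ValueError("samples outside the sphere")
        return np.sqrt(np.maximum(self.R**2 - r2, 0.0))

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def xyz(self) -> np.ndarray:
        cols = [self.x, self.y] + ([self.z] if self.z is not None else [])
        return np.column_stack(cols)

    def radial_unit(self) -> np.ndarray:
        """Unit vectors from sphere center to each sample."""
        if self.R is None:
            raise ValueError("sphere geometry required")
        xc, yc = self.center
        v = np.column_stack([self.x - xc, self.y - yc, self.z])
        return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass
class OrientationTrajectory:
    """Timestamped unit orientation vectors, octant-mapped (all components
    >= 0) when ``octant`` is set; ``angular_noise`` records the instrument
    precision in radians (default 1 degree)."""

    t: np.ndarray
    u: np.ndarray
    octant: bool = False
    angular_noise: float = 1.0 * DEG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        norms = np.linalg.norm(self.u, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"orientation row {bad} is not unit norm (|u| = {norms[bad]:.6f})"
            )
        if self.octant and np.any(self.u < -1e-12):
            raise ValueError("octant-mapped orientations must be non-negative")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class NormalSeries:
    """Windowed membrane-normal estimates and derived angle series."""

    t: np.ndarray
    n: np.ndarray
    r_hat: np.ndarray | None = None
    theta: np.ndarray | None = None
    tilt: np.ndarray | None = None
    theta_parallel: np.ndarray | None = None
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class LagStatistic:
    """A lag-dependent statistic (MSD/MSAD/covariance) with standard errors
    and effective pair counts."""

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_pairs: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        if self.lags.size == 0:
            raise ValueError("empty lag grid")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def log_lag_grid(dt: float, span: float, per_decade: int = 15) -> np.ndarray:
    """Log-spaced lag grid from dt to span/4, ~per_decade points per decade,
    snapped to integer multiples of dt."""
    hi = span / 4.0
    if hi <= dt:
        return np.array([dt])
    n = max(2, int(np.ceil(np.log10(hi / dt) * per_decade)))
    lags = np.geomspace(dt, hi, n)
    steps = np.unique(np.maximum(1, np.round(lags / dt).astype(int)))
    return steps * dt


def _lag_steps(lags, dt, n_samples, kind):
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag list")
    steps = np.round(lags / dt).astype(int)
    ok = (steps >= 1) & (steps < n_samples)
    if not np.all(ok):
        warnings.warn(
            f"{kind}: {np.sum(~ok)} lag(s) outside the record span were omitted",
            stacklevel=3,
        )
    steps = np.unique(steps[ok])
    if steps.size == 0:
        raise ValueError("no requested lag lies within the record span")
    return steps


def _pair_statistic(series: np.ndarray, steps: np.ndarray, dt: float, kind: str):
    """Time-averaged squared-displacement statistic over overlapping pairs.

    ``series`` is (N,) or (N, d); squared displacements are summed over d.
    stderr uses a block-decorrelated count: pairs a full lag apart are
    treated as independent.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n = series.shape[0]
    values, stderr, n_pairs = [], [], []
    for k in steps:
        d = series[k:] - series[:-k]
        sq = (d**2).sum(axis=1)
        m = sq.mean()
        n_eff = max(1, (n - k) // k)
        values.append(m)
        stderr.append(sq.std(ddof=1) / np.sqrt(n_eff) if sq.size > 1 else 0.0)
        n_pairs.append(n - k)
    return LagStatistic(
        lags=steps * dt,
        values=np.array(values),
        stderr=np.array(stderr),
        n_pairs=np.array(n_pairs),
        kind=kind,
        meta={"overlapping": True},
    )


def compute_msd(traj: PositionTrajectory, lags) -> LagStatistic:
    """Translational MSD <|r(t+tau) - r(t)|^2> over overlapping pairs."""
    xyz = traj.xyz()
    if xyz.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    steps = _lag_steps(lags, traj.dt, xyz.shape[0], "msd")
    return _pair_statistic(xyz, steps, traj.dt, "msd")


def compute_msad_raw(traj: OrientationTrajectory, lags) -> LagStatistic:
    """Raw MSAD <|u(t+tau) - u(t)|^2> of (possibly octant-folded) orientations.

    For octant-mapped input this is bounded at long lags and must be mapped
    to a physical MSAD with :func:`raw_to_physical_msad`.
    """
    steps = _lag_steps(lags, traj.dt, traj.u.shape[0], "msad_raw")
    out = _pair_statistic(traj.u, steps, traj.dt, "msad_raw")
    out.meta["octant"] = traj.octant
    return out


# ---------------------------------------------------------------------------
# octant raw -> physical mapping


class OctantMap:
    """Monotone mapping between the physical MSAD of a rotor and the raw MSAD
    of its octant-folded orientation.

    The physical MSAD is the unbounded mean-squared (unwrapped) rotation
    angle <dphi^2>; the raw MSAD is the mean squared chord of the folded
    unit vector.  The forward map is tabulated from the stated geometry and
    inverted by monotone (PCHIP) interpolation.

    Geometries
    ----------
    ``planar_rotor``
        Rod rotating in a coordinate plane; folding takes componentwise
        absolute values.  The forward expectation is computed by dense
        quadrature over the stationary phase and the Gaussian increment
        (no Monte Carlo).
    ``tilted_rotor``
        Rod rotating in a uniformly random oriented plane; forward map
        averaged over plane orientations by seeded Monte Carlo.
    """

    def __init__(self, geometry: str = "planar_rotor", m_max: float = 4.0,
                 n_grid: int = 121, seed: int = 12345):
        self.geometry = geometry
        grid = np.linspace(0.0, m_max, n_grid)
        if geometry == "planar_rotor":
            raw = self._forward_planar(grid)
        elif geometry == "tilted_rotor":
            raw = self._forward_tilted(grid, seed)
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        # enforce strict monotonicity for the inverse interpolant
        raw = np.maximum.accumulate(raw)
        keep = np.concatenate([[True], np.diff(raw) > 1e-12])
        self._phys_grid = grid[keep]
        self._raw_grid = raw[keep]
        self.saturation = float(raw[-1])
        self._fwd = PchipInterpolator(self._phys_grid, self._raw_grid)
        self._inv = PchipInterpolator(self._raw_grid, self._phys_grid)

    @staticmethod
    def _forward_planar(m_grid: np.ndarray) -> np.ndarray:
        """E[raw | physical = m] for a rotor folded in its own plane.

        raw(m) = E_{dphi ~ N(0, m)} g(dphi) with
        g(d) = 2 - (2/pi) Int_0^{2pi} |cos(p+d) cos p| dp  (phase-averaged).
        """
        p = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
        cos_p = np.cos(p)

        def g(deltas):
            # c(d) = phase average of |cos(p+d) cos(p)|; sin term equals it
            c = np.abs(np.cos(p[None, :] + deltas[:, None]) * cos_p).mean(axis=1)
            return 2.0 - 4.0 * c

        out = np.empty_like(m_grid)
        for i, m in enumerate(m_grid):
            if m == 0:
                out[i] = 0.0
                continue
            s = np.sqrt(m)
            d = np.linspace(-6 * s, 6 * s, 801)
            pdf = np.exp(-0.5 * (d / s) ** 2) / (s * np.sqrt(2 * np.pi))
            out[i] = np.trapezoid(g(d) * pdf, d)
        return out

    @staticmethod
    def _forward_tilted(m_grid: np.ndarray, seed: int) -> np.ndarray:
        """Monte Carlo forward map for a rotor in a random tilted plane."""
        rng = np.random.default_rng(seed)
        n = 200_000
        # random orthonormal frames (e1, e2)
        a = rng.normal(size=(n, 3))
        e1 = a / np.linalg.norm(a, axis=1, keepdims=True)
        b = rng.normal(size=(n, 3))
        b -= (b * e1).sum(axis=1, keepdims=True) * e1
        e2 = b / np.linalg.norm(b, axis=1, keepdims=True)
        phi1 = rng.uniform(0, 2 * np.pi, size=n)
        z = rng.normal(size=n)
        out = np.empty_like(m_grid)
        for i, m in enumerate(m_grid):
            phi2 = phi1 + np.sqrt(m) * z
            u1 = np.abs(np.cos(phi1)[:, None] * e1 + np.sin(phi1)[:, None] * e2)
            u2 = np.abs(np.cos(phi2)[:, None] * e1 + np.sin(phi2)[:, None] * e2)
            out[i] = ((u2 - u1) ** 2).sum(axis=1).mean()
        return out

    def forward(self, physical):
        """Raw MSAD produced by folding at the given physical MSAD."""
        return self._fwd(np.clip(physical, 0, self._phys_grid[-1]))

    def invert(self, raw):
        """Physical MSAD for a raw value; NaN at/above saturation."""
        raw = np.asarray(raw, dtype=float)
        out = np.where(
            raw < self.saturation, self._inv(np.clip(raw, 0, self.saturation)), np.nan
        )
        return out

    def derivative(self, raw):
        """d(physical)/d(raw), for propagating standard errors."""
        return self._inv.derivative()(np.clip(raw, 0, self.saturation))


_MAP_CACHE: dict[str, OctantMap] = {}


def get_octant_map(geometry: str = "planar_rotor") -> OctantMap:
    if geometry not in _MAP_CACHE:
        _MAP_CACHE[geometry] = OctantMap(geometry)
    return _MAP_CACHE[geometry]


def raw_to_physical_msad(
    raw: LagStatistic, geometry: str = "planar_rotor"
) -> LagStatistic:
    """Map a raw (octant-folded) MSAD to the physical unbounded MSAD.

    Values at or above the folding saturation cannot be inverted; they are
    dropped (reported in ``meta['n_unmappable']``), never extrapolated.
    """
    omap = get_octant_map(geometry)
    phys = omap.invert(raw.values)
    ok = np.isfinite(phys)
    n_bad = int(np.sum(~ok))
    if n_bad:
        warnings.warn(
            f"{n_bad} raw MSAD value(s) at/above the folding saturation "
            f"({omap.saturation:.4f}) were flagged unmappable",
            stacklevel=2,
        )
    if not np.any(ok):
        raise ValueError("no raw MSAD value is below the folding saturation")
    deriv = omap.derivative(raw.values[ok])
    return LagStatistic(
        lags=raw.lags[ok],
        values=phys[ok],
        stderr=raw.stderr[ok] * np.abs(deriv),
        n_pairs=raw.n_pairs[ok],
        kind="msad_physical",
        meta={**raw.meta, "geometry": geometry, "n_unmappable": n_bad},
    )


# ---------------------------------------------------------------------------
# membrane-normal estimation


def unfold_octant(u_folded: np.ndarray, u0: np.ndarray | None = None) -> np.ndarray:
    """Greedy sign reconstruction of octant-folded orientations.

    Each sample's component signs are chosen to maximize continuity with the
    previous reconstructed sample (valid at high sampling rates, where the
    rod rotates by a small angle per frame)."""
    u = np.array(u_folded, dtype=float)
    prev = u[0] if u0 is None else np.asarray(u0, dtype=float)
    out = np.empty_like(u)
    for i in range(u.shape[0]):
        s = np.where(prev * u[i] < 0, -1.0, 1.0)
        out[i] = s * u[i]
        prev = out[i]
    return out


_SIGN_PATTERNS = np.array(
    [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float
)


def _plane_fit(block: np.ndarray):
    """Least-variance direction of a (W, 3) set (plane through the origin).
    Returns (normal, degenerate_flag)."""
    _, sv, vt = np.linalg.svd(block, full_matrices=True)
    if sv[1] < 1e-8 * sv[0]:
        return None, True
    return vt[2], False


def _octant_objective(folded: np.ndarray, n_hat: np.ndarray) -> float:
    """Mean squared out-of-plane residual after optimal sign reassignment."""
    cand = np.einsum("pk,wk->pw", _SIGN_PATTERNS * n_hat, folded)
    return float((np.abs(cand).min(axis=0) ** 2).mean())


def _grid_directions(n: int = 128) -> np.ndarray:
    """Quasi-uniform hemisphere directions (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere suffices: n and -n define the same plane
    phi = np.pi * (1 + np.sqrt(5)) * i
    s = np.sqrt(1 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


_GRID = _grid_directions()


def _octant_plane_fit(folded: np.ndarray, n_init: np.ndarray | None,
                      n_iter: int = 6):
    """Plane fit of octant-folded orientations.

    Folding destroys component signs, so folded points do not lie on a
    plane.  Each sample's signs are chosen (among the four patterns modulo
    global sign) to minimize |u . n| against the current normal, the plane
    is refit by SVD, and the assignment is iterated to a fixed point.  The
    Folded data constrain the normal only up to the signs of its components
    (all variants (+-nx, +-ny, +-nz) fold identically), so an anchor --
    the previous window's normal or the outward radial direction -- selects
    the physical branch; its solution is kept unless it fits poorly, in
    which case a coarse hemisphere grid search restarts the iteration.
    """

    def iterate(n0):
        n_hat = n0
        for _ in range(n_iter):
            cand = np.einsum("pk,wk->pw", _SIGN_PATTERNS * n_hat, folded)
            pick = np.argmin(np.abs(cand), axis=0)
            signed = _SIGN_PATTERNS[pick] * folded
            n_new, degen = _plane_fit(signed)
            if degen:
                return None
            if n_new @ n_hat < 0:
                n_new = -n_new
            converged = abs(n_new @ n_hat) > 1.0 - 1e-12
            n_hat = n_new
            if converged:
                break
        return n_hat

    if n_init is not None:
        n_a = iterate(np.asarray(n_init, float) / np.linalg.norm(n_init))
        # rms out-of-plane residual below ~4 degrees: trust the anchor basin
        if n_a is not None and _octant_objective(folded, n_a) < 5e-3:
            return n_a, False
    scores = [_octant_objective(folded, g) for g in _GRID]
    n_b = iterate(_GRID[int(np.argmin(scores))])
    if n_b is None:
        return None, True
    return n_b, False


def estimate_normals(
    traj: OrientationTrajectory,
    window: int = 20,
    stride: int | None = None,
    positions: PositionTrajectory | None = None,
) -> NormalSeries:
    """Estimate the membrane normal per window by an SVD plane fit.

    The rod lies prone in the membrane and its in-plane rotation decorrelates
    within a window, so the window's orientation vectors span the local
    tangent plane; the normal is the singular direction of least variance of
    the (window, 3) orientation matrix (plane through the origin).  The
    procedure assumes the normal moves slowly compared to the in-plane
    rotation over one window.

    For octant-mapped input the component signs are reassigned against the
    current plane estimate and the fit iterated (see
    :func:`_octant_plane_fit`), seeded by the outward radial direction when
    vesicle ``positions`` are given, else by the previous window's normal.
    Windows with nearly collinear orientations leave the plane undetermined
    and are flagged invalid.  Signs are fixed by continuity and, on a
    vesicle, anchored outward (n . r_hat >= 0).
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    stride = window if stride is None else stride
    n_samp = traj.u.shape[0]
    starts = np.arange(0, n_samp - window + 1, stride)
    if starts.size == 0:
        raise ValueError("trajectory shorter than one window")

    anchor = None
    if positions is not None and positions.R is not None:
        r = positions.radial_unit()
        anchor = np.stack([r[s : s + window].mean(axis=0) for s in starts])
        anchor /= np.linalg.norm(anchor, axis=1, keepdims=True)

    u_signed = None
    if traj.octant and anchor is None:
        u_signed = unfold_octant(traj.u)

    normals = np.full((starts.size, 3), np.nan)
    valid = np.ones(starts.size, dtype=bool)
    t_mid = np.empty(starts.size)
    prev = None
    for j, s in enumerate(starts):
        t_mid[j] = traj.t[s : s + window].mean()
        block = traj.u[s : s + window]
        if traj.octant:
            if anchor is not None:
                n_init = anchor[j]
            elif prev is not None:
                n_init = prev
            else:
                n0, degen = _plane_fit(u_signed[s : s + window])
                if degen:
                    valid[j] = False
                    continue
                n_init = n0
            n_hat, degen = _octant_plane_fit(block, n_init)
        else:
            n_hat, degen = _plane_fit(block)
        if degen:
            valid[j] = False
            continue
        normals[j] = n_hat
        prev = n_hat

    # sign continuity, then optional radial anchoring
    prev = None
    for j in range(starts.size):
        if not valid[j]:
            continue
        if prev is not None and normals[j] @ prev < 0:
            normals[j] = -normals[j]
        prev = normals[j]
    if anchor is not None:
        flip = np.einsum("ij,ij->i", np.nan_to_num(normals), anchor) < 0
        normals[flip] = -normals[flip]

    return NormalSeries(
        t=t_mid,
        n=normals,
        valid=valid,
        meta={"window": window, "stride": stride, "octant_input": traj.octant},
    )


def _window_centers(values: np.ndarray, window: int, stride: int) -> np.ndarray:
    starts = np.arange(0, values.shape[0] - window + 1, stride)
    return np.stack([values[s : s + window].mean(axis=0) for s in starts])


def radial_anchor_for(positions: PositionTrajectory, normals: NormalSeries):
    """Window-averaged outward radial unit vectors matching a NormalSeries."""
    w, s = normals.meta["window"], normals.meta["stride"]
    r = _window_centers(positions.radial_unit(), w, s)
    return r / np.linalg.norm(r, axis=1, keepdims=True)


def out_of_plane_angles(
    normals: NormalSeries,
    reference: str = "sphere_radial",
    positions: PositionTrajectory | None = None,
) -> NormalSeries:
    """Out-of-plane angle series theta = arccos(n . ref) and the signed
    two-component tilt of n about the reference direction.

    ``sphere_radial`` uses the outward radial direction of the vesicle at
    each window (requires ``positions`` with sphere geometry);
    ``mean_plane`` uses the trajectory-mean normal (cell recordings).
    """
    ok = normals.valid if normals.valid is not None else np.ones(len(normals.t), bool)
    if reference == "sphere_radial":
        if positions is None or positions.R is None:
            raise ValueError("sphere_radial reference requires vesicle positions")
        ref = radial_anchor_for(positions, normals)
    elif reference == "mean_plane":
        m = np.nanmean(np.where(ok[:, None], normals.n, np.nan), axis=0)
        ref = np.tile(m / np.linalg.norm(m), (len(normals.t), 1))
    else:
        raise ValueError(f"unknown reference {reference!r}")

    n = normals.n
    dot = np.clip(np.einsum("ij,ij->i", np.nan_to_num(n), ref), -1.0, 1.0)
    theta = np.where(ok, np.arccos(dot), np.nan)

    # tangent basis about the reference direction (continuous by projection
    # of a fixed helper axis)
    helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(ref, helper)
    bad = np.linalg.norm(e1, axis=1) < 1e-6
    if np.any(bad):
        e1[bad] = np.cross(ref[bad], np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(ref, e1)
    tilt = np.column_stack(
        [np.einsum("ij,ij->i", np.nan_to_num(n), e1),
         np.einsum("ij,ij->i", np.nan_to_num(n), e2)]
    )
    tilt[~ok] = np.nan

    return NormalSeries(
        t=normals.t,
        n=normals.n,
        r_hat=ref,
        theta=theta,
        tilt=tilt,
        valid=ok,
        meta={**normals.meta, "reference": reference},
    )


def in_plane_angles(traj: OrientationTrajectory, n_bar: np.ndarray) -> np.ndarray:
    """Unwrapped in-plane azimuth of the rod orientation about n_bar (rad)."""
    n_bar = np.asarray(n_bar, dtype=float)
    n_bar = n_bar / np.linalg.norm(n_bar)
    u = unfold_octant(traj.u) if traj.octant else traj.u
    helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n_bar, helper)
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n_bar, np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_bar, e1)
    phi = np.arctan2(u @ e2, u @ e1)
    return np.unwrap(phi)


# ---------------------------------------------------------------------------
# scalar/tilt lag statistics


def _series_dt(t) -> float:
    t = np.asarray(t, dtype=float)
    return float(np.median(np.diff(t)))


def compute_theta_msd(theta: np.ndarray, lags, dt: float) -> LagStatistic:
    """MSD of an angle series: scalar <(x(t+tau)-x(t))^2>, or the vector MSAD
    of the membrane normal when given an (N, 2) tilt-component series."""
    theta = np.asarray(theta, dtype=float)
    theta = theta[~np.isnan(theta).any(axis=-1)] if theta.ndim > 1 else theta[
        ~np.isnan(theta)
    ]
    steps = _lag_steps(lags, dt, theta.shape[0], "theta_msd")
    return _pair_statistic(theta, steps, dt, "theta_msd")


def compute_angle_covariance(
    theta: np.ndarray, lags, dt: float, subtract_mean: bool = True
) -> LagStatistic:
    """Lagged covariance A(tau) = <theta(t+tau) theta(t)> over overlapping
    pairs (series mean removed by default).

    ``meta['pair_var']`` holds, per lag, the mean of (theta(t)^2 +
    theta(t+tau)^2)/2 over the same pair set, so that
    2*pair_var - 2*A(tau) equals :func:`compute_theta_msd` exactly.
    """
    th = np.asarray(theta, dtype=float)
    th = th[~np.isnan(th)]
    if subtract_mean:
        th = th - th.mean()
    n = th.shape[0]
    steps = _lag_steps(lags, dt, n, "covariance")
    values, stderr, n_pairs, pair_var = [], [], [], []
    for k in steps:
        prod = th[k:] * th[:-k]
        n_eff = max(1, (n - k) // k)
        values.append(prod.mean())
        stderr.append(prod.std(ddof=1) / np.sqrt(n_eff) if prod.size > 1 else 0.0)
        n_pairs.append(n - k)
        pair_var.append(0.5 * ((th[k:] ** 2).mean() + (th[:-k] ** 2).mean()))
    return LagStatistic(
        lags=steps * dt,
        values=np.array(values),
        stderr=np.array(stderr),
        n_pairs=np.array(n_pairs),
        kind="covariance",
        meta={
            "overlapping": True,
            "mean_subtracted": subtract_mean,
            "pair_var": np.array(pair_var),
            "variance": float((th**2).mean()),
        },
    )


def theta_msd_from_covariance(cov: LagStatistic) -> np.ndarray:
    """<dtheta^2(tau)> = 2<theta^2> - 2<theta(t) theta(t+tau)>, evaluated on
    the covariance's own pair sets (exact algebraic identity)."""
    return 2.0 * cov.meta["pair_var"] - 2.0 * cov.values
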