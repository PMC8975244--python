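"""Dynamically triangulated Monte Carlo simulation of a closed membrane
with a bound rigid nanorod.

The membrane is a triangulated sphere-topology surface with Canham-Helfrich
bending energy (kappa/2)(c1+c2)^2 per unit area, discretized through a
per-vertex area-weighted shape operator built from edge dihedrals.  Vertex
displacement moves and edge (link) flips sample shape and connectivity;
tether bounds (edge length in [a0, sqrt(3) a0]) and vertex self-avoidance
enforce surface integrity, and a hard volume window controls the excess
area (tense vs floppy states).  The rod binds through a truncated-shifted
Lennard-Jones potential between evenly spaced sites on its axis and the
mesh vertices and moves by Metropolis translation/rotation.

MC sweeps are not physical time: comparisons with experiment are orderings
and exponents, never rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dtmc_core as core
from ._dtmc_core import MAXD

__all__ = [
    "TriMeshState",
    "RodState",
    "MCState",
    "icosphere",
    "init_mesh",
    "helfrich_energy",
    "vertex_curvatures",
    "DTMCSimulation",
    "undulation_spectrum",
    "measure_rod_observables",
]


# ---------------------------------------------------------------------------
# mesh construction


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron on the unit sphere: (vertices, triangles),
    triangles oriented outward (CCW seen from outside)."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(level):
        verts_list = list(verts)
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_tris = []
        for i, j, k in tris:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
            new_tris += [[i, a, c], [j, b, a], [k, c, b], [a, b, c]]
        verts = np.array(verts_list)
        tris = np.array(new_tris, dtype=np.int64)
    # orient outward
    for n in range(tris.shape[0]):
        i, j, k = tris[n]
        nrm = np.cross(verts[j] - verts[i], verts[k] - verts[i])
        if nrm @ (verts[i] + verts[j] + verts[k]) < 0:
            tris[n] = tris[n, ::-1]
    return verts, tris


def _build_adjacency(n_verts: int, tri: np.ndarray):
    """Fixed-width adjacency arrays from an oriented triangle list."""
    v_nbr = np.full((n_verts, MAXD), -1, dtype=np.int64)
    v_edge = np.full((n_verts, MAXD), -1, dtype=np.int64)
    v_deg = np.zeros(n_verts, dtype=np.int64)
    v_face = np.full((n_verts, MAXD), -1, dtype=np.int64)
    v_nfa = np.zeros(n_verts, dtype=np.int64)
    edge_id: dict[tuple[int, int], int] = {}
    edges_list = []
    edge_face_list = []
    for f, (i, j, k) in enumerate(tri):
        for v in (i, j, k):
            v_face[v, v_nfa[v]] = f
            v_nfa[v] += 1
        for a, b in ((i, j), (j, k), (k, i)):
            key = (min(a, b), max(a, b))
            if key not in edge_id:
                edge_id[key] = len(edges_list)
                edges_list.append([a, b])
                edge_face_list.append([f, -1])
                e = edge_id[key]
                v_nbr[a, v_deg[a]] = b
                v_edge[a, v_deg[a]] = e
                v_deg[a] += 1
                v_nbr[b, v_deg[b]] = a
                v_edge[b, v_deg[b]] = e
                v_deg[b] += 1
            else:
                edge_face_list[edge_id[key]][1] = f
    edges = np.array(edges_list, dtype=np.int64)
    edge_face = np.array(edge_face_list, dtype=np.int64)
    if np.any(edge_face < 0):
        raise ValueError("mesh is not a closed 2-manifold")
    return v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face


@dataclass
class TriMeshState:
    """Triangulated membrane state (positions + mutable connectivity)."""

    pos: np.ndarray
    tri: np.ndarray
    v_nbr: np.ndarray
    v_edge: np.ndarray
    v_deg: np.ndarray
    v_face: np.ndarray
    v_nfa: np.ndarray
    edges: np.ndarray
    edge_face: np.ndarray
    a0: float
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_triangulation(cls, pos, tri, a0):
        adj = _build_adjacency(pos.shape[0], tri)
        return cls(np.ascontiguousarray(pos, dtype=float),
                   np.ascontiguousarray(tri), *adj, a0=a0)

    @property
    def n_vertices(self) -> int:
        return self.pos.shape[0]

    def euler_characteristic(self) -> int:
        return self.pos.shape[0] - self.edges.shape[0] + self.tri.shape[0]

    def edge_lengths(self) -> np.ndarray:
        d = self.pos[self.edges[:, 0]] - self.pos[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def volume(self) -> float:
        return float(core.total_volume(self.pos, self.tri))

    def area(self) -> float:
        return float(core.total_area(self.pos, self.tri))

    def reduced_volume(self) -> float:
        R_A = np.sqrt(self.area() / (4 * np.pi))
        return self.volume() / (4 * np.pi / 3 * R_A**3)

    def check_integrity(self) -> None:
        """Assert manifold invariants (debug aid; O(N^2) self-avoidance)."""
        assert self.euler_characteristic() == 2
        le = self.edge_lengths()
        assert le.min() >= self.a0 * (1 - 1e-9)
        assert le.max() <= np.sqrt(3) * self.a0 * (1 + 1e-9)
        d2 = ((self.pos[:, None, :] - self.pos[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= self.a0 * (1 - 1e-9)

    def copy(self) -> "TriMeshState":
        return TriMeshState(
            self.pos.copy(), self.tri.copy(), self.v_nbr.copy(),
            self.v_edge.copy(), self.v_deg.copy(), self.v_face.copy(),
            self.v_nfa.copy(), self.edges.copy(), self.edge_face.copy(),
            self.a0, dict(self.meta),
        )


@dataclass
class RodState:
    """Rigid rod bound to the membrane: center, unit axis, length, and the
    number of evenly spaced binding sites along the axis."""

    center: np.ndarray
    axis: np.ndarray
    length: float
    n_sites: int = 9

    def sites(self) -> np.ndarray:
        out = np.empty((self.n_sites, 3))
        core.rod_sites(self.center, self.axis, self.length, self.n_sites, out)
        return out


@dataclass
class MCState:
    """MC parameters (energies in kBT, lengths in bead units a0-ish)."""

    kappa: float = 10.0
    amp_vertex: float = 0.12
    amp_rod_t: float = 0.10
    amp_rod_r: float = 0.06
    amp_rod_spin: float = 0.30
    n_rod_moves: int = 60
    lj_eps: float = 1.5
    lj_r_min: float = 1.0          # in units of a0
    lj_cut_factor: float = 3.5     # cutoff = factor * r_min
    v_window_frac: float = 0.005
    a_window_frac: float = 0.01
    do_flips: bool = True
    seed: int = 0
    counters: np.ndarray = field(
        default_factory=lambda: np.zeros(10, dtype=np.int64)
    )

    def acceptance(self) -> dict:
        c = self.counters
        names = ("vertex", "flip", "rod_translate", "rod_rotate", "rod_spin")
        return {
            nm: (c[2 * i] / c[2 * i + 1] if c[2 * i + 1] else float("nan"))
            for i, nm in enumerate(names)
        }

    def lj_params(self, a0: float) -> tuple[float, float, float, float]:
        """(eps, sigma^2, cutoff^2, shift) for the truncated-shifted LJ."""
        r_min = self.lj_r_min * a0
        sigma = r_min / 2 ** (1 / 6)
        rc = self.lj_cut_factor * r_min
        x6 = (sigma / rc) ** 6
        shift = 4.0 * self.lj_eps * (x6 * x6 - x6)
        return self.lj_eps, sigma**2, rc**2, shift


def init_mesh(level: int = 3, reduced_volume: float = 0.975) -> TriMeshState:
    """Icosphere mesh with tether scale a0 set from the initial edge lengths.

    ``reduced_volume`` < 1 is the target excess-area state (tense ~ 0.975,
    floppy ~ 0.85); the volume target is stored in ``meta`` and reached by
    annealing during burn-in.
    """
    if level < 2:
        raise ValueError("level must be >= 2 (at least 162 vertices)")
    if not 0.6 < reduced_volume <= 1.0:
        raise ValueError("reduced_volume must be in (0.6, 1]")
    verts, tris = icosphere(level)
    mesh = TriMeshState.from_triangulation(verts, tris, a0=1.0)
    le = mesh.edge_lengths()
    # scale so the shortest edge sits 10% above the tether floor a0 = 1
    scale = 1.1 / le.min()
    mesh.pos *= scale
    if mesh.edge_lengths().max() >= np.sqrt(3) * 0.98:
        raise ValueError("tether bounds infeasible for this triangulation")
    R_A = np.sqrt(mesh.area() / (4 * np.pi))
    mesh.meta["v_target"] = reduced_volume * 4 * np.pi / 3 * R_A**3
    mesh.meta["reduced_volume"] = reduced_volume
    mesh.meta["level"] = level
    return mesh


def helfrich_energy(
    mesh: TriMeshState, kappa: float, backend: str = "shape_operator"
) -> float:
    """Total bending energy sum_v (kappa/2)(c1+c2)^2 A_v (kBT units).

    ``shape_operator`` is the discretization used by the MC moves;
    ``cotan`` is an independent cotangent-Laplacian mean-curvature backend
    for cross-validation.
    """
    if backend == "shape_operator":
        if np.any(
            np.abs(np.linalg.norm(
                mesh.pos[mesh.tri[:, 1]] - mesh.pos[mesh.tri[:, 0]], axis=1
            )) < 1e-12
        ):
            raise ValueError("degenerate triangle")
        return float(
            core.total_energy(
                mesh.pos, mesh.tri, mesh.v_nbr, mesh.v_deg, mesh.v_face,
                mesh.v_nfa, kappa,
            )
        )
    if backend == "cotan":
        return _cotan_energy(mesh, kappa)
    raise ValueError(f"unknown backend {backend!r}")


def _cotan_energy(mesh: TriMeshState, kappa: float) -> float:
    """Cotangent-Laplacian backend: E_v = (kappa/2) |K_v|^2 A_v with the
    discrete mean-curvature normal K_v = (1/2A_v) sum (cot a + cot b) e."""
    pos, tri = mesh.pos, mesh.tri
    n = pos.shape[0]
    K = np.zeros((n, 3))
    A = np.zeros(n)
    for f in range(tri.shape[0]):
        i, j, k = tri[f]
        for (a, b, c) in ((i, j, k), (j, k, i), (k, i, j)):
            # angle at c, opposite edge (a, b)
            u = pos[a] - pos[c]
            v = pos[b] - pos[c]
            cot = (u @ v) / np.linalg.norm(np.cross(u, v))
            K[a] += cot * (pos[a] - pos[b])
            K[b] += cot * (pos[b] - pos[a])
        area = 0.5 * np.linalg.norm(np.cross(pos[j] - pos[i], pos[k] - pos[i]))
        for v_ in (i, j, k):
            A[v_] += area / 3.0
    # |K_acc|/(2A) = |mean-curvature normal| = 2H = c1 + c2
    h2 = (K**2).sum(axis=1) / (2 * A) ** 2
    return float(np.sum(0.5 * kappa * h2 * A))


def vertex_curvatures(mesh: TriMeshState) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex principal curvatures (c1, c2) from the tangent-projected
    shape operator (c1 >= c2)."""
    n = mesh.n_vertices
    c1 = np.empty(n)
    c2 = np.empty(n)
    S = np.empty((3, 3))
    for v in range(n):
        A_v, nx, ny, nz = core.vertex_shape_operator(
            v, mesh.pos, mesh.tri, mesh.v_nbr, mesh.v_deg, mesh.v_face,
            mesh.v_nfa, S,
        )
        if A_v <= 0:
            c1[v] = c2[v] = np.nan
            continue
        nv = np.array([nx, ny, nz])
        T = np.eye(3) - np.outer(nv, nv)
        St = T @ S @ T
        c2[v], c1[v] = np.sort(_tangent_eigs(St, nv))
    return c1, c2


def _tangent_eigs(St: np.ndarray, nv: np.ndarray) -> np.ndarray:
    """Eigenvalues of the shape operator within the tangent plane."""
    # orthonormal tangent basis
    h = np.array([1.0, 0.0, 0.0]) if abs(nv[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(nv, h)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nv, e1)
    M = np.array([[e1 @ St @ e1, e1 @ St @ e2], [e2 @ St @ e1, e2 @ St @ e2]])
    return np.linalg.eigvalsh(M)


# ---------------------------------------------------------------------------
# simulation driver


class DTMCSimulation:
    """Driver: burn-in with volume annealing and amplitude auto-tuning, then
    production sweeps with periodic sampling of rod and membrane state."""

    def __init__(self, mesh: TriMeshState, rod: RodState | None, mc: MCState):
        self.mesh = mesh
        self.mc = mc
        if rod is None:
            # inert rod far away (no LJ interaction within cutoff)
            rod = RodState(
                center=np.array([0.0, 0.0, 1e6]),
                axis=np.array([1.0, 0.0, 0.0]),
                length=3.5 * mesh.a0,
            )
        self.rod = rod
        core.seed_rng(mc.seed)
        self.volume = mesh.volume()
        self.area = mesh.area()
        self.v_target_final = mesh.meta.get("v_target", self.volume)
        # membranes are area-incompressible: the excess-area state is set by
        # deflating the volume at (near-)fixed total area
        self.a_target = mesh.meta.get("a_target", self.area)

    def _run(self, n_sweeps: int, v_target: float,
             v_window: float | None = None, v_penalty: float = 0.0,
             a_window: float | None = None, a_penalty: float = 0.0) -> None:
        m, mc = self.mesh, self.mc
        eps, s2, rc2, shift = mc.lj_params(m.a0)
        if v_window is None:
            v_window = mc.v_window_frac * abs(self.v_target_final)
        if a_window is None:
            a_window = mc.a_window_frac * self.a_target
        self.volume, self.area = core.run_sweeps(
            n_sweeps,
            m.pos, m.tri, m.v_nbr, m.v_edge, m.v_deg, m.v_face, m.v_nfa,
            m.edges, m.edge_face,
            mc.kappa, m.a0, mc.amp_vertex, v_target, v_window, v_penalty,
            self.volume,
            self.a_target, a_window, a_penalty, self.area,
            self.rod.center, self.rod.axis, self.rod.length, self.rod.n_sites,
            mc.amp_rod_t, mc.amp_rod_r, mc.amp_rod_spin, mc.n_rod_moves,
            eps, s2, rc2, shift,
            mc.counters, mc.do_flips,
        )

    def burn_in(self, n_sweeps: int = 300, tune: bool = True,
                max_anneal_bursts: int = 400) -> None:
        """Drive the volume to its target, then equilibrate.

        During annealing a soft harmonic volume penalty (inside a wide
        window) drives the volume to the target; the production run then
        uses the hard +/-0.5% window with no penalty, so burn-in bias does
        not affect sampled equilibrium.  ``n_sweeps`` equilibration sweeps
        run at the final target while the vertex amplitude is tuned toward
        30-50% acceptance; amplitudes are frozen afterwards (detailed
        balance holds for the production run).
        """
        final = self.v_target_final
        window = self.mc.v_window_frac * abs(final)
        a_window = self.mc.a_window_frac * self.a_target
        wide_v = 0.25 * abs(final)
        wide_a = 0.25 * self.a_target
        penalty = 2.0e6  # kBT per unit squared fractional deviation
        burst = 0
        while (abs(self.volume - final) > 0.5 * window
               or abs(self.area - self.a_target) > 0.5 * a_window):
            self._run(2, final, v_window=wide_v, v_penalty=penalty,
                      a_window=wide_a, a_penalty=penalty)
            burst += 1
            if burst > max_anneal_bursts:
                raise RuntimeError(
                    "anneal did not reach the target volume/area state"
                )
        n_stages = 10
        for _ in range(n_stages):
            before = self.mc.counters.copy()
            self._run(max(1, n_sweeps // n_stages), final)
            if tune:
                d = self.mc.counters - before
                acc = d[0] / max(d[1], 1)
                if acc < 0.30:
                    self.mc.amp_vertex *= 0.85
                elif acc > 0.50:
                    self.mc.amp_vertex = min(self.mc.amp_vertex * 1.15,
                                             0.5 * self.mesh.a0)
        self.mc.counters[:] = 0  # amplitudes frozen; restart statistics

    def run(self, n_sweeps: int, sample_every: int = 10,
            store_pos_every: int = 50) -> dict:
        """Production sweeps; returns sampled rod axis/center, the true local
        membrane normal near the rod, energy, volume and area series."""
        n_samples = n_sweeps // sample_every
        out = {
            "sweep": np.empty(n_samples, dtype=int),
            "rod_axis": np.empty((n_samples, 3)),
            "rod_center": np.empty((n_samples, 3)),
            "local_normal": np.empty((n_samples, 3)),
            "energy": np.empty(n_samples),
            "volume": np.empty(n_samples),
            "area": np.empty(n_samples),
            "pos_samples": [],
        }
        for s in range(n_samples):
            self._run(sample_every, self.v_target_final)
            out["sweep"][s] = (s + 1) * sample_every
            out["rod_axis"][s] = self.rod.axis
            out["rod_center"][s] = self.rod.center
            out["local_normal"][s] = local_membrane_normal(
                self.mesh, self.rod.center, radius=0.5 * self.rod.length
            )
            out["energy"][s] = helfrich_energy(self.mesh, self.mc.kappa)
            out["volume"][s] = self.volume
            out["area"][s] = self.mesh.area()
            if s % store_pos_every == 0:
                out["pos_samples"].append(self.mesh.pos.copy())
        return out


def local_membrane_normal(
    mesh: TriMeshState, point: np.ndarray, radius: float
) -> np.ndarray:
    """Area-weighted outward normal of the faces whose centroids lie within
    ``radius`` of ``point`` (the membrane patch under the rod)."""
    p0 = mesh.pos[mesh.tri[:, 0]]
    p1 = mesh.pos[mesh.tri[:, 1]]
    p2 = mesh.pos[mesh.tri[:, 2]]
    cent = (p0 + p1 + p2) / 3.0
    d2 = ((cent - point) ** 2).sum(axis=1)
    sel = d2 <= radius**2
    if not np.any(sel):
        sel = d2 <= np.partition(d2, 3)[3] + 1e-12  # nearest few faces
    nrm = np.cross(p1[sel] - p0[sel], p2[sel] - p0[sel]).sum(axis=0)
    return nrm / np.linalg.norm(nrm)


# ---------------------------------------------------------------------------
# observables


def undulation_spectrum(
    pos_samples: list[np.ndarray], l_max: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-spherical undulation spectrum from mesh snapshots.

    Projects the relative radial displacement u = r/<r> - 1 of each snapshot
    onto real spherical harmonics (quasi-uniform vertex quadrature) and
    averages |u_lm|^2 over m and snapshots.  Returns (l values, <|u_l|^2>).
    """
    from scipy.special import sph_harm_y

    ls = np.arange(2, l_max + 1)
    power = np.zeros(ls.size)
    count = np.zeros(ls.size)
    for pos in pos_samples:
        c = pos.mean(axis=0)
        d = pos - c
        r = np.linalg.norm(d, axis=1)
        u = r / r.mean() - 1.0
        theta = np.arccos(np.clip(d[:, 2] / r, -1, 1))
        phi = np.arctan2(d[:, 1], d[:, 0])
        w = 4 * np.pi / pos.shape[0]
        for i, l in enumerate(ls):
            for m in range(-l, l + 1):
                y = sph_harm_y(l, m, theta, phi)
                ulm = w * np.sum(u * np.conj(y))
                power[i] += np.abs(ulm) ** 2
                count[i] += 1
    return ls, power / count


def fit_spectrum_equipartition(
    ls: np.ndarray, power: np.ndarray
) -> tuple[float, float, float]:
    """Fit the quasi-spherical equipartition spectrum

        <|u_l|^2> = kBT / [kappa (l-1)(l+2) (l(l+1) + sbar)]

    for (kappa_eff in kBT, sbar = sigma R^2/kappa).  The fit minimizes
    log-space residuals (equal relative weight per mode, as the power spans
    decades).  Returns (kappa_eff, sbar, R^2 of log power).
    """
    from scipy.optimize import least_squares

    ls = np.asarray(ls, float)
    lp = np.log(power)

    def model(x):
        kap, sbar = np.exp(x[0]), x[1]
        den = kap * (ls - 1) * (ls + 2) * (ls * (ls + 1) + sbar)
        return -np.log(den)

    sol = least_squares(
        lambda x: model(x) - lp, x0=[np.log(10.0), 0.0],
        bounds=([-5, -5.9], [10, 1e4]),
    )
    kap, sbar = float(np.exp(sol.x[0])), float(sol.x[1])
    resid = model(sol.x) - lp
    r2 = 1.0 - np.sum(resid**2) / np.sum((lp - lp.mean()) ** 2)
    return kap, sbar, float(r2)


def measure_rod_observables(run: dict, window: int = 20) -> dict:
    """Rod statistics from a production run, referenced like the vesicle
    experiment: the in-plane angle is the rod-axis azimuth about the local
    radial direction (nematic, unwrapped mod pi) and the out-of-plane
    motion is the tilt of the true local membrane normal relative to the
    radial direction.  Also reports the angle delta between the true local
    normal and the normal inferred from the rod orientations by the
    windowed SVD plane fit used on experimental data."""
    from .estimators import (
        OrientationTrajectory,
        _pair_statistic,
        estimate_normals,
    )

    axis = run["rod_axis"]
    normal = run["local_normal"]
    center = run["rod_center"]
    sweeps = run["sweep"].astype(float)
    ds = sweeps[1] - sweeps[0]
    n = axis.shape[0]
    ks = np.unique(np.geomspace(1, max(2, n // 5), 20).astype(int))

    # radial reference at the rod position, with a parallel-transported
    # tangent frame
    r_hat = center / np.linalg.norm(center, axis=1, keepdims=True)
    e1 = np.empty_like(r_hat)
    e2 = np.empty_like(r_hat)
    h = np.array([0.0, 0.0, 1.0])
    if abs(r_hat[0] @ h) > 0.9:
        h = np.array([1.0, 0.0, 0.0])
    prev = h
    for i in range(n):
        v = prev - (prev @ r_hat[i]) * r_hat[i]
        e1[i] = v / np.linalg.norm(v)
        e2[i] = np.cross(r_hat[i], e1[i])
        prev = e1[i]

    # in-plane azimuth of the (nematic) rod axis, unwrapped mod pi
    phi = np.arctan2(np.einsum("ij,ij->i", axis, e2),
                     np.einsum("ij,ij->i", axis, e1))
    dphi = np.diff(phi)
    dphi = (dphi + np.pi / 2) % np.pi - np.pi / 2
    phi_unwrapped = np.concatenate([[phi[0]], dphi]).cumsum()
    msad = _pair_statistic(phi_unwrapped, ks, ds, "theta_msd")
    msad.kind = "msad_inplane"

    # out-of-plane tilt of the true local normal about the radial direction
    nrm = normal.copy()
    flip = np.einsum("ij,ij->i", nrm, r_hat) < 0
    nrm[flip] = -nrm[flip]
    tilt = np.column_stack(
        [np.einsum("ij,ij->i", nrm, e1), np.einsum("ij,ij->i", nrm, e2)]
    )
    msad_normal = _pair_statistic(tilt, ks, ds, "theta_msd")

    # nematic sign alignment for the plane fit
    ax = axis.copy()
    for i in range(1, n):
        if ax[i] @ ax[i - 1] < 0:
            ax[i] = -ax[i]
    traj = OrientationTrajectory(t=sweeps, u=ax, octant=False, angular_noise=0.0)
    est = estimate_normals(traj, window=window)
    starts = np.arange(0, n - window + 1, window)
    true_n = np.stack([nrm[s : s + window].mean(axis=0) for s in starts])
    true_n /= np.linalg.norm(true_n, axis=1, keepdims=True)
    dot = np.abs(np.einsum("ij,ij->i", est.n, true_n))
    delta = np.degrees(np.arccos(np.clip(dot, -1, 1)))
    delta = delta[est.valid]

    return {
        "msad_inplane": msad,
        "msad_normal": msad_normal,
        "tilt": tilt,
        "delta_deg": delta,
        "median_delta_deg": float(np.nanmedian(delta)),
    }
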