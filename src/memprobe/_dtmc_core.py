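"""Numba kernels for the dynamically triangulated Monte Carlo simulator.

Mesh connectivity is kept in fixed-width adjacency arrays so that all moves
(vertex displacement, edge flip, rod translation/rotation) mutate state in
place inside nopython code:

    pos       (N, 3) float64   vertex positions
    tri       (F, 3) int64     oriented triangles (outward CCW)
    v_nbr     (N, MAXD) int64  neighbor vertex ids
    v_edge    (N, MAXD) int64  edge id to each neighbor (parallel to v_nbr)
    v_deg     (N,) int64
    v_face    (N, MAXD) int64  incident face ids
    v_nfa     (N,) int64
    edges     (E, 2) int64
    edge_face (E, 2) int64

Energy units are kBT; lengths are in units where the tether floor a0 sets
the bead scale.  The elastic energy is a per-vertex area-weighted shape
operator built from edge dihedrals (each edge's integrated total curvature
|e| * phi_e split evenly between its endpoints), projected on the vertex
normal's tangent plane.
"""

import numpy as np
from numba import njit

MAXD = 16


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _face_normal_area(pos, tri, f):
    i, j, k = tri[f, 0], tri[f, 1], tri[f, 2]
    ax = pos[j, 0] - pos[i, 0]
    ay = pos[j, 1] - pos[i, 1]
    az = pos[j, 2] - pos[i, 2]
    bx = pos[k, 0] - pos[i, 0]
    by = pos[k, 1] - pos[i, 1]
    bz = pos[k, 2] - pos[i, 2]
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    n2 = np.sqrt(cx * cx + cy * cy + cz * cz)
    return cx, cy, cz, 0.5 * n2


@njit(cache=False)
def face_volume(pos, tri, f):
    """Signed tetrahedron volume of face f against the origin."""
    i, j, k = tri[f, 0], tri[f, 1], tri[f, 2]
    return (
        pos[i, 0] * (pos[j, 1] * pos[k, 2] - pos[j, 2] * pos[k, 1])
        + pos[i, 1] * (pos[j, 2] * pos[k, 0] - pos[j, 0] * pos[k, 2])
        + pos[i, 2] * (pos[j, 0] * pos[k, 1] - pos[j, 1] * pos[k, 0])
    ) / 6.0


@njit(cache=False)
def total_volume(pos, tri):
    v = 0.0
    for f in range(tri.shape[0]):
        v += face_volume(pos, tri, f)
    return v


@njit(cache=False)
def total_area(pos, tri):
    a = 0.0
    for f in range(tri.shape[0]):
        _, _, _, af = _face_normal_area(pos, tri, f)
        a += af
    return a


@njit(cache=False)
def vertex_shape_operator(v, pos, tri, v_nbr, v_deg, v_face, v_nfa, S):
    """Fill S (3,3) with the area-weighted shape operator at vertex v.

    Returns (A_v, nvx, nvy, nvz) = mixed vertex area and unit vertex normal;
    A_v <= 0 signals a degenerate configuration.
    """
    A_v = 0.0
    nvx = 0.0
    nvy = 0.0
    nvz = 0.0
    for fi in range(v_nfa[v]):
        f = v_face[v, fi]
        cx, cy, cz, af = _face_normal_area(pos, tri, f)
        A_v += af / 3.0
        nvx += 0.5 * cx
        nvy += 0.5 * cy
        nvz += 0.5 * cz
    nn = np.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
    if A_v <= 1e-12 or nn <= 1e-14:
        return -1.0, 0.0, 0.0, 0.0
    nvx /= nn
    nvy /= nn
    nvz /= nn

    for a in range(3):
        for b in range(3):
            S[a, b] = 0.0

    for ui in range(v_deg[v]):
        u = v_nbr[v, ui]
        # the two faces sharing edge (v, u); f1 has v->u in cyclic order
        f1 = -1
        f2 = -1
        for fi in range(v_nfa[v]):
            f = v_face[v, fi]
            for c in range(3):
                if tri[f, c] == v:
                    if tri[f, (c + 1) % 3] == u:
                        f1 = f
                    elif tri[f, (c + 2) % 3] == u:
                        f2 = f
        if f1 < 0 or f2 < 0:
            return -1.0, 0.0, 0.0, 0.0
        n1x, n1y, n1z, a1 = _face_normal_area(pos, tri, f1)
        n2x, n2y, n2z, a2 = _face_normal_area(pos, tri, f2)
        if a1 <= 1e-12 or a2 <= 1e-12:
            return -1.0, 0.0, 0.0, 0.0
        m1 = 2.0 * a1
        m2 = 2.0 * a2
        n1x /= m1
        n1y /= m1
        n1z /= m1
        n2x /= m2
        n2y /= m2
        n2z /= m2
        ex = pos[u, 0] - pos[v, 0]
        ey = pos[u, 1] - pos[v, 1]
        ez = pos[u, 2] - pos[v, 2]
        le = np.sqrt(ex * ex + ey * ey + ez * ez)
        ex /= le
        ey /= le
        ez /= le
        # signed dihedral: positive where the surface is convex outward
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sphi = cxx * ex + cxy * ey + cxz * ez
        cphi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sphi, cphi)
        # edge binormal: (n1 + n2) x e, normalized
        sx = n1x + n2x
        sy = n1y + n2y
        sz = n1z + n2z
        bx = sy * ez - sz * ey
        by = sz * ex - sx * ez
        bz = sx * ey - sy * ex
        bn = np.sqrt(bx * bx + by * by + bz * bz)
        if bn <= 1e-14:
            continue
        bx /= bn
        by /= bn
        bz /= bn
        w = le * phi
        S[0, 0] += w * bx * bx
        S[0, 1] += w * bx * by
        S[0, 2] += w * bx * bz
        S[1, 0] += w * by * bx
        S[1, 1] += w * by * by
        S[1, 2] += w * by * bz
        S[2, 0] += w * bz * bx
        S[2, 1] += w * bz * by
        S[2, 2] += w * bz * bz
    inv = 1.0 / (2.0 * A_v)
    for a in range(3):
        for b in range(3):
            S[a, b] *= inv
    return A_v, nvx, nvy, nvz


@njit(cache=False)
def vertex_energy(v, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S):
    """Bending energy (kappa/2) (c1+c2)^2 A_v at vertex v (kBT units).

    Returns a large penalty for degenerate local geometry so such moves are
    always rejected.
    """
    A_v, nx, ny, nz = vertex_shape_operator(
        v, pos, tri, v_nbr, v_deg, v_face, v_nfa, S
    )
    if A_v <= 0.0:
        return 1e12
    tr = S[0, 0] + S[1, 1] + S[2, 2]
    nsn = (
        nx * (S[0, 0] * nx + S[0, 1] * ny + S[0, 2] * nz)
        + ny * (S[1, 0] * nx + S[1, 1] * ny + S[1, 2] * nz)
        + nz * (S[2, 0] * nx + S[2, 1] * ny + S[2, 2] * nz)
    )
    h = tr - nsn  # c1 + c2 in the tangent plane
    return 0.5 * kappa * h * h * A_v


@njit(cache=False)
def total_energy(pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa):
    S = np.empty((3, 3))
    e = 0.0
    for v in range(pos.shape[0]):
        e += vertex_energy(v, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    return e


@njit(cache=False, inline="always")
def _lj_pair(r2, s2, eps, rc2, vshift):
    if r2 >= rc2:
        return 0.0
    x = s2 / r2
    x6 = x * x * x
    return 4.0 * eps * (x6 * x6 - x6) - vshift


@njit(cache=False)
def lj_vertex(vx, vy, vz, sites, eps, s2, rc2, vshift):
    e = 0.0
    for i in range(sites.shape[0]):
        dx = vx - sites[i, 0]
        dy = vy - sites[i, 1]
        dz = vz - sites[i, 2]
        e += _lj_pair(dx * dx + dy * dy + dz * dz, s2, eps, rc2, vshift)
    return e


@njit(cache=False)
def lj_total(pos, sites, eps, s2, rc2, vshift):
    e = 0.0
    for v in range(pos.shape[0]):
        e += lj_vertex(pos[v, 0], pos[v, 1], pos[v, 2], sites, eps, s2, rc2, vshift)
    return e


@njit(cache=False)
def rod_sites(center, axis, length, k, out):
    for i in range(k):
        f = length * (i / (k - 1.0) - 0.5)
        out[i, 0] = center[0] + f * axis[0]
        out[i, 1] = center[1] + f * axis[1]
        out[i, 2] = center[2] + f * axis[2]


@njit(cache=False)
def try_vertex_move(
    pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
    kappa, a0, amp, v_target, v_window, v_penalty, volume,
    a_target, a_window, a_penalty, area,
    sites, eps, s2, rc2, vshift,
    S, v_forced,
):
    """One Metropolis vertex-displacement attempt.

    Returns (accepted, new_volume, new_area).  ``v_forced`` >= 0 targets a
    specific vertex (used by sampling-correctness tests); -1 picks uniformly."""
    n = pos.shape[0]
    v = np.random.randint(0, n) if v_forced < 0 else v_forced
    dx = amp * (np.random.random() - 0.5) * 2.0
    dy = amp * (np.random.random() - 0.5) * 2.0
    dz = amp * (np.random.random() - 0.5) * 2.0
    ox, oy, oz = pos[v, 0], pos[v, 1], pos[v, 2]
    nx, ny, nz = ox + dx, oy + dy, oz + dz

    # tether bounds to neighbors
    lo2 = a0 * a0
    hi2 = 3.0 * a0 * a0
    for ui in range(v_deg[v]):
        u = v_nbr[v, ui]
        ddx = nx - pos[u, 0]
        ddy = ny - pos[u, 1]
        ddz = nz - pos[u, 2]
        r2 = ddx * ddx + ddy * ddy + ddz * ddz
        if r2 < lo2 or r2 > hi2:
            return False, volume, area
    # self-avoidance against all non-neighbor vertices
    for u in range(n):
        if u == v:
            continue
        isnbr = False
        for ui in range(v_deg[v]):
            if v_nbr[v, ui] == u:
                isnbr = True
                break
        if isnbr:
            continue
        ddx = nx - pos[u, 0]
        ddy = ny - pos[u, 1]
        ddz = nz - pos[u, 2]
        if ddx * ddx + ddy * ddy + ddz * ddz < lo2:
            return False, volume, area

    # volume and area change from the incident-face fan
    dvol = 0.0
    darea = 0.0
    for fi in range(v_nfa[v]):
        f = v_face[v, fi]
        dvol -= face_volume(pos, tri, f)
        _, _, _, af = _face_normal_area(pos, tri, f)
        darea -= af
    # energy before (v and its 1-ring)
    e_before = vertex_energy(v, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    for ui in range(v_deg[v]):
        e_before += vertex_energy(
            v_nbr[v, ui], pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S
        )
    e_before += lj_vertex(ox, oy, oz, sites, eps, s2, rc2, vshift)

    pos[v, 0], pos[v, 1], pos[v, 2] = nx, ny, nz
    for fi in range(v_nfa[v]):
        f = v_face[v, fi]
        dvol += face_volume(pos, tri, f)
        _, _, _, af = _face_normal_area(pos, tri, f)
        darea += af
    new_volume = volume + dvol
    new_area = area + darea
    if abs(new_volume - v_target) > v_window or abs(new_area - a_target) > a_window:
        pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
        return False, volume, area

    e_after = vertex_energy(v, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    for ui in range(v_deg[v]):
        e_after += vertex_energy(
            v_nbr[v, ui], pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S
        )
    e_after += lj_vertex(nx, ny, nz, sites, eps, s2, rc2, vshift)

    de = e_after - e_before
    if v_penalty > 0.0:
        x_new = (new_volume - v_target) / v_target
        x_old = (volume - v_target) / v_target
        de += 0.5 * v_penalty * (x_new * x_new - x_old * x_old)
    if a_penalty > 0.0:
        y_new = (new_area - a_target) / a_target
        y_old = (area - a_target) / a_target
        de += 0.5 * a_penalty * (y_new * y_new - y_old * y_old)
    if de <= 0.0 or np.random.random() < np.exp(-de):
        return True, new_volume, new_area
    pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
    return False, volume, area


@njit(cache=False)
def _find_nbr_slot(v_nbr, v_deg, a, b):
    for i in range(v_deg[a]):
        if v_nbr[a, i] == b:
            return i
    return -1


@njit(cache=False)
def _remove_nbr(v_nbr, v_edge, v_deg, a, b):
    i = _find_nbr_slot(v_nbr, v_deg, a, b)
    last = v_deg[a] - 1
    v_nbr[a, i] = v_nbr[a, last]
    v_edge[a, i] = v_edge[a, last]
    v_deg[a] = last


@njit(cache=False)
def _add_nbr(v_nbr, v_edge, v_deg, a, b, e):
    v_nbr[a, v_deg[a]] = b
    v_edge[a, v_deg[a]] = e
    v_deg[a] += 1


@njit(cache=False)
def _remove_face(v_face, v_nfa, a, f):
    for i in range(v_nfa[a]):
        if v_face[a, i] == f:
            v_face[a, i] = v_face[a, v_nfa[a] - 1]
            v_nfa[a] -= 1
            return


@njit(cache=False)
def _replace_edge_face(edge_face, e, old, new):
    if edge_face[e, 0] == old:
        edge_face[e, 0] = new
    else:
        edge_face[e, 1] = new


@njit(cache=False)
def apply_flip(e, pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face):
    """Flip edge e: (a,b) shared by f1=(a,b,c), f2=(b,a,d) -> edge (c,d) with
    f1'=(a,d,c), f2'=(d,b,c).  Assumes validity was checked. Orientation of
    both faces is preserved."""
    a = edges[e, 0]
    b = edges[e, 1]
    f1 = edge_face[e, 0]
    f2 = edge_face[e, 1]
    # ensure f1 is the face with a->b in cyclic order
    hasab = False
    for c in range(3):
        if tri[f1, c] == a and tri[f1, (c + 1) % 3] == b:
            hasab = True
    if not hasab:
        f1, f2 = f2, f1
    # opposite vertices
    c = -1
    d = -1
    for i in range(3):
        if tri[f1, i] != a and tri[f1, i] != b:
            c = tri[f1, i]
        if tri[f2, i] != a and tri[f2, i] != b:
            d = tri[f2, i]

    # connectivity updates
    _remove_nbr(v_nbr, v_edge, v_deg, a, b)
    _remove_nbr(v_nbr, v_edge, v_deg, b, a)
    _add_nbr(v_nbr, v_edge, v_deg, c, d, e)
    _add_nbr(v_nbr, v_edge, v_deg, d, c, e)
    edges[e, 0] = c
    edges[e, 1] = d

    tri[f1, 0] = a
    tri[f1, 1] = d
    tri[f1, 2] = c
    tri[f2, 0] = d
    tri[f2, 1] = b
    tri[f2, 2] = c

    _remove_face(v_face, v_nfa, a, f2)
    _remove_face(v_face, v_nfa, b, f1)
    v_face[c, v_nfa[c]] = f2
    v_nfa[c] += 1
    v_face[d, v_nfa[d]] = f1
    v_nfa[d] += 1

    # edge (a,d) moves from f2 to f1; edge (b,c) moves from f1 to f2
    sad = _find_nbr_slot(v_nbr, v_deg, a, d)
    _replace_edge_face(edge_face, v_edge[a, sad], f2, f1)
    sbc = _find_nbr_slot(v_nbr, v_deg, b, c)
    _replace_edge_face(edge_face, v_edge[b, sbc], f1, f2)
    return a, b, c, d


@njit(cache=False)
def try_flip(
    pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
    kappa, a0, v_target, v_window, v_penalty, volume,
    a_target, a_window, a_penalty, area, S,
):
    """One Metropolis link-flip attempt. Returns (accepted, new_volume, new_area)."""
    ne = edges.shape[0]
    e = np.random.randint(0, ne)
    a = edges[e, 0]
    b = edges[e, 1]
    f1 = edge_face[e, 0]
    f2 = edge_face[e, 1]
    if v_deg[a] <= 3 or v_deg[b] <= 3:
        return False, volume, area
    # opposite vertices
    c = -1
    d = -1
    for i in range(3):
        if tri[f1, i] != a and tri[f1, i] != b:
            c = tri[f1, i]
        if tri[f2, i] != a and tri[f2, i] != b:
            d = tri[f2, i]
    if v_deg[c] >= MAXD - 1 or v_deg[d] >= MAXD - 1:
        return False, volume, area
    if _find_nbr_slot(v_nbr, v_deg, c, d) >= 0:
        return False, volume, area
    dx = pos[c, 0] - pos[d, 0]
    dy = pos[c, 1] - pos[d, 1]
    dz = pos[c, 2] - pos[d, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < a0 * a0 or r2 > 3.0 * a0 * a0:
        return False, volume, area

    e_before = 0.0
    dvol = -face_volume(pos, tri, f1) - face_volume(pos, tri, f2)
    _, _, _, af1 = _face_normal_area(pos, tri, f1)
    _, _, _, af2 = _face_normal_area(pos, tri, f2)
    darea = -af1 - af2
    e_before += vertex_energy(a, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    e_before += vertex_energy(b, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    e_before += vertex_energy(c, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
    e_before += vertex_energy(d, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)

    apply_flip(e, pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face)
    dvol += face_volume(pos, tri, f1) + face_volume(pos, tri, f2)
    _, _, _, af1 = _face_normal_area(pos, tri, f1)
    _, _, _, af2 = _face_normal_area(pos, tri, f2)
    new_volume = volume + dvol
    new_area = area + darea + af1 + af2

    reject = (abs(new_volume - v_target) > v_window
              or abs(new_area - a_target) > a_window)
    if not reject:
        e_after = 0.0
        e_after += vertex_energy(a, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
        e_after += vertex_energy(b, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
        e_after += vertex_energy(c, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
        e_after += vertex_energy(d, pos, tri, v_nbr, v_deg, v_face, v_nfa, kappa, S)
        de = e_after - e_before
        if v_penalty > 0.0:
            x_new = (new_volume - v_target) / v_target
            x_old = (volume - v_target) / v_target
            de += 0.5 * v_penalty * (x_new * x_new - x_old * x_old)
        if a_penalty > 0.0:
            y_new = (new_area - a_target) / a_target
            y_old = (area - a_target) / a_target
            de += 0.5 * a_penalty * (y_new * y_new - y_old * y_old)
        if de > 0.0 and np.random.random() >= np.exp(-de):
            reject = True
    if reject:
        apply_flip(e, pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face)
        return False, volume, area
    return True, new_volume, new_area


@njit(cache=False)
def try_rod_move(
    pos, rod_center, rod_axis, rod_len, nsites, amp_t, amp_r, rotate,
    eps, s2, rc2, vshift, sites_buf, sites_new, nbr_idx,
):
    """One Metropolis rod translation (rotate=False) or rotation attempt.

    Only vertices within reach of the rod (collected in nbr_idx, a scratch
    int64 array of length >= N) are evaluated; the selection radius covers
    the LJ cutoff plus the rod half-length plus the move amplitude, so the
    energy difference is exact."""
    reach = 0.5 * rod_len + np.sqrt(rc2) + amp_t + 1e-9
    reach2 = reach * reach
    nn = 0
    for v in range(pos.shape[0]):
        dx = pos[v, 0] - rod_center[0]
        dy = pos[v, 1] - rod_center[1]
        dz = pos[v, 2] - rod_center[2]
        if dx * dx + dy * dy + dz * dz <= reach2:
            nbr_idx[nn] = v
            nn += 1
    rod_sites(rod_center, rod_axis, rod_len, nsites, sites_buf)
    e_before = 0.0
    for ii in range(nn):
        v = nbr_idx[ii]
        e_before += lj_vertex(
            pos[v, 0], pos[v, 1], pos[v, 2], sites_buf[:nsites], eps, s2, rc2, vshift
        )
    ncx, ncy, ncz = rod_center[0], rod_center[1], rod_center[2]
    nax, nay, naz = rod_axis[0], rod_axis[1], rod_axis[2]
    if rotate == 1:
        # free axis perturbation (tilt + in-plane)
        nax += amp_r * np.random.normal()
        nay += amp_r * np.random.normal()
        naz += amp_r * np.random.normal()
        norm = np.sqrt(nax * nax + nay * nay + naz * naz)
        nax /= norm
        nay /= norm
        naz /= norm
    elif rotate == 2:
        # spin about the outward radial direction at the rod center
        # (~ local membrane normal on a quasi-spherical vesicle); symmetric
        # proposal, Rodrigues rotation by a uniform angle in [-amp_r, amp_r]
        knorm = np.sqrt(ncx * ncx + ncy * ncy + ncz * ncz)
        kx, ky, kz = ncx / knorm, ncy / knorm, ncz / knorm
        xi = amp_r * (np.random.random() - 0.5) * 2.0
        c, s = np.cos(xi), np.sin(xi)
        crx = ky * naz - kz * nay
        cry = kz * nax - kx * naz
        crz = kx * nay - ky * nax
        kd = kx * nax + ky * nay + kz * naz
        nax = nax * c + crx * s + kx * kd * (1.0 - c)
        nay = nay * c + cry * s + ky * kd * (1.0 - c)
        naz = naz * c + crz * s + kz * kd * (1.0 - c)
        norm = np.sqrt(nax * nax + nay * nay + naz * naz)
        nax /= norm
        nay /= norm
        naz /= norm
    else:
        ncx += amp_t * (np.random.random() - 0.5) * 2.0
        ncy += amp_t * (np.random.random() - 0.5) * 2.0
        ncz += amp_t * (np.random.random() - 0.5) * 2.0
    center_new = np.empty(3)
    center_new[0], center_new[1], center_new[2] = ncx, ncy, ncz
    axis_new = np.empty(3)
    axis_new[0], axis_new[1], axis_new[2] = nax, nay, naz
    rod_sites(center_new, axis_new, rod_len, nsites, sites_new)
    e_after = 0.0
    for ii in range(nn):
        v = nbr_idx[ii]
        e_after += lj_vertex(
            pos[v, 0], pos[v, 1], pos[v, 2], sites_new[:nsites], eps, s2, rc2, vshift
        )
    de = e_after - e_before
    if de <= 0.0 or np.random.random() < np.exp(-de):
        rod_center[0], rod_center[1], rod_center[2] = ncx, ncy, ncz
        rod_axis[0], rod_axis[1], rod_axis[2] = nax, nay, naz
        return True
    return False


@njit(cache=False)
def run_sweeps(
    n_sweeps,
    pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
    kappa, a0, amp_vertex, v_target, v_window, v_penalty, volume_in,
    a_target, a_window, a_penalty, area_in,
    rod_center, rod_axis, rod_len, nsites, amp_t, amp_r, amp_spin, n_rod_moves,
    eps, s2, rc2, vshift,
    counters, do_flips,
):
    """Run n_sweeps sweeps; a sweep is N vertex attempts, E flip attempts and
    n_rod_moves rod translation+rotation attempt pairs.  Returns the running
    (volume, area).  counters accumulates [vert_acc, vert_try, flip_acc, flip_try,
    rod_t_acc, rod_t_try, rod_r_acc, rod_r_try]."""
    S = np.empty((3, 3))
    sites_buf = np.empty((nsites, 3))
    sites_new = np.empty((nsites, 3))
    nbr_idx = np.empty(pos.shape[0], dtype=np.int64)
    volume = volume_in
    area = area_in
    n = pos.shape[0]
    ne = edges.shape[0]
    for _ in range(n_sweeps):
        for _ in range(n):
            rod_sites(rod_center, rod_axis, rod_len, nsites, sites_buf)
            acc, volume, area = try_vertex_move(
                pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
                kappa, a0, amp_vertex, v_target, v_window, v_penalty, volume,
                a_target, a_window, a_penalty, area,
                sites_buf[:nsites], eps, s2, rc2, vshift, S, -1,
            )
            counters[1] += 1
            if acc:
                counters[0] += 1
        for _ in range(ne if do_flips else 0):
            acc, volume, area = try_flip(
                pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
                kappa, a0, v_target, v_window, v_penalty, volume,
                a_target, a_window, a_penalty, area, S,
            )
            counters[3] += 1
            if acc:
                counters[2] += 1
        for _ in range(n_rod_moves):
            acc = try_rod_move(
                pos, rod_center, rod_axis, rod_len, nsites, amp_t, amp_r, 0,
                eps, s2, rc2, vshift, sites_buf, sites_new, nbr_idx,
            )
            counters[5] += 1
            if acc:
                counters[4] += 1
            acc = try_rod_move(
                pos, rod_center, rod_axis, rod_len, nsites, amp_t, amp_r, 1,
                eps, s2, rc2, vshift, sites_buf, sites_new, nbr_idx,
            )
            counters[7] += 1
            if acc:
                counters[6] += 1
            acc = try_rod_move(
                pos, rod_center, rod_axis, rod_len, nsites, amp_t, amp_spin, 2,
                eps, s2, rc2, vshift, sites_buf, sites_new, nbr_idx,
            )
            counters[9] += 1
            if acc:
                counters[8] += 1
    return volume, area


@njit(cache=False)
def sample_single_vertex(
    v, n_attempts, thin,
    pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
    kappa, a0, amp, volume,
):
    """Metropolis-sample one vertex with all others frozen (no volume/area
    constraint, no rod); returns its positions every ``thin`` attempts.
    Used to validate the sampler against direct Boltzmann quadrature."""
    S = np.empty((3, 3))
    sites = np.zeros((1, 3))
    sites[0, 2] = 1e9  # far away: no LJ contribution
    out = np.empty((n_attempts // thin, 3))
    vol = volume
    area = total_area(pos, tri)
    big = 1e30
    k = 0
    for i in range(n_attempts):
        _, vol, area = try_vertex_move(
            pos, tri, v_nbr, v_edge, v_deg, v_face, v_nfa, edges, edge_face,
            kappa, a0, amp, vol, big, 0.0, vol, area, big, 0.0, area,
            sites, 1.0, 0.01, 0.02, 0.0, S, v,
        )
        if (i + 1) % thin == 0:
            out[k] = pos[v]
            k += 1
    return out[:k]
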