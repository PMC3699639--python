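"""Solute cavity construction: interlocked atomic spheres tessellated by the
GEPOL scheme with Gauss-Bonnet exposed areas.

Each sphere starts from a pentakis-dodecahedral mesh (60 spherical
triangles, subdivided to 240 or 960).  A triangle overlapped by a
neighbouring sphere is clipped against that sphere's intersection circle;
the exposed region is a spherical polygon bounded by great-circle and
small-circle arcs whose area follows from the Gauss-Bonnet theorem

    A = 2*pi - sum_arcs int k_g ds - sum_vertices theta_ext

(k_g = 0 on great circles, cot(theta_c) on a circle of angular radius
theta_c).  Retained tesserae carry the exposed area and a representative
point relocated to the exposed region.

The polyhedral mesh is seeded in a molecule-fixed frame so that the
tessellation — and every quantity downstream — is invariant under rigid
rotation of the solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import ConvexHull

from .molecule import Molecule
from .units import ANGSTROM_TO_BOHR, BONDI_RADII

_TWO_PI = 2.0 * math.pi


class CavityError(ValueError):
    pass


@dataclass(frozen=True)
class Sphere:
    atom_index: int
    center: np.ndarray  # bohr
    radius: float  # bohr


@dataclass
class Cavity:
    spheres: list
    positions: np.ndarray  # (n, 3) bohr, representative points
    areas: np.ndarray  # (n,) bohr^2
    sphere_index: np.ndarray  # (n,) parent sphere
    n_initial_per_sphere: int
    frame: np.ndarray  # (3, 3) mesh seed rotation, rows are frame axes
    scheme: str = "gepol-gb"

    @property
    def n_tesserae(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def normals(self) -> np.ndarray:
        centers = np.array([self.spheres[i].center for i in self.sphere_index])
        radii = np.array([self.spheres[i].radius for i in self.sphere_index])
        return (self.positions - centers) / radii[:, None]

    def to_csv(self, path) -> None:
        """Per-tessera dump: index, sphere, x, y, z (bohr), area (bohr^2)."""
        with open(path, "w") as fh:
            fh.write("index,sphere,x,y,z,area\n")
            for i in range(self.n_tesserae):
                x, y, z = self.positions[i]
                fh.write(
                    f"{i},{self.sphere_index[i]},{x:.10f},{y:.10f},{z:.10f},{self.areas[i]:.10f}\n"
                )


def assign_radii(
    mol: Molecule,
    radii_table: dict | None = None,
    scale: float = 1.2,
    include_hydrogens: bool = True,
) -> list:
    """One sphere per atom; radius = table value (angstrom) x scale, in bohr."""
    if scale <= 0.0:
        raise CavityError("radius scale factor must be positive")
    table = BONDI_RADII if radii_table is None else radii_table
    spheres = []
    for i, sym in enumerate(mol.symbols):
        if not include_hydrogens and sym == "H":
            continue
        if sym not in table:
            raise CavityError(f"no cavity radius tabulated for element {sym!r}")
        spheres.append(Sphere(i, mol.coords[i].copy(), table[sym] * scale * ANGSTROM_TO_BOHR))
    return spheres


# ---------------------------------------------------------------------------
# fast scalar helpers for 3-vectors (hot path; numpy ufunc dispatch is slow
# at this size)


def _cross3(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _dot3(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _norm3(a):
    return math.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


def _unit3(a):
    n = _norm3(a)
    return (a[0] / n, a[1] / n, a[2] / n) if n > 0 else a


# ---------------------------------------------------------------------------
# base polyhedral meshes


@lru_cache(maxsize=8)
def _base_mesh(n_per_sphere: int) -> np.ndarray:
    """(n, 3, 3) unit-sphere triangles, outward CCW orientation."""
    if n_per_sphere not in (60, 240, 960):
        raise CavityError("tesserae per sphere must be 60, 240 or 960")
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    v = np.array(verts)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    hull = ConvexHull(v)
    faces = hull.simplices  # (20, 3)
    centers = v[faces].mean(axis=1)
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    edge_faces = {}
    for fi, f in enumerate(faces):
        for k in range(3):
            e = tuple(sorted((f[k], f[(k + 1) % 3])))
            edge_faces.setdefault(e, []).append(fi)
    tris = []
    for (a, b), (f1, f2) in edge_faces.items():
        for apex in (a, b):
            tris.append([v[apex], centers[f1], centers[f2]])
    tris = np.array(tris)  # (60, 3, 3)
    det = np.einsum("ij,ij->i", tris[:, 0], np.cross(tris[:, 1], tris[:, 2]))
    flip = det < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    while len(tris) < n_per_sphere:
        tris = _subdivide(tris)
    return tris


def _subdivide(tris: np.ndarray) -> np.ndarray:
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab = a + b
    bc = b + c
    ca = c + a
    for m in (ab, bc, ca):
        m /= np.linalg.norm(m, axis=1, keepdims=True)
    return np.concatenate(
        [
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ]
    )


def molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Deterministic rotation-equivariant frame from index-weighted moments.

    Smooth in the coordinates (no argmax tie-breaking), so cavities rebuilt
    at finitely displaced geometries vary continuously.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    if n == 1:
        return np.eye(3)
    center = coords.mean(axis=0)
    rel = coords - center
    w1 = np.arange(1, n + 1, dtype=float)
    w2 = w1**2
    v1 = (w1[:, None] * rel).sum(axis=0)
    v2 = (w2[:, None] * rel).sum(axis=0)
    if np.linalg.norm(v1) < 1e-8:
        v1 = rel[0] if np.linalg.norm(rel[0]) > 1e-8 else np.array([1.0, 0.0, 0.0])
    e1 = v1 / np.linalg.norm(v1)
    v2p = v2 - (v2 @ e1) * e1
    if np.linalg.norm(v2p) < 1e-8:
        ref = np.zeros(3)
        ref[int(np.argmin(np.abs(e1)))] = 1.0
        v2p = ref - (ref @ e1) * e1
    e2 = v2p / np.linalg.norm(v2p)
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


# ---------------------------------------------------------------------------
# spherical polygons: (verts, edges); edge i joins vert i to vert i+1
# (cyclic).  edge = ("G",) great arc, or ("S", u, costh, a1, a2) small-circle
# arc about axis u with u.x = costh, traversed in the direction of
# decreasing azimuth (measured in the a1/a2 basis) so the removed cap lies
# on the right of travel.


def _azimuth(x, a1, a2):
    return math.atan2(_dot3(x, a2), _dot3(x, a1))


def _circle_basis(u):
    ref = [0.0, 0.0, 0.0]
    ref[int(np.argmin(np.abs(u)))] = 1.0
    a1 = _unit3(_cross3(ref, u))
    a2 = _cross3(u, a1)
    return np.array(a1), np.array(a2)


def _edge_tangent(edge, va, vb, x):
    """Unit tangent of the edge, in the direction of travel, at point x."""
    if edge[0] == "G":
        n = _cross3(va, vb)
        nn = _norm3(n)
        if nn < 1e-14:
            return None
        t = _cross3((n[0] / nn, n[1] / nn, n[2] / nn), x)
    else:
        u = edge[1]
        t = _cross3(x, u)  # = -(u x x)
    tn = _norm3(t)
    return (t[0] / tn, t[1] / tn, t[2] / tn) if tn > 1e-14 else None


def polygon_area(verts, edges) -> float:
    """Gauss-Bonnet area of a spherical polygon on the unit sphere."""
    m = len(verts)
    area = _TWO_PI
    for i in range(m):
        edge = edges[i]
        if edge[0] == "S":
            _, u, c, a1, a2 = edge
            va, vb = verts[i], verts[(i + 1) % m]
            dphi = (_azimuth(va, a1, a2) - _azimuth(vb, a1, a2)) % _TWO_PI
            area += c * dphi  # -(integral of k_g ds) = +cos(theta_c) * dphi
    for i in range(m):
        vprev = verts[i - 1]
        v = verts[i]
        vnext = verts[(i + 1) % m]
        t_in = _edge_tangent(edges[i - 1], vprev, v, v)
        t_out = _edge_tangent(edges[i], v, vnext, v)
        if t_in is None or t_out is None:
            continue
        cr = _cross3(t_in, t_out)
        area -= math.atan2(_dot3(v, cr), _dot3(t_in, t_out))
    return area


def polygon_centroid_raw(verts, edges) -> np.ndarray:
    """Unnormalized surface centroid int x dA = (1/2) closed-int x x dl.

    Continuous in the polygon geometry (unlike a vertex average, which
    jumps when a near-tangent clip inserts vertices), so representative
    points move smoothly as the molecule deforms.
    """
    m = len(verts)
    acc = np.zeros(3)
    for i in range(m):
        va, vb = verts[i], verts[(i + 1) % m]
        e = edges[i]
        if e[0] == "G":
            n = _cross3(va, vb)
            nn = _norm3(n)
            if nn < 1e-14:
                continue
            omega = math.atan2(nn, _dot3(va, vb))
            acc[0] += n[0] / nn * omega
            acc[1] += n[1] / nn * omega
            acc[2] += n[2] / nn * omega
        else:
            _, u, c, a1, a2 = e
            phis = _azimuth(va, a1, a2)
            phie = _azimuth(vb, a1, a2)
            dphi = (phis - phie) % _TWO_PI
            sth = math.sqrt(max(0.0, 1.0 - c * c))
            coef = c * sth
            acc += (
                -dphi * (1.0 - c * c) * u
                - coef * (math.sin(phie) - math.sin(phis)) * a1
                + coef * (math.cos(phie) - math.cos(phis)) * a2
            )
    return 0.5 * acc


def _tri_centroids_raw(tris: np.ndarray) -> np.ndarray:
    """Vectorized int x dA for uncut spherical triangles, (n, 3)."""
    acc = np.zeros((len(tris), 3))
    for k in range(3):
        a = tris[:, k]
        b = tris[:, (k + 1) % 3]
        n = np.cross(a, b)
        nn = np.linalg.norm(n, axis=1)
        omega = np.arctan2(nn, np.einsum("ij,ij->i", a, b))
        acc += n * (omega / nn)[:, None]
    return 0.5 * acc


def _great_arc_point(x1, x2, s, omega):
    so = math.sin(omega)
    w1 = math.sin(omega - s) / so
    w2 = math.sin(s) / so
    return (
        w1 * x1[0] + w2 * x2[0],
        w1 * x1[1] + w2 * x2[1],
        w1 * x1[2] + w2 * x2[2],
    )


def _great_edge_crossings(x1, x2, u, c):
    """Crossing parameters s in (0, omega) of great arc x1->x2 with u.x = c."""
    cosw = max(-1.0, min(1.0, _dot3(x1, x2)))
    omega = math.acos(cosw)
    if omega < 1e-12:
        return omega, []
    a, b = _dot3(u, x1), _dot3(u, x2)
    p = a * math.sin(omega)
    q = b - a * cosw
    h = math.hypot(p, q)
    t = c * math.sin(omega)
    if h < 1e-14 or abs(t) > h:
        return omega, []
    alpha = math.atan2(q, p)
    beta = math.acos(max(-1.0, min(1.0, t / h)))
    out = []
    for s in (alpha - beta, alpha + beta):
        for cand in (s, s + _TWO_PI, s - _TWO_PI):
            if 1e-9 < cand < omega - 1e-9:
                out.append(cand)
    return omega, sorted(set(out))


def _small_edge_crossings(edge, va, vb, u2, c2):
    """Crossings of a small-circle edge with circle u2.x = c2, as offsets
    (azimuth decrease from the edge start) in (0, dphi_edge)."""
    _, u1, c1, a1, a2 = edge
    dots = _dot3(u1, u2)
    denom = 1.0 - dots * dots
    if denom < 1e-14:
        return []
    alpha = (c1 - c2 * dots) / denom
    beta = (c2 - c1 * dots) / denom
    cross = _cross3(u1, u2)
    g2 = 1.0 - alpha * alpha - beta * beta - 2.0 * alpha * beta * dots
    if g2 < 1e-14:
        return []
    gamma = math.sqrt(g2 / _dot3(cross, cross))
    phi_a = _azimuth(va, a1, a2)
    dphi_edge = (phi_a - _azimuth(vb, a1, a2)) % _TWO_PI
    out = []
    for sgn in (1.0, -1.0):
        x = np.array(
            [
                alpha * u1[k] + beta * u2[k] + sgn * gamma * cross[k]
                for k in range(3)
            ]
        )
        x /= _norm3(x)
        off = (phi_a - _azimuth(x, a1, a2)) % _TWO_PI
        if 1e-9 < off < dphi_edge - 1e-9:
            out.append((off, x))
    return sorted(out, key=lambda t: t[0])


def _small_edge_point(edge, va, offset):
    _, u, c, a1, a2 = edge
    phi = _azimuth(va, a1, a2) - offset
    sth = math.sqrt(max(0.0, 1.0 - c * c))
    ca, sa = math.cos(phi), math.sin(phi)
    return np.array([c * u[k] + sth * (ca * a1[k] + sa * a2[k]) for k in range(3)])


def clip_polygon(verts, edges, u, c, a1c, a2c):
    """Clip a spherical polygon, removing the cap {x : u.x > c}.

    Returns (polygons, touched): a list of (verts, edges) exposed pieces and
    a flag telling whether the circle actually intersected the boundary.
    When untouched, the caller decides between fully-exposed, fully-covered
    and cap-hole cases from vertex signs.
    """
    m = len(verts)
    segments = []  # [p_start, p_end, edge_descriptor, exposed]
    any_cross = False
    for i in range(m):
        va, vb = verts[i], verts[(i + 1) % m]
        edge = edges[i]
        if edge[0] == "G":
            omega, ss = _great_edge_crossings(va, vb, u, c)
            pts = [va] + [_great_arc_point(va, vb, s, omega) for s in ss] + [vb]
            params = [0.0] + ss + [omega]
            midf = lambda j: _great_arc_point(
                va, vb, 0.5 * (params[j] + params[j + 1]), omega
            )
        else:
            crossings = _small_edge_crossings(edge, va, vb, u, c)
            ss = [off for off, _ in crossings]
            pts = [va] + [p for _, p in crossings] + [vb]
            _, ue, ce, a1e, a2e = edge
            dphi_edge = (_azimuth(va, a1e, a2e) - _azimuth(vb, a1e, a2e)) % _TWO_PI
            params = [0.0] + ss + [dphi_edge]
            midf = lambda j: _small_edge_point(edge, va, 0.5 * (params[j] + params[j + 1]))
        if ss:
            any_cross = True
        for j in range(len(pts) - 1):
            mid = midf(j)
            exposed = _dot3(u, mid) < c
            segments.append((pts[j], pts[j + 1], edge, exposed))
    if not any_cross:
        return None, False
    nseg = len(segments)
    start = 0
    for i in range(nseg):
        if segments[i][3] and not segments[i - 1][3]:
            start = i
            break
    segments = segments[start:] + segments[:start]
    chains = []
    cur = None
    for seg in segments:
        if seg[3]:
            if cur is None:
                cur = []
            cur.append(seg)
        else:
            if cur is not None:
                chains.append(cur)
                cur = None
    if cur is not None:
        chains.append(cur)
    if not chains:
        return [], True
    entries = [(_azimuth(ch[0][0], a1c, a2c), ci) for ci, ch in enumerate(chains)]
    exits = [(_azimuth(ch[-1][1], a1c, a2c), ci) for ci, ch in enumerate(chains)]
    polys = []
    used = [False] * len(chains)
    for ci in range(len(chains)):
        if used[ci]:
            continue
        vlist, elist = [], []
        cur_ci = ci
        while True:
            used[cur_ci] = True
            ch = chains[cur_ci]
            for p1, p2, edge, _ in ch:
                vlist.append(p1)
                elist.append(edge)
            exit_phi = exits[cur_ci][0]
            best = None
            for phi_n, cj in entries:
                d = (exit_phi - phi_n) % _TWO_PI
                if best is None or d < best[0]:
                    best = (d, cj)
            vlist.append(ch[-1][1])
            elist.append(("S", u, c, a1c, a2c))
            nxt = best[1]
            if nxt == ci:
                break
            if used[nxt]:  # degenerate topology; bail to fallback
                raise CavityError("degenerate clip topology")
            cur_ci = nxt
        polys.append((vlist, elist))
    return polys, True


# ---------------------------------------------------------------------------
# per-sphere tessellation


def _caps_on_sphere(si: int, spheres) -> list:
    """Caps cutting sphere si: list of (u, costh, a1, a2) or 'buried'."""
    s = spheres[si]
    caps = []
    for j, o in enumerate(spheres):
        if j == si:
            continue
        dvec = o.center - s.center
        d = float(np.linalg.norm(dvec))
        if d >= s.radius + o.radius:
            continue
        if d + s.radius <= o.radius and (s.radius < o.radius or j < si):
            return "buried"  # ties (coincident equal spheres) keep the lower index
        if d + o.radius <= s.radius:
            continue  # other sphere inside this one; surface untouched
        costh = (d * d + s.radius**2 - o.radius**2) / (2.0 * d * s.radius)
        u = dvec / d
        a1, a2 = _circle_basis(u)
        caps.append((u, float(np.clip(costh, -1.0, 1.0)), a1, a2))
    return caps


def _sample_area(tri, caps, depth: int = 3):
    """Fallback: exposed area of a triangle by subdivision sampling.

    Uses the same surface-centroid definition as the exact clipping path so
    a flip between the two paths moves the representative point little.
    """
    tris = np.asarray(tri)[None]
    for _ in range(depth):
        tris = _subdivide(tris)
    centers = tris.mean(axis=1)
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    keep = np.ones(len(tris), dtype=bool)
    for u, c, _, _ in caps:
        keep &= centers @ u < c
    if not keep.any():
        return 0.0, None
    areas = np.array([polygon_area(list(t), [("G",)] * 3) for t in tris[keep]])
    centroid = _tri_centroids_raw(tris[keep]).sum(axis=0)
    nc = np.linalg.norm(centroid)
    if nc < 1e-12:
        return float(areas.sum()), None
    return float(areas.sum()), centroid / nc


_GREAT3 = [("G",)] * 3


def _exposed_pieces(tri, caps):
    """Clip one unit-sphere triangle against all caps.

    Returns list of (area, representative_point) on the unit sphere.
    """
    polys = [([tri[0], tri[1], tri[2]], _GREAT3)]
    for u, c, a1c, a2c in caps:
        new_polys = []
        for verts, edges in polys:
            try:
                clipped, touched = clip_polygon(verts, edges, u, c, a1c, a2c)
            except (CavityError, ValueError, ZeroDivisionError):
                return [_sample_area(tri, caps)]
            if not touched:
                if all(_dot3(u, v) > c for v in verts):
                    continue  # fully covered
                if _cap_pole_in_triangle(u, tri):
                    return [_sample_area(tri, caps)]  # cap hole inside
                new_polys.append((verts, edges))
            else:
                new_polys.extend(clipped)
        polys = new_polys
        if not polys:
            return []
    out = []
    for verts, edges in polys:
        area = polygon_area(verts, edges)
        if not (0.0 <= area <= _TWO_PI):
            return [_sample_area(tri, caps)]
        cen = polygon_centroid_raw(verts, edges)
        nc = _norm3(cen)
        if nc < 1e-9:
            return [_sample_area(tri, caps)]
        out.append((area, cen / nc))
    return out


def _cap_pole_in_triangle(u, tri) -> bool:
    for k in range(3):
        if _dot3(u, _cross3(tri[k], tri[(k + 1) % 3])) < 0.0:
            return False
    return True


@lru_cache(maxsize=8)
def _base_areas(n_per_sphere: int) -> np.ndarray:
    """Unit-sphere areas of the uncut mesh triangles (rotation invariant)."""
    mesh = _base_mesh(n_per_sphere)
    return np.array([polygon_area(list(t), _GREAT3) for t in mesh])


@lru_cache(maxsize=8)
def _base_centroids(n_per_sphere: int) -> np.ndarray:
    """Normalized surface centroids of the uncut mesh triangles."""
    cen = _tri_centroids_raw(_base_mesh(n_per_sphere))
    return cen / np.linalg.norm(cen, axis=1, keepdims=True)


def _tessellate_sphere(s: Sphere, caps, mesh, min_area: float, base_areas, mesh_centroids):
    """Tesserae of one sphere: (positions, areas) lists (bohr units)."""
    positions, areas = [], []
    ntri = len(mesh)
    if caps:
        margin = _mesh_margin_for(ntri, mesh)
        uarr = np.array([cap[0] for cap in caps])
        carr = np.array([cap[1] for cap in caps])
        d = np.einsum("tvk,ck->tvc", mesh, uarr)  # (ntri, 3, ncaps)
        covered = (d > (carr + margin)[None, None, :]).all(axis=1).any(axis=1)
        near = (d.max(axis=1) > (carr - margin)[None, :]) & (
            d.min(axis=1) < (carr + margin)[None, :]
        )
        cut_any = near.any(axis=1)
    r2 = s.radius * s.radius
    for ti in range(ntri):
        tri = mesh[ti]
        if caps:
            if covered[ti]:
                continue
            if cut_any[ti]:
                pieces = _exposed_pieces(tri, [caps[kc] for kc in np.where(near[ti])[0]])
            else:
                pieces = [(base_areas[ti], mesh_centroids[ti])]
        else:
            pieces = [(base_areas[ti], mesh_centroids[ti])]
        for area_u, point_u in pieces:
            if point_u is None or area_u * r2 < min_area:
                continue
            if caps:
                point_u = _push_outside(point_u, caps)
            positions.append(s.center + s.radius * point_u)
            areas.append(area_u * r2)
    return positions, areas


_margin_cache = {}


def _mesh_margin_for(ntri, mesh) -> float:
    # u.x over a spherical triangle deviates from the vertex values by at
    # most the largest edge sagitta 1 - cos(omega/2)
    m = _margin_cache.get(ntri)
    if m is None:
        worst = 0.0
        for k in range(3):
            cosw = np.einsum(
                "tk,tk->t", mesh[:, k], mesh[:, (k + 1) % 3]
            )
            half = np.cos(0.5 * np.arccos(np.clip(cosw, -1.0, 1.0)))
            worst = max(worst, float(np.max(1.0 - half)))
        m = 1.5 * worst + 1e-9
        _margin_cache[ntri] = m
    return m


def _push_outside(point, caps, margin=1e-9):
    """Rotate a representative point out of any cap it fell into."""
    for _ in range(4):
        moved = False
        for u, c, a1, a2 in caps:
            if _dot3(point, u) > c:
                perp = point - _dot3(point, u) * u
                npn = _norm3(perp)
                if npn < 1e-12:
                    perp, npn = a1, 1.0
                perp = perp / npn
                sth = math.sqrt(max(0.0, 1.0 - (c - margin) ** 2))
                point = (c - margin) * u + sth * perp
                moved = True
        if not moved:
            break
    return point


def tessellate_gepol(
    spheres,
    n_per_sphere: int = 60,
    frame: np.ndarray | None = None,
    min_area: float = 1e-6,
    reference: "Cavity | None" = None,
) -> Cavity:
    """GEPOL tessellation with Gauss-Bonnet exposed areas.

    ``frame`` seeds the mesh orientation; pass the frame of a reference
    geometry to make finite-difference rebuilds continuous.  With
    ``reference`` (same sphere count and settings), spheres whose center,
    radius and cap environment are unchanged reuse the reference tesserae.
    """
    if not spheres:
        raise CavityError("cavity needs at least one sphere")
    if frame is None:
        frame = molecular_frame(np.array([s.center for s in spheres]))
    mesh = _base_mesh(n_per_sphere) @ frame  # rotate seed into molecule frame
    base_areas = _base_areas(n_per_sphere)
    mesh_centroids = _base_centroids(n_per_sphere) @ frame
    all_caps = [_caps_on_sphere(si, spheres) for si in range(len(spheres))]
    reuse = [False] * len(spheres)
    if reference is not None and len(reference.spheres) == len(spheres):
        ref_caps = [_caps_on_sphere(si, reference.spheres) for si in range(len(spheres))]
        for si in range(len(spheres)):
            if not np.array_equal(reference.spheres[si].center, spheres[si].center):
                continue
            if reference.spheres[si].radius != spheres[si].radius:
                continue
            rc, nc = ref_caps[si], all_caps[si]
            if isinstance(rc, str) or isinstance(nc, str):
                reuse[si] = rc == nc
                continue
            if len(rc) != len(nc):
                continue
            same = all(
                np.array_equal(r[0], n[0]) and r[1] == n[1]
                for r, n in zip(rc, nc)
            )
            reuse[si] = same
    positions, areas, sph_idx = [], [], []
    for si, s in enumerate(spheres):
        caps = all_caps[si]
        if caps == "buried":
            continue
        if reuse[si]:
            mask = reference.sphere_index == si
            pos_s = list(reference.positions[mask])
            area_s = list(reference.areas[mask])
        else:
            pos_s, area_s = _tessellate_sphere(
                s, caps, mesh, min_area, base_areas, mesh_centroids
            )
        positions.extend(pos_s)
        areas.extend(area_s)
        sph_idx.extend([si] * len(area_s))
    return Cavity(
        spheres=list(spheres),
        positions=np.array(positions).reshape(-1, 3),
        areas=np.array(areas),
        sphere_index=np.array(sph_idx, dtype=int),
        n_initial_per_sphere=n_per_sphere,
        frame=frame,
    )


def cavity_displacement_rebuild(cavity: Cavity, mol_displaced: Molecule) -> Cavity:
    """Rebuild the cavity at displaced coordinates with the reference mesh
    frame, reusing every sphere whose local environment is unchanged."""
    new_spheres = [
        Sphere(s.atom_index, mol_displaced.coords[s.atom_index].copy(), s.radius)
        for s in cavity.spheres
    ]
    return tessellate_gepol(
        new_spheres,
        cavity.n_initial_per_sphere,
        frame=cavity.frame,
        reference=cavity,
    )


def build_cavity(
    mol: Molecule,
    n_per_sphere: int = 60,
    radii_table: dict | None = None,
    scale: float = 1.2,
    frame: np.ndarray | None = None,
) -> Cavity:
    """Convenience: spheres from the radii table, then GEPOL tessellation."""
    return tessellate_gepol(
        assign_radii(mol, radii_table, scale), n_per_sphere, frame=frame
    )
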