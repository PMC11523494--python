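"""The six dental-topographic metrics.

* DNE  — Dirichlet normal energy: the integral over the surface of the
  squared variation of the unit-normal field; a sharpness/bending measure,
  invariant to scale and rigid motion.  Per face, the energy density is
  e(f) = tr(I^-1 H) where I is the first fundamental form of the triangle
  and H the matching form of the linearly interpolated (angle-weighted)
  vertex normals; the face contributes e(f)*area(f).  The largest 1% of
  contributions are discarded ("DNE 99%") and boundary faces are kept.
* RFI  — relief index, 0.5*ln(SA3D/OA2D) (half-log convention; the raw log
  is available via ``TopoConfig.rfi_half_log=False``).
* OPCR — orientation patch count rotated: contiguous same-aspect face
  patches (8 azimuth sectors, patches of >= 3 faces), averaged over 8
  rotations of 5.625 degrees about z.
* PCV  — portion de ciel visible: per-vertex fraction of 256 northern-
  hemisphere directions not occluded by the surface itself; a wear-
  resistance proxy (flat, exposed surfaces approach 1).
* SA3D — 3D surface area; OA2D — area of the occlusal footprint on z=0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union
from scipy.spatial import Delaunay

from .mesh import TriMesh, TopoConfig, surface_area

__all__ = [
    "TopographyResult",
    "ProjectionResult",
    "dne",
    "projected_area",
    "rfi",
    "opcr",
    "pcv",
    "compute_all",
    "hemisphere_directions",
    "DegenerateProjectionError",
]

log = logging.getLogger(__name__)


class DegenerateProjectionError(ValueError):
    """All vertices project to (nearly) a single point or line."""


@dataclass
class ProjectionResult:
    area: float
    outline: object  # shapely geometry
    mode: str
    alpha: float | None = None
    check2d_flag: bool = False


@dataclass
class TopographyResult:
    """All six metrics for one occlusal surface plus per-element maps."""

    dne_total: float
    dne_convex: float
    dne_concave: float
    rfi: float
    opcr: float
    opc_per_rotation: np.ndarray
    pcv: float
    pcv_unweighted: float
    sa3d: float
    oa2d: float
    face_dne: np.ndarray
    face_opc_bin: np.ndarray
    vertex_pcv: np.ndarray
    alpha_used: float | None = None
    n_faces: int = 0

    METRIC_NAMES = ("dne", "rfi", "opcr", "pcv", "sa3d", "oa2d")

    def as_dict(self) -> dict[str, float]:
        return {
            "dne": self.dne_total,
            "dne_convex": self.dne_convex,
            "dne_concave": self.dne_concave,
            "rfi": self.rfi,
            "opcr": self.opcr,
            "pcv": self.pcv,
            "sa3d": self.sa3d,
            "oa2d": self.oa2d,
        }


# ---------------------------------------------------------------------------
# DNE
# ---------------------------------------------------------------------------

def _fundamental_forms(mesh: TriMesh, normals: np.ndarray):
    f = mesh.faces
    t = mesh.triangles()
    u = t[:, 1] - t[:, 0]
    v = t[:, 2] - t[:, 0]
    nu = normals[f[:, 1]] - normals[f[:, 0]]
    nv = normals[f[:, 2]] - normals[f[:, 0]]
    E = np.einsum("ij,ij->i", u, u)
    F = np.einsum("ij,ij->i", u, v)
    G = np.einsum("ij,ij->i", v, v)
    return u, v, nu, nv, E, F, G


def dne(mesh: TriMesh, config: TopoConfig | None = None):
    """Dirichlet normal energy with convex/concave split and outlier trim.

    Returns ``(dne_total, dne_convex, dne_concave, face_dne)`` where
    ``face_dne`` holds each face's retained energy*area contribution, signed
    by the convexity label (positive convex, negative concave) and zeroed
    for trimmed faces.
    """
    config = config or TopoConfig()
    normals = mesh.vertex_normals()
    u, v, nu, nv, E, F, G = _fundamental_forms(mesh, normals)
    det = E * G - F * F
    areas = 0.5 * np.sqrt(np.maximum(det, 0.0))
    scale = max(np.median(det[det > 0]), 1e-300) if (det > 0).any() else 1.0
    good = det > 1e-12 * scale
    n_bad = int((~good).sum())
    if n_bad:
        log.warning("dne: excluded %d faces with degenerate metric", n_bad)

    e = np.einsum("ij,ij->i", nu, nu)
    fm = np.einsum("ij,ij->i", nu, nv)
    g = np.einsum("ij,ij->i", nv, nv)
    density = np.zeros(len(E))
    density[good] = (e * G - 2.0 * fm * F + g * E)[good] / det[good]
    contrib = density * areas

    # convexity: sign of the mean-curvature estimate from the interpolated
    # normal field (positive = bends toward the normal, i.e. a dome)
    b11 = np.einsum("ij,ij->i", u, nu)
    b12 = 0.5 * (np.einsum("ij,ij->i", u, nv) + np.einsum("ij,ij->i", v, nu))
    b22 = np.einsum("ij,ij->i", v, nv)
    mean_curv = np.zeros(len(E))
    mean_curv[good] = (b11 * G - 2.0 * b12 * F + b22 * E)[good] / det[good]
    convex = mean_curv >= 0.0

    considered = good.copy()
    if config.dne_boundary_mode == "exclude":
        considered &= ~mesh.boundary_face_mask()
    keep = considered.copy()
    if config.dne_outlier_quantile > 0.0:
        n_considered = int(considered.sum())
        n_trim = math.ceil(config.dne_outlier_quantile * n_considered)
        if n_trim > 0 and n_considered > n_trim:
            idx = np.flatnonzero(considered)
            order = idx[np.argsort(contrib[idx], kind="stable")]
            keep[order[-n_trim:]] = False

    total = float(contrib[keep].sum())
    cx = float(contrib[keep & convex].sum())
    cc = float(contrib[keep & ~convex].sum())
    face_dne = np.where(keep, np.where(convex, contrib, -contrib), 0.0)
    return total, cx, cc, face_dne


# ---------------------------------------------------------------------------
# Projected occlusal area
# ---------------------------------------------------------------------------

def _projected_polygons(mesh: TriMesh) -> list[Polygon]:
    t2 = mesh.triangles()[:, :, :2]
    e1 = t2[:, 1] - t2[:, 0]
    e2 = t2[:, 2] - t2[:, 0]
    areas2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    scale = max(float(areas2.max(initial=0.0)), 0.0)
    keep = areas2 > 1e-12 * max(scale, 1e-300)
    return [Polygon(tri) for tri in t2[keep]]


def _check_projection(mesh: TriMesh) -> np.ndarray:
    pts = mesh.vertices[:, :2]
    span = pts.max(0) - pts.min(0)
    if np.any(span <= 0) or len(pts) < 3:
        raise DegenerateProjectionError("projection collapses to a point or line")
    # rank check: all points on one line
    c = pts - pts.mean(0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-12 * s[0]:
        raise DegenerateProjectionError("projection collapses to a line")
    return pts


def _alpha_shape(points: np.ndarray, alpha: float, tri: Delaunay):
    simp = tri.simplices
    p = points[simp]
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    kept = simp[circum_r <= alpha]
    if len(kept) == 0:
        return None, kept
    polys = [Polygon(points[s]) for s in kept]
    return unary_union(polys), kept


def projected_area(mesh: TriMesh, config: TopoConfig | None = None) -> ProjectionResult:
    """Area of the mesh footprint on the z=0 plane (the occlusal shadow).

    'union' mode computes the exact union of all projected triangles;
    'alpha_auto' sweeps alpha upward from the mean projected edge length
    until the alpha shape of the projected vertices is a single polygon
    enclosing all points, mimicking tool chains that outline the crown with
    an automatically chosen alpha.  In alpha mode the result is flagged when
    it deviates from the union area by more than 5% (a 2D-projection check).
    """
    config = config or TopoConfig()
    pts = _check_projection(mesh)
    union_geom = unary_union(_projected_polygons(mesh))
    if config.oa_mode == "union":
        return ProjectionResult(float(union_geom.area), union_geom, "union")

    tri = Delaunay(pts)
    edges, _ = mesh.edges_unique()
    elen = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    alpha = max(float(elen.mean()), 1e-12)
    diag = float(np.linalg.norm(pts.max(0) - pts.min(0)))
    shape = None
    while alpha <= 4.0 * diag:
        shape, kept = _alpha_shape(pts, alpha, tri)
        if shape is not None and shape.geom_type == "Polygon":
            covered = np.zeros(len(pts), dtype=bool)
            covered[np.unique(kept)] = True
            if covered.all():
                break
        alpha *= 1.3
    else:
        shape = Polygon(pts[tri.convex_hull[:, 0]]).convex_hull
        alpha = float("inf")
    area = float(shape.area)
    flag = abs(area - union_geom.area) > 0.05 * max(union_geom.area, 1e-300)
    if flag:
        log.warning("projected_area: alpha-shape area deviates >5%% from union area")
    return ProjectionResult(area, shape, "alpha_auto", alpha, flag)


def rfi(mesh: TriMesh, config: TopoConfig | None = None) -> float:
    """Relief index: 0.5*ln(SA3D/OA2D) by default (see module docstring)."""
    config = config or TopoConfig()
    sa = surface_area(mesh)
    oa = projected_area(mesh, config).area
    r = math.log(sa / oa)
    return 0.5 * r if config.rfi_half_log else r


# ---------------------------------------------------------------------------
# OPCR
# ---------------------------------------------------------------------------

def _face_adjacency(mesh: TriMesh) -> np.ndarray:
    edge_map: dict[tuple[int, int], int] = {}
    pairs = []
    for fi, f in enumerate(mesh.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            other = edge_map.pop(key, None)
            if other is None:
                edge_map[key] = fi
            else:
                pairs.append((other, fi))
    return np.array(pairs, dtype=np.int64) if pairs else np.empty((0, 2), dtype=np.int64)


def _bin_faces(mesh: TriMesh, az_offset_deg: float, config: TopoConfig) -> np.ndarray:
    """Azimuth-sector label per face; -1 for faces flatter than the slope
    tolerance (they carry no aspect)."""
    n = mesh.face_normals()
    slope = np.degrees(np.arctan2(np.hypot(n[:, 0], n[:, 1]), n[:, 2]))
    az = np.degrees(np.arctan2(n[:, 1], n[:, 0])) + az_offset_deg
    width = 360.0 / config.opcr_bins
    bins = np.floor(np.mod(az + width / 2.0, 360.0) / width).astype(np.int64)
    bins[slope <= config.opcr_slope_tol_deg] = -1
    return bins


def _patch_sizes(bins: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Sizes of edge-connected components of same-bin (non-flat) faces."""
    parent = np.arange(len(bins))

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in adjacency:
        if bins[a] != -1 and bins[a] == bins[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = {}
    for i in range(len(bins)):
        if bins[i] == -1:
            continue
        r = find(i)
        roots[r] = roots.get(r, 0) + 1
    return np.array(sorted(roots.values()), dtype=np.int64)


def opcr(mesh: TriMesh, config: TopoConfig | None = None):
    """Orientation patch count rotated.

    Returns ``(opcr, opc_per_rotation, face_opc_bin)``; ``face_opc_bin`` is
    the sector label of each face at rotation 0 (-1 = flat).
    """
    config = config or TopoConfig()
    adjacency = _face_adjacency(mesh)
    counts = np.empty(config.opcr_rotations, dtype=np.int64)
    face_bins0 = None
    for k in range(config.opcr_rotations):
        # rotating the mesh by +angle about z adds the angle to every
        # normal's azimuth, so the bins can be computed without moving it
        bins = _bin_faces(mesh, k * config.opcr_step_deg, config)
        if k == 0:
            face_bins0 = bins
        sizes = _patch_sizes(bins, adjacency)
        counts[k] = int((sizes >= config.opcr_min_patch).sum())
    return float(counts.mean()), counts, face_bins0


# ---------------------------------------------------------------------------
# PCV
# ---------------------------------------------------------------------------

def hemisphere_directions(count: int) -> np.ndarray:
    """Deterministic quasi-uniform (Fibonacci spiral) directions on the +z
    hemisphere."""
    i = np.arange(count)
    z = (i + 0.5) / count
    r = np.sqrt(1.0 - z * z)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = i * golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _direction_basis(d: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(d, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    return np.column_stack([t1, t2, d])


def _parallel_occlusion(origins: np.ndarray, tris: np.ndarray, d: np.ndarray) -> np.ndarray:
    """For parallel rays from ``origins`` along ``d``: True where a ray hits
    any triangle at t > 0.  2D grid bucketing prunes candidate triangles."""
    B = _direction_basis(d)
    O = origins @ B
    T = tris.reshape(-1, 3) @ B
    T = T.reshape(-1, 3, 3)
    nt = len(T)
    lo = T[:, :, :2].min(axis=1)
    hi = T[:, :, :2].max(axis=1)
    gmin = lo.min(axis=0)
    gmax = hi.max(axis=0)
    span = np.maximum(gmax - gmin, 1e-300)
    ncell = int(np.clip(math.sqrt(nt / 2.0), 1, 128))
    inv = ncell / span

    ix0 = np.clip(((lo[:, 0] - gmin[0]) * inv[0]).astype(np.int64), 0, ncell - 1)
    ix1 = np.clip(((hi[:, 0] - gmin[0]) * inv[0]).astype(np.int64), 0, ncell - 1)
    iy0 = np.clip(((lo[:, 1] - gmin[1]) * inv[1]).astype(np.int64), 0, ncell - 1)
    iy1 = np.clip(((hi[:, 1] - gmin[1]) * inv[1]).astype(np.int64), 0, ncell - 1)
    nxs = ix1 - ix0 + 1
    nys = iy1 - iy0 + 1
    counts = nxs * nys
    tri_rep = np.repeat(np.arange(nt), counts)
    total = int(counts.sum())
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    local = np.arange(total) - np.repeat(starts, counts)
    cx = ix0[tri_rep] + local % nxs[tri_rep]
    cy = iy0[tri_rep] + local // nxs[tri_rep]
    cell_of_tri = cx * ncell + cy
    order = np.argsort(cell_of_tri, kind="stable")
    cell_sorted = cell_of_tri[order]
    tri_sorted = tri_rep[order]

    vx = np.clip(((O[:, 0] - gmin[0]) * inv[0]).astype(np.int64), 0, ncell - 1)
    vy = np.clip(((O[:, 1] - gmin[1]) * inv[1]).astype(np.int64), 0, ncell - 1)
    vcell = vx * ncell + vy
    left = np.searchsorted(cell_sorted, vcell, side="left")
    right = np.searchsorted(cell_sorted, vcell, side="right")
    vcounts = right - left
    nv = len(O)
    pair_v = np.repeat(np.arange(nv), vcounts)
    ptotal = int(vcounts.sum())
    if ptotal == 0:
        return np.zeros(nv, dtype=bool)
    pstarts = np.concatenate([[0], np.cumsum(vcounts)[:-1]])
    poff = np.arange(ptotal) - np.repeat(pstarts, vcounts)
    pair_t = tri_sorted[np.repeat(left, vcounts) + poff]

    hit = _parallel_hits(O[pair_v], T[pair_t])
    occluded = np.zeros(nv, dtype=bool)
    np.logical_or.at(occluded, pair_v, hit)
    return occluded


def _parallel_hits(P: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Ray (0,0,1) in local coordinates vs triangles: barycentric containment
    in xy plus strictly positive travel along z."""
    a, b, c = T[:, 0], T[:, 1], T[:, 2]
    e1 = b[:, :2] - a[:, :2]
    e2 = c[:, :2] - a[:, :2]
    denom = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    ok = denom != 0.0
    q = P[:, :2] - a[:, :2]
    safe = np.where(ok, denom, 1.0)
    wb = (q[:, 0] * e2[:, 1] - q[:, 1] * e2[:, 0]) / safe
    wc = (e1[:, 0] * q[:, 1] - e1[:, 1] * q[:, 0]) / safe
    wa = 1.0 - wb - wc
    inside = ok & (wa >= 0.0) & (wb >= 0.0) & (wc >= 0.0)
    zhit = wa * a[:, 2] + wb * b[:, 2] + wc * c[:, 2]
    return inside & (zhit > P[:, 2])


def pcv(mesh: TriMesh, config: TopoConfig | None = None):
    """Portion de ciel visible (ambient occlusion from the occlusal sky).

    Returns ``(pcv_area_weighted, pcv_unweighted, vertex_pcv)``.  A vertex
    sees a direction d when d points out of the surface (d . n > 0) and a
    ray from the vertex (offset a small epsilon along its normal) along d
    hits no face of the mesh.
    """
    config = config or TopoConfig()
    dirs = hemisphere_directions(config.pcv_count)
    vn = mesh.vertex_normals()
    eps = 1e-4 * mesh.bbox_diagonal()
    origins = mesh.vertices + eps * vn
    tris = mesh.triangles()
    seen = np.zeros(mesh.n_vertices, dtype=np.int64)
    for d in dirs:
        facing = vn @ d > 0.0
        occ = _parallel_occlusion(origins, tris, d)
        seen += facing & ~occ
    vertex_pcv = seen / float(config.pcv_count)
    areas = mesh.face_areas()
    w = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(w, mesh.faces[:, corner], areas / 3.0)
    wsum = w.sum()
    pcv_w = float((w * vertex_pcv).sum() / wsum) if wsum > 0 else float(vertex_pcv.mean())
    return pcv_w, float(vertex_pcv.mean()), vertex_pcv


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------

def compute_all(mesh: TriMesh, config: TopoConfig | None = None, preprocess: bool = False) -> TopographyResult:
    """Compute every metric on an (already preprocessed) occlusal surface.

    ``preprocess=True`` first runs the standard chain
    clean -> decimate -> Taubin smooth with the config's parameters.
    Deterministic: identical mesh + config give bit-identical results.
    """
    config = config or TopoConfig()
    if preprocess:
        from .mesh import clean_mesh, taubin_smooth
        from .decimate import decimate as _decimate

        mesh = clean_mesh(mesh, config)
        mesh = _decimate(mesh, config.decimate_target)
        mesh = taubin_smooth(mesh, config.taubin_lambda, config.taubin_mu, config.taubin_iters)
    d_total, d_cx, d_cc, face_dne = dne(mesh, config)
    proj = projected_area(mesh, config)
    sa = surface_area(mesh)
    r = math.log(sa / proj.area)
    if config.rfi_half_log:
        r *= 0.5
    oc, per_rot, face_bins = opcr(mesh, config)
    p_w, p_u, vertex_pcv = pcv(mesh, config)
    return TopographyResult(
        dne_total=d_total,
        dne_convex=d_cx,
        dne_concave=d_cc,
        rfi=r,
        opcr=oc,
        opc_per_rotation=per_rot,
        pcv=p_w,
        pcv_unweighted=p_u,
        sa3d=sa,
        oa2d=proj.area,
        face_dne=face_dne,
        face_opc_bin=face_bins,
        vertex_pcv=vertex_pcv,
        alpha_used=proj.alpha,
        n_faces=mesh.n_faces,
    )
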