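"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a production quantity by the most direct method
available — full enumeration, all-pairs ray casting, pixel counting,
networkx connected components — sharing no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import networkx as nx
from scipy.stats import rankdata

from molartopo import TriMesh, TopoConfig, rotate_mesh
from molartopo.metrics import hemisphere_directions


# ---------------------------------------------------------------------------
# PCV: all-faces Möller–Trumbore ray casting
# ---------------------------------------------------------------------------

def brute_force_pcv(mesh: TriMesh, count: int) -> np.ndarray:
    """Per-vertex visible-direction fraction by testing every ray against
    every face in 3D (no spatial pruning, no projection)."""
    dirs = hemisphere_directions(count)
    vn = mesh.vertex_normals()
    eps = 1e-4 * mesh.bbox_diagonal()
    origins = mesh.vertices + eps * vn
    t = mesh.triangles()
    v0, e1, e2 = t[:, 0], t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]
    seen = np.zeros(mesh.n_vertices, dtype=np.int64)
    for d in dirs:
        pvec = np.cross(d, e2)  # (nf, 3)
        det = np.einsum("fj,fj->f", e1, pvec)
        ok = det != 0.0
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origins[:, None, :] - v0[None, :, :]  # (nv, nf, 3)
        u = np.einsum("vfj,fj->vf", tvec, pvec) * inv
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("vfj,j->vf", qvec, d) * inv
        tt = np.einsum("vfj,fj->vf", qvec, e2) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (tt > 0)
        occluded = hit.any(axis=1)
        facing = vn @ d > 0
        seen += facing & ~occluded
    return seen / float(count)


# ---------------------------------------------------------------------------
# OPCR: networkx connected components on explicitly rotated meshes
# ---------------------------------------------------------------------------

def brute_force_opc(mesh: TriMesh, config: TopoConfig) -> list[int]:
    """Patch counts per rotation via physical mesh rotation and networkx."""
    counts = []
    width = 360.0 / config.opcr_bins
    for k in range(config.opcr_rotations):
        m = rotate_mesh(mesh, "z", k * config.opcr_step_deg)
        n = m.face_normals()
        slope = np.degrees(np.arctan2(np.hypot(n[:, 0], n[:, 1]), n[:, 2]))
        az = np.degrees(np.arctan2(n[:, 1], n[:, 0]))
        bins = np.floor(np.mod(az + width / 2.0, 360.0) / width).astype(int)
        bins[slope <= config.opcr_slope_tol_deg] = -1
        g = nx.Graph()
        g.add_nodes_from(i for i in range(m.n_faces) if bins[i] != -1)
        edge_owner: dict[tuple[int, int], int] = {}
        for fi, f in enumerate(m.faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                if key in edge_owner:
                    fj = edge_owner[key]
                    if bins[fi] != -1 and bins[fi] == bins[fj]:
                        g.add_edge(fi, fj)
                else:
                    edge_owner[key] = fi
        sizes = [len(c) for c in nx.connected_components(g)]
        counts.append(sum(1 for s in sizes if s >= config.opcr_min_patch))
    return counts


# ---------------------------------------------------------------------------
# Projected area: supersampled pixel counting
# ---------------------------------------------------------------------------

def rasterized_projected_area(mesh: TriMesh, n_pixels: int = 4096) -> float:
    """Fraction of pixel centers covered by any projected triangle, times
    the bounding-box area."""
    pts = mesh.vertices[:, :2]
    lo, hi = pts.min(0), pts.max(0)
    span = hi - lo
    hx, hy = span / n_pixels
    mask = np.zeros((n_pixels, n_pixels), dtype=bool)
    t2 = mesh.triangles()[:, :, :2]
    for a, b, c in t2:
        denom = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if denom == 0.0:
            continue
        tlo = np.minimum(np.minimum(a, b), c)
        thi = np.maximum(np.maximum(a, b), c)
        i0 = max(int((tlo[0] - lo[0]) / hx), 0)
        i1 = min(int((thi[0] - lo[0]) / hx) + 1, n_pixels)
        j0 = max(int((tlo[1] - lo[1]) / hy), 0)
        j1 = min(int((thi[1] - lo[1]) / hy) + 1, n_pixels)
        if i0 >= i1 or j0 >= j1:
            continue
        xs = lo[0] + (np.arange(i0, i1) + 0.5) * hx
        ys = lo[1] + (np.arange(j0, j1) + 0.5) * hy
        px, py = np.meshgrid(xs, ys, indexing="ij")
        wb = ((px - a[0]) * (c[1] - a[1]) - (py - a[1]) * (c[0] - a[0])) / denom
        wc = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) / denom
        wa = 1.0 - wb - wc
        mask[i0:i1, j0:j1] |= (wa >= 0) & (wb >= 0) & (wc >= 0)
    return float(mask.mean() * span[0] * span[1])


# ---------------------------------------------------------------------------
# Exact rank tests: full enumeration
# ---------------------------------------------------------------------------

def signed_rank_p_bruteforce(diffs) -> tuple[float, float]:
    """(statistic, two-sided p) over all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([1, -1], repeat=n):
        s = np.array(signs)
        ws.append(ranks[s > 0].sum())
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return float(w_obs), min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_p_bruteforce(a, b) -> tuple[float, float]:
    """(U=min(Ua,Ub), two-sided p) over all C(n1+n2, n1) labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    ua_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_obs = min(ua_obs, n1 * n2 - ua_obs)
    uas = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        uas.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0)
    uas = np.array(uas)
    p_le = float((uas <= ua_obs + 1e-12).mean())
    p_ge = float((uas >= ua_obs - 1e-12).mean())
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))
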