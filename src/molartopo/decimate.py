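"""Quadric edge-collapse decimation.

Topographic metrics such as DNE and OPCR are summative and sensitive to
triangle count, so all surfaces are reduced to a common budget
(~10 000 faces) before metrics are computed.  The reduction is the classic
Garland–Heckbert scheme: each vertex accumulates the squared-distance
quadric of its supporting planes, edges are collapsed cheapest-first to the
position minimising the combined quadric, and collapses that would flip a
face normal are rejected (normal preservation).  Boundary edges receive
perpendicular constraint quadrics so open occlusal crops keep their outline
and surface area.
"""

from __future__ import annotations

import heapq

import numpy as np

from .mesh import TriMesh

__all__ = ["decimate"]

_FLIP_TOL = 0.2  # minimum dot(old normal, new normal) for an accepted collapse
_BOUNDARY_WEIGHT = 1e3


def _face_normal_area(verts: np.ndarray, f) -> tuple[np.ndarray, float]:
    a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
    cr = np.cross(b - a, c - a)
    n = np.linalg.norm(cr)
    return (cr / n if n > 0 else cr), 0.5 * n


def _plane_quadric(normal: np.ndarray, point: np.ndarray, weight: float) -> np.ndarray:
    p = np.empty(4)
    p[:3] = normal
    p[3] = -normal.dot(point)
    return weight * np.outer(p, p)


def _optimal_position(Q: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> tuple[np.ndarray, float]:
    A = Q[:3, :3]
    b = Q[:3, 3]
    pos = None
    if abs(np.linalg.det(A)) > 1e-10 * max(np.abs(A).max() ** 3, 1e-300):
        pos = np.linalg.solve(A, -b)
    candidates = [pos] if pos is not None else []
    candidates += [v1, v2, 0.5 * (v1 + v2)]
    best, best_cost = None, np.inf
    for c in candidates:
        h = np.append(c, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = c, cost
    return best, max(best_cost, 0.0)


def decimate(mesh: TriMesh, target_faces: int) -> TriMesh:
    """Collapse edges until the face count reaches ``target_faces``.

    Returns the input unchanged (a copy) when it is already at or below the
    target.  If blocked collapses exhaust the candidate edges before the
    target is reached the achieved count is returned as-is.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return mesh.copy()

    verts = mesh.vertices.copy()
    faces = [tuple(f) for f in mesh.faces]
    alive = [True] * len(faces)
    n_alive = len(faces)

    vfaces: list[set[int]] = [set() for _ in range(len(verts))]
    for fi, f in enumerate(faces):
        for v in f:
            vfaces[v].add(fi)

    quadrics = np.zeros((len(verts), 4, 4))
    for fi, f in enumerate(faces):
        n, area = _face_normal_area(verts, f)
        if area == 0.0:
            continue
        K = _plane_quadric(n, verts[f[0]], area)
        for v in f:
            quadrics[v] += K

    # boundary constraint quadrics: planes through each boundary edge,
    # perpendicular to its single supporting face
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            edge_faces.setdefault(key, []).append(fi)
    neighbors: list[set[int]] = [set() for _ in range(len(verts))]
    for (a, b), fl in edge_faces.items():
        neighbors[a].add(b)
        neighbors[b].add(a)
        if len(fl) == 1:
            n, area = _face_normal_area(verts, faces[fl[0]])
            edge = verts[b] - verts[a]
            elen = np.linalg.norm(edge)
            if elen == 0.0 or area == 0.0:
                continue
            cn = np.cross(edge / elen, n)
            K = _plane_quadric(cn, verts[a], _BOUNDARY_WEIGHT * elen * elen)
            quadrics[a] += K
            quadrics[b] += K

    version = np.zeros(len(verts), dtype=np.int64)
    heap: list[tuple[float, int, int, int, int, int]] = []
    counter = 0

    def push_edge(a: int, b: int) -> None:
        nonlocal counter
        Q = quadrics[a] + quadrics[b]
        _, cost = _optimal_position(Q, verts[a], verts[b])
        heapq.heappush(heap, (cost, counter, a, b, version[a], version[b]))
        counter += 1

    for a in range(len(verts)):
        for b in neighbors[a]:
            if a < b:
                push_edge(a, b)

    while n_alive > target_faces and heap:
        cost, _, a, b, va, vb = heapq.heappop(heap)
        if version[a] != va or version[b] != vb:
            continue
        if b not in neighbors[a]:
            continue
        Q = quadrics[a] + quadrics[b]
        pos, _ = _optimal_position(Q, verts[a], verts[b])

        dying = vfaces[a] & vfaces[b]
        surviving = (vfaces[a] | vfaces[b]) - dying
        # reject collapses that flip or degenerate any surviving face
        ok = True
        old_a, old_b = verts[a].copy(), verts[b].copy()
        for fi in surviving:
            n_old, area_old = _face_normal_area(verts, faces[fi])
            if area_old == 0.0:
                continue
            f_new = tuple(a if v == b else v for v in faces[fi])
            if len(set(f_new)) < 3:
                ok = False
                break
            verts[a] = pos
            n_new, area_new = _face_normal_area(verts, f_new)
            verts[a] = old_a
            if area_new <= 0.0 or float(n_old.dot(n_new)) < _FLIP_TOL:
                ok = False
                break
        if not ok:
            continue

        # commit: merge b into a at the optimal position
        verts[a] = pos
        quadrics[a] = Q
        for fi in dying:
            if alive[fi]:
                alive[fi] = False
                n_alive -= 1
            for v in faces[fi]:
                vfaces[v].discard(fi)
        for fi in list(vfaces[b]):
            faces[fi] = tuple(a if v == b else v for v in faces[fi])
            vfaces[b].discard(fi)
            vfaces[a].add(fi)
        for nb in list(neighbors[b]):
            neighbors[nb].discard(b)
            if nb != a:
                neighbors[nb].add(a)
                neighbors[a].add(nb)
        neighbors[a].discard(a)
        neighbors[a].discard(b)
        neighbors[b].clear()
        # only a's quadric and position changed, so only a's edges re-cost
        version[a] += 1
        version[b] += 1
        for nb in neighbors[a]:
            push_edge(min(a, nb), max(a, nb))

    out_faces = np.array([faces[i] for i in range(len(faces)) if alive[i]], dtype=np.int64)
    used = np.unique(out_faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(verts[used], remap[out_faces])
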