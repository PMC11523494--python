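"""Parametric molar-like test surfaces and a wear operator.

Real occlusal scans are not redistributable, so the package ships a
generator of height-field surfaces that emulate the two molar morphotypes
under study: cusped (tall Gaussian bumps, the forbivore-like form) and
crested (Gaussian ridges along axes, the graminivore/mixed-feeder-like
form).  A small analytic fixture family (flat disc, unit hemisphere,
Gaussian cusps) provides closed-form oracles for every metric.  Wear is
modelled as truncation of the height field at a quantile followed by one
smoothing pass, which provably lowers relief, sharpness and complexity and
raises sky exposure — the qualitative signature of worn molars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .mesh import TriMesh, taubin_smooth

__all__ = [
    "Feature",
    "MolarSpec",
    "make_fixture",
    "make_molar",
    "apply_wear",
    "cusped_molar_spec",
    "crested_molar_spec",
]


@dataclass
class Feature:
    """One occlusal feature: a cusp (radial Gaussian bump) or a crest
    (Gaussian ridge along a segment).  Heights and widths in mm."""

    kind: str  # 'cusp' | 'crest'
    center: tuple[float, float] | None = None  # cusp apex (x, y)
    axis: tuple[tuple[float, float], tuple[float, float]] | None = None  # crest segment
    height: float = 1.0
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("cusp", "crest"):
            raise ValueError("feature kind must be 'cusp' or 'crest'")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("feature height and width must be positive")
        if self.kind == "cusp" and self.center is None:
            raise ValueError("cusp needs a center")
        if self.kind == "crest" and self.axis is None:
            raise ValueError("crest needs an axis segment")


@dataclass
class MolarSpec:
    """Recipe for a synthetic molar surface; the seed fixes it exactly."""

    grid_n: int = 80
    extent: float = 4.0  # mm, square base side
    base_noise_sd: float = 0.02  # mm (0.5% of the default extent)
    features: list[Feature] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n < 16:
            raise ValueError("grid_n must be >= 16")
        if self.extent <= 0:
            raise ValueError("extent must be positive")


def _grid_mesh(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> TriMesh:
    """Triangulated height-field grid with a uniform diagonal direction."""
    n, m = z.shape
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    idx = np.arange(n * m).reshape(n, m)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return TriMesh(verts, faces)


def _height(spec: MolarSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    z = np.zeros_like(xx)
    for f in spec.features:
        if f.kind == "cusp":
            cx, cy = f.center
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            z += f.height * np.exp(-r2 / (2.0 * f.width**2))
        else:
            (x0, y0), (x1, y1) = f.axis
            px, py = xx - x0, yy - y0
            dx, dy = x1 - x0, y1 - y0
            L2 = dx * dx + dy * dy
            t = np.clip((px * dx + py * dy) / max(L2, 1e-300), 0.0, 1.0)
            d2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
            z += f.height * np.exp(-d2 / (2.0 * f.width**2))
    return z


# Control lattice for the band-limited surface roughness.  The correlation
# length (~extent/8) keeps slopes everywhere above the OPCR flatness
# tolerance — no degenerate exactly-flat regions — while leaving the
# anatomical features (cusps, crests) as the dominant patch structure.
_NOISE_GRID = 9


def make_molar(spec: MolarSpec) -> TriMesh:
    """Height-field molar surface: sum of features plus band-limited
    Gaussian roughness, triangulated on a regular grid.

    The roughness is white noise drawn once on a fixed 33x33 control
    lattice (from the seed) and spline-interpolated to the render grid, so
    the same seed describes the same surface at every ``grid_n`` and the
    mesh converges under refinement — like a real scanned surface, whose
    roughness is spatially correlated rather than per-vertex.
    """
    from scipy.interpolate import RectBivariateSpline

    n = spec.grid_n
    half = spec.extent / 2.0
    x = np.linspace(-half, half, n)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    z = _height(spec, xx, yy)
    if spec.base_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coarse = rng.normal(0.0, spec.base_noise_sd, size=(_NOISE_GRID, _NOISE_GRID))
        xc = np.linspace(-half, half, _NOISE_GRID)
        z = z + RectBivariateSpline(xc, xc, coarse, kx=3, ky=3)(x, x)
    return _grid_mesh(x, x, z)


def cusped_molar_spec(seed: int = 0, n_cusps: int = 4, height: float = 1.2,
                      width: float = 0.45, grid_n: int = 80) -> MolarSpec:
    """Forbivore-like morphotype: a ring of tall, pointed cusps."""
    feats = []
    for k in range(n_cusps):
        ang = 2.0 * math.pi * k / n_cusps + math.pi / 4.0
        feats.append(Feature("cusp", center=(1.0 * math.cos(ang), 1.0 * math.sin(ang)),
                             height=height, width=width))
    return MolarSpec(grid_n=grid_n, features=feats, seed=seed)


def crested_molar_spec(seed: int = 0, n_crests: int = 2, height: float = 1.2,
                       width: float = 0.45, grid_n: int = 80) -> MolarSpec:
    """Graminivore-like morphotype: low parallel ridges (lophs)."""
    feats = []
    for k in range(n_crests):
        y = -1.0 + 2.0 * k / max(n_crests - 1, 1) if n_crests > 1 else 0.0
        feats.append(Feature("crest", axis=((-1.4, y), (1.4, y)), height=height, width=width))
    return MolarSpec(grid_n=grid_n, features=feats, seed=seed)


def make_fixture(name: str, resolution: int = 32) -> TriMesh:
    """Deterministic analytic surfaces with closed-form metric values.

    flat_disc    : planar unit disc (RFI 0, DNE 0, PCV 1, OPCR 0).
    hemisphere   : open unit hemisphere (SA -> 2*pi, OA -> pi, DNE -> 4*pi).
    single_cusp  : one centered Gaussian bump, height 1 mm, sigma 0.5 mm,
                   on a 4x4 mm base (8 orientation patches).
    two_cusps    : two well-separated identical bumps (16 patches).
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    if name == "flat_disc":
        x = np.linspace(-1.0, 1.0, resolution)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 1.0 + 1e-12]
        tri = Delaunay(pts)
        faces = tri.simplices.astype(np.int64)
        p = pts[faces]
        cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                 - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
        keep = np.abs(cross) > 1e-12  # drop collinear slivers on the rim
        faces, cross = faces[keep], cross[keep]
        faces[cross < 0] = faces[cross < 0][:, ::-1]  # normals toward +z
        verts = np.column_stack([pts, np.zeros(len(pts))])
        return TriMesh(verts, faces)
    if name == "hemisphere":
        m = resolution  # latitude rings below the pole
        n_az = 4 * resolution
        theta = np.linspace(0.0, math.pi / 2.0, m + 1)[1:]
        phi = np.linspace(0.0, 2.0 * math.pi, n_az, endpoint=False)
        verts = [np.array([0.0, 0.0, 1.0])]
        for t in theta:
            st, ct = math.sin(t), math.cos(t)
            ring = np.column_stack([st * np.cos(phi), st * np.sin(phi),
                                    np.full(n_az, ct)])
            verts.append(ring)
        verts = np.vstack(verts)
        faces = []
        for j in range(n_az):  # pole fan
            faces.append([0, 1 + j, 1 + (j + 1) % n_az])
        for i in range(m - 1):
            r0 = 1 + i * n_az
            r1 = r0 + n_az
            for j in range(n_az):
                jn = (j + 1) % n_az
                faces.append([r0 + j, r1 + j, r1 + jn])
                faces.append([r0 + j, r1 + jn, r0 + jn])
        return TriMesh(verts, np.array(faces, dtype=np.int64))
    if name in ("single_cusp", "two_cusps"):
        if name == "single_cusp":
            feats = [Feature("cusp", center=(0.0, 0.0), height=1.0, width=0.5)]
        else:
            # far enough apart that each tail is below the OPCR slope
            # tolerance before the fields overlap: truly disjoint cusps
            feats = [Feature("cusp", center=(-1.2, 0.0), height=1.0, width=0.25),
                     Feature("cusp", center=(1.2, 0.0), height=1.0, width=0.25)]
        spec = MolarSpec(grid_n=max(resolution, 16), extent=4.0,
                         base_noise_sd=0.0, features=feats, seed=0)
        return make_molar(spec)
    raise ValueError(f"unknown fixture {name!r}")


def apply_wear(mesh: TriMesh, wear_fraction: float) -> TriMesh:
    """Truncate the height field at the (1 - wear_fraction) quantile of
    vertex heights, then round the truncation rim with a short pure-diffusion
    schedule (three umbrella-Laplacian steps, step 0.5).

    The rim rounding deliberately avoids a two-step (Taubin) pass: the
    inflate step raises a ring of vertices just inside the truncation
    plateau, which injects spurious orientation patches into OPCR; pure
    diffusion only ever moves the rim downhill, so wear removes surface
    structure and never creates it.  ``wear_fraction`` 0 is the identity.
    """
    if not 0.0 <= wear_fraction < 1.0:
        raise ValueError("wear_fraction must be in [0, 1)")
    if wear_fraction == 0.0:
        return mesh.copy()
    z = mesh.vertices[:, 2]
    cut = float(np.quantile(z, 1.0 - wear_fraction))
    verts = mesh.vertices.copy()
    verts[:, 2] = np.minimum(z, cut)
    worn = TriMesh(verts, mesh.faces.copy())
    return taubin_smooth(worn, 0.5, 0.0, 3)
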