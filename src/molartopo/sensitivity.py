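"""Orientation-sensitivity protocol.

Topographic metrics differ in how much they depend on how the occlusal
surface is aligned with +z: DNE and 3D surface area are rigid-motion
invariant, while RFI, OPCR, PCV and the 2D projected area are not.  The
protocol tilts the mesh clockwise and anticlockwise about x and y — five
variants including the original — recomputes every metric, and summarises
each metric's spread as a coefficient of variation (population sd / mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TriMesh, TopoConfig, rotate_mesh
from .metrics import compute_all

__all__ = ["SensitivityReport", "orientation_sensitivity", "coefficient_of_variation"]


def coefficient_of_variation(values) -> float:
    """Population standard deviation divided by the population mean.

    All-zero inputs give 0; a zero mean with nonzero spread is undefined.
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    sd = float(v.std(ddof=0))
    mean = float(v.mean())
    if mean == 0.0:
        if sd == 0.0:
            return 0.0
        raise ValueError("CV undefined: zero mean with nonzero spread")
    return sd / mean


@dataclass
class SensitivityReport:
    variants: list[tuple[str, float]]  # (axis, angle in degrees)
    values: pd.DataFrame  # one row per variant, one column per metric
    summary: pd.DataFrame  # per metric: mean, population sd, cv

    def cv(self, metric: str) -> float:
        return float(self.summary.loc[metric, "cv"])


def orientation_sensitivity(
    mesh: TriMesh,
    tilt_deg: float = 5.0,
    config: TopoConfig | None = None,
) -> SensitivityReport:
    """Tilt the mesh +-tilt_deg about x and y, recompute all six metrics on
    the five variants and report per-metric coefficients of variation."""
    if tilt_deg < 0:
        raise ValueError("tilt_deg must be >= 0")
    config = config or TopoConfig()
    variants = [("none", 0.0), ("x", tilt_deg), ("x", -tilt_deg),
                ("y", tilt_deg), ("y", -tilt_deg)]
    rows = []
    for axis, angle in variants:
        m = mesh if axis == "none" else rotate_mesh(mesh, axis, angle)
        res = compute_all(m, config)
        rows.append({"dne": res.dne_total, "rfi": res.rfi, "opcr": res.opcr,
                     "pcv": res.pcv, "sa3d": res.sa3d, "oa2d": res.oa2d})
    values = pd.DataFrame(rows, index=[f"{a}{g:+g}" if a != "none" else "original"
                                       for a, g in variants])
    summary = pd.DataFrame({
        "mean": values.mean(),
        "sd": values.std(ddof=0),
    })
    cv = []
    for metric in values.columns:
        col = values[metric].to_numpy()
        cv.append(coefficient_of_variation(col))
    summary["cv"] = cv
    return SensitivityReport(variants, values, summary)
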