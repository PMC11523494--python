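"""Batch pipeline: preprocess meshes, compute metrics, join metadata and run
the full statistical comparison, emitting plain CSV tables and plots.

Outputs mirror the structure of a comparative dental-topography study:

* ``metrics.csv``       — one row per mesh, all six metrics + provenance.
* ``table1_tests.csv``  — rank-test comparisons (side within groups, sex by
  side) with exact p-values and effect sizes.
* ``table2_descriptives.csv`` — mean (sd) by species x sex x side.
* ``table3_best_models.csv``  — coefficients of each metric's best model.
* ``model_selection.csv``     — 8 rows per metric: effects, k, logLik,
  AICc, delta-AICc, Akaike weight.
* ``pearson_*.csv``     — correlation matrices for the full sample and
  per-species/sex subsets.
* ``plot_<metric>.png`` — values by group with left/right lines connecting
  the two molars of each individual.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriMesh, TopoConfig, read_mesh, write_mesh, clean_mesh, taubin_smooth
from .decimate import decimate
from .metrics import compute_all
from . import stats as _stats

__all__ = ["RunConfig", "run_metrics", "run_analysis", "preprocess"]

log = logging.getLogger(__name__)

_METRICS = ["dne", "rfi", "opcr", "pcv", "sa3d", "oa2d"]


@dataclass
class RunConfig:
    """Everything one batch run needs; the manifest (if given) fixes the
    mesh order so runs are independent of filesystem glob order."""

    input_glob: str | None = None
    manifest: list[str] | None = None
    metadata_csv: str | None = None
    topo: TopoConfig = field(default_factory=TopoConfig)
    output_dir: str = "molartopo_out"
    estimator: str = "random_intercept"
    export_maps: bool = False
    seed: int = 0

    def mesh_paths(self) -> list[Path]:
        if self.manifest:
            return [Path(p) for p in self.manifest]
        if self.input_glob:
            return sorted(Path(p) for p in _glob.glob(self.input_glob))
        raise ValueError("RunConfig needs input_glob or manifest")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preprocess(mesh: TriMesh, config: TopoConfig) -> TriMesh:
    """The standard chain: clean -> decimate -> Taubin smooth."""
    m = clean_mesh(mesh, config)
    m = decimate(m, config.decimate_target)
    return taubin_smooth(m, config.taubin_lambda, config.taubin_mu, config.taubin_iters)


def run_metrics(config: RunConfig) -> pd.DataFrame:
    """Preprocess and measure every mesh; one CSV row per mesh.

    Per-mesh failures are logged and skipped, never fatal.  Rerunning with
    the same config and inputs reproduces the table exactly.
    """
    paths = config.mesh_paths()
    if not paths:
        raise ValueError("no input meshes")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    rows = []
    for path in paths:
        t0 = time.perf_counter()
        try:
            raw = read_mesh(path)
            faces_in = raw.n_faces
            m = preprocess(raw, config.topo)
            res = compute_all(m, config.topo)
        except Exception as exc:
            log.warning("skipping %s: %s", path.name, exc)
            continue
        row = {"mesh_id": path.stem, **res.as_dict(),
               "faces_in": faces_in, "faces_after_preprocess": res.n_faces,
               "alpha_used": res.alpha_used if res.alpha_used is not None else np.nan,
               "config_hash": chash}
        rows.append(row)
        log.info("%s: %d -> %d faces in %.2fs", path.stem, faces_in,
                 res.n_faces, time.perf_counter() - t0)
        if config.export_maps:
            write_mesh(m, outdir / f"{path.stem}_maps.ply",
                       vertex_scalars={"pcv": res.vertex_pcv},
                       face_scalars={"dne_signed": res.face_dne,
                                     "opc_bin": res.face_opc_bin.astype(float)})
    if not rows:
        raise ValueError("every mesh in the batch failed")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "metrics.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def _paired_side_rows(df: pd.DataFrame, label: str, metrics: list[str]) -> list[dict]:
    wide = df.pivot_table(index="individual_id", columns="side", values=metrics,
                          aggfunc="first")
    rows = []
    for metric in metrics:
        if ("L" not in wide[metric]) or ("R" not in wide[metric]):
            continue
        sub = wide[metric][["L", "R"]].dropna()
        if len(sub) < 2:
            continue
        diff = (sub["L"] - sub["R"]).to_numpy()
        if np.all(diff == 0):
            continue
        test = _stats.signed_rank_exact(diff)
        eff = _stats.effect_sizes(sub["L"].to_numpy(), sub["R"].to_numpy(), paired=True)
        rows.append({"comparison": "side", "group": label, "metric": metric,
                     "n": test.n, "statistic": test.statistic,
                     "p_exact": test.p_two_sided, "method": test.method,
                     "cohens_d_pooled": eff.cohens_d_pooled,
                     "cohens_d_paired": eff.cohens_d_paired,
                     "rank_r": eff.rank_r})
    return rows


def _sex_rows(df: pd.DataFrame, species: str, metrics: list[str]) -> list[dict]:
    rows = []
    sdf = df[df["species"] == species]
    sexes = sorted(sdf["sex"].unique())
    if len(sexes) != 2:
        return rows
    for side in sorted(sdf["side"].unique()):
        part = sdf[sdf["side"] == side]
        a = part[part["sex"] == sexes[0]]
        b = part[part["sex"] == sexes[1]]
        if len(a) < 2 or len(b) < 2:
            log.warning("sex comparison skipped for %s side %s: empty group", species, side)
            continue
        for metric in metrics:
            av = a[metric].dropna().to_numpy()
            bv = b[metric].dropna().to_numpy()
            if len(av) < 2 or len(bv) < 2:
                continue
            test = _stats.mann_whitney_exact(av, bv)
            eff = _stats.effect_sizes(av, bv)
            rows.append({"comparison": f"sex ({sexes[0]} vs {sexes[1]})",
                         "group": f"{species} / {side}", "metric": metric,
                         "n": test.n, "statistic": test.statistic,
                         "p_exact": test.p_two_sided, "method": test.method,
                         "cohens_d_pooled": eff.cohens_d_pooled,
                         "cohens_d_paired": None, "rank_r": eff.rank_r})
    return rows


def _descriptives(df: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    rows = []
    for species in sorted(df["species"].unique()):
        sdf = df[df["species"] == species]
        for sex in sorted(sdf["sex"].unique()):
            xdf = sdf[sdf["sex"] == sex]
            for side in sorted(xdf["side"].unique()) + ["both"]:
                part = xdf if side == "both" else xdf[xdf["side"] == side]
                row = {"species": species, "sex": sex, "side": side,
                       "n": part["individual_id"].nunique(), "sd_kind": "sample"}
                for metric in metrics:
                    vals = part[metric].dropna()
                    row[f"{metric}_mean"] = vals.mean()
                    row[f"{metric}_sd"] = vals.std(ddof=1)
                rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    metrics_df: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Join metrics to metadata and produce the full report bundle."""
    missing = set(metrics_df["mesh_id"]) - set(metadata["mesh_id"])
    if missing:
        raise ValueError(f"meshes without metadata rows: {sorted(missing)}")
    df = metrics_df.merge(metadata, on="mesh_id", how="inner")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = [m for m in _METRICS if m in df.columns]
    out: dict[str, pd.DataFrame] = {}

    rows = _paired_side_rows(df, "all", metrics)
    for species in sorted(df["species"].unique()):
        rows += _paired_side_rows(df[df["species"] == species], species, metrics)
        for sex in sorted(df.loc[df["species"] == species, "sex"].unique()):
            sub = df[(df["species"] == species) & (df["sex"] == sex)]
            if sub["individual_id"].nunique() >= 2:
                rows += _paired_side_rows(sub, f"{species} / {sex}", metrics)
        rows += _sex_rows(df, species, metrics)
    out["table1_tests"] = pd.DataFrame(rows)

    out["table2_descriptives"] = _descriptives(df, metrics)

    selection_rows, best_rows = [], []
    for metric in metrics:
        try:
            fits = _stats.fit_model_family(df, metric, estimator=config.estimator)
        except ValueError as exc:
            log.warning("model family skipped for %s: %s", metric, exc)
            continue
        for f in fits:
            selection_rows.append({"metric": metric,
                                   "effects": "+".join(f.fixed_effects) or "(intercept)",
                                   "k": f.k, "loglik": f.loglik, "aicc": f.aicc,
                                   "delta_aicc": f.delta_aicc,
                                   "weight": f.akaike_weight,
                                   "estimator": f.estimator})
        best = fits[0]
        best_rows.append({"metric": metric,
                          "effects": "+".join(best.fixed_effects) or "(intercept)",
                          **best.coefficients})
    out["model_selection"] = pd.DataFrame(selection_rows)
    out["table3_best_models"] = pd.DataFrame(best_rows)

    out["pearson_all"] = _stats.pearson_matrix(df, metrics)
    for species in sorted(df["species"].unique()):
        if (df["species"] == species).sum() >= 3:
            out[f"pearson_{species.replace(' ', '_')}"] = _stats.pearson_matrix(
                df, metrics, subset={"species": species})

    for name, table in out.items():
        table.to_csv(outdir / f"{name}.csv", index=name.startswith("pearson"))
    _plots(df, metrics, outdir)
    (outdir / "run_info.json").write_text(json.dumps(
        {"config_hash": config.config_hash(), "n_meshes": len(df)}, indent=2))
    return out


def _plots(df: pd.DataFrame, metrics: list[str], outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(df["species"].unique())
    for metric in metrics:
        fig, ax = plt.subplots(figsize=(5, 4))
        for gi, species in enumerate(groups):
            sdf = df[df["species"] == species]
            for ind in sorted(sdf["individual_id"].unique()):
                idf = sdf[sdf["individual_id"] == ind].sort_values("side")
                x = [gi + (0.15 if s == "R" else -0.15) for s in idf["side"]]
                ax.plot(x, idf[metric], "o-", color="C%d" % gi, alpha=0.5, ms=4)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups)
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} by species (L-R pairs connected)")
        fig.tight_layout()
        fig.savefig(outdir / f"plot_{metric}.png", dpi=100)
        plt.close(fig)
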