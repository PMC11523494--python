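"""Statistical comparison layer for topographic metrics.

Exact rank tests (Wilcoxon signed-rank for left/right pairs, Mann-Whitney
rank-sum for sex contrasts), Cohen's d effect sizes, Pearson correlation
matrices, and model selection over the fixed-effect family

    metric ~ side + sex + species (+ random intercept per individual)

with AICc and Akaike weights.  All 2^3 = 8 fixed-effect subsets (including
the intercept-only null) are fitted per metric; factors are coded with
left / female / alphabetically-first species as reference levels, so a
positive coefficient means right, male or the second species has greater
values.

The exact null distributions are computed in-package: the signed-rank test
enumerates the 2^n equiprobable sign assignments through a subset-sum
convolution (ties midranked, the half-integer ranks doubled to integers);
the rank-sum test uses the classic tie-free count recurrence, falling back
to full label enumeration when ties are present and the sample is small.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "SpecimenRecord",
    "RankTestResult",
    "EffectSizes",
    "ModelFit",
    "signed_rank_exact",
    "mann_whitney_exact",
    "effect_sizes",
    "pearson_matrix",
    "fit_model",
    "fit_model_family",
    "aicc",
    "records_to_frame",
    "EXACT_LIMIT",
]

EXACT_LIMIT = 25  # largest n for exact enumeration of the null
_TIE_ENUM_LIMIT = 16  # largest n1+n2 for full enumeration when ties exist


@dataclass
class SpecimenRecord:
    """One molar's metadata joined to its topographic metrics."""

    individual_id: str
    species: str
    sex: str
    side: str
    metrics: dict[str, float] = field(default_factory=dict)


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    seen = set()
    for r in records:
        key = (r.individual_id, r.side)
        if key in seen:
            raise ValueError(f"duplicate (individual, side) record {key}")
        seen.add(key)
        rows.append({"individual_id": r.individual_id, "species": r.species,
                     "sex": r.sex, "side": r.side, **r.metrics})
    return pd.DataFrame(rows)


@dataclass
class RankTestResult:
    method: str  # 'signed_rank_exact' | 'rank_sum_exact' | 'normal_approx'
    statistic: float
    p_two_sided: float
    n: int
    n1: int | None = None
    n2: int | None = None
    effect_cohens_d: float | None = None
    effect_rank_r: float | None = None


@dataclass
class EffectSizes:
    cohens_d_pooled: float
    cohens_d_paired: float | None
    rank_r: float
    band: str  # interpretation of |pooled d|: negligible/small/medium/large


@dataclass
class ModelFit:
    fixed_effects: tuple[str, ...]
    coefficients: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = math.nan
    akaike_weight: float = math.nan
    estimator: str = "ols"
    converged: bool = True
    stderr: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Exact rank tests
# ---------------------------------------------------------------------------

def _signed_rank_counts(scaled_ranks: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign assignments with positive-rank sum s
    (ranks scaled x2 so midranks are integers)."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


def signed_rank_exact(paired_differences) -> RankTestResult:
    """Exact Wilcoxon signed-rank test (the paired two-sided comparison).

    Zero differences are dropped before ranking; absolute values are
    midranked; the statistic is the sum of ranks of positive differences.
    For n <= 25 the two-sided p is exact over the 2^n equiprobable sign
    assignments, p = min(1, 2*min(P(W<=w), P(W>=w))); larger n uses the
    tie-corrected normal approximation (flagged in ``method``).
    """
    d = np.asarray(paired_differences, dtype=np.float64)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: no information")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = 0.0 if var == 0 else (w - mean) / math.sqrt(var)

    if n <= EXACT_LIMIT:
        scaled = np.rint(2.0 * ranks).astype(np.int64)
        counts = _signed_rank_counts(scaled)
        total = 2.0**n
        ws = int(round(2.0 * w))
        p_le = counts[: ws + 1].sum() / total
        p_ge = counts[ws:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "signed_rank_exact"
    else:
        # continuity-corrected, matching the standard fallback when
        # exactness is out of reach
        from scipy.stats import norm
        zc = 0.0 if var == 0 else (abs(w - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(max(zc, 0.0)))
        method = "normal_approx"
    return RankTestResult(method, w, p, n, effect_rank_r=abs(z) / math.sqrt(n))


def _u_counts_no_ties(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of labelings with U_a statistic u (no ties).

    The generating function is the Gaussian binomial coefficient
    prod_{i=1..n1} (1 - x^(n2+i)) / (1 - x^i); multiplication subtracts a
    shifted copy and division is a strided cumulative sum, all in exact
    integer arithmetic.
    """
    size = n1 * n2 + 1
    c = np.zeros(size, dtype=np.int64)
    c[0] = 1
    for i in range(1, n1 + 1):
        s = n2 + i
        if s < size:
            c[s:] -= c[: size - s].copy()
        for u in range(i, size):
            c[u] += c[u - i]
    return c


def mann_whitney_exact(sample_a, sample_b) -> RankTestResult:
    """Exact two-sample Mann-Whitney U test (two-sided).

    U_a counts pairs (a, b) with a > b, plus 1/2 per tie; the reported
    statistic is U = min(U_a, U_b) and p = min(1, 2*P(U' <= U)) under the
    label-permutation null.  Exact for n1+n2 <= 25 without ties (count
    recurrence) or n1+n2 <= 16 with ties (full enumeration); otherwise the
    tie-corrected normal approximation is used and flagged.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    ua = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    ub = n1 * n2 - ua
    u = min(ua, ub)

    has_ties = len(np.unique(combined)) < n1 + n2
    mean = n1 * n2 / 2.0
    N = n1 + n2
    _, tc = np.unique(combined, return_counts=True)
    var = n1 * n2 / 12.0 * (N + 1 - (tc**3 - tc).sum() / (N * (N - 1)))
    z = 0.0 if var == 0 else (ua - mean) / math.sqrt(var)

    if not has_ties and N <= EXACT_LIMIT:
        counts = _u_counts_no_ties(n1, n2)
        total = math.comb(N, n1)
        ui = int(round(u))
        p = min(1.0, 2.0 * float(counts[: ui + 1].sum()) / total)
        method = "rank_sum_exact"
    elif has_ties and N <= _TIE_ENUM_LIMIT:
        uas = []
        for combo in itertools.combinations(range(N), n1):
            uas.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0)
        uas = np.array(uas)
        p_le = float((uas <= ua + 1e-9).mean())
        p_ge = float((uas >= ua - 1e-9).mean())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "rank_sum_exact"
    else:
        from scipy.stats import norm
        zc = 0.0 if var == 0 else (abs(ua - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(max(zc, 0.0)))
        method = "normal_approx"
    return RankTestResult(method, u, p, N, n1=n1, n2=n2,
                          effect_rank_r=abs(z) / math.sqrt(N))


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

_BANDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"), (0.0, "negligible"))


def _band(d: float) -> str:
    for cut, name in _BANDS:
        if abs(d) >= cut:
            return name
    return "negligible"


def effect_sizes(sample_a, sample_b, paired: bool = False) -> EffectSizes:
    """Cohen's d (pooled-sd and, when paired, difference-sd variants) and the
    rank-based r = |z|/sqrt(N) from the matching rank test."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("samples must have >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    s_pooled = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    delta = a.mean() - b.mean()
    if s_pooled == 0.0:
        d_pooled = 0.0 if delta == 0.0 else math.inf * np.sign(delta)
        if delta != 0.0:
            warnings.warn("zero pooled variance with unequal means: infinite d")
    else:
        d_pooled = delta / s_pooled

    d_paired = None
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diff = a - b
        sd = diff.std(ddof=1)
        d_paired = 0.0 if (sd == 0.0 and diff.mean() == 0.0) else (
            math.inf * np.sign(diff.mean()) if sd == 0.0 else diff.mean() / sd)
        nonzero = diff[diff != 0.0]
        rank_r = signed_rank_exact(diff).effect_rank_r if len(nonzero) else 0.0
    else:
        rank_r = mann_whitney_exact(a, b).effect_rank_r
    return EffectSizes(float(d_pooled), d_paired, float(rank_r), _band(d_pooled))


# ---------------------------------------------------------------------------
# Pearson correlations
# ---------------------------------------------------------------------------

def pearson_matrix(data, metrics: list[str], subset: dict[str, str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over metric columns.

    ``data`` is a DataFrame (or list of SpecimenRecord); ``subset`` filters
    rows by metadata equality, e.g. {'species': 'V. nigricornis'}.  Constant
    columns yield NaN entries and a warning, never a silent zero.
    """
    df = records_to_frame(data) if not isinstance(data, pd.DataFrame) else data
    if subset:
        for col, val in subset.items():
            df = df[df[col] == val]
    sub = df[list(metrics)].astype(float)
    n_complete = sub.notna().astype(int).T @ sub.notna().astype(int)
    if (n_complete.values[np.triu_indices(len(metrics), 1)] < 3).any():
        raise ValueError("need >= 3 complete rows for every metric pair")
    const = [m for m in metrics if sub[m].dropna().nunique() <= 1]
    if const:
        warnings.warn(f"constant metric column(s) {const}: correlations undefined (NaN)")
    return sub.corr(method="pearson", min_periods=3)


# ---------------------------------------------------------------------------
# Model family and AICc
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction
    2k(k+1)/(n-k-1); undefined (ValueError) when n <= k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


_FACTORS = ("side", "sex", "species")


def _design(df: pd.DataFrame, effects: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for eff in effects:
        levels = sorted(df[eff].astype(str).unique())
        ref = levels[0]
        for lvl in levels[1:]:
            cols.append((df[eff].astype(str) == lvl).to_numpy(float))
            names.append(f"{eff}[{lvl}]")
    return np.column_stack(cols), names


def fit_model(
    data,
    metric: str,
    effects: tuple[str, ...] = _FACTORS,
    estimator: str = "random_intercept",
    reml: bool = False,
) -> ModelFit:
    """Fit one fixed-effect subset for one metric.

    ``reml=True`` (random-intercept estimator only) gives less biased
    variance components and hence better-calibrated coefficient standard
    errors; its likelihood is NOT comparable across different fixed-effect
    sets, so model selection must use ``reml=False``.
    """
    df = records_to_frame(data) if not isinstance(data, pd.DataFrame) else data
    df = df.dropna(subset=[metric])
    y = df[metric].to_numpy(float)
    X, names = _design(df, tuple(effects))
    fit = _fit_one(y, X, names, df, tuple(effects), estimator, len(y), reml=reml)
    if fit is None:
        raise ValueError("AICc undefined for this model (n <= k+1)")
    return fit


def fit_model_family(
    data,
    metric: str,
    estimator: str = "random_intercept",
) -> list[ModelFit]:
    """Fit all 8 fixed-effect subsets of side+sex+species for one metric.

    Estimators: 'ols' (Gaussian ML) or 'random_intercept' (per-individual
    intercept, fitted by ML — not REML — so AICc is comparable across
    fixed-effect sets).  Returns the fits sorted by AICc with delta-AICc and
    Akaike weights filled in; models whose AICc is undefined (n <= k+1) are
    dropped with a warning.
    """
    if estimator not in ("ols", "random_intercept"):
        raise ValueError("estimator must be 'ols' or 'random_intercept'")
    df = records_to_frame(data) if not isinstance(data, pd.DataFrame) else data
    df = df.dropna(subset=[metric])
    if df["individual_id"].nunique() < 2:
        raise ValueError("need >= 2 individuals")
    y = df[metric].to_numpy(float)
    n = len(y)
    fits: list[ModelFit] = []
    for r in range(len(_FACTORS) + 1):
        for effects in itertools.combinations(_FACTORS, r):
            X, names = _design(df, effects)
            fit = _fit_one(y, X, names, df, effects, estimator, n)
            if fit is not None:
                fits.append(fit)
    finite = [f for f in fits if math.isfinite(f.aicc)]
    if not finite:
        raise ValueError("no model had a defined AICc")
    best = min(f.aicc for f in finite)
    for f in finite:
        f.delta_aicc = f.aicc - best
    rel = np.array([math.exp(-0.5 * f.delta_aicc) for f in finite])
    rel /= rel.sum()
    for f, w in zip(finite, rel):
        f.akaike_weight = float(w)
    return sorted(finite, key=lambda f: f.aicc)


def _fit_one(y, X, names, df, effects, estimator, n, reml=False) -> ModelFit | None:
    p = X.shape[1]
    if estimator == "random_intercept" and df["individual_id"].nunique() < n:
        groups = df["individual_id"].to_numpy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=groups).fit(reml=reml, method="lbfgs")
            llf = float(res.llf)
            params = dict(zip(names, np.asarray(res.fe_params, dtype=float)))
            stderr = dict(zip(names, np.asarray(res.bse_fe, dtype=float)))
            k = p + 2  # fixed effects + residual variance + intercept variance
            converged = bool(res.converged)
        except Exception:
            return _ols_fit(y, X, names, effects, n, label="ols_fallback")
    else:
        return _ols_fit(y, X, names, effects, n,
                        label=estimator if estimator == "ols" else "ols_fallback")
    try:
        a = aicc(llf, k, n)
    except ValueError:
        warnings.warn(f"AICc undefined for effects {effects} (n={n}, k={k}); model dropped")
        return None
    label = "random_intercept_reml" if reml else "random_intercept"
    return ModelFit(effects, params, llf, k, n, a, estimator=label,
                    converged=converged, stderr=stderr)


def _ols_fit(y, X, names, effects, n, label="ols") -> ModelFit | None:
    res = sm.OLS(y, X).fit()
    llf = float(res.llf)
    params = dict(zip(names, np.asarray(res.params, dtype=float)))
    stderr = dict(zip(names, np.asarray(res.bse, dtype=float)))
    k = X.shape[1] + 1  # coefficients + residual variance
    try:
        a = aicc(llf, k, n)
    except ValueError:
        warnings.warn(f"AICc undefined for effects {effects} (n={n}, k={k}); model dropped")
        return None
    return ModelFit(effects, params, llf, k, n, a, estimator=label, stderr=stderr)
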