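"""Random-effects meta-analysis of Spearman correlations across cohorts.

For every feature pair, the Spearman correlation is computed separately in each
dataset, Fisher Z-transformed (z = atanh(rho), variance 1/(n-3)), and the
per-dataset z values are pooled with a random-effects model whose
between-dataset variance tau^2 is estimated by restricted maximum likelihood
(REML).  The combined estimate is back-transformed with tanh and p-values are
corrected with the Benjamini-Hochberg step-up procedure.

The REML criterion, profiled over the pooled mean mu(tau^2) = sum(w_i z_i) /
sum(w_i) with w_i = 1/(v_i + tau^2), is

    l_R(tau^2) = -1/2 [ sum ln(v_i + tau^2) + ln sum w_i + sum w_i (z_i - mu)^2 ]

maximized over tau^2 >= 0 by bounded one-dimensional optimization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .aggregate import FeatureTable
from .core_rank import harmonize

logger = logging.getLogger(__name__)

#: Clamp applied to |rho| = 1 before the Z transform.
RHO_CLAMP = 1.0 - 1e-6

#: Upper bound for the tau^2 search (far above any Fisher-Z heterogeneity).
TAU2_MAX = 100.0


def spearman(x, y) -> tuple[float, int]:
    """Spearman rho and the number of pairs used (NaN-pairs dropped).

    Zeros are data, not missing.  Returns (nan, n) when either vector is
    constant; callers skip such datasets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), n
    rho = stats.spearmanr(x, y).statistic
    return float(rho), n


def fisher_z(rho: float, n: int, variance_model: str = "zcor") -> tuple[float, float]:
    """Fisher Z transform and its sampling variance.

    variance_model 'zcor' gives v = 1/(n-3); 'fieller' gives the Fieller-type
    1.06/(n-3) sometimes used for Spearman correlations.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(rho) >= 1.0:
        warnings.warn(f"|rho| = {abs(rho)} clamped to {RHO_CLAMP}", stacklevel=2)
        rho = math.copysign(RHO_CLAMP, rho)
    z = math.atanh(rho)
    scale = {"zcor": 1.0, "fieller": 1.06}[variance_model]
    return z, scale / (n - 3)


def reml_criterion(tau2: float, zs: np.ndarray, vs: np.ndarray) -> float:
    """-2 * restricted log-likelihood (constants dropped); lower is better."""
    w = 1.0 / (vs + tau2)
    mu = np.dot(w, zs) / w.sum()
    return float(
        np.log(vs + tau2).sum() + np.log(w.sum()) + np.dot(w, (zs - mu) ** 2)
    )


@dataclass(frozen=True)
class REMLResult:
    mu: float      # combined estimate on the Z scale
    tau2: float    # between-dataset variance
    se: float      # standard error of mu
    p: float       # two-sided p-value
    k: int         # number of datasets pooled


def reml_combine(
    zs, vs, knapp_hartung: bool = False, tau2_max: float = TAU2_MAX
) -> REMLResult:
    """REML random-effects pooling of Fisher-Z values.

    Requires k >= 2 estimates with positive variances.  The default p-value is
    the Wald normal tail of mu/SE; `knapp_hartung` switches to the
    Hartung-Knapp-Sidik-Jonkman adjusted t test with k-1 degrees of freedom.
    """
    zs = np.asarray(zs, dtype=float)
    vs = np.asarray(vs, dtype=float)
    if zs.shape != vs.shape or zs.ndim != 1:
        raise ValueError("zs and vs must be 1-D arrays of equal length")
    k = len(zs)
    if k < 2:
        raise ValueError(
            "REML pooling needs >= 2 datasets; report the single estimate unpooled"
        )
    if not np.all(vs > 0):
        raise ValueError("all variances must be positive")

    res = minimize_scalar(
        reml_criterion, args=(zs, vs), bounds=(0.0, tau2_max),
        method="bounded", options={"xatol": 1e-12},
    )
    if not res.success:  # pragma: no cover - bounded Brent on smooth criterion
        raise RuntimeError(f"REML optimization failed: {res.message}")
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on the boundary; snap to 0
    # when the boundary is at least as good
    if reml_criterion(0.0, zs, vs) <= res.fun + 1e-12:
        tau2 = 0.0
    w = 1.0 / (vs + tau2)
    mu = float(np.dot(w, zs) / w.sum())
    se = float(w.sum() ** -0.5)
    if knapp_hartung:
        q = float(np.dot(w, (zs - mu) ** 2) / (k - 1))
        se_kh = se * math.sqrt(max(q, 1.0))  # with the common truncation at 1
        p = 2.0 * stats.t.sf(abs(mu / se_kh), df=k - 1)
        se = se_kh
    else:
        p = 2.0 * stats.norm.sf(abs(mu / se)) if se > 0 else float(mu == 0.0)
    return REMLResult(mu=mu, tau2=tau2, se=se, p=float(p), k=k)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, mapped back to
    the input order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_matrix(mat: np.ndarray) -> np.ndarray:
    return stats.rankdata(mat, method="average", axis=1)


def _pairwise_spearman(mat: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix over rows; constant rows give NaN."""
    r = _rank_matrix(mat)
    sd = r.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(r)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def meta_correlate(
    tables: list[FeatureTable],
    features: list | None = None,
    alpha: float = 0.05,
    min_k: int = 2,
    variance_model: str = "zcor",
    knapp_hartung: bool = False,
) -> pd.DataFrame:
    """REML meta-analysis of all unordered feature pairs across datasets.

    Returns one row per pair with per-dataset rho/n, the pooled estimate and
    BH-adjusted q (computed jointly over all pooled pairs).  Pairs with fewer
    than `min_k` datasets contributing a defined rho are reported with their
    single estimate (if any) and q = NaN, excluded from the FDR family.
    """
    mats = harmonize(tables)
    if features is not None:
        mats = [m.loc[list(features)] for m in mats]
    feats = list(mats[0].index)
    ds_ids = [t.dataset_id for t in tables]

    rhos, ns = {}, {}
    for ds_id, m in zip(ds_ids, mats):
        arr = m.to_numpy()
        rhos[ds_id] = _pairwise_spearman(arr)
        ns[ds_id] = arr.shape[1]

    rows = []
    for i, j in combinations(range(len(feats)), 2):
        zs, vs, per_ds = [], [], {}
        for ds_id in ds_ids:
            rho = rhos[ds_id][i, j]
            n = ns[ds_id]
            per_ds[f"rho_{ds_id}"] = rho
            per_ds[f"n_{ds_id}"] = n
            if np.isnan(rho):
                continue
            z, v = fisher_z(rho, n, variance_model)
            zs.append(z)
            vs.append(v)
        row = {"featureA": feats[i], "featureB": feats[j], "k": len(zs)}
        if len(zs) >= min_k:
            res = reml_combine(zs, vs, knapp_hartung=knapp_hartung)
            row.update(
                mu=res.mu, tau2=res.tau2, se=res.se, p=res.p,
                rho_combined=math.tanh(res.mu), pooled=True,
            )
        else:
            row.update(
                mu=zs[0] if zs else np.nan, tau2=np.nan, se=np.nan, p=np.nan,
                rho_combined=math.tanh(zs[0]) if zs else np.nan, pooled=False,
            )
            logger.info(
                "pair (%s, %s): only %d dataset(s) with defined rho; not pooled",
                feats[i], feats[j], len(zs),
            )
        row.update(per_ds)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        pooled = out["pooled"].to_numpy()
        if pooled.any():
            out.loc[pooled, "q"] = bh_adjust(out.loc[pooled, "p"].to_numpy())
        out["significant"] = out["q"] < alpha
    return out


def select_top_ko(
    summaries: pd.DataFrame,
    n: int = 50,
    min_mean_det: float = 0.75,
    ribosomal_kos: frozenset | set = frozenset(),
    exclude_ribosomal: bool = True,
) -> list:
    """Most abundant KO functions among those detected in all datasets and in
    at least `min_mean_det` of subjects on average, ribosomal proteins
    optionally excluded."""
    sel = summaries["core_datasets"] & (summaries["mean_det_freq"] >= min_mean_det)
    if exclude_ribosomal:
        sel &= ~summaries.index.isin(list(ribosomal_kos))
    sub = summaries.loc[sel].sort_values("mean_pct", ascending=False, kind="mergesort")
    if len(sub) < n:
        warnings.warn(f"only {len(sub)} KO functions pass the filters (< {n})",
                      stacklevel=2)
    return list(sub.index[:n])


def select_pathways(summaries: pd.DataFrame, min_mean_pct: float = 1.0) -> list:
    """Pathways detected in all subjects with mean abundance strictly above
    `min_mean_pct` percent."""
    sel = summaries["core_subjects"] & (summaries["mean_pct"] > min_mean_pct)
    return list(summaries.index[sel])


def correlate_with_covariate(
    tables: list[FeatureTable],
    metadata: pd.DataFrame,
    covariate: str = "age",
    alpha: float = 0.05,
    min_k: int = 2,
    min_n: int = 5,
    variance_model: str = "zcor",
) -> pd.DataFrame:
    """Meta-analysis of each feature's Spearman correlation with a subject
    covariate, using the same Fisher-Z/REML/BH machinery."""
    if covariate not in metadata.columns:
        raise ValueError(f"covariate {covariate!r} missing from metadata")
    mats = harmonize(tables)
    feats = list(mats[0].index)
    meta = metadata.set_index(["dataset", "subject"])[covariate]
    if meta.dropna().empty:
        raise ValueError(f"covariate {covariate!r} has no non-missing values")

    rows = []
    per_ds_cache = {}
    for t, m in zip(tables, mats):
        y = np.array(
            [meta.get((t.dataset_id, s), np.nan) for s in m.columns], dtype=float
        )
        keep = ~np.isnan(y)
        if keep.sum() < min_n or np.all(y[keep] == y[keep][0]):
            logger.info("%s: covariate %s unusable (missing or constant); skipped",
                        t.dataset_id, covariate)
            per_ds_cache[t.dataset_id] = None
            continue
        per_ds_cache[t.dataset_id] = (m.to_numpy()[:, keep], y[keep])

    for i, f in enumerate(feats):
        zs, vs, per_ds = [], [], {}
        for t in tables:
            cached = per_ds_cache[t.dataset_id]
            per_ds[f"rho_{t.dataset_id}"] = np.nan
            if cached is None:
                continue
            x_mat, y = cached
            x = x_mat[i]
            if np.all(x == x[0]):
                continue
            rho = stats.spearmanr(x, y).statistic
            per_ds[f"rho_{t.dataset_id}"] = rho
            z, v = fisher_z(float(rho), len(y), variance_model)
            zs.append(z)
            vs.append(v)
        row = {"feature": f, "covariate": covariate, "k": len(zs)}
        if len(zs) >= min_k:
            res = reml_combine(zs, vs)
            row.update(mu=res.mu, tau2=res.tau2, se=res.se, p=res.p,
                       rho_combined=math.tanh(res.mu), pooled=True)
        else:
            row.update(mu=np.nan, tau2=np.nan, se=np.nan, p=np.nan,
                       rho_combined=np.nan, pooled=False)
        row.update(per_ds)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        pooled = out["pooled"].to_numpy()
        if pooled.any():
            out.loc[pooled, "q"] = bh_adjust(out.loc[pooled, "p"].to_numpy())
        out["significant"] = out["q"] < alpha
    return out


def rho_matrix(meta: pd.DataFrame, features: list) -> pd.DataFrame:
    """Square combined-rho matrix from a meta_correlate result (missing -> 0)."""
    mat = pd.DataFrame(0.0, index=features, columns=features)
    np.fill_diagonal(mat.to_numpy(), 1.0)
    for _, r in meta.iterrows():
        a, b = r["featureA"], r["featureB"]
        if a in mat.index and b in mat.index:
            val = r["rho_combined"]
            if pd.notna(val):
                mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def order_by_clustering(rho: pd.DataFrame) -> list:
    """Leaf order of average-linkage clustering on distance 1 - rho.

    Deterministic; when every off-diagonal distance is equal (e.g. an identity
    rho matrix) the input order is returned unchanged.
    """
    if rho.shape[0] != rho.shape[1]:
        raise ValueError("rho matrix must be square")
    feats = list(rho.index)
    if len(feats) <= 2:
        return feats
    d = 1.0 - rho.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    cond = squareform(d, checks=False)
    if np.allclose(cond, cond[0]):
        return feats
    order = leaves_list(linkage(cond, method="average"))
    return [feats[i] for i in order]
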