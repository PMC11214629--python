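"""Cross-cohort feature summaries: ranks, abundance/CV statistics, core catalogs.

Datasets are harmonized to the union of their features (a feature absent from a
dataset is zero-abundance there) before pooling.  Ranks are computed within each
subject (rank 1 = most abundant, average ties, undetected features share the
worst ranks) and summarized over the pooled subject axis; abundance and CV are
computed per dataset and then averaged unweighted across datasets.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .aggregate import FeatureTable

logger = logging.getLogger(__name__)


def harmonize(tables: list[FeatureTable]) -> list[pd.DataFrame]:
    """Reindex every table (unassigned rows dropped) to the union of features."""
    mats = [t.without_unassigned() for t in tables]
    universe = mats[0].index
    for m in mats[1:]:
        universe = universe.union(m.index)
    universe = universe.sort_values()
    return [m.reindex(universe, fill_value=0.0) for m in mats]


def rank_features(table: FeatureTable, drop_undetected: bool = False) -> pd.DataFrame:
    """Within-subject ranks of a feature table (1 = most abundant, ties averaged).

    With ``drop_undetected`` zero-abundance features get NaN instead of sharing
    the worst ranks; the default keeps every subject's rank vector over the
    same feature universe, which pooled medians require.
    """
    df = table.without_unassigned() if isinstance(table, FeatureTable) else table
    if df.empty:
        raise ValueError("cannot rank an empty feature table")
    ranks = pd.DataFrame(
        rankdata(-df.to_numpy(), method="average", axis=0),
        index=df.index, columns=df.columns,
    )
    if drop_undetected:
        ranks = ranks.where(df > 0)
    return ranks


def rank_summary(
    tables: list[FeatureTable], drop_undetected: bool = False
) -> pd.DataFrame:
    """Pooled per-feature rank summaries: median, IQR and IQR/median.

    Features are harmonized across datasets first; summaries run over all
    subjects of all datasets.  Quartiles use linear interpolation between
    order statistics.
    """
    mats = harmonize(tables)
    pooled = []
    for t, m in zip(tables, mats):
        r = rank_features(FeatureTable(t.dataset_id, t.feature_class, m),
                          drop_undetected=drop_undetected)
        r.columns = [f"{t.dataset_id}:{s}" for s in r.columns]
        pooled.append(r)
    ranks = pd.concat(pooled, axis=1)
    med = ranks.median(axis=1)
    q1 = ranks.quantile(0.25, axis=1, interpolation="linear")
    q3 = ranks.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    return pd.DataFrame(
        {"median_rank": med, "iqr": iqr, "iqr_over_median": iqr / med}
    )


def feature_stats(tables: list[FeatureTable]) -> pd.DataFrame:
    """Cross-dataset mean relative abundance and mean coefficient of variation.

    Per dataset: mean over subjects, and CV = 100 * sample SD / mean (n-1
    denominator; undefined when the dataset mean is zero and then excluded for
    that dataset).  Cross-dataset values are unweighted means over the datasets
    where defined.
    """
    mats = harmonize(tables)
    means = pd.concat([m.mean(axis=1) for m in mats], axis=1)
    cvs = []
    for m in mats:
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=1)
        cv = 100.0 * sd / mu
        cv[mu <= 0] = np.nan
        cvs.append(cv)
    cvs = pd.concat(cvs, axis=1)
    absent = means.sum(axis=1) <= 0
    if absent.any():
        logger.info("%d features absent from every dataset excluded", int(absent.sum()))
    out = pd.DataFrame(
        {"mean_pct": means.mean(axis=1), "mean_cv": cvs.mean(axis=1)}
    )
    return out.loc[~absent]


def detection_frequencies(tables: list[FeatureTable]) -> pd.DataFrame:
    """Per-dataset fraction of subjects in which each feature is detected (>0)."""
    mats = harmonize(tables)
    freq = pd.concat(
        [(m > 0).mean(axis=1).rename(t.dataset_id) for t, m in zip(tables, mats)],
        axis=1,
    )
    return freq


def core_features(tables: list[FeatureTable], mode: str) -> set:
    """Features detected in every subject ('all-subjects') or in at least one
    subject of every dataset ('all-datasets')."""
    if mode not in ("all-subjects", "all-datasets"):
        raise ValueError(f"mode must be all-subjects or all-datasets, got {mode!r}")
    mats = harmonize(tables)
    if mode == "all-subjects":
        ok = np.logical_and.reduce([(m > 0).all(axis=1) for m in mats])
    else:
        ok = np.logical_and.reduce([(m > 0).any(axis=1) for m in mats])
    return set(mats[0].index[ok])


def summarize_features(tables: list[FeatureTable]) -> pd.DataFrame:
    """Full per-feature summary across datasets.

    Columns: mean_pct, mean_cv, median_rank, iqr, iqr_over_median,
    det_freq_pooled, mean_det_freq (unweighted over datasets),
    core_subjects, core_datasets.
    """
    stats = feature_stats(tables)
    ranks = rank_summary(tables)
    freq = detection_frequencies(tables)
    mats = harmonize(tables)
    pooled_det = pd.concat([(m > 0) for m in mats], axis=1).mean(axis=1)
    cs = core_features(tables, "all-subjects")
    cd = core_features(tables, "all-datasets")
    out = stats.join(ranks, how="left")
    out["det_freq_pooled"] = pooled_det
    out["mean_det_freq"] = freq.mean(axis=1)
    out["core_subjects"] = out.index.isin(cs)
    out["core_datasets"] = out.index.isin(cd)
    return out


def variability_ranking(
    summaries: pd.DataFrame,
    min_mean_pct: float = 0.01,
    require_all_datasets: bool = True,
    n_top: int = 10,
) -> tuple[list, list]:
    """The n_top lowest- and highest-CV features among those detected in all
    datasets with mean abundance strictly above `min_mean_pct` percent."""
    sel = summaries["mean_pct"] > min_mean_pct
    if require_all_datasets:
        sel &= summaries["core_datasets"]
    sub = summaries.loc[sel].dropna(subset=["mean_cv"])
    if len(sub) < n_top:
        warnings.warn(
            f"only {len(sub)} features pass the variability filters (< {n_top})",
            stacklevel=2,
        )
    by_cv = sub.sort_values("mean_cv", kind="mergesort")
    return list(by_cv.index[:n_top]), list(by_cv.index[::-1][:n_top])


def write_summary(summaries: pd.DataFrame, feature_class: str, path) -> None:
    df = summaries.copy()
    df.insert(0, "class", feature_class)
    df.index.name = "feature"
    df.to_csv(path, sep="\t")
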