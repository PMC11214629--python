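"""Taxon-specific contribution to functions.

Three analyses over taxon-function tables:

* phylum contrast — per function, a two-sided paired t test on log-transformed
  abundances assigned to the two dominant phyla across all subjects, with a
  mean log-ratio for ranking and BH correction across functions;
* genus specificity — classify each function by how much of its abundance is
  unassignable at genus rank and, within the genus-annotated portion, how much
  belongs to the single top genus;
* attribution matrix — mixed-rank taxon x enzyme mean-abundance matrix for a
  chosen KO set, with per-column totals equal to the plain KO means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import UNASSIGNED, FeatureTable
from .corr_meta import bh_adjust

logger = logging.getLogger(__name__)


def paired_t(d: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test on a vector of differences.

    Zero-variance differences: p = 1 when the mean difference is 0, else p = 0
    (flagged by the caller as degenerate).
    """
    n = len(d)
    if n < 2:
        raise ValueError("paired t test needs >= 2 pairs")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    # constant differences up to float noise count as zero-variance
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return (0.0, 1.0) if abs(mean) <= 1e-12 else (math.copysign(math.inf, mean), 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, float(p)


def _function_rows(table: FeatureTable, taxon: str) -> pd.DataFrame:
    """Rows of a (taxon, function) table for one taxon, indexed by function."""
    df = table.data
    if taxon in df.index.get_level_values(0):
        return df.xs(taxon, level=0)
    return pd.DataFrame(columns=df.columns, dtype=float)


def phylum_contrast(
    tables: list[FeatureTable],
    phylum_a: str = "Bacillota",
    phylum_b: str = "Bacteroidota",
    pseudocount: float | None = None,
    log_base: float = math.e,
    stratified: bool = False,
) -> pd.DataFrame:
    """Paired contrast of per-function abundances between two phyla.

    `tables` are per-dataset phylum-function tables.  Subjects are pooled
    across datasets into one paired test per function; with `stratified` the
    dataset becomes the experimental unit instead: a one-sample t test on the
    per-dataset mean log-differences.  The pseudocount defaults to half the
    smallest nonzero abundance observed in the two phyla's rows across all
    datasets.
    """
    funcs = set()
    vals_a, vals_b = [], []
    for t in tables:
        a = _function_rows(t, phylum_a)
        b = _function_rows(t, phylum_b)
        funcs |= set(a.index) | set(b.index)
        vals_a.append(a)
        vals_b.append(b)
    funcs = sorted(funcs)
    if not funcs:
        return pd.DataFrame(
            columns=["function", "mean_log_ratio", "t", "p", "q", "n_pairs",
                     "degenerate"]
        )
    if pseudocount is None:
        nz = [
            df.to_numpy()[df.to_numpy() > 0]
            for df in (*vals_a, *vals_b) if df.size
        ]
        nz = np.concatenate([v for v in nz if v.size]) if nz else np.array([])
        if nz.size == 0:
            raise ValueError("no positive abundance in either phylum")
        pseudocount = float(nz.min()) / 2.0
    logb = math.log(log_base)

    rows = []
    for f in funcs:
        d_all = []
        present = False
        for t, a, b in zip(tables, vals_a, vals_b):
            n_subj = len(t.subjects)
            av = a.loc[f].to_numpy() if f in a.index else np.zeros(n_subj)
            bv = b.loc[f].to_numpy() if f in b.index else np.zeros(n_subj)
            if av.any() or bv.any():
                present = True
            d = (np.log(av + pseudocount) - np.log(bv + pseudocount)) / logb
            d_all.append(d)
        if not present:
            continue  # absent in both phyla everywhere
        d = np.concatenate(d_all)
        if stratified:
            t_stat, p = paired_t(np.array([di.mean() for di in d_all]))
        else:
            t_stat, p = paired_t(d)
        rows.append({
            "function": f,
            "mean_log_ratio": float(np.mean(d)),
            "t": t_stat,
            "p": p,
            "n_pairs": len(d),
            "degenerate": not np.isfinite(t_stat),
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("mean_log_ratio", ascending=False).reset_index(drop=True)


@dataclass(frozen=True)
class SpecificityThresholds:
    missing_max: float = 0.5   # mean missing-at-genus fraction must be strictly below
    specific_min: float = 0.9  # top-genus share for "genus-specific"
    shared_max: float = 0.75   # top-genus share strictly below -> "shared"


def genus_specificity(
    tables: list[FeatureTable],
    missing_max: float = 0.5,
    specific_min: float = 0.9,
    shared_max: float = 0.75,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Classify functions by genus specificity.

    Per function and dataset: the missing fraction is the genus-unassigned
    share of the function's (subject-summed) abundance, and genus shares are
    computed over the genus-annotated portion only; both are averaged
    unweighted across the datasets where defined.  Classification:
    'not-evaluable' when mean missing >= missing_max, else 'genus-specific'
    when the top genus's mean share >= specific_min, 'shared' when it is
    < shared_max, otherwise 'intermediate'.  `per_subject` computes the
    missing fraction per subject and averages, instead of on subject sums.
    """
    funcs = sorted({f for t in tables for f in t.data.index.get_level_values(1)})
    missing_per_ds: dict[str, list] = {f: [] for f in funcs}
    shares_per_ds: dict[str, list] = {f: [] for f in funcs}

    for t in tables:
        df = t.data
        for f in funcs:
            try:
                sub = df.xs(f, level=1)
            except KeyError:
                continue
            totals = sub.sum(axis=1)  # per-taxon subject-summed abundance
            total = totals.sum()
            if total <= 0:
                continue
            unass = totals.get(UNASSIGNED, 0.0)
            if per_subject:
                colsum = sub.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    fr = (sub.loc[UNASSIGNED] if UNASSIGNED in sub.index
                          else colsum * 0.0) / colsum
                missing_per_ds[f].append(float(fr.dropna().mean()))
            else:
                missing_per_ds[f].append(float(unass / total))
            genus_tot = totals.drop(UNASSIGNED, errors="ignore")
            if genus_tot.sum() > 0:
                shares_per_ds[f].append(genus_tot / genus_tot.sum())

    rows = []
    for f in funcs:
        if not missing_per_ds[f]:
            logger.info("function %s has zero total abundance everywhere; skipped", f)
            continue
        mean_missing = float(np.mean(missing_per_ds[f]))
        if shares_per_ds[f]:
            shares = (
                pd.concat(shares_per_ds[f], axis=1).fillna(0.0).mean(axis=1)
            )
            top_genus = shares.idxmax()
            top_share = float(shares.max())
        else:
            top_genus, top_share = None, float("nan")
        eps = 1e-12  # keep exact threshold hits on the side the rules state
        if mean_missing >= missing_max - eps or top_genus is None:
            cls = "not-evaluable"
        elif top_share >= specific_min - eps:
            cls = "genus-specific"
        elif top_share < shared_max - eps:
            cls = "shared"
        else:
            cls = "intermediate"
        rows.append({
            "function": f,
            "missing_frac": mean_missing,
            "top_genus": top_genus,
            "top_share": top_share,
            "class": cls,
        })
    return pd.DataFrame(rows)


def attribution_matrix(
    deepest_tables: list[FeatureTable],
    ko_list: list[str],
    plain_ko_tables: list[FeatureTable] | None = None,
    min_datasets: int = 6,
    min_mean_pct: float = 0.001,
) -> pd.DataFrame:
    """Mixed-rank taxon x KO matrix of cross-dataset mean abundances.

    `deepest_tables` are per-dataset deepest-resolvable-rank taxon-KO tables
    (see aggregate.aggregate_deepest_taxon_function).  KOs are kept when
    detected in strictly more than `min_datasets` datasets and their
    cross-dataset mean abundance is strictly above `min_mean_pct` percent.
    Rows are taxa ("rank:name" labels plus "Bacteria/unassigned"); a final
    "total" row carries the per-KO column sums, which equal the plain KO
    table means by construction.
    """
    if not ko_list:
        raise ValueError("empty KO list")
    ko_list = list(dict.fromkeys(ko_list))

    # per-dataset per-(taxon, ko) mean over subjects
    per_ds = []
    for t in deepest_tables:
        df = t.data
        sel = df[df.index.get_level_values(1).isin(ko_list)]
        per_ds.append(sel.mean(axis=1))
    cells = pd.concat(per_ds, axis=1).fillna(0.0)
    mean_cells = cells.mean(axis=1)

    ko_totals_per_ds = cells.groupby(level=1).sum()
    n_detected = (ko_totals_per_ds > 0).sum(axis=1)
    ko_mean = ko_totals_per_ds.mean(axis=1)
    kept = [
        k for k in ko_list
        if n_detected.get(k, 0) > min_datasets and ko_mean.get(k, 0.0) > min_mean_pct
    ]
    if not kept:
        logger.info("no KO passed the attribution filters")

    taxa = sorted({t for t, k in mean_cells.index if k in kept})
    mat = pd.DataFrame(0.0, index=taxa, columns=kept)
    for (taxon, ko), v in mean_cells.items():
        if ko in kept:
            mat.loc[taxon, ko] = v
    mat.loc["total"] = mat.sum(axis=0)

    if plain_ko_tables is not None:
        plain = pd.concat(
            [t.data.reindex(kept, fill_value=0.0).mean(axis=1) for t in plain_ko_tables],
            axis=1,
        ).mean(axis=1)
        diff = (mat.loc["total"] - plain).abs().max() if kept else 0.0
        if kept and diff > 1e-9:
            raise AssertionError(
                f"attribution totals disagree with plain KO means by {diff}"
            )
    return mat


def attribution_long(mat: pd.DataFrame) -> pd.DataFrame:
    """Long-format (KO, taxon, rank, mean_pct) view of an attribution matrix."""
    rows = []
    for taxon in mat.index:
        rank = taxon.split(":", 1)[0] if ":" in taxon else taxon
        for ko in mat.columns:
            v = mat.loc[taxon, ko]
            if v > 0 or taxon == "total":
                rows.append({"ko": ko, "taxon": taxon, "rank": rank, "mean_pct": v})
    return pd.DataFrame(rows)
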