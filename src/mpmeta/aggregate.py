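"""Collapse peptide abundances into feature x subject tables.

A feature's abundance for a subject is the sum of the abundances of all peptides
carrying that feature among their annotations.  Taxon tables therefore partition
the subject's signal (plus an "unassigned" residual for peptides whose lineage
stops above the requested rank); function tables do not, because a peptide with
several KO annotations contributes its full abundance to each KO.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .peptide_io import RANKS, PeptideDataset

logger = logging.getLogger(__name__)

#: Reserved feature id for signal not resolvable at the requested rank.
UNASSIGNED = "unassigned"

#: Row label for signal not resolvable at any reported rank in the
#: deepest-rank attribution tables.
UNASSIGNED_DEEP = "Bacteria/unassigned"

TAXON_RANKS = ("phylum", "genus")
FUNCTION_LEVELS = ("KO", "pathway")


@dataclass
class FeatureTable:
    """Feature x subject relative-abundance matrix for one dataset."""

    dataset_id: str
    feature_class: str  # e.g. "genus", "KO", "genus-KO", "deepest-KO"
    data: pd.DataFrame  # index: feature ids (str or (taxon, function) tuples)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.columns)

    def without_unassigned(self) -> pd.DataFrame:
        idx = self.data.index
        if isinstance(idx, pd.MultiIndex):
            keep = ~idx.get_level_values(0).isin([UNASSIGNED, UNASSIGNED_DEEP])
        else:
            keep = ~idx.isin([UNASSIGNED, UNASSIGNED_DEEP])
        return self.data.loc[keep]


def _require_normalized(ds: PeptideDataset) -> None:
    if not ds.normalized:
        raise ValueError(
            f"{ds.dataset_id}: dataset must be renormalized before aggregation"
        )


def _finalize(rows: dict, subjects: list[str]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(index=pd.Index([], name="feature"), columns=subjects, dtype=float)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=subjects)
    return df.fillna(0.0).astype(float)


def _add(rows: dict, key, subjects: list[str], ab: dict[str, float]) -> None:
    row = rows.get(key)
    if row is None:
        row = rows[key] = dict.fromkeys(subjects, 0.0)
    for s, a in ab.items():
        row[s] += a


def aggregate_taxa(ds: PeptideDataset, rank: str) -> FeatureTable:
    """Sum peptide abundances by taxon at `rank` (phylum or genus).

    Peptides whose lineage stops above `rank` accumulate into the reserved
    UNASSIGNED feature, so the table partitions each subject's total signal.
    """
    _require_normalized(ds)
    if rank not in TAXON_RANKS:
        raise ValueError(f"rank must be one of {TAXON_RANKS}, got {rank!r}")
    rows: dict = {}
    for p in ds.peptides:
        name = p.rank_name(rank)
        _add(rows, name if name is not None else UNASSIGNED, ds.subjects, p.abundances)
    df = _finalize(rows, ds.subjects)
    # stable order: unassigned last, taxa sorted
    order = sorted(df.index.difference([UNASSIGNED])) + (
        [UNASSIGNED] if UNASSIGNED in df.index else []
    )
    return FeatureTable(ds.dataset_id, rank, df.loc[order])


def _peptide_pathways(kos, pathway_map) -> frozenset:
    pws: set = set()
    for k in kos:
        pws.update(pathway_map.get(k, ()))
    return frozenset(pws)


def aggregate_functions(
    ds: PeptideDataset, level: str, pathway_map: dict | None = None
) -> FeatureTable:
    """Sum peptide abundances by KO or by pathway.

    A peptide with several KOs contributes its full abundance to each of them;
    at the pathway level it contributes once per pathway even when several of
    its KOs share the pathway.
    """
    _require_normalized(ds)
    if level not in FUNCTION_LEVELS:
        raise ValueError(f"level must be one of {FUNCTION_LEVELS}, got {level!r}")
    if level == "pathway" and pathway_map is None:
        raise ValueError("pathway aggregation requires a KO->pathway map")
    rows: dict = {}
    unmapped: set = set()
    for p in ds.peptides:
        if not p.ko_ids:
            continue
        if level == "KO":
            feats = p.ko_ids
        else:
            feats = _peptide_pathways(p.ko_ids, pathway_map)
            unmapped.update(k for k in p.ko_ids if not pathway_map.get(k))
        for f in feats:
            _add(rows, f, ds.subjects, p.abundances)
    if unmapped:
        logger.info(
            "%s: %d KOs absent from the pathway map contribute to no pathway",
            ds.dataset_id, len(unmapped),
        )
    if not rows:
        warnings.warn(
            f"{ds.dataset_id}: no functionally annotated peptides at level {level}",
            stacklevel=2,
        )
    df = _finalize(rows, ds.subjects)
    return FeatureTable(ds.dataset_id, level, df.sort_index())


def aggregate_taxon_function(
    ds: PeptideDataset, rank: str, level: str, pathway_map: dict | None = None
) -> FeatureTable:
    """Sum abundances by (taxon at `rank`, function) pairs.

    Peptides not resolving to `rank` contribute to (UNASSIGNED, function), so
    per function the table marginalizes exactly to the plain function table.
    """
    _require_normalized(ds)
    if rank not in TAXON_RANKS:
        raise ValueError(f"rank must be one of {TAXON_RANKS}, got {rank!r}")
    if level not in FUNCTION_LEVELS:
        raise ValueError(f"level must be one of {FUNCTION_LEVELS}, got {level!r}")
    if level == "pathway" and pathway_map is None:
        raise ValueError("pathway aggregation requires a KO->pathway map")
    rows: dict = {}
    for p in ds.peptides:
        if not p.ko_ids:
            continue
        taxon = p.rank_name(rank) or UNASSIGNED
        feats = p.ko_ids if level == "KO" else _peptide_pathways(p.ko_ids, pathway_map)
        for f in feats:
            _add(rows, (taxon, f), ds.subjects, p.abundances)
    df = _finalize(rows, ds.subjects)
    if len(df):
        df.index = pd.MultiIndex.from_tuples(df.index, names=["taxon", "function"])
        df = df.sort_index()
    else:
        df.index = pd.MultiIndex.from_arrays([[], []], names=["taxon", "function"])
    return FeatureTable(ds.dataset_id, f"{rank}-{level}", df)


def aggregate_deepest_taxon_function(
    ds: PeptideDataset,
    level: str = "KO",
    ranks: tuple[str, ...] = ("phylum", "order", "genus", "species"),
    pathway_map: dict | None = None,
) -> FeatureTable:
    """Taxon-function table at the deepest resolvable of the given ranks.

    Each peptide is labelled "rank:name" for the deepest rank of `ranks`
    present in its lineage; peptides resolving to none of them fall into
    the UNASSIGNED_DEEP row.  Used for mixed-rank attribution matrices.
    """
    _require_normalized(ds)
    if level not in FUNCTION_LEVELS:
        raise ValueError(f"level must be one of {FUNCTION_LEVELS}, got {level!r}")
    rank_order = [r for r in RANKS if r in ranks]
    rows: dict = {}
    for p in ds.peptides:
        if not p.ko_ids:
            continue
        label = UNASSIGNED_DEEP
        for r in reversed(rank_order):
            name = p.rank_name(r)
            if name is not None:
                label = f"{r}:{name}"
                break
        feats = p.ko_ids if level == "KO" else _peptide_pathways(p.ko_ids, pathway_map)
        for f in feats:
            _add(rows, (label, f), ds.subjects, p.abundances)
    df = _finalize(rows, ds.subjects)
    if len(df):
        df.index = pd.MultiIndex.from_tuples(df.index, names=["taxon", "function"])
        df = df.sort_index()
    else:
        df.index = pd.MultiIndex.from_arrays([[], []], names=["taxon", "function"])
    return FeatureTable(ds.dataset_id, f"deepest-{level}", df)


def unassigned_fraction(ds: PeptideDataset, rank: str) -> pd.Series:
    """Per-subject abundance-weighted fraction not resolvable at `rank`."""
    _require_normalized(ds)
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    unass = dict.fromkeys(ds.subjects, 0.0)
    total = dict.fromkeys(ds.subjects, 0.0)
    for p in ds.peptides:
        resolved = p.resolves_to(rank)
        for s, a in p.abundances.items():
            total[s] += a
            if not resolved:
                unass[s] += a
    return pd.Series(
        {s: (unass[s] / total[s]) if total[s] > 0 else 0.0 for s in ds.subjects},
        dtype=float,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """TSV with a '# dataset=<id> class=<tag>' metadata line, then the matrix."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dataset={table.dataset_id} class={table.feature_class}\n")
        df = table.data.copy()
        if isinstance(df.index, pd.MultiIndex):
            df.index = ["||".join(map(str, t)) for t in df.index]
        df.index.name = "feature"
        df.to_csv(fh, sep="\t")


def read_feature_table(path) -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# dataset="):
            raise ValueError(f"{path}: missing feature-table metadata line")
        fields = dict(kv.split("=", 1) for kv in meta[2:].split(" "))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if len(df) and df.index.astype(str).str.contains(r"\|\|").all():
        df.index = pd.MultiIndex.from_tuples(
            [tuple(str(i).split("||", 1)) for i in df.index],
            names=["taxon", "function"],
        )
    return FeatureTable(fields["dataset"], fields["class"], df.astype(float))
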