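"""Reading, validation, filtering and renormalization of annotated peptide tables.

The quantitative unit of a metaproteomic dataset is the peptide: an amino-acid
sequence carrying a (possibly truncated) taxonomic lineage from lowest-common-
ancestor assignment, zero or more KEGG Orthology (KO) identifiers, and one MS1
abundance value per subject.  Tables are tab-separated text with one peptide per
row; abundances are arbitrary intensity units until :func:`renormalize` rescales
each subject's column to a total of 100 (percent of the subject's signal).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks in order, domain first.  A lineage is a prefix-closed path:
#: it may stop at any rank but may not skip one.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Phylum renames (old name -> current name) applied at parse time, so that
#: datasets annotated with different taxonomy releases aggregate together.
TAXON_SYNONYMS = {
    "Firmicutes": "Bacillota",
    "Bacteroidetes": "Bacteroidota",
    "Actinobacteria": "Actinomycetota",
    "Proteobacteria": "Pseudomonadota",
}

_KO_RE = re.compile(r"^K\d{5}$")

DEFAULT_DOMAINS = frozenset({"Bacteria", "Archaea"})


class PeptideTableFormatError(ValueError):
    """Malformed peptide table (header, columns, lineage syntax)."""


class PeptideValidationError(ValueError):
    """Well-formed table with invalid content (negative abundance, bad KO)."""


@dataclass(frozen=True)
class PeptideRecord:
    """One annotated peptide with per-subject abundances."""

    sequence: str
    lineage: tuple[tuple[str, str], ...]  # ((rank, name), ...) domain downward
    ko_ids: frozenset[str]
    abundances: dict[str, float]  # subject id -> abundance (>= 0)

    def rank_name(self, rank: str) -> str | None:
        """Taxon name at `rank`, or None if the lineage stops above it."""
        for r, name in self.lineage:
            if r == rank:
                return name
        return None

    @property
    def domain(self) -> str | None:
        return self.rank_name("domain")

    def resolves_to(self, rank: str) -> bool:
        return self.rank_name(rank) is not None


@dataclass
class PeptideDataset:
    """All peptides of one dataset plus subject metadata."""

    dataset_id: str
    subjects: list[str]
    peptides: list[PeptideRecord]
    ages: dict[str, float | None] = field(default_factory=dict)
    normalized: bool = False

    def subject_totals(self) -> pd.Series:
        tot = {s: 0.0 for s in self.subjects}
        for p in self.peptides:
            for s, a in p.abundances.items():
                tot[s] += a
        return pd.Series(tot, dtype=float)


def validate_lineage(lineage: tuple[tuple[str, str], ...]) -> None:
    """Lineage ranks must be RANKS[0..k] in order with no gaps."""
    for i, (rank, name) in enumerate(lineage):
        if rank not in _RANK_INDEX:
            raise PeptideTableFormatError(f"unknown rank {rank!r}")
        if _RANK_INDEX[rank] != i:
            raise PeptideTableFormatError(
                f"lineage ranks out of order or gapped at {rank!r}: {lineage!r}"
            )
        if not name:
            raise PeptideTableFormatError(f"empty taxon name at rank {rank!r}")


def _parse_lineage(text: str, row: int) -> tuple[tuple[str, str], ...]:
    text = text.strip()
    if not text:
        return ()
    pairs = []
    for part in text.split(";"):
        if ":" not in part:
            raise PeptideTableFormatError(
                f"row {row}: lineage entry {part!r} is not 'rank:name'"
            )
        rank, name = part.split(":", 1)
        rank, name = rank.strip(), name.strip()
        pairs.append((rank, TAXON_SYNONYMS.get(name, name)))
    lineage = tuple(pairs)
    try:
        validate_lineage(lineage)
    except PeptideTableFormatError as e:
        raise PeptideTableFormatError(f"row {row}: {e}") from None
    return lineage


def _parse_kos(text: str, row: int) -> frozenset[str]:
    text = text.strip()
    if not text:
        return frozenset()
    kos = set()
    for k in text.split(","):
        k = k.strip()
        if not _KO_RE.match(k):
            raise PeptideValidationError(f"row {row}: malformed KO id {k!r}")
        kos.add(k)
    return frozenset(kos)


def read_peptide_table(path, dataset_id: str | None = None) -> PeptideDataset:
    """Parse a peptide TSV (columns: peptide, lineage, ko, one per subject)."""
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line:
        raise PeptideTableFormatError(f"{path}: empty file, no header")
    header = header_line.split("\t")
    if header[:3] != ["peptide", "lineage", "ko"]:
        raise PeptideTableFormatError(
            f"{path}: header must start with peptide, lineage, ko; got {header[:3]}"
        )
    subjects = header[3:]
    if not subjects:
        raise PeptideTableFormatError(f"{path}: no subject columns")
    if len(set(subjects)) != len(subjects):
        dupes = sorted({s for s in subjects if subjects.count(s) > 1})
        raise PeptideTableFormatError(f"{path}: duplicate subject columns {dupes}")

    df = pd.read_csv(
        path, sep="\t", header=0, names=header, dtype={0: str, 1: str, 2: str},
        keep_default_na=False, skiprows=0,
    )
    peptides = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        lineage = _parse_lineage(row[1], i)
        kos = _parse_kos(row[2], i)
        ab = {}
        for s, v in zip(subjects, row[3:]):
            v = float(v)
            if not (v >= 0.0) or v != v:
                raise PeptideValidationError(
                    f"{path} row {i}: negative or non-finite abundance for {s}"
                )
            ab[s] = v
        peptides.append(PeptideRecord(str(row[0]), lineage, kos, ab))
    return PeptideDataset(
        dataset_id=dataset_id or str(path), subjects=list(subjects), peptides=peptides
    )


def write_peptide_table(ds: PeptideDataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["peptide", "lineage", "ko", *ds.subjects]) + "\n")
        for p in ds.peptides:
            lin = ";".join(f"{r}:{n}" for r, n in p.lineage)
            kos = ",".join(sorted(p.ko_ids))
            vals = "\t".join(repr(p.abundances[s]) for s in ds.subjects)
            fh.write(f"{p.sequence}\t{lin}\t{kos}\t{vals}\n")


def filter_microbial(
    ds: PeptideDataset, allowed_domains: frozenset[str] = DEFAULT_DOMAINS
) -> PeptideDataset:
    """Keep peptides whose domain is in `allowed_domains`.

    Peptides with an empty lineage have no domain and are removed: they cannot
    be attributed to bacteria or archaea.  The result is unnormalized (totals
    change), so callers renormalize afterwards.
    """
    kept = [p for p in ds.peptides if p.domain in allowed_domains]
    n_drop = len(ds.peptides) - len(kept)
    if n_drop:
        logger.info(
            "%s: filter_microbial removed %d of %d peptides",
            ds.dataset_id, n_drop, len(ds.peptides),
        )
    if not kept and ds.peptides:
        warnings.warn(
            f"{ds.dataset_id}: no peptides left after domain filtering",
            stacklevel=2,
        )
    return PeptideDataset(
        dataset_id=ds.dataset_id,
        subjects=list(ds.subjects),
        peptides=kept,
        ages=dict(ds.ages),
        normalized=False,
    )


def renormalize(ds: PeptideDataset) -> PeptideDataset:
    """Rescale each subject's abundances so the subject total is 100."""
    totals = ds.subject_totals()
    zero = [s for s in ds.subjects if totals[s] <= 0.0]
    if zero:
        raise PeptideValidationError(
            f"{ds.dataset_id}: zero total abundance for subject(s) {zero}"
        )
    scale = {s: 100.0 / totals[s] for s in ds.subjects}
    peptides = [
        replace(p, abundances={s: a * scale[s] for s, a in p.abundances.items()})
        for p in ds.peptides
    ]
    return PeptideDataset(
        dataset_id=ds.dataset_id,
        subjects=list(ds.subjects),
        peptides=peptides,
        ages=dict(ds.ages),
        normalized=True,
    )


def read_ko_pathway_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (KO id, pathway) into a KO -> pathways multimap."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PeptideTableFormatError(
                    f"{path} row {i}: expected 2 tab-separated columns"
                )
            ko, pw = parts[0].strip(), parts[1].strip()
            if ko == "ko" and pw == "pathway" and i == 1:
                continue  # optional header
            if not _KO_RE.match(ko):
                raise PeptideTableFormatError(f"{path} row {i}: malformed KO id {ko!r}")
            if not pw:
                raise PeptideTableFormatError(f"{path} row {i}: empty pathway name")
            mapping.setdefault(ko, set()).add(pw)
    if not mapping:
        warnings.warn(f"{path}: empty KO->pathway map", stacklevel=2)
    return {k: frozenset(v) for k, v in mapping.items()}


def write_ko_pathway_map(mapping: dict[str, frozenset[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ko\tpathway\n")
        for ko in sorted(mapping):
            for pw in sorted(mapping[ko]):
                fh.write(f"{ko}\t{pw}\n")


def write_subject_metadata(datasets, path) -> None:
    """Write a subject metadata TSV (subject, dataset, age) for many datasets."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject\tdataset\tage\n")
        for ds in datasets:
            for s in ds.subjects:
                age = ds.ages.get(s)
                fh.write(f"{s}\t{ds.dataset_id}\t{'' if age is None else age}\n")


def read_subject_metadata(path) -> pd.DataFrame:
    """Subject metadata TSV with columns subject, dataset, age (age may be blank)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "dataset": str})
    for col in ("subject", "dataset"):
        if col not in df.columns:
            raise PeptideTableFormatError(f"{path}: missing column {col!r}")
    if "age" not in df.columns:
        df["age"] = float("nan")
    return df
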