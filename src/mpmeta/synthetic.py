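"""Synthetic multi-cohort annotated-peptide-table generator with ground truth.

The generator emulates the *post-identification, post-annotation* stage of a
fecal metaproteomics study: per-dataset tables of peptides, each carrying a
taxonomic lineage (possibly truncated above genus by lowest-common-ancestor
ambiguity), one or more KO annotations, and per-subject MS1-style abundances.

Structure of a simulated community:

* a small number of phyla dominated by two (defaults 60% / 35%, matching the
  ubiquitous Bacillota/Bacteroidota dominance of the healthy gut), each holding
  several genera whose base weights decay geometrically within the phylum;
* subject compositions drawn logistic-normally around the base weights with a
  per-dataset batch offset (log scale) and per-subject noise;
* each genus expresses a set of specialist KOs plus a common pool of
  "housekeeping" KOs; a (genus, KO) signal for a subject is
  composition x expression x log-normal noise, split across 1-5 peptides with
  Dirichlet weights;
* lineage truncation is applied per peptide with a probability boosted for
  housekeeping KOs (conserved sequences drive LCA ambiguity) and calibrated so
  the abundance-weighted genus-unassigned fraction hits its target (70% by
  default);
* features named in `planted_pairs` become community-wide functions driven by
  a Gaussian-copula latent per subject; pair latents are correlated with
  Pearson r = 2 sin(pi * rho / 6) so their population Spearman correlation
  equals the requested rho.  Features of rho = 0 pairs are mutually
  independent and serve as negative controls.

All randomness flows from the single integer seed via named
``numpy.random.SeedSequence`` streams, so identical configs give
byte-identical outputs and :func:`composition_draw` can be evaluated
standalone for any (dataset, subject) index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_io import PeptideDataset, PeptideRecord

_PHYLUM_NAMES = ("Bacillota", "Bacteroidota", "Actinomycetota", "Pseudomonadota",
                 "Verrucomicrobiota", "Euryarchaeota")

#: Subject counts of the ten cohorts the default simulation emulates.
DEFAULT_SUBJECTS = (6, 16, 20, 17, 19, 20, 8, 12, 10, 6)

_AA = "ACDEFGHIKLMNPQRSTVWY"


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-dataset cohort.

    Defaults reproduce the study conditions the generator emulates: ten
    datasets with 134 subjects in total, two dominant phyla at 60%/35% mean
    relative abundance, and ~70% of peptide abundance unassignable at genus
    rank (~19% resolving further to species).
    """

    n_datasets: int = 10
    subjects_per_dataset: tuple[int, ...] = DEFAULT_SUBJECTS
    n_phyla: int = 4
    genera_per_phylum: int = 5
    n_ko: int = 80
    ko_per_genus: int = 10
    housekeeping_ko_fraction: float = 0.15
    genus_unassigned_target: float = 0.70
    species_annotation_target: float = 0.19
    batch_effect_sd: float = 0.30
    subject_noise_sd: float = 0.60
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    dominant_phyla_weights: tuple[float, ...] = (0.60, 0.35, 0.03, 0.02)
    human_fraction: float = 0.0  # abundance share of non-microbial peptides
    knockouts: tuple[tuple[int, str], ...] = ()  # (dataset index, genus) zeroed
    planted_latent_sd: float = 0.8  # log-scale amplitude of planted latents
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1 or len(self.subjects_per_dataset) != self.n_datasets:
            raise SimConfigError(
                "subjects_per_dataset must list one count per dataset"
            )
        if any(s < 5 for s in self.subjects_per_dataset):
            raise SimConfigError("each dataset needs >= 5 subjects")
        for name in ("genus_unassigned_target", "species_annotation_target",
                     "housekeeping_ko_fraction", "human_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.batch_effect_sd < 0 or self.subject_noise_sd < 0:
            raise SimConfigError("noise SDs must be nonnegative")
        if len(self.dominant_phyla_weights) != self.n_phyla:
            raise SimConfigError(
                "dominant_phyla_weights must have one weight per phylum"
            )
        if any(w <= 0 for w in self.dominant_phyla_weights) or not math.isclose(
            sum(self.dominant_phyla_weights), 1.0, abs_tol=1e-9
        ):
            raise SimConfigError("dominant_phyla_weights must be positive and sum to 1")
        seen = set()
        for a, b, rho in self.planted_pairs:
            if not -1.0 < rho < 1.0:
                raise SimConfigError(f"planted rho must be in (-1, 1), got {rho}")
            if a == b or a in seen or b in seen:
                raise SimConfigError(
                    "each feature may appear in at most one planted pair"
                )
            seen |= {a, b}
        if self.species_annotation_target > 1.0 - self.genus_unassigned_target + 1e-9:
            raise SimConfigError(
                "species_annotation_target cannot exceed the genus-assigned fraction"
            )

    # --- deterministic community structure -------------------------------

    def phylum_names(self) -> list[str]:
        names = list(_PHYLUM_NAMES[: self.n_phyla])
        names += [f"Phylum{i:02d}" for i in range(len(names), self.n_phyla)]
        return names

    def genus_names(self) -> list[str]:
        return [
            f"{p}_g{g + 1}"
            for p in self.phylum_names()
            for g in range(self.genera_per_phylum)
        ]

    def genus_phylum(self) -> dict[str, str]:
        return {g: g.rsplit("_g", 1)[0] for g in self.genus_names()}

    def base_weights(self) -> pd.Series:
        """Genus base weights: phylum weight split geometrically (ratio 0.6)."""
        w = {}
        for p, pw in zip(self.phylum_names(), self.dominant_phyla_weights):
            shares = 0.6 ** np.arange(self.genera_per_phylum)
            shares /= shares.sum()
            for g in range(self.genera_per_phylum):
                w[f"{p}_g{g + 1}"] = pw * shares[g]
        return pd.Series(w, dtype=float)

    def ko_names(self) -> list[str]:
        return [f"K{i:05d}" for i in range(1, self.n_ko + 1)]

    def housekeeping_kos(self) -> list[str]:
        n_hk = round(self.housekeeping_ko_fraction * self.n_ko)
        return self.ko_names()[:n_hk]

    def planted_features(self) -> list[str]:
        return [f for pair in self.planted_pairs for f in pair[:2]]


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort, for recovery testing."""

    config: SimConfig
    composition: pd.DataFrame       # ecological genus simplex, rows (dataset, subject)
    effective_composition: pd.DataFrame  # expected abundance-scale genus shares
    expression: pd.DataFrame        # genus x KO mean expression
    planted_pairs: list[tuple[str, str, float]]
    truncation: dict[str, pd.DataFrame] = field(default_factory=dict)
    # per dataset: peptide sequence -> truncated flag + rank reached

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        with open(path / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
        self.composition.to_csv(path / "composition.tsv", sep="\t")
        self.effective_composition.to_csv(
            path / "effective_composition.tsv", sep="\t"
        )
        self.expression.to_csv(path / "expression.tsv", sep="\t")
        with open(path / "planted_pairs.tsv", "w") as fh:
            fh.write("featureA\tfeatureB\trho\n")
            for a, b, r in self.planted_pairs:
                fh.write(f"{a}\t{b}\t{r}\n")
        for ds_id, df in self.truncation.items():
            df.to_csv(path / f"truncation_{ds_id}.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path) -> "GroundTruth":
        path = Path(path)
        with open(path / "config.json") as fh:
            cfg = json.load(fh)
        for key in ("subjects_per_dataset", "dominant_phyla_weights"):
            cfg[key] = tuple(cfg[key])
        cfg["planted_pairs"] = tuple(
            (a, b, float(r)) for a, b, r in cfg["planted_pairs"]
        )
        cfg["knockouts"] = tuple((int(d), g) for d, g in cfg["knockouts"])
        config = SimConfig(**cfg)
        comp = pd.read_csv(path / "composition.tsv", sep="\t", index_col=[0, 1])
        eff = pd.read_csv(
            path / "effective_composition.tsv", sep="\t", index_col=[0, 1]
        )
        expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
        pp = pd.read_csv(path / "planted_pairs.tsv", sep="\t")
        pairs = [tuple(r) for r in pp.itertuples(index=False)]
        trunc = {}
        for f in sorted(path.glob("truncation_*.tsv")):
            trunc[f.stem.replace("truncation_", "")] = pd.read_csv(
                f, sep="\t", index_col=0
            )
        return cls(config, comp, eff, expr,
                   [(a, b, float(r)) for a, b, r in pairs], trunc)


def _rng(config: SimConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 977, *key)))


def _batch_offsets(config: SimConfig, d: int) -> np.ndarray:
    """Per-dataset log-scale genus offsets (the batch effect)."""
    rng = _rng(config, 1, d)
    n_genera = config.n_phyla * config.genera_per_phylum
    return rng.normal(0.0, config.batch_effect_sd, size=n_genera)


def composition_draw(config: SimConfig, dataset_index: int, subject_index: int
                     ) -> pd.Series:
    """Logistic-normal genus composition for one subject.

    log base weights + dataset batch offset + subject noise, softmax-closed to
    the simplex.  With both noise SDs at zero the draw equals the base weights
    exactly.  Genera knocked out for this dataset are set to zero before
    closure.
    """
    if not 0 <= dataset_index < config.n_datasets:
        raise IndexError(f"dataset index {dataset_index} out of range")
    if not 0 <= subject_index < config.subjects_per_dataset[dataset_index]:
        raise IndexError(f"subject index {subject_index} out of range")
    base = config.base_weights()
    logw = np.log(base.to_numpy())
    logw = logw + _batch_offsets(config, dataset_index)
    rng = _rng(config, 2, dataset_index, subject_index)
    logw = logw + rng.normal(0.0, config.subject_noise_sd, size=len(base))
    w = np.exp(logw - logw.max())
    comp = pd.Series(w, index=base.index)
    for d, g in config.knockouts:
        if d == dataset_index:
            comp[g] = 0.0
    return comp / comp.sum()


def _expression(config: SimConfig) -> pd.DataFrame:
    """Genus x KO mean expression matrix (0 where a genus lacks the KO).

    Housekeeping KOs are expressed by every genus; each genus additionally
    expresses `ko_per_genus` specialist KOs.  Community-wide planted features
    are expressed uniformly (mean 1) by all genera so the subject latent, not
    the composition, drives their total abundance.
    """
    genera = config.genus_names()
    kos = config.ko_names()
    hk = set(config.housekeeping_kos())
    planted = set(config.planted_features())
    unknown = planted - set(kos)
    if unknown:
        raise SimConfigError(f"planted features not in the KO pool: {sorted(unknown)}")
    hk_list = config.housekeeping_kos()
    pool = [k for k in kos if k not in hk and k not in planted]
    rng = _rng(config, 3)
    expr = pd.DataFrame(0.0, index=genera, columns=kos)
    for g in genera:
        for k in hk_list:
            expr.loc[g, k] = rng.lognormal(mean=0.5, sigma=0.8)
        chosen = rng.choice(len(pool), size=min(config.ko_per_genus, len(pool)),
                            replace=False)
        for ci in chosen:
            expr.loc[g, pool[ci]] = rng.lognormal(mean=0.0, sigma=1.0)
    # normalize each genus's proteome to the same total, so a genus's share of
    # the community signal reflects its ecological share rather than a random
    # per-genus expression budget
    expr = expr.div(expr.sum(axis=1), axis=0)
    # planted community-wide features are minor constituents: a small uniform
    # expression keeps their share of the total signal low, so compositional
    # closure does not couple them to each other or to the rest
    for k in config.planted_features():
        expr[k] = 0.005
    return expr


def _planted_latents(config: SimConfig, d: int, n_subj: int) -> pd.DataFrame:
    """Per-subject latent multipliers for planted community-wide features."""
    feats = config.planted_features()
    if not feats:
        return pd.DataFrame(index=range(n_subj))
    rng = _rng(config, 4, d)
    cols = {}
    for a, b, rho in config.planted_pairs:
        r = 2.0 * math.sin(math.pi * rho / 6.0)  # Spearman -> Pearson (copula)
        cov = [[1.0, r], [r, 1.0]]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n_subj,
                                    method="cholesky")
        cols[a] = z[:, 0]
        cols[b] = z[:, 1]
    return pd.DataFrame(cols, index=range(n_subj))


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _lineage_for(genus: str, phylum: str, depth: str) -> tuple[tuple[str, str], ...]:
    """Synthetic lineage for a genus truncated at `depth`."""
    full = (
        ("domain", "Bacteria"),
        ("phylum", phylum),
        ("class", f"{phylum}_cl"),
        ("order", f"{phylum}_or{genus.rsplit('_g', 1)[1]}"),
        ("family", f"{genus}_fam"),
        ("genus", genus),
        ("species", f"{genus}_sp1"),
    )
    stop = {"domain": 1, "phylum": 2, "class": 3, "order": 4,
            "family": 5, "genus": 6, "species": 7}[depth]
    return full[:stop]


def _simulate_dataset(
    config: SimConfig, d: int, expr: pd.DataFrame
) -> tuple[PeptideDataset, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One dataset: peptides, ecological & effective compositions, truncation log."""
    n_subj = config.subjects_per_dataset[d]
    ds_id = f"D{d + 1:02d}"
    subjects = [f"{ds_id}_s{j + 1:02d}" for j in range(n_subj)]
    genera = config.genus_names()
    phylum_of = config.genus_phylum()
    kos = config.ko_names()
    hk = set(config.housekeeping_kos())
    planted = set(config.planted_features())

    comp = pd.DataFrame(
        [composition_draw(config, d, j).to_numpy() for j in range(n_subj)],
        index=subjects, columns=genera,
    )
    latents = _planted_latents(config, d, n_subj)
    rng = _rng(config, 5, d)

    # signal[(genus, ko)] per subject
    expr_np = expr.to_numpy()
    signal: dict[tuple[str, str], np.ndarray] = {}
    for gi, g in enumerate(genera):
        for ki, k in enumerate(kos):
            e = expr_np[gi, ki]
            if e <= 0:
                continue
            base = comp[g].to_numpy() * e
            if k in planted:
                mult = np.exp(config.planted_latent_sd * latents[k].to_numpy())
            else:
                mult = np.exp(rng.normal(0.0, config.subject_noise_sd, size=n_subj))
            vals = base * mult
            if vals.any():
                signal[(g, k)] = vals

    # effective (abundance-scale) genus composition
    eff = pd.DataFrame(0.0, index=subjects, columns=genera)
    for (g, k), vals in signal.items():
        eff[g] += vals
    eff = eff.div(eff.sum(axis=1), axis=0)

    # split each (genus, ko) signal across 1-5 peptides with Dirichlet weights
    peptide_rows = []  # (sequence, genus, ko, per-subject values)
    for (g, k), vals in sorted(signal.items()):
        n_pep = int(rng.integers(1, 6))
        weights = rng.dirichlet(np.ones(n_pep))
        for w in weights:
            peptide_rows.append([_random_peptide(rng), g, k, vals * w])

    # calibrate per-peptide truncation probabilities on the abundance scale
    tot_hk = sum(r[3].sum() for r in peptide_rows if r[2] in hk)
    tot_all = sum(r[3].sum() for r in peptide_rows)
    tot_o = tot_all - tot_hk
    target = config.genus_unassigned_target
    p_hk = min(1.0, target * 1.3) if target > 0 else 0.0
    if tot_o > 0:
        p_o = (target * tot_all - p_hk * tot_hk) / tot_o
        p_o = min(1.0, max(0.0, p_o))
    else:
        p_o = 0.0
    if tot_hk > 0 and tot_o > 0:  # re-solve p_hk if p_o clipped
        p_hk = min(1.0, max(0.0, (target * tot_all - p_o * tot_o) / tot_hk))
    # conditional species probability among genus-resolved peptides
    assigned = 1.0 - target
    p_species = (
        min(1.0, config.species_annotation_target / assigned) if assigned > 0 else 0.0
    )
    trunc_depth_choices = ["domain", "phylum", "order"]
    trunc_depth_p = [0.10, 0.50, 0.40]

    records = []
    trunc_log = []
    for seq, g, k, vals in peptide_rows:
        p_t = p_hk if k in hk else p_o
        truncated = rng.random() < p_t
        if truncated:
            depth = trunc_depth_choices[
                int(rng.choice(len(trunc_depth_choices), p=trunc_depth_p))
            ]
        else:
            depth = "species" if rng.random() < p_species else "genus"
        lineage = _lineage_for(g, phylum_of[g], depth)
        records.append(PeptideRecord(
            sequence=seq, lineage=lineage, ko_ids=frozenset({k}),
            abundances=dict(zip(subjects, (vals * 1e6).tolist())),
        ))
        trunc_log.append({"peptide": seq, "genus": g, "ko": k,
                          "depth": depth, "truncated": truncated})

    if config.human_fraction > 0:
        # non-microbial contaminants: human peptides without lineage/KO share
        n_human = max(1, len(peptide_rows) // 20)
        human_total = tot_all * config.human_fraction / (1 - config.human_fraction)
        w = rng.dirichlet(np.ones(n_human))
        for i in range(n_human):
            vals = rng.dirichlet(np.ones(n_subj)) * human_total * w[i]
            records.append(PeptideRecord(
                sequence=_random_peptide(rng),
                lineage=(("domain", "Eukaryota"), ("phylum", "Chordata")),
                ko_ids=frozenset(),
                abundances=dict(zip(subjects, (vals * 1e6).tolist())),
            ))

    ages = {s: float(a) for s, a in
            zip(subjects, rng.integers(20, 71, size=n_subj))}
    ds = PeptideDataset(dataset_id=ds_id, subjects=subjects, peptides=records,
                        ages=ages, normalized=False)
    trunc_df = pd.DataFrame(trunc_log).set_index("peptide")
    return ds, comp, eff, trunc_df


def simulate_cohorts(config: SimConfig) -> tuple[list[PeptideDataset], GroundTruth]:
    """Generate all datasets of a synthetic cohort collection with ground truth."""
    expr = _expression(config)
    datasets, comps, effs, truncs = [], [], [], {}
    for d in range(config.n_datasets):
        ds, comp, eff, trunc = _simulate_dataset(config, d, expr)
        datasets.append(ds)
        comp.index = pd.MultiIndex.from_product(
            [[ds.dataset_id], comp.index], names=["dataset", "subject"]
        )
        eff.index = comp.index
        comps.append(comp)
        effs.append(eff)
        truncs[ds.dataset_id] = trunc
    gt = GroundTruth(
        config=config,
        composition=pd.concat(comps),
        effective_composition=pd.concat(effs),
        expression=expr,
        planted_pairs=list(config.planted_pairs),
        truncation=truncs,
    )
    return datasets, gt


def default_pathway_map(config: SimConfig, n_pathways: int = 15) -> dict:
    """Deterministic KO -> pathway multimap for a simulated KO pool.

    Each KO maps to 1-3 of `n_pathways` synthetic pathways; housekeeping KOs
    all share pathway 'pw00' (a ribosome-like module).
    """
    rng = _rng(config, 6)
    pws = [f"pw{i:02d}" for i in range(n_pathways)]
    hk = set(config.housekeeping_kos())
    mapping = {}
    for k in config.ko_names():
        n = int(rng.integers(1, 4))
        chosen = set(rng.choice(pws[1:], size=n, replace=False).tolist())
        if k in hk:
            chosen.add(pws[0])
        mapping[k] = frozenset(chosen)
    return mapping
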