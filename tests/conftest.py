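import pytest

from mpmeta.peptide_io import PeptideDataset, PeptideRecord
from mpmeta.synthetic import SimConfig, simulate_cohorts


def make_peptide(seq, lineage, kos, abundances):
    return PeptideRecord(
        sequence=seq, lineage=tuple(lineage), ko_ids=frozenset(kos),
        abundances=dict(abundances),
    )


LIN_FAECA = (
    ("domain", "Bacteria"), ("phylum", "Bacillota"), ("class", "Clostridia"),
    ("order", "Eubacteriales"), ("family", "Oscillospiraceae"),
    ("genus", "Faecalibacterium"),
)
LIN_BACT_PHYLUM = (("domain", "Bacteria"), ("phylum", "Bacillota"))
LIN_PREVO = (
    ("domain", "Bacteria"), ("phylum", "Bacteroidota"), ("class", "Bacteroidia"),
    ("order", "Bacteroidales"), ("family", "Prevotellaceae"),
    ("genus", "Prevotella"),
)
LIN_HUMAN = (("domain", "Eukaryota"), ("phylum", "Chordata"))


@pytest.fixture
def toy_dataset():
    """Two-subject toy dataset mixing resolved, truncated and human peptides."""
    peptides = [
        make_peptide("PEPTIDEA", LIN_FAECA, {"K00248"}, {"s1": 4.0, "s2": 2.0}),
        make_peptide("PEPTIDEB", LIN_BACT_PHYLUM, {"K00248"}, {"s1": 6.0, "s2": 1.0}),
        make_peptide("PEPTIDEC", LIN_PREVO, {"K00001", "K00002"}, {"s1": 5.0, "s2": 3.0}),
        make_peptide("PEPTIDED", LIN_HUMAN, set(), {"s1": 2.0, "s2": 2.0}),
        make_peptide("PEPTIDEE", (), set(), {"s1": 1.0, "s2": 1.0}),
    ]
    return PeptideDataset(
        dataset_id="toy", subjects=["s1", "s2"], peptides=peptides,
        ages={"s1": 30.0, "s2": 45.0},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two small simulated datasets with default noise, shared across tests."""
    cfg = SimConfig(n_datasets=2, subjects_per_dataset=(6, 6), seed=42)
    return simulate_cohorts(cfg)
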