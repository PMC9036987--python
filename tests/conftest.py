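import numpy as np
import pytest

from phycosignal.refdb import ProteinRecord, Subtype, dedupe
from phycosignal.simulate import (
    SimulationConfig,
    make_abundance_series,
    make_references,
    make_taxonomy,
)
from phycosignal.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Small but complete study configuration used across modules."""
    return SimulationConfig(seed=42, n_samples=6, reads_per_sample=60)


@pytest.fixture(scope="session")
def references(sim_config):
    records, templates = make_references(sim_config)
    return records


@pytest.fixture(scope="session")
def reference_db(references):
    return dedupe(references, 0.97)


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """root -> Bacteria -> (Comamonadaceae -> {Hydrogenophaga, Variovorax},
    Pseudomonadaceae -> Pseudomonas); ranks collapsed to the ones that matter."""
    return TaxonomyTree(
        [
            TaxNode(1, "root", "root", 1),
            TaxNode(2, "Bacteria", "superkingdom", 1),
            TaxNode(10, "Comamonadaceae", "family", 2),
            TaxNode(11, "Hydrogenophaga", "genus", 10),
            TaxNode(12, "Variovorax", "genus", 10),
            TaxNode(20, "Pseudomonadaceae", "family", 2),
            TaxNode(21, "Pseudomonas", "genus", 20),
        ]
    )


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
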