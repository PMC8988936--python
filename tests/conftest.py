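import pytest

from kglit import synth

# Worked RDF example (Tadalafil / CAV1 / pulmonary hypertension):
# four relations among six entities.
SNIPPET_TRIPLES = [
    ("doid:14557", "has_disease_phenotype", "hp:0011675"),
    ("entrez:857", "has_disease_association", "doid:14557"),
    ("stitch:00110635", "has_sideeffect", "hp:0002027"),
    ("stitch:00110635", "has_indication", "doid:65"),
]


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale world for fast unit tests (not the study conditions)."""
    return synth.SynthConfig(
        n_drugs=30,
        n_genes=40,
        n_diseases=15,
        n_phenotypes=12,
        n_classes=8,
        n_docs=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    kg, gt = synth.generate_synthetic_kg(small_config)
    docs, id_map = synth.generate_synthetic_abstracts(kg, gt, small_config)
    return kg, gt, docs, id_map


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions (200 drugs / 300 genes / 2,000 docs)."""
    cfg = synth.preset("default", seed=1)
    kg, gt = synth.generate_synthetic_kg(cfg)
    docs, id_map = synth.generate_synthetic_abstracts(kg, gt, cfg)
    return cfg, kg, gt, docs, id_map
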