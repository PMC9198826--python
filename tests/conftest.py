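import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tcmrec.ontology import DrugNode, DrugOntology  # noqa: E402
from tcmrec.synth import CohortConfig, generate_cohort, generate_ontology  # noqa: E402


@pytest.fixture(scope="session")
def tiny_onto() -> DrugOntology:
    """Two first categories; X has two category-II formulas with two herbs
    each, Y has one; plus one parentless Western-medicine leaf."""
    return DrugOntology([
        DrugNode("X", "warming", "category1", None),
        DrugNode("X.a", "formula-a", "category2", "X"),
        DrugNode("X.a.1", "herb-a1", "leaf", "X.a"),
        DrugNode("X.a.2", "herb-a2", "leaf", "X.a"),
        DrugNode("X.b", "formula-b", "category2", "X"),
        DrugNode("X.b.1", "herb-b1", "leaf", "X.b"),
        DrugNode("Y", "cooling", "category1", None),
        DrugNode("Y.a", "formula-ya", "category2", "Y"),
        DrugNode("Y.a.1", "herb-ya1", "leaf", "Y.a"),
        DrugNode("W", "aspirin", "leaf", None),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """60 noiseless patients with their generating ontology and config."""
    cfg = CohortConfig(n_patients=60, n_syndromes=5, n_category1=5,
                       leaves_per_category=3, seed=42)
    onto = generate_ontology(cfg)
    records = generate_cohort(cfg, onto)
    return cfg, onto, records


def random_ontology(rng: np.random.Generator) -> DrugOntology:
    """Random 3-level ontology for property tests."""
    n_cat1 = int(rng.integers(1, 6))
    nodes = []
    for c in range(n_cat1):
        nodes.append(DrugNode(f"c{c}", f"cat{c}", "category1", None))
        for f in range(int(rng.integers(1, 3))):
            nodes.append(DrugNode(f"c{c}.f{f}", "formula", "category2", f"c{c}"))
            for l in range(int(rng.integers(1, 4))):
                nodes.append(DrugNode(f"c{c}.f{f}.l{l}", "herb", "leaf", f"c{c}.f{f}"))
    return DrugOntology(nodes)
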