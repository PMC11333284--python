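import json

import pytest

from rareburden.cohort_db import build_db
from rareburden.ontology import OntologyGraph
from rareburden.synthetic_data import (
    SimConfig,
    simulate_cohort,
    simulate_region_fixture,
)


@pytest.fixture
def diamond_graph():
    """root <- A <- {B, C} <- D, plus leaf E directly under root."""
    return OntologyGraph(
        terms={"root", "A", "B", "C", "D", "E"},
        parents={
            "root": set(),
            "A": {"root"},
            "B": {"A"},
            "C": {"A"},
            "D": {"B", "C"},
            "E": {"root"},
        },
        root="root",
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Small end-to-end bundle: 80 case trios, 300 controls, causal + 3 genes."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(
        n_case_trios=80,
        n_control_families=300,
        n_background_genes=3,
        de_novo_rate=0.15,
        background_rare_rate=0.01,
        seed=123,
    )
    bundle = simulate_cohort(cfg, out)
    db = build_db(bundle.vcf, bundle.ped, bundle.phenotypes, bundle.transcripts)
    truth = json.loads(bundle.truth.read_text())
    return bundle, db, truth


@pytest.fixture(scope="session")
def region_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("region")
    bundle = simulate_region_fixture(out, seed=0)
    db = build_db(bundle.vcf, bundle.ped, bundle.phenotypes, bundle.transcripts)
    truth = json.loads(bundle.truth.read_text())
    return bundle, db, truth
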