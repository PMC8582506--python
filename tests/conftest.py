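import numpy as np
import pandas as pd
import pytest

import ffpe16s as f


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return f.simulate_cohort(f.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def preprocessed(cohort):
    """The cohort after the full cascade, with report and NTC-free metadata."""
    table, report = f.run_preprocessing(cohort.table, cohort.taxonomy, "NTC")
    meta = f.SampleMetadata(cohort.metadata.frame.drop(index=["NTC"]))
    return table, report, meta


@pytest.fixture
def tiny_tables():
    """Minimal valid 2-ASV x 3-sample dataset (one FF/FFPE pair + NTC)."""
    counts = pd.DataFrame(
        {"P1-FF": [5, 3], "P1-FFPE": [2, 4], "NTC": [0, 1]},
        index=["asv_a", "asv_b"],
    )
    table = f.AsvTable(counts)
    tax = f.TaxonomyTable(
        pd.DataFrame(
            {
                "kingdom": ["Bacteria", "Bacteria"],
                "phylum": ["Bacteroidetes", "Firmicutes"],
                "class": ["Bacteroidia", "Clostridia"],
                "order": ["Bacteroidales", "Clostridiales"],
                "family": ["Bacteroidaceae", "Lachnospiraceae"],
                "genus": ["Bacteroides", "Blautia"],
            },
            index=["asv_a", "asv_b"],
        )
    )
    meta = f.SampleMetadata(
        pd.DataFrame(
            {"patient_id": ["P1", "P1", ""], "preservation": ["FF", "FFPE", "NTC"]},
            index=["P1-FF", "P1-FFPE", "NTC"],
        )
    )
    return table, tax, meta


def random_asv_table(rng: np.random.Generator, n_asvs: int, n_samples: int):
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(n_asvs, n_samples)),
        index=[f"asv{i:03d}" for i in range(n_asvs)],
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )
    return f.AsvTable(counts)
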