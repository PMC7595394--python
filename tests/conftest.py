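import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import prairienet as pn

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return pn.default_registry()


@pytest.fixture(scope="session")
def small_reg():
    return pn.small_registry(
        bees={"Halictidae": 2, "Apidae": 2}, plants=4, pooled=False
    )


@pytest.fixture(scope="session")
def dataset(registry):
    """One study-scale synthetic realization shared across tests."""
    truth = pn.default_truth(registry, seed=11)
    bees, plants, visits, truth = pn.generate_dataset(truth, registry)
    return {
        "bees": bees,
        "plants": plants,
        "visits": visits,
        "truth": truth,
        "registry": registry,
    }


@pytest.fixture()
def tiny_survey(small_reg):
    """Four sampling events, hand-sized counts; valid against small_reg."""
    rows = []
    taxa = small_reg.bees
    rng = np.random.default_rng(5)
    for site in ("S1", "S2"):
        for treatment in ("strip", "control"):
            for month in ("May", "Jun"):
                for t in taxa:
                    v = int(rng.integers(0, 6))
                    if v:
                        rows.append((site, treatment, 2016, month, t, v))
    return pn.SurveyTable(
        pd.DataFrame(
            rows, columns=["site", "treatment", "year", "month", "taxon", "value"]
        ),
        role="bee",
    )
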