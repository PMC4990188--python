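import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crce

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_table(rows):
    """Long-format survey frame from (habitat, block, treatment, plot,
    cluster, quadrat, species, group[, present]) tuples."""
    cols = [
        "habitat", "block", "treatment", "plot",
        "cluster", "quadrat", "species", "group",
    ]
    if rows and len(rows[0]) == 9:
        cols = cols + ["present"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def toy_survey():
    """One full block: control/removal/releasing plots with a few species."""
    rows = []
    richness = {"control": 2, "removal": 5, "releasing": 4}
    for treatment, n_sp in richness.items():
        plot = f"P-{treatment}"
        for cl in range(1, 6):
            for q in range(1, 6):
                for i in range(n_sp):
                    rows.append(
                        ("valley", "B1", treatment, plot, cl, q, f"sp{i}", "focal")
                    )
    return crce.from_frame(make_table(rows))


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default synthetic experiment (case-study layout)."""
    return crce.simulate_survey(crce.CommunityParams(), seed=20202)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(991)
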