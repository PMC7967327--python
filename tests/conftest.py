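import numpy as np
import pytest

import riskrules as rr


@pytest.fixture(scope="session")
def top_rule_fixture():
    """386-subject incidence matrix reproducing the printed top-rule counts:
    207 cases / 179 controls; 20 cases and 1 control carry the triad."""
    return rr.exact_fixture(
        207,
        179,
        {
            (("A", "B", "C"), "case"): 20,
            (("A", "B", "C"), "control"): 1,
        },
    )


def random_incidence(rng, n_subjects, n_items, p=0.4, phenotype_item="MS"):
    """Small random incidence matrix with a phenotype item appended."""
    cells = rng.random((n_subjects, n_items + 1)) < p
    cells[:, -1] = rng.random(n_subjects) < 0.5
    items = [f"i{j}" for j in range(n_items)] + [phenotype_item]
    return rr.IncidenceMatrix(
        subject_ids=[f"s{k}" for k in range(n_subjects)],
        item_ids=items,
        cells=cells,
        phenotype_item=phenotype_item,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
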