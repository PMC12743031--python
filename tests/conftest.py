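import numpy as np
import pandas as pd
import pytest

from lcvar import SimDesign, make_panel, simulate_design


def panel_from_rows(rows, outcomes, **kw):
    """rows: list of dicts with person_id/day/beep + outcome values."""
    return make_panel(pd.DataFrame(rows), outcomes=outcomes, **kw)


@pytest.fixture(scope="session")
def two_cluster_panel():
    """Well-separated 2-cluster panel (differences in lagged effects),
    no within-cluster variation — the workhorse EM fixture."""
    design = SimDesign(K=2, p=1, n_subj=20, n_t=80, diff_locus="phi",
                       within_sd=0.0, seed=42)
    panel, labels, truth = simulate_design(design)
    return panel, labels, truth


@pytest.fixture(scope="session")
def one_cluster_panel():
    design = SimDesign(K=1, p=1, n_subj=12, n_t=60, seed=7)
    panel, labels, truth = simulate_design(design)
    return panel, labels, truth


@pytest.fixture
def gappy_panel():
    """One person, two days, with a missing cell: days/beeps
    (1,1), (1,2 missing outcome), (1,3), (2,1), (2,2)."""
    rows = [
        dict(person_id="a", day=1, beep=1, y=1.0),
        dict(person_id="a", day=1, beep=2, y=np.nan),
        dict(person_id="a", day=1, beep=3, y=3.0),
        dict(person_id="a", day=2, beep=1, y=4.0),
        dict(person_id="a", day=2, beep=2, y=5.0),
    ]
    return panel_from_rows(rows, ["y"])
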