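import numpy as np
import pandas as pd
import pytest

from dtscoring import (GeneratorConfig, RaterIRT, RatingTable, generate_study,
                       to_wide)


def make_table(rows, K=5, level="response", raters=None):
    """Build a RatingTable from (participant, task, unit, rater, rating) tuples."""
    df = pd.DataFrame(rows, columns=["participant_id", "task_id", "unit_id",
                                     "rater_id", "rating"])
    return RatingTable(df, K=K, level=level, raters=raters)


@pytest.fixture()
def toy_table():
    """Two participants, one task, four responses, three raters, complete."""
    rows = []
    ratings = {"u1": (2, 3, 2), "u2": (4, 5, 4), "u3": (1, 2, 1), "u4": (3, 3, 4)}
    pid = {"u1": "p1", "u2": "p1", "u3": "p2", "u4": "p2"}
    for uid, rs in ratings.items():
        for j, r in enumerate(rs):
            rows.append((pid[uid], "T1", uid, f"r{j+1}", r))
    return make_table(rows)


@pytest.fixture(scope="session")
def small_study():
    """A 60-participant synthetic study shared by read-only tests."""
    return generate_study(GeneratorConfig(n_participants=60, seed=1))


@pytest.fixture(scope="session")
def small_grm(small_study):
    wide = to_wide(small_study.individual_table)
    return RaterIRT(family="grm", K=5).fit(wide), wide
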