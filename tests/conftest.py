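import numpy as np
import pandas as pd
import pytest

from beliefmed import SynthTruth, TrialTable, generate_mediation_dataset

#: 17-row delimited fixture mirroring the canonical long-format layout:
#: three participants, beliefs 60/30, 55/35, 70/60 per cue level (DiffBelief 30/20/10); the
#: third participant is missing one level-2 trial.  JOL and ST values
#: are synthetic.
EXAMPLE_CSV = """SubID,Cue,Belief,ST,JOL
1,1,60,1.2,70
1,1,60,0.9,65
1,1,60,1.1,75
1,-1,30,1.5,40
1,-1,30,1.7,35
1,-1,30,1.4,45
2,1,55,1.0,60
2,1,55,1.3,55
2,1,55,0.8,65
2,-1,35,1.6,50
2,-1,35,1.2,45
2,-1,35,1.1,55
3,1,70,0.7,80
3,1,70,0.9,85
3,1,70,1.0,75
3,-1,60,1.3,65
3,-1,60,1.4,70
"""


@pytest.fixture
def example_csv() -> str:
    return EXAMPLE_CSV


@pytest.fixture
def example_table() -> TrialTable:
    from beliefmed import read_trials

    return read_trials(EXAMPLE_CSV)


@pytest.fixture
def small_table() -> TrialTable:
    """Balanced 3-participant table with beliefs 60/30, 50/40, 70/60."""
    rows = []
    for pid, (b1, b2) in enumerate([(60, 30), (50, 40), (70, 60)], start=1):
        for cue, b in ((1.0, b1), (-1.0, b2)):
            for _ in range(3):
                rows.append((str(pid), cue, float(b), 50.0 + 0.5 * b + 5 * cue))
    return TrialTable(pd.DataFrame(rows, columns=["participant", "cue", "belief", "jol"]))


@pytest.fixture(scope="session")
def recovery_table():
    """One medium generator dataset used across model tests."""
    table, truth = generate_mediation_dataset(
        SynthTruth(), n_participants=30, trials_per_level=20, seed=20260924
    )
    return table, truth


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
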