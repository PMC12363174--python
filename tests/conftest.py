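import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from t6sscomp import CountTable, read_newick


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — the worked example tree."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_tree():
    return read_newick("(A:1,B:1);")


def make_confrontation_table(values: dict, strains=("X", "Y")) -> CountTable:
    """Build a small two-arm count table.

    ``values``: {(arm, timepoint): {strain: [per-replicate counts]}}.
    """
    rows, meta, idx = [], [], []
    for (arm, t), per_strain in values.items():
        n_reps = len(next(iter(per_strain.values())))
        for r in range(n_reps):
            idx.append(f"{arm}_t{t:g}_r{r + 1}")
            rows.append([per_strain[s][r] for s in strains])
            meta.append({"arm": arm, "timepoint_h": t, "replicate": r + 1})
    counts = pd.DataFrame(rows, index=idx, columns=list(strains))
    return CountTable(counts, pd.DataFrame(meta, index=idx))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
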