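import numpy as np
import pandas as pd
import pytest

import copeind as ci
from copeind.reference import load_indicator_reference


@pytest.fixture(scope="session")
def default_survey():
    """One synthetic survey drawn from the default design (seed 1)."""
    return ci.generate(ci.SyntheticDesign(seed=1))


@pytest.fixture(scope="session")
def indicator_reference():
    return load_indicator_reference()


@pytest.fixture()
def small_abundance():
    """Tiny hand-checkable abundance matrix (3 stations x 2 taxa)."""
    df = pd.DataFrame(
        [[10.0, 0.0], [20.0, 2.0], [30.0, 0.0]],
        index=["s1", "s2", "s3"],
        columns=["taxA", "taxB"],
    )
    return ci.AbundanceMatrix(df)


def groups_from_sizes(sizes, labels=("A", "B", "C")):
    """Station ids St01.. plus a partition with the given group sizes."""
    ids, grp = [], []
    for lab, n in zip(labels, sizes):
        for _ in range(n):
            ids.append(f"St{len(ids) + 1:02d}")
            grp.append(lab)
    return ids, ci.GroupPartition(pd.Series(grp, index=ids))


def constant_group_matrix(group_means, sizes, taxon="tax"):
    """Single-taxon matrix whose abundance is constant within each group,
    so the group means are exact and fidelity is 1 wherever the mean is
    positive."""
    ids, partition = groups_from_sizes(sizes)
    vals = []
    for mean, n in zip(group_means, sizes):
        vals.extend([mean] * n)
    abund = ci.AbundanceMatrix(
        pd.DataFrame({taxon: vals}, index=ids)
    )
    return abund, partition
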