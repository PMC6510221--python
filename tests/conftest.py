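import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscope import OtuTable


@pytest.fixture
def balanced_tree() -> TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1); — d(A,B)=2, d(A,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def caterpillar_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def star_tree() -> TreeNode:
    """Equal-branch star: all off-diagonal cophenetic distances equal."""
    return TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))


@pytest.fixture
def small_table() -> OtuTable:
    df = pd.DataFrame(
        {
            "s1": [6, 0, 2, 1],
            "s2": [2, 2, 0, 4],
            "s3": [1, 5, 3, 0],
        },
        index=["A", "B", "C", "D"],
    )
    return OtuTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
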