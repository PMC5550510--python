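import numpy as np
import pandas as pd
import pytest

from votesig.expression import ExpressionMatrix
from votesig.signature import PipelineConfig
from votesig.synthetic import SyntheticParams, generate_dataset


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def tiny_matrix():
    """Two contrasts worth of samples is overkill here: one matrix,
    two groups, hand-checkable values."""
    values = pd.DataFrame(
        {
            "s1": [7.5, 6.0, 4.0],
            "s2": [7.5, 6.0, 4.0],
            "c1": [6.0, 6.0, 2.0],
            "c2": [6.0, 6.0, 2.0],
        },
        index=["gA", "gB", "gC"],
    )
    group_of = {"s1": "treated", "s2": "treated", "c1": "sham", "c2": "sham"}
    return ExpressionMatrix(values=values, group_of=group_of)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted dataset shared by read-only tests."""
    params = SyntheticParams(
        seed=7,
        n_genes=300,
        n_consensus_up=15,
        n_consensus_down=5,
        n_specific_per_contrast=5,
        n_subfloor_decoys=10,
    )
    matrices, contrasts, truth = generate_dataset(params)
    return params, matrices, contrasts, truth


def brute_force_votes(call_tables):
    """Independent oracle: re-derive vote counts with plain loops from
    per-contrast direction calls."""
    universe = sorted({g for df in call_tables.values() for g in df.index})
    votes = {}
    for g in universe:
        up = down = 0
        for df in call_tables.values():
            if g in df.index:
                d = df.loc[g, "direction"]
                if d == "up":
                    up += 1
                elif d == "down":
                    down += 1
        votes[g] = (up, down)
    return votes


def brute_force_direction(log2fc, max_group_mean, fc_log2=1.0, expr_floor=5.0):
    """Independent restatement of the dysregulation filter."""
    if max_group_mean < expr_floor:
        return "none"
    if log2fc > fc_log2:
        return "up"
    if log2fc < -fc_log2:
        return "down"
    return "none"
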