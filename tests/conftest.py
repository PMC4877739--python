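import numpy as np
import pandas as pd
import pytest

from dualomics.core_io import RNA, ExperimentDesign, ExpressionMatrix


@pytest.fixture
def design():
    return ExperimentDesign(
        conditions=("cellobiose", "xylose", "alpha_cellulose", "xylan"),
        reference="cellobiose",
    )


@pytest.fixture
def two_condition_design():
    return ExperimentDesign(conditions=("cb", "xy"), reference="cb")


@pytest.fixture
def make_matrix():
    """Build an ExpressionMatrix from {locus: {(condition, replicate): value}}."""

    def _make(values, design, omic=RNA):
        frame = pd.DataFrame.from_dict(values, orient="index")
        frame = frame.reindex(columns=design.columns())
        frame.columns = pd.MultiIndex.from_tuples(
            design.columns(), names=["condition", "replicate"]
        )
        frame.index.name = "locus"
        return ExpressionMatrix(omic=omic, data=frame.astype(float))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
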