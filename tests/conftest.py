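import numpy as np
import pytest

from chemrisk import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    DiscreteVariable,
    build_illustrative_model,
)


@pytest.fixture(scope="session")
def xy_net():
    """Two-node chain X -> Y with P(X=a)=0.6, P(Y=u|a)=0.9, P(Y=u|b)=0.2.

    Hand-checkable: P(X=a, Y=u) = 0.54, P(Y=u) = 0.62,
    P(X=a | Y=u) = 0.54/0.62 = 0.870967...
    """
    variables = {
        "X": DiscreteVariable("X", "X", ("a", "b")),
        "Y": DiscreteVariable("Y", "Y", ("u", "v")),
    }
    cpts = {
        "X": ConditionalProbabilityTable("X", (), np.array([0.6, 0.4])),
        "Y": ConditionalProbabilityTable(
            "Y", ("X",), np.array([[0.9, 0.1], [0.2, 0.8]])
        ),
    }
    return BayesianNetwork(variables, {("X", "Y")}, cpts)


@pytest.fixture(scope="session")
def illustrative_model():
    return build_illustrative_model()
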