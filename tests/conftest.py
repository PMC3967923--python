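import numpy as np
import pytest

from mexmod import AlterationMatrix, MEParameters


@pytest.fixture
def toy_matrix() -> AlterationMatrix:
    """Rows {100, 010, 110, 000}: coverage 3/4, one impure alteration."""
    return AlterationMatrix.from_values(
        [[1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 0]]
    )


def random_parameters(
    rng: np.random.Generator, with_errors: bool = True
) -> MEParameters:
    """Random valid parameter draw over the full valid ranges."""
    if with_errors:
        return MEParameters(
            coverage=rng.uniform(0.0, 1.0),
            impurity=rng.uniform(0.0, 1.0),
            fp_rate=rng.uniform(0.0, 0.5 - 1e-9),
            fn_rate=rng.uniform(0.0, 0.5 - 1e-9),
            variant="full",
        )
    return MEParameters(
        coverage=rng.uniform(0.0, 1.0), impurity=rng.uniform(0.0, 1.0)
    )
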