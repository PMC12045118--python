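import numpy as np
import pytest

from otss.indecision_model import ModelParams, Order, ResponseCounts, StimulusCell


def make_counts(rows):
    """rows: iterable of (x, order, n_higher, n_lower, n_dk)."""
    return [
        ResponseCounts(
            cell=StimulusCell(x=x, order=Order(order) if isinstance(order, str) else order),
            n_ref_higher=nh,
            n_ref_lower=nl,
            n_dk=nd,
        )
        for x, order, nh, nl, nd in rows
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def example_params():
    return ModelParams(mu=-8.0, sigma=5.0, delta1=-2.0, delta2=3.0)
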