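import math

import pytest

from heni.composition import resolve_components
from heni.characterization import dietary_impact
from heni.fixtures import yogurt_fixture


@pytest.fixture(scope="session")
def yogurt():
    """(recipe, drf_table) for the packaged strawberry-yogurt example."""
    return yogurt_fixture()


@pytest.fixture(scope="session")
def yogurt_result(yogurt):
    recipe, drf = yogurt
    return dietary_impact(resolve_components(recipe), drf)


@pytest.fixture
def loglinear_curve():
    """Two-knot log-linear RR curve rising from RR=1 at the TMREL edge.

    RR(x) = exp(beta * (x - t)) for x > t, clamped to 1 on [0, t].
    Closed forms for PAF and its derivative are available, making this the
    standard oracle curve across the epi tests.
    """
    from heni.epi import RRCurve, TMRELRange

    t, beta = 2.0, 0.5
    curve = RRCurve(
        component_id="sodium",
        knots=((t, 1.0), (t + 1.0 / beta, math.e)),
        tmrel=TMRELRange(low=0.0, high=t),
    )
    return curve, t, beta
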