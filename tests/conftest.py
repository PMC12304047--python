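import numpy as np
import pytest

import growthssd as g


def _example1(m=1000, seed=1, **kw):
    """Replication design: yearly assessments over four years, linear decline.

    Variance components and effect size taken from a published youth-survey
    growth analysis: var_e=0.0262, var_u0=0.0333, var_u1=0.0030, delta=0.40.
    """
    base = dict(
        time_grid=g.TimeGrid(np.array([0.0, 1.0, 2.0, 3.0, 4.0])),
        vc=g.VarianceComponents(var_e=0.0262, var_u0=0.0333, var_u1=0.0030),
        effect=g.EffectSpec(delta=0.40),
        bf_threshold=3.0,
        eta_target=0.80,
        m_datasets=m,
        seed=seed,
    )
    base.update(kw)
    return g.TrialDesign(**base)


def _growth_ref(m=1000, seed=1, duration=4.0, frequency=1.0, **kw):
    """Reference simulation design (equidistant grid built from D and f).

    var_u1=0.001 with delta=0.8 gives the interaction coefficient 0.0253.
    """
    base = dict(
        time_grid=g.TimeGrid.from_duration(duration, frequency),
        vc=g.VarianceComponents(var_e=0.02, var_u0=0.0333, var_u1=0.001),
        effect=g.EffectSpec(delta=0.8),
        bf_threshold=3.0,
        eta_target=0.80,
        m_datasets=m,
        seed=seed,
    )
    base.update(kw)
    return g.TrialDesign(**base)


@pytest.fixture
def make_example1():
    return _example1


@pytest.fixture
def make_growth_ref():
    return _growth_ref
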