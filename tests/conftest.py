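"""Shared fixtures.

The headline neutral-theory curve (J = 21,060, m = 0.075, theta = 52.1) takes
a few seconds to compute, so it is built once per session and shared by the
zero-sum, octave and fitting tests.
"""

import numpy as np
import pytest

from sadinv import neutral_theory as nt

#: headline local-community parameters (J, m, theta)
HEADLINE = dict(J=21_060, m=0.075, theta=52.1)

#: gamma-lognormal parameters the headline fit should recover
HEADLINE_GLN = dict(lam=0.00205, a=0.491, alpha=0.0559)


@pytest.fixture(scope="session")
def sad_headline() -> nt.ExpectedSAD:
    """Expected neutral SAD at the headline parameters."""
    return nt.expected_sad(nt.NeutralParams(**HEADLINE))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
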