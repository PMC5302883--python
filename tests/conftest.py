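import numpy as np
import pytest

import pigmentnoise as pn


@pytest.fixture(scope="session")
def spr_template() -> pn.SinglePhotonResponse:
    """Default single-photon response template (1 pA peak, T_i ~ 0.82 s)."""
    return pn.make_spr_template()


@pytest.fixture(scope="session")
def dark_trace_with_truth():
    """One 600-s dark recording at 0.01 s^-1 with its ground-truth events."""
    cfg = pn.TraceSimConfig(duration=600.0, event_rate=0.01, seed=42)
    return pn.simulate_dark_trace(cfg)


@pytest.fixture(scope="session")
def lws_template_pair():
    """Polynomial template pair for an LWS-like pigment (11-cis at 560 nm,
    9-cis blue-shifted to 525 nm), fitted over 510-750 nm."""
    grid = np.arange(300.0, 751.0, 2.0)
    t11 = pn.pigment_template_spectrum(560.0, grid)
    t9 = pn.pigment_template_spectrum(525.0, grid)
    p11, _ = pn.fit_template(t11, degree=10, fit_range=(510.0, 750.0))
    p9, _ = pn.fit_template(t9, degree=10, fit_range=(510.0, 750.0))
    return pn.TemplatePair(p11, p9, (510.0, 750.0)), t11, t9, grid
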