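import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pcmkin

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref() -> pcmkin.ReferenceParameters:
    return pcmkin.reference_parameters()


@pytest.fixture(scope="session")
def exact_decay_run():
    """Noise-free exponential oxidant decay with a known constant."""

    def _make(k: float = 1.91e-4, cat0: float = 2.0e-3, pcm0: float = 4.0e-2,
              n: int = 10, t_end: float | None = None) -> pcmkin.TitrationTimeSeries:
        t = np.linspace(0.0, t_end if t_end is not None else 0.63 / k, n)
        conditions = pcmkin.ReactionConditions(
            cat0=cat0, pcm0=pcm0, os_total=5.0e-5, oh=0.05, temperature=308.15
        )
        return pcmkin.TitrationTimeSeries(
            run_id="exact", replicate_id=1, times=t, values=cat0 * np.exp(-k * t),
            value_unit="mol_per_dm3", conditions=conditions,
        )

    return _make
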