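import numpy as np
import pytest

from meltkin import Condition, KineticTrace


@pytest.fixture
def condition():
    return Condition(variant="WT", detergent_mM=5.0, protein_uM=5.0,
                     temperature_C=80.0)


def make_decay(
    rates_amps,
    y_inf=0.0,
    duration_min=5.0,
    dt_s=1.0,
    noise=0.0,
    seed=0,
    condition=None,
    t_start_s=0.0,
):
    """Synthetic multi-exponential decay trace: sum of a*exp(-k t) + y_inf.

    ``rates_amps`` is a list of (rate_per_min, amplitude) pairs. Used as the
    independent generator for fit tests — built directly from the model
    expression, not through the fitting code paths.
    """
    if condition is None:
        condition = Condition("WT", 5.0, 5.0, 80.0)
    t_s = np.arange(t_start_s, duration_min * 60.0 + 0.5 * dt_s, dt_s)
    t = t_s / 60.0
    y = np.full(t.shape, float(y_inf))
    for k, a in rates_amps:
        y = y + a * np.exp(-k * t)
    if noise:
        y = y + np.random.default_rng(seed).normal(0.0, noise, t.size)
    return KineticTrace(
        time_s=t_s, signal=y, signal_kind="fraction_unfolded",
        condition=condition,
    )
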