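import numpy as np
import pytest

import megrsn as m

RATE = 312.5


@pytest.fixture(scope="session")
def lower_alpha():
    return m.get_band("lower_alpha")


@pytest.fixture(scope="session")
def small_setup():
    """Reduced cohort conditions for replicate-heavy checks: 12 ROIs in two
    disjoint 4-member networks, two 2048-sample epochs at 312.5 Hz."""
    labels = tuple(f"R{i}_{h}" for i in range(1, 7) for h in ("L", "R"))
    registry = m.RoiRegistry(labels)
    networks = [
        m.RsnDefinition("NetA", labels[:4]),
        m.RsnDefinition("NetB", labels[4:8]),
    ]
    recording = m.CohortRecordingConfig(n_epochs=2, epoch_length=2048)
    return registry, networks, recording


@pytest.fixture(scope="session")
def rsn4_setup():
    """Four named resting-state networks with reduced 4-ROI memberships at
    the full five-epoch recording scale."""
    labels = tuple(
        f"N{k}_{j}_{h}" for k in range(4) for j in (1, 2) for h in ("L", "R")
    )
    registry = m.RoiRegistry(labels)
    names = ["DMN", "FPN_left", "FPN_right", "ECN"]
    networks = [
        m.RsnDefinition(name, labels[4 * k : 4 * k + 4])
        for k, name in enumerate(names)
    ]
    recording = m.CohortRecordingConfig()  # 5 x 4096 at 312.5 Hz
    return registry, networks, recording


@pytest.fixture(scope="session")
def narrowband_pair(lower_alpha):
    """Two independent band-limited noise channels plus white noise."""
    from megrsn.synthetic import _narrowband_noise_multi

    rng = np.random.default_rng(7)
    sig = _narrowband_noise_multi(rng, 2, 4096, RATE, lower_alpha)
    return sig + rng.standard_normal(sig.shape)
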