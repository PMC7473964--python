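import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from navpkpd.core import DoseEvent, DoseRegimen, PKParams


@pytest.fixture
def default_pk() -> PKParams:
    from navpkpd.synthetic import DEFAULT_PK

    return DEFAULT_PK


@pytest.fixture
def bolus_regimen() -> DoseRegimen:
    return DoseRegimen([DoseEvent(0.0, "iv_bolus", 1.0)])


def random_regimen(rng: np.random.Generator) -> DoseRegimen:
    """A random 1-3 event regimen mixing routes, for oracle sweeps."""
    events = []
    n = int(rng.integers(1, 4))
    for _ in range(n):
        t0 = float(rng.uniform(0, 2))
        amount = float(rng.uniform(0.2, 5))
        kind = rng.integers(0, 3)
        if kind == 0:
            events.append(DoseEvent(t0, "iv_bolus", amount))
        elif kind == 1:
            events.append(
                DoseEvent(t0, "iv_infusion", amount, duration=float(rng.uniform(0.25, 2)))
            )
        else:
            events.append(
                DoseEvent(t0, "extravascular", amount,
                          ka=float(rng.uniform(0.3, 3)), F=float(rng.uniform(0.5, 1)))
            )
    return DoseRegimen(events)
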