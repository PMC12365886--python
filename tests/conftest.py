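import numpy as np
import pytest

from nanoscreen.viability import ViabilityGroup, ViabilityPlate


@pytest.fixture
def three_group_plate() -> ViabilityPlate:
    """The hand-checkable 3x3 layout: SSB = SSW = 6, F = 3, eta_p = 0.5."""
    return ViabilityPlate(
        (
            ViabilityGroup("control", None, [1.0, 2.0, 3.0]),
            ViabilityGroup("low", 10.0, [2.0, 3.0, 4.0]),
            ViabilityGroup("high", 100.0, [3.0, 4.0, 5.0]),
        ),
        control_label="control",
    )


def make_plate(groups, control="control"):
    """Build a plate from {label: (conc, values)} preserving order."""
    return ViabilityPlate(
        tuple(
            ViabilityGroup(label, conc, np.asarray(vals, float))
            for label, (conc, vals) in groups.items()
        ),
        control_label=control,
    )
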