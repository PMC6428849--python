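import numpy as np
import pytest

from seromir.preprocess import ArrayScan
from seromir.synthetic import CohortSpec, PlantedMarker


def make_scan(sample_id="S1", targets=None, controls=None, nc=None, flags=0):
    """Build a small ArrayScan from linear signal lists."""
    targets = targets if targets is not None else {}
    controls = controls if controls is not None else {}
    nc = list(nc) if nc is not None else []
    probe_ids = list(targets) + list(controls) + [f"NC-{i}" for i in range(len(nc))]
    classes = (
        ["target"] * len(targets)
        + ["internal_control"] * len(controls)
        + ["negative_control"] * len(nc)
    )
    signals = list(targets.values()) + list(controls.values()) + nc
    flagged = np.zeros(len(signals), dtype=bool)
    flagged[: int(flags)] = True
    return ArrayScan(
        sample_id=sample_id,
        probe_ids=probe_ids,
        probe_classes=np.array(classes, dtype=object),
        signals=np.array(signals, dtype=float),
        flagged=flagged,
    )


@pytest.fixture
def small_planted_spec():
    """Compact three-group study with three strong step-wise markers."""
    return CohortSpec(
        n_healthy=24,
        n_benign=24,
        n_malignant=24,
        n_mirna=40,
        n_negative_controls=20,
        planted_markers=(
            PlantedMarker("miR-A", 1.0, 3.0),
            PlantedMarker("miR-B", 1.0, 3.0),
            PlantedMarker("miR-C", 1.0, 3.0),
        ),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
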