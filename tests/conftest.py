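import numpy as np
import pytest

import vhmea
from vhmea.detect import detect_segment
from vhmea.preprocess import preprocess_segment


@pytest.fixture(scope="session")
def geometry():
    return vhmea.ArrayGeometry.default()


@pytest.fixture(scope="session")
def control_preset():
    return vhmea.build_preset("control", "basal")


@pytest.fixture(scope="session")
def full_slice(geometry, control_preset):
    """One full-scale (50 s, 64 electrodes) control-basal slice, rendered,
    preprocessed and detected once for the whole session."""
    segment, truth = vhmea.render_recording(
        geometry, control_preset, vhmea.NoiseModel(), seed=123, slice_id="fixture"
    )
    filtered = preprocess_segment(segment)
    table, waveforms, active, thresholds = detect_segment(filtered)
    return {
        "segment": segment,
        "truth": truth,
        "filtered": filtered,
        "table": table,
        "waveforms": waveforms,
        "active": active,
        "thresholds": thresholds,
    }


@pytest.fixture()
def small_preset():
    """Scaled-down condition for fast end-to-end tests (5-s segments)."""
    return vhmea.ConditionPreset(
        genotype="control", drug="basal", n_active_electrodes=3,
        units_per_active_electrode=3, aggregate_rate_hz=6.0, inactive_rate_hz=0.0,
    )


@pytest.fixture()
def small_criterion():
    # same 1 Hz activity criterion, expressed over a 5-s window
    return vhmea.ActivityCriterion(min_spikes=5, window_s=5.0)
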