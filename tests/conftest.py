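import numpy as np
import pytest

import fatemap as fm


@pytest.fixture(scope="session")
def area_model():
    return fm.default_area_model()


@pytest.fixture(scope="session")
def reference_design():
    return fm.default_cohort_design()


@pytest.fixture(scope="session")
def small_volume():
    """Small test volume so rendering stays fast."""
    return fm.ImagingVolume(120, 120, 50, 1.0)


@pytest.fixture(scope="session")
def rendered_scene(small_volume):
    """A noise-free rendered stack of 8 neurons + 8 glia with ground truth."""
    scene = fm.sample_cell_scene(8, 8, small_volume, seed=42)
    stack = fm.render_stack(scene, small_volume, blur_sigma=0.0,
                            noise_scale=0.0, seed=42)
    return scene, stack


def match_truth(record, truth):
    """Ground-truth cell nearest to a segmented record's centroid."""
    return min(
        truth,
        key=lambda t: sum((a - b) ** 2 for a, b in zip(t.centroid,
                                                       record.centroid)),
    )


@pytest.fixture(scope="session")
def reference_neuron_counts():
    """Per-timepoint neuron count parameters (mean, sd) of the design."""
    return {"E7.5": (23, 1), "E8.5": (38, 7), "E9.5": (63, 4),
            "E10.5": (26, 3), "E11.5": (9, 3)}
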