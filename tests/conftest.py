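import dataclasses

import numpy as np
import pytest

from conformalseg import MondrianConformalSegmenter, PhantomSpec, generate_cohort

# Reduced-scale phantom for unit tests: ~24 mm field of view, ~1-3 mL organs.
SMALL_SPEC = PhantomSpec(
    grid_shape=(48, 48, 12),
    spacing=(0.5, 0.5, 3.0),
    semi_axis_x=(6.0, 9.0),
    semi_axis_y=(6.0, 9.0),
    semi_axis_z=(6.0, 9.0),
    deformation=0.06,
    sharpness=2.0,
    bias_mm=0.75,
    noise_amplitude=0.12,
    noise_correlation_mm=3.0,
    reader_noise_sd=0.05,
)

# Same geometry without bias, deformation, or reader noise.
SMALL_CLEAN_SPEC = dataclasses.replace(
    SMALL_SPEC, deformation=0.0, bias_mm=0.0, noise_amplitude=0.05, reader_noise_sd=0.0
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_SPEC, 24, master_seed=11)


@pytest.fixture(scope="session")
def fitted_segmenter(small_cohort):
    cal = small_cohort[:8]
    return MondrianConformalSegmenter(alpha=0.15, per_class_cap=2000, random_state=3).fit(
        [e.prob for e in cal], [e.mask for e in cal]
    )


@pytest.fixture(scope="session")
def eval_exams(small_cohort):
    return small_cohort[8:]
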