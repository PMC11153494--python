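import numpy as np
import pytest

import taumap as tm


@pytest.fixture(scope="session")
def small_template():
    """Minimal-size template: 48-vertex skeleton, 0.5 mm grid."""
    return tm.make_template((32, 24, 24), (0.5, 0.5, 0.5), seed=0,
                            skeleton_shape=(8, 6))


@pytest.fixture(scope="session")
def medium_template():
    """Mid-size template used for cohort-level statistics tests."""
    return tm.make_template((48, 36, 28), (0.4, 0.4, 0.4), seed=0,
                            skeleton_shape=(24, 14))


@pytest.fixture(scope="session")
def full_template():
    """Full-size default template for the recovery experiments."""
    return tm.make_template(seed=1)


@pytest.fixture(scope="session")
def recovery_cohort(full_template):
    """Default-truth cohort of 40 specimens with realized volumes."""
    return tm.simulate_cohort(full_template, 40, truth=tm.default_truth(), seed=1)


@pytest.fixture(scope="session")
def recovery_fields(recovery_cohort):
    """Thickness fields measured from the specimen segmentations."""
    return tm.measure_thickness_fields(recovery_cohort)


@pytest.fixture(scope="session")
def recovery_table(recovery_cohort, recovery_fields):
    rois = tm.analysis_roi_set("combined_14")
    return tm.roi_summary_table(recovery_cohort, rois, fields=recovery_fields)
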