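import dataclasses

import numpy as np
import pytest

from richfuse.emr_schema import StructuredRecord, load_schema
from richfuse.synthetic import CohortParams, TEST_PRESET, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_valid_record(rng: np.random.Generator, schema, patient_id="p0", label="benign"):
    values = tuple(int(rng.integers(0, f.max_code + 1)) for f in schema)
    return StructuredRecord(patient_id=patient_id, values=values, label=label)


@pytest.fixture(scope="session")
def record_matrix(schema):
    """200 encoded synthetic records (balanced classes) for raiser fitting."""
    from richfuse.emr_schema import encode_record
    from richfuse.synthetic import generate_record

    gen = np.random.default_rng(7)
    rows = []
    for i in range(200):
        label = "malignant" if i % 2 else "benign"
        rows.append(encode_record(generate_record(label, TEST_PRESET, gen, f"p{i}"))[0])
    return np.stack(rows)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A very small paired cohort for plumbing tests (fast to generate)."""
    params = dataclasses.replace(
        TEST_PRESET, n_patients=16, images_per_patient=(2, 2), image_side=32,
        image_signal=3.0, record_signal=3.0,
    )
    return generate_cohort(params, seed=5)


@pytest.fixture(scope="session")
def tiny_backbone_spec():
    from richfuse.image_backbone import BackboneSpec

    return BackboneSpec(stage_channels=(4, 8, 8, 16, 16),
                        convs_per_stage=(1, 1, 1, 1, 1), input_side=32)
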