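import numpy as np
import pytest

import osteotex as ot


def make_region(pixels, bit_depth=8, **kw):
    defaults = dict(
        patient_id="P0",
        region_kind="bone",
        modality="T1",
        source_format="PNG",
        age_years=12,
    )
    defaults.update(kw)
    return ot.Region(pixels=np.asarray(pixels), bit_depth=bit_depth, **defaults)


def make_normalized(pixels, bit_depth=12):
    """Wrap raw integers as a NormalizedRegion without renormalizing, for
    feature tests that need full control over the pixel values."""
    px = np.asarray(pixels, dtype=np.int64)
    return ot.NormalizedRegion(
        pixels=px,
        bit_depth=bit_depth,
        gray_max=2**bit_depth - 1,
        mu=float(px.mean()),
        sigma=float(px.std()),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-effect cohort shared by pipeline-level tests."""
    spec = ot.CohortSpec(n_patients=10, total_images=18, effect_strength=1.0, seed=11)
    return ot.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_bone_table(small_cohort):
    return ot.cohort_to_feature_table(small_cohort, "bone", "T1", 12)
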