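"""Shared phantoms and tracking fixtures.

Heavy fixtures are session-scoped; everything is generated from fixed seeds
so the suite is fully deterministic.
"""

import numpy as np
import pytest

import tractquant as tq


def in_bundle_mask(field: tq.OrientationField, params: tq.TrackingParams):
    """Voxels offering at least one orientation at/above the QA threshold."""
    return field.qa.max(axis=-1) >= params.qa_threshold


@pytest.fixture(scope="session")
def params():
    return tq.TrackingParams()


@pytest.fixture(scope="session")
def straight_spec():
    return tq.BundleSpec(
        name="vertical",
        centerline=((10.0, 10.0, 6.0), (10.0, 10.0, 54.0)),
        radius_mm=3.0,
        qa_inside=0.6,
        qa_outside=0.0,
        endpoint_region_a="TOP",
        endpoint_region_b="BOTTOM",
    )


@pytest.fixture(scope="session")
def straight_phantom(straight_spec):
    return tq.make_straight_bundle((20, 20, 60), 1.0, straight_spec)


@pytest.fixture(scope="session")
def straight_tracts(straight_phantom, params):
    field, _ = straight_phantom
    return tq.whole_brain_track(
        field, in_bundle_mask(field, params), 1000, params, rng_seed=42
    )


@pytest.fixture(scope="session")
def crossing_specs():
    spec_a = tq.BundleSpec(
        name="A",
        centerline=((20.0, 20.0, 8.0), (20.0, 20.0, 32.0)),
        radius_mm=3.0,
        qa_inside=0.6,
        qa_outside=0.0,
        endpoint_region_a="A_TOP",
        endpoint_region_b="A_BOTTOM",
    )
    spec_b = tq.BundleSpec(
        name="B",
        centerline=((8.0, 20.0, 20.0), (32.0, 20.0, 20.0)),
        radius_mm=3.0,
        qa_inside=0.6,
        qa_outside=0.0,
        endpoint_region_a="B_LEFT",
        endpoint_region_b="B_RIGHT",
    )
    return spec_a, spec_b


@pytest.fixture(scope="session")
def crossing_phantom(crossing_specs):
    spec_a, spec_b = crossing_specs
    return tq.make_crossing_phantom((40, 40, 40), 1.0, spec_a, spec_b, 90.0)


@pytest.fixture(scope="session")
def crossing_tracts_from_a(crossing_phantom, params):
    field, _ = crossing_phantom
    # seed only inside bundle A (slot 0 carries A's QA)
    mask_a = field.qa[..., 0] >= params.qa_threshold
    return tq.whole_brain_track(field, mask_a, 600, params, rng_seed=11)


@pytest.fixture(scope="session")
def mirrored_template():
    return tq.MirroredTemplate(
        grid_shape=(44, 24, 44),
        voxel_size_mm=1.0,
        bundle=tq.BundleSpec(
            name="paired",
            centerline=((11.0, 11.5, 7.0), (11.0, 11.5, 37.0)),
            radius_mm=3.0,
            qa_inside=0.6,
            qa_outside=0.0,
            endpoint_region_a="IPS",
            endpoint_region_b="FG",
        ),
    )
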