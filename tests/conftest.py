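import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toddler_params():
    """Pooled 2-year cohort size parameters (mean ~21.4 μm)."""
    from myosize.synthetic import make_cohort_params

    return make_cohort_params("2 years", "pooled")


@pytest.fixture(scope="session")
def section(toddler_params):
    """One 300-fiber synthetic section shared by the image-based tests."""
    from myosize.synthetic import SectionGeometryConfig, generate_section

    geo = SectionGeometryConfig(n_fibers=300, seed=11)
    image, mask, truth = generate_section(toddler_params, geo)
    return {"image": image, "mask": mask, "truth": truth, "geo": geo}


@pytest.fixture(scope="session")
def segmented(section):
    """Tissue mask and predicted fiber labels for the shared section."""
    from myosize.segmentation import detect_tissue, segment_fibers

    tissue = detect_tissue(section["image"])
    pred = segment_fibers(section["image"], tissue)
    return {"tissue": tissue, "pred": pred}


@pytest.fixture(scope="session")
def measured_truth(section):
    """Morphometry of the ground-truth label mask."""
    from myosize.morphometry import measure_mask

    return measure_mask(section["mask"])


@pytest.fixture(scope="session")
def measured_pred(segmented):
    """Morphometry of the segmented (predicted) label mask."""
    from myosize.morphometry import measure_mask

    return measure_mask(segmented["pred"])


def random_convex_polygon(rng: np.random.Generator, n: int = 12, scale: float = 10.0):
    """Convex hull of random points (helper for geometry tests)."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n, 2)) * scale
    hull = ConvexHull(pts)
    return pts[hull.vertices]
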