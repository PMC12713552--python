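"""Synthetic muscle-biopsy data with known ground truth.

Real normative biopsy data are not publicly available, so this module
generates the two kinds of input the pipeline consumes:

* **Measurement-level samples** — per-fiber minFeret/area tables drawn
  from a lognormal moment-matched to a cohort's published mean and SD.
  The lognormal is the natural right-skewed, positive-support family and
  reproduces the mean > median pattern of the published cohort tables.
* **Section images** — schematic pseudo-H&E renderings of a transverse
  section: a Lloyd-relaxed Voronoi tessellation of polygonal fibers
  separated by pale interstitium, with dark boundary nuclei and a few
  small non-fiber objects (capillary-like artifacts) whose sizes straddle
  the area filter, plus an exact label mask and per-object ground truth.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .morphometry import min_feret
from .reference import cohort_stats_row, load_cohort_stats
from .samples import BiopsySample, normalize_sex
from .segmentation import LabelMask

#: ratio of realized mean cell minFeret to the hexagonal-lattice
#: prediction sqrt(2A/sqrt(3)) for Lloyd-relaxed Voronoi cells; measured
#: once on an independent calibration tessellation
LLOYD_SHAPE_FACTOR = 0.94

DEFAULT_PIXEL_SIZE = 0.25  # μm/px, standing in for 40x scans


# ---------------------------------------------------------------------------
# size-distribution parameters


@dataclass(frozen=True)
class SizeDistributionParams:
    """Lognormal fiber-size parameters moment-matched to a target mean/SD.

    ``sigma^2 = ln(1 + sd^2/mean^2)`` and ``mu = ln(mean) - sigma^2/2`` so
    that the lognormal's first two moments equal the targets exactly. The
    zero-variance limit (sd = 0) degenerates to all fibers at the mean.
    """

    target_mean_minferet: float
    target_sd_minferet: float
    lognormal_mu: float
    lognormal_sigma: float

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "SizeDistributionParams":
        if mean <= 0:
            raise ValueError("target mean must be positive")
        if sd < 0:
            raise ValueError("target sd must be nonnegative")
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return cls(mean, sd, mu, math.sqrt(sigma2))


def make_cohort_params(cohort_id: str, sex: str) -> SizeDistributionParams:
    """Moment-matched lognormal parameters for a cohort/sex cell.

    ``sex`` may be ``"male"``, ``"female"``, or ``"pooled"``; pooling
    combines the two sexes' published moments as a fiber-count-weighted
    mixture before moment matching.
    """
    if str(sex).strip().lower() == "pooled":
        from .norms import canonical_cohort_id

        cid = canonical_cohort_id(cohort_id)
        df = load_cohort_stats()
        sub = df[df["cohort"] == cid]
        if sub.empty:
            raise KeyError(f"unknown cohort {cohort_id!r}")
        w = sub["n_fibers"].to_numpy(dtype=float)
        w = w / w.sum()
        m = sub["mean_um"].to_numpy(dtype=float)
        s = sub["sd_um"].to_numpy(dtype=float)
        mean = float(np.sum(w * m))
        var = float(np.sum(w * (s**2 + m**2)) - mean**2)
        return SizeDistributionParams.from_moments(mean, math.sqrt(max(var, 0.0)))
    row = cohort_stats_row(cohort_id, sex)
    return SizeDistributionParams.from_moments(float(row["mean_um"]), float(row["sd_um"]))


# ---------------------------------------------------------------------------
# measurement-level synthesis


def generate_measurements(
    params: SizeDistributionParams, n_fibers: int, seed: int, sample_id: str = "synthetic",
    age_months: float = 0.0, sex: str = "female",
) -> BiopsySample:
    """Draw an i.i.d. lognormal biopsy of ``n_fibers`` measurements.

    minFeret values are lognormal(mu, sigma); areas derive from the
    diameter as pi*(d/2)^2 times a shape factor drawn uniformly in
    [1.0, 1.4] (the published data measure both but specify no joint
    model). Bit-reproducible for a fixed seed.
    """
    n_fibers = int(n_fibers)
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    rng = np.random.default_rng(seed)
    if params.lognormal_sigma == 0:
        d = np.full(n_fibers, math.exp(params.lognormal_mu))
    else:
        d = rng.lognormal(params.lognormal_mu, params.lognormal_sigma, n_fibers)
    shape_factor = rng.uniform(1.0, 1.4, n_fibers)
    area = math.pi * (d / 2.0) ** 2 * shape_factor
    fibers = pd.DataFrame(
        {"label_id": np.arange(1, n_fibers + 1), "area_um2": area, "minferet_um": d}
    )
    return BiopsySample(sample_id=sample_id, age_months=age_months, sex=sex, fibers=fibers)


def generate_cohort_samples(
    params: SizeDistributionParams,
    n_biopsies: int,
    n_fibers: int,
    seed: int,
    age_months: float = 0.0,
    sex: str = "female",
    between_biopsy_cv: float = 0.15,
) -> list[BiopsySample]:
    """A cohort of biopsies with realistic between-biopsy variability.

    Each biopsy's size scale is multiplied by a lognormal jitter with the
    given coefficient of variation (default 0.15, in the range of the
    published between-biopsy percentile SD/mean ratios), emulating that
    different normal children of the same age have different fiber sizes.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(int(n_biopsies)):
        if between_biopsy_cv > 0:
            s2 = math.log1p(between_biopsy_cv**2)
            scale = rng.lognormal(-s2 / 2.0, math.sqrt(s2))
        else:
            scale = 1.0
        p = SizeDistributionParams.from_moments(
            params.target_mean_minferet * scale, params.target_sd_minferet * scale
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            generate_measurements(
                p, n_fibers, sub_seed, sample_id=f"synthetic-{i:03d}",
                age_months=age_months, sex=sex,
            )
        )
    return out


def apply_disease_transform(
    sample: BiopsySample, mode: str, factor: float, floor_um: float = 0.5
) -> BiopsySample:
    """Impose a disease-like size abnormality on a biopsy.

    ``uniform_hypotrophy`` multiplies every minFeret by ``factor`` (< 1
    expected): all fibers small but normally dispersed, the myotubular-
    myopathy-like pattern. ``variance_inflation`` rescales deviations
    about the median by ``factor`` (> 1 expected) with the median
    preserved: normal central size but excessive variation, the
    dystrophy-like pattern. Areas rescale with the squared diameter
    ratio. Inflated values are floored at ``floor_um`` to keep diameters
    positive.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    d = sample.minferet
    if mode == "uniform_hypotrophy":
        new = d * factor
    elif mode == "variance_inflation":
        med = float(np.median(d))
        new = np.maximum(med + factor * (d - med), floor_um)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fibers = sample.fibers.copy()
    ratio = np.divide(new, d, out=np.ones_like(new), where=d > 0)
    fibers["minferet_um"] = new
    fibers["area_um2"] = fibers["area_um2"].to_numpy() * ratio**2
    return sample.with_fibers(fibers)


# ---------------------------------------------------------------------------
# section-image synthesis


@dataclass
class SectionGeometryConfig:
    """Geometry of a synthetic section rendering.

    ``image_size`` (pixels, square) may be None, in which case the
    smallest image holding ``n_fibers`` at the target fiber size is
    derived. Artifact sizes may deliberately fall outside the fiber-size
    filters — that is their purpose.
    """

    n_fibers: int = 500
    image_size: int | None = None
    pixel_size: float = DEFAULT_PIXEL_SIZE
    interstitium_width: float = 2.0  # μm
    artifact_count: int = 6
    artifact_size_range: tuple[float, float] = (20.0, 200.0)  # μm²
    lloyd_iterations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_fibers < 50:
            raise ValueError("need at least 50 fibers for a representative section")
        if self.interstitium_width < 0 or self.artifact_count < 0:
            raise ValueError("invalid section geometry")


@dataclass
class GroundTruth:
    """Generator ground truth: per-object geometry and the true label mask.

    ``records`` has one row per rendered object (label_id, is_fiber,
    area_um2, minferet_um, x_um, y_um); ``polygons`` maps fiber label ids
    to their true outline vertices (μm); ``mask`` is the rasterized true
    label mask. Fiber and artifact id sets are disjoint.
    """

    records: pd.DataFrame
    polygons: dict[int, np.ndarray]
    mask: LabelMask

    @property
    def fiber_ids(self) -> list[int]:
        return [int(i) for i in self.records.loc[self.records["is_fiber"], "label_id"]]

    @property
    def artifact_ids(self) -> list[int]:
        return [int(i) for i in self.records.loc[~self.records["is_fiber"], "label_id"]]


def _lloyd_voronoi(points: np.ndarray, lo: float, hi: float, iterations: int) -> list[Polygon]:
    """Voronoi cells of points in [lo, hi]^2 after Lloyd relaxation.

    Boundedness comes from mirroring the points across the four box edges
    before triangulating, which clips every interior cell to the box.
    """
    bounds = box(lo, lo, hi, hi)

    def cells(pts: np.ndarray) -> list[Polygon]:
        mirrored = [pts]
        for axis, edge in ((0, lo), (0, hi), (1, lo), (1, hi)):
            m = pts.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
        vor = Voronoi(np.vstack(mirrored))
        out = []
        for i in range(len(pts)):
            region = vor.regions[vor.point_region[i]]
            poly = Polygon(vor.vertices[region])
            if not poly.is_valid:
                poly = poly.buffer(0)
            out.append(poly.intersection(bounds))
        return out

    for _ in range(iterations):
        cs = cells(points)
        points = np.array([[c.centroid.x, c.centroid.y] for c in cs])
    return cells(points)


def generate_section(
    params: SizeDistributionParams, geo: SectionGeometryConfig
) -> tuple[np.ndarray, LabelMask, GroundTruth]:
    """Render a synthetic pseudo-H&E section with exact ground truth.

    Fibers are Lloyd-relaxed Voronoi cells shrunk by half the
    interstitium width on each side, rendered eosin-pink on a pale
    background with dark boundary nuclei; the ground-truth mean minFeret
    is calibrated to the target mean (within 10%, enforced). Capillary-
    like artifacts are placed in the background margin. Returns the RGB
    image (uint8), the true label mask, and the ground truth.
    """
    rng = np.random.default_rng(geo.seed)
    ps = geo.pixel_size
    n = geo.n_fibers

    w_raw = params.target_mean_minferet + geo.interstitium_width
    cell_area = (math.sqrt(3) / 2.0) * (w_raw / LLOYD_SHAPE_FACTOR) ** 2
    tess_side = math.sqrt(n * cell_area)  # μm

    r_art_max = math.sqrt(max(geo.artifact_size_range) / math.pi)
    margin = max(0.02 * tess_side, 2.0 * r_art_max + 1.0) if geo.artifact_count else 0.02 * tess_side

    if geo.image_size is None:
        side_px = int(math.ceil((tess_side + 2 * margin) / ps))
    else:
        side_px = int(geo.image_size)
        avail = side_px * ps - 2 * margin
        if avail <= 0 or avail**2 < n * cell_area:
            need = int(math.ceil((tess_side + 2 * margin) / ps))
            raise ValueError(
                f"image of {side_px} px at {ps} μm/px cannot hold {n} fibers of "
                f"target minFeret {params.target_mean_minferet:.2f} μm; "
                f"needs >= {need} px"
            )
        tess_side = avail

    lo = margin
    hi = margin + tess_side

    pts = rng.uniform(lo, hi, size=(n, 2))
    cells = _lloyd_voronoi(pts, lo, hi, geo.lloyd_iterations)

    mask = np.zeros((side_px, side_px), dtype=np.int32)
    records = []
    polygons: dict[int, np.ndarray] = {}
    for i, cell in enumerate(cells, start=1):
        shrunk = cell.buffer(-geo.interstitium_width / 2.0, join_style=2)
        if shrunk.is_empty:
            raise ValueError(
                f"interstitium width {geo.interstitium_width} μm erases fibers at "
                f"target size {params.target_mean_minferet:.2f} μm"
            )
        if shrunk.geom_type != "Polygon":  # extremely rare sliver split
            shrunk = max(shrunk.geoms, key=lambda g: g.area)
        coords = np.asarray(shrunk.exterior.coords)[:-1]
        polygons[i] = coords
        # rasterize against a quarter-pixel-eroded outline so the union of
        # pixel squares tracks the true polygon without systematic dilation
        raster = shrunk.buffer(-ps / 4.0, join_style=2)
        rcoords = np.asarray(raster.exterior.coords)[:-1]
        rr, cc = draw_polygon(rcoords[:, 1] / ps - 0.5, rcoords[:, 0] / ps - 0.5, shape=mask.shape)
        mask[rr, cc] = i
        records.append(
            {
                "label_id": i,
                "is_fiber": True,
                "area_um2": float(shrunk.area),
                "minferet_um": float(min_feret(coords)),
                "x_um": float(shrunk.centroid.x),
                "y_um": float(shrunk.centroid.y),
            }
        )

    # capillary-like artifacts in the background margin band
    next_id = n + 1
    for _ in range(geo.artifact_count):
        a = rng.uniform(*geo.artifact_size_range)
        r_um = math.sqrt(a / math.pi)
        # place the disk in the background margin band around the tessellation
        full = side_px * ps
        along = rng.uniform(r_um + 0.5, full - r_um - 0.5)
        across = rng.uniform(r_um + 0.5, lo - r_um)
        band = int(rng.integers(4))
        if band == 0:  # left
            x, y = across, along
        elif band == 1:  # right
            x, y = full - across, along
        elif band == 2:  # top
            x, y = along, across
        else:  # bottom
            x, y = along, full - across
        rr, cc = draw_disk((y / ps - 0.5, x / ps - 0.5), r_um / ps, shape=mask.shape)
        if mask[rr, cc].any():
            continue  # never overwrite fiber pixels
        mask[rr, cc] = next_id
        records.append(
            {
                "label_id": next_id,
                "is_fiber": False,
                "area_um2": float(a),
                "minferet_um": 2.0 * r_um,
                "x_um": x,
                "y_um": y,
            }
        )
        next_id += 1

    label_mask = LabelMask(mask, pixel_size=ps)
    truth = GroundTruth(records=pd.DataFrame(records), polygons=polygons, mask=label_mask)

    fiber_mean = truth.records.loc[truth.records["is_fiber"], "minferet_um"].mean()
    if abs(fiber_mean - params.target_mean_minferet) > 0.1 * params.target_mean_minferet:
        raise RuntimeError(
            f"generated mean minFeret {fiber_mean:.2f} μm deviates more than 10% "
            f"from target {params.target_mean_minferet:.2f} μm"
        )

    image = _render(mask, truth, rng, ps)
    return image, label_mask, truth


def _render(mask: np.ndarray, truth: GroundTruth, rng: np.random.Generator, ps: float) -> np.ndarray:
    """Schematic two-tone pseudo-H&E rendering of a label mask."""
    h, w = mask.shape
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[...] = (244, 242, 246)  # pale background / interstitium

    base_pink = np.array([231, 146, 160], dtype=float)
    from scipy import ndimage as ndi

    slices = ndi.find_objects(mask)
    for rec in truth.records.itertuples():
        tint = rng.integers(-12, 13, size=3)
        color = np.clip(base_pink + tint, 0, 255).astype(np.uint8)
        if not rec.is_fiber:
            color = np.array([186, 96, 110], dtype=np.uint8)  # capillary red
        sl = slices[rec.label_id - 1]
        if sl is None:
            continue
        sub = mask[sl] == rec.label_id
        image[sl][sub] = color

    # hematoxylin-dark nuclei at a subset of fiber-boundary vertices,
    # drawn on interstitium only so the true mask stays exact
    nucleus = np.array([72, 48, 114], dtype=np.uint8)
    for coords in truth.polygons.values():
        k = max(1, len(coords) // 3)
        idx = rng.choice(len(coords), size=k, replace=False)
        for x, y in coords[idx]:
            rr, cc = draw_disk((y / ps - 0.5, x / ps - 0.5), 0.9 / ps, shape=(h, w))
            keep = mask[rr, cc] == 0
            image[rr[keep], cc[keep]] = nucleus
    return image
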