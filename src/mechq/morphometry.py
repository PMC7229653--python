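"""Segmentation-based fluorescence read-outs.

Implements the per-nucleus and per-field measurements used across the
pipeline: nucleus segmentation, DNA-damage foci counts, region
intensities (mean, total, total per nuclear volume), EdU-positive
fractions, spheroid sprout lengths from skeleton paths, collagen-gel
contraction, and cell-shape descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "RegionMeasurements",
    "SproutingMetrics",
    "GelContractionSeries",
    "segment_nuclei",
    "count_foci",
    "region_intensities",
    "normalized_nuclear_intensity",
    "edu_positive_fraction",
    "sprout_metrics",
    "gel_contraction",
    "cell_shape",
]


@dataclass
class RegionMeasurements:
    """Per-region measurement row."""

    region_id: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    mean_intensity: dict[str, float] = field(default_factory=dict)
    total_intensity: dict[str, float] = field(default_factory=dict)
    total_per_volume: dict[str, float] = field(default_factory=dict)
    volume_um3: float | None = None
    foci_count: int | None = None
    aspect_ratio: float | None = None


@dataclass
class SproutingMetrics:
    """Sprout-length summary for one spheroid field."""

    avg_sprout_length_um: float
    total_skeleton_length_um: float
    n_sprouts: int
    sprout_lengths_um: list[float]


@dataclass
class GelContractionSeries:
    """Normalized gel area over time; frame 0 defines the reference."""

    times: list[float]
    areas_px: list[float]
    normalized_area: list[float]
    percent_contraction: list[float]
    flagged: bool = False


# ---------------------------------------------------------------------------
# Nucleus segmentation and foci counting
# ---------------------------------------------------------------------------

def segment_nuclei(
    image: np.ndarray,
    min_area_px: int = 50,
    watershed_footprint_px: int = 7,
) -> np.ndarray:
    """Label nuclei: Otsu threshold, hole fill, watershed split.

    Touching nuclei are separated by a watershed on the distance
    transform seeded at its local maxima; regions smaller than
    ``min_area_px`` are discarded.  A blank image yields an empty
    labeling, not an error.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=int)
    binary = image > filters.threshold_otsu(image)
    if not binary.any():
        return np.zeros(image.shape, dtype=int)
    binary = ndimage.binary_fill_holes(binary)

    distance = ndimage.distance_transform_edt(binary)
    peak_coords = peak_local_max(
        distance,
        labels=binary,
        footprint=np.ones((watershed_footprint_px,) * 2),
        exclude_border=False,
    )
    markers = np.zeros(image.shape, dtype=int)
    for i, (r, c) in enumerate(peak_coords, start=1):
        markers[r, c] = i
    markers, _ = ndimage.label(markers > 0)
    labels = segmentation.watershed(-distance, markers, mask=binary)

    # drop small regions and renumber, preserving the watershed split
    out = np.zeros_like(labels)
    next_id = 1
    for region_id in np.unique(labels):
        if region_id == 0:
            continue
        region = labels == region_id
        if region.sum() >= min_area_px:
            out[region] = next_id
            next_id += 1
    return out


def count_foci(
    foci_channel: np.ndarray,
    nucleus_masks: np.ndarray,
    spot_sigma_um: float,
    prominence_factor: float = 7.0,
    pixel_size_um: float = 1.0,
) -> dict[int, int]:
    """Count bright puncta per nucleus.

    A Laplacian-of-Gaussian band-pass at the expected spot scale
    suppresses background and slowly varying nuclear texture (so a
    constant intensity offset does not change the counts); local
    response maxima whose prominence exceeds ``prominence_factor``
    times the nucleus-local robust noise scale (MAD) are counted
    inside each mask.  The default factor of 7 sits above the expected
    extreme of LoG-filtered noise over a nucleus-sized area (the
    maximum of thousands of correlated noise samples reaches ~5 MAD),
    while genuine foci exceed the background by an order of magnitude
    more.  Spots closer than about 1.5 sigma merge into one detection
    — the resolution limit of the band-pass.
    """
    if spot_sigma_um <= 0:
        raise ValueError("spot_sigma_um must be positive")
    foci_channel = np.asarray(foci_channel, dtype=float)
    nucleus_masks = np.asarray(nucleus_masks)
    if foci_channel.shape != nucleus_masks.shape:
        raise ValueError("foci channel and masks must be aligned")

    sigma_px = spot_sigma_um / pixel_size_um
    response = -ndimage.gaussian_laplace(foci_channel, sigma_px) * sigma_px**2

    min_dist = max(1, int(round(1.5 * sigma_px)))
    counts: dict[int, int] = {}
    for region_id in np.unique(nucleus_masks):
        if region_id == 0:
            continue
        mask = nucleus_masks == region_id
        local = response[mask]
        mad = np.median(np.abs(local - np.median(local))) * 1.4826
        threshold = np.median(local) + prominence_factor * max(mad, 1e-12)
        peaks = peak_local_max(
            response,
            labels=mask.astype(int),
            min_distance=min_dist,
            threshold_abs=threshold,
            exclude_border=False,
        )
        counts[int(region_id)] = len(peaks)
    return counts


# ---------------------------------------------------------------------------
# Region intensities
# ---------------------------------------------------------------------------

def region_intensities(
    channels: dict[str, np.ndarray],
    masks: np.ndarray,
    mode: str = "mean",
    pixel_size_um: float = 1.0,
    z_step_um: float | None = None,
) -> list[RegionMeasurements]:
    """Per-region intensity statistics for one or more channels.

    ``mode`` selects ``mean`` (sum / pixel count), ``total`` (sum), or
    ``total_per_volume`` (sum divided by region volume in um^3 — the
    masks and channels must then be z-stacks with ``z_step_um`` set).
    Empty regions are skipped with a warning.
    """
    if mode not in {"mean", "total", "total_per_volume"}:
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "total_per_volume" and z_step_um is None:
        raise ValueError("total_per_volume requires z_step_um")
    masks = np.asarray(masks)
    for name, ch in channels.items():
        if np.asarray(ch).shape != masks.shape:
            raise ValueError(f"channel {name!r} shape differs from masks")

    out: list[RegionMeasurements] = []
    for region_id in np.unique(masks):
        if region_id == 0:
            continue
        mask = masks == region_id
        npx = int(mask.sum())
        if npx == 0:
            warnings.warn(f"region {region_id} is empty; skipped", stacklevel=2)
            continue
        centroid = tuple(float(c) for c in ndimage.center_of_mass(mask))
        volume = (
            npx * pixel_size_um**2 * z_step_um if z_step_um is not None else None
        )
        row = RegionMeasurements(
            region_id=int(region_id),
            area_px=npx,
            area_um2=npx * pixel_size_um**2,
            centroid=centroid,
            volume_um3=volume,
        )
        for name, ch in channels.items():
            total = float(np.asarray(ch, dtype=float)[mask].sum())
            row.total_intensity[name] = total
            row.mean_intensity[name] = total / npx
            if mode == "total_per_volume":
                row.total_per_volume[name] = total / volume
        out.append(row)
    return out


def normalized_nuclear_intensity(
    values: np.ndarray, control_values: np.ndarray
) -> np.ndarray:
    """Divide per-nucleus values by the control-condition mean."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control condition has no nuclei")
    control_mean = control_values.mean()
    if control_mean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    return np.asarray(values, dtype=float) / control_mean


def edu_positive_fraction(
    edu_channel: np.ndarray,
    nucleus_masks: np.ndarray,
    threshold: float | None = None,
) -> tuple[float, np.ndarray]:
    """Percentage of EdU-positive nuclei in a field of view.

    Each nucleus is scored by its mean EdU intensity; nuclei above the
    threshold are positive.  By default the threshold is the Otsu
    split of the per-nucleus means (needs >= 2 nuclei); pass an
    explicit ``threshold`` to override.

    Returns ``(percent_positive, per_nucleus_means)``.
    """
    edu_channel = np.asarray(edu_channel, dtype=float)
    nucleus_masks = np.asarray(nucleus_masks)
    ids = [r for r in np.unique(nucleus_masks) if r != 0]
    if not ids:
        raise ValueError("no nuclei in the field")
    means = np.array([
        edu_channel[nucleus_masks == r].mean() for r in ids
    ])
    if threshold is None:
        if len(means) < 2:
            raise ValueError(
                "Otsu thresholding needs >= 2 nuclei; pass a fixed threshold"
            )
        threshold = filters.threshold_otsu(means)
    percent = 100.0 * float((means > threshold).sum()) / len(means)
    return percent, means


# ---------------------------------------------------------------------------
# Sprout length
# ---------------------------------------------------------------------------

def sprout_metrics(
    image: np.ndarray,
    core_removal_radius_um: float,
    pixel_size_um: float = 1.0,
    min_sprout_length_um: float = 5.0,
) -> SproutingMetrics:
    """Average sprout length of a spheroid by skeleton path tracing.

    The bright structure is thresholded and reduced to its largest
    connected component; a morphological opening at the core-removal
    radius isolates the spheroid core (thin sprouts do not survive the
    opening).  The remainder is skeletonized and each sprout's length
    is the geodesic distance along its skeleton from its far endpoint
    back to the core boundary, scaled to micrometres.  Step lengths use
    the Kulpa-corrected weights (0.948 per axial, 1.340 per diagonal
    step) rather than raw 1/sqrt(2): a digitized straight line
    systematically overestimates its Euclidean length by up to ~8% at
    intermediate angles, and these weights remove that bias.  Stubs
    shorter than ``min_sprout_length_um`` are ignored as segmentation
    debris.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return SproutingMetrics(0.0, 0.0, 0, [])
    binary = image > filters.threshold_otsu(image)
    if not binary.any():
        return SproutingMetrics(0.0, 0.0, 0, [])
    labels = measure.label(binary)
    largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1

    radius_px = max(1, int(round(core_removal_radius_um / pixel_size_um)))
    # Euclidean opening via two distance transforms (fast for large radii)
    eroded = ndimage.distance_transform_edt(largest) >= radius_px
    core = (
        ndimage.distance_transform_edt(~eroded) <= radius_px
        if eroded.any()
        else eroded
    )
    sprout_region = largest & ~core
    if not sprout_region.any():
        return SproutingMetrics(0.0, 0.0, 0, [])

    skeleton = morphology.skeletonize(sprout_region)
    # distance to the core: roots sit where the skeleton meets it, tips far out
    dist_to_core = (
        ndimage.distance_transform_edt(~core)
        if core.any()
        else np.full(core.shape, np.inf)
    )
    # skeletonization retracts each tip by about the local half-width;
    # the EDT of the sprout region at the tip measures exactly that
    half_width = ndimage.distance_transform_edt(sprout_region)
    root_tol_px = 4.0
    tip_min_px = 8.0

    graph = nx.Graph()
    coords = np.argwhere(skeleton)
    coord_set = {tuple(c) for c in coords}
    for r, c in coords:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nbr = (r + dr, c + dc)
                if nbr in coord_set:
                    weight = 1.340 if dr and dc else 0.948
                    graph.add_edge((r, c), nbr, weight=weight)
    for node in coord_set:
        graph.add_node(node)

    total_length_px = sum(d["weight"] for _, _, d in graph.edges(data=True))
    lengths_um: list[float] = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        closest = min(comp, key=lambda n: dist_to_core[n])
        gap_px = float(dist_to_core[closest])
        if gap_px > 3 * root_tol_px:
            continue  # debris not attached to the spheroid
        roots = [n for n in comp if dist_to_core[n] <= max(gap_px, root_tol_px)]
        dist = nx.multi_source_dijkstra_path_length(sub, roots, weight="weight")
        # one sprout per free endpoint: each skeleton tip traces back to
        # the core, so touching sprouts in one component stay separate;
        # the gap the skeleton leaves at the junction is added back
        endpoints = [
            n
            for n in comp
            if sub.degree(n) <= 1 and dist_to_core[n] > tip_min_px
        ]
        for tip in endpoints:
            length_px = dist.get(tip, 0.0) + gap_px + float(half_width[tip])
            length_um = length_px * pixel_size_um
            if length_um >= min_sprout_length_um:
                lengths_um.append(length_um)

    avg = float(np.mean(lengths_um)) if lengths_um else 0.0
    return SproutingMetrics(
        avg, total_length_px * pixel_size_um, len(lengths_um), lengths_um
    )


# ---------------------------------------------------------------------------
# Gel contraction
# ---------------------------------------------------------------------------

def gel_contraction(
    images: list[np.ndarray],
    times: list[float] | None = None,
) -> GelContractionSeries:
    """Fractional decrease in gel area over a day series.

    Per frame: threshold, keep the largest component, fill holes, count
    pixels.  Areas are normalized to frame 0; percent contraction is
    ``100 * (1 - normalized)``.  A frame whose gel shrinks below 1% of
    the field is flagged (segmentation is then unreliable).
    """
    if len(images) < 1:
        raise ValueError("need at least one frame")
    if times is None:
        times = list(range(len(images)))
    if len(times) != len(images):
        raise ValueError("times and images must share length")

    areas: list[float] = []
    flagged = False
    for img in images:
        img = np.asarray(img, dtype=float)
        binary = img > filters.threshold_otsu(img) if np.ptp(img) else np.zeros(
            img.shape, bool
        )
        if binary.any():
            labels = measure.label(binary)
            largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
            largest = ndimage.binary_fill_holes(largest)
            area = float(largest.sum())
        else:
            area = 0.0
        if area < 0.01 * img.size:
            flagged = True
        areas.append(area)

    if areas[0] == 0:
        raise ValueError("no gel detected in the reference frame")
    normalized = [a / areas[0] for a in areas]
    percent = [100.0 * (1.0 - n) for n in normalized]
    return GelContractionSeries(list(times), areas, normalized, percent, flagged)


# ---------------------------------------------------------------------------
# Cell shape
# ---------------------------------------------------------------------------

def cell_shape(
    mask: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float]:
    """Area (um^2) and aspect ratio of a single-region mask.

    The aspect ratio is major/minor axis of the best-fit ellipse from
    the region's second moments; regions below 5 pixels are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx < 5:
        raise ValueError("region must cover at least 5 pixels")
    props = measure.regionprops(mask.astype(int))[0]
    area_um2 = npx * pixel_size_um**2
    minor = props.axis_minor_length
    aspect = props.axis_major_length / minor if minor > 0 else float("inf")
    return area_um2, float(aspect)
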