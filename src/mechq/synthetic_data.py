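"""Ground-truth generators for every pipeline stage.

Each generator produces the input one analysis stage consumes together
with the quantity that stage is supposed to recover, so the whole
pipeline can be exercised end-to-end without any experimental data:

* bead-image pairs deformed by a known traction field on a
  linear-elastic half-space (traction force microscopy);
* nucleus time-lapses whose pixel intensities decorrelate with a known
  drop rate ``alpha`` and time constant ``tau`` (chromatin dynamics);
* spheroids with sprouts of known geodesic length (sprouting assay);
* nuclei carrying a known number of bright foci (DNA-damage read-out);
* shrinking gel silhouettes (collagen contraction assay);
* qPCR Ct tables with known fold changes (delta-delta-Ct).

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cli_io import ImageFrameSeries
from .tfm import ElasticSubstrate, DisplacementField, forward_displacement

__all__ = [
    "TractionTruth",
    "NucleusDynamicsTruth",
    "random_balanced_truth",
    "dipole_truth",
    "generate_bead_image_pair",
    "generate_nucleus_timelapse",
    "generate_sprout_image",
    "generate_foci_stack",
    "generate_gel_series",
    "generate_ct_table",
]


# ---------------------------------------------------------------------------
# Traction truth fields and bead-image pairs
# ---------------------------------------------------------------------------

@dataclass
class TractionTruth:
    """A balanced traction field on a linear-elastic half-space.

    The net force (grid sum of each component) must vanish: a
    half-space inversion cannot represent a field that pushes the whole
    substrate sideways.
    """

    grid_shape: tuple[int, int]
    grid_spacing_um: float
    tx: np.ndarray
    ty: np.ndarray
    young_modulus_Pa: float
    poisson_ratio: float
    #: analytic description of the Gaussian patches the grids were
    #: sampled from (one dict per signed patch: cx, cy, sigma, fx, fy),
    #: plus the constant balancing offset; lets tests evaluate the
    #: continuous field off-grid
    components: list[dict] | None = None
    balance_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        if self.tx.shape != tuple(self.grid_shape) or self.ty.shape != tuple(
            self.grid_shape
        ):
            raise ValueError("tx/ty must match grid_shape")
        # substrate validity (raises for nu >= 0.5 or E <= 0)
        ElasticSubstrate(self.young_modulus_Pa, self.poisson_ratio)
        if not self.grid_spacing_um > 0:
            raise ValueError("grid_spacing_um must be positive")
        scale = np.hypot(self.tx, self.ty).mean() * self.tx.size
        if scale > 0:
            net = max(abs(self.tx.sum()), abs(self.ty.sum())) / scale
            if net > 1e-10:
                raise ValueError(
                    f"traction field carries net force (relative {net:.2e}); "
                    "a half-space inversion requires a balanced field"
                )

    @property
    def substrate(self) -> ElasticSubstrate:
        return ElasticSubstrate(self.young_modulus_Pa, self.poisson_ratio)

    def traction_at(
        self, x_um: np.ndarray, y_um: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Continuous traction components at arbitrary positions.

        Only available when the truth was built from analytic patches
        (``components`` set); the constant balancing offset applies
        everywhere inside the field.
        """
        if self.components is None:
            raise ValueError("truth has no analytic patch description")
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        tx = np.full(x.shape, -self.balance_offset[0])
        ty = np.full(x.shape, -self.balance_offset[1])
        for c in self.components:
            g = np.exp(
                -(((x - c["cx"]) ** 2 + (y - c["cy"]) ** 2)
                  / (2 * c["sigma"] ** 2))
            )
            tx = tx + c["fx"] * g
            ty = ty + c["fy"] * g
        return tx, ty


def dipole_truth(
    grid_shape: tuple[int, int],
    grid_spacing_um: float,
    center_um: tuple[float, float],
    separation_um: float,
    patch_sigma_um: float,
    amplitude_Pa: float,
    angle_rad: float = 0.0,
    young_modulus_Pa: float = 1000.0,
    poisson_ratio: float = 0.45,
) -> TractionTruth:
    """A single balanced dipole: two opposed Gaussian traction patches.

    The two patches sit ``separation_um`` apart along ``angle_rad`` and
    pull toward each other, mimicking a contractile cell.
    """
    ny, nx = grid_shape
    y, x = np.mgrid[0:ny, 0:nx] * grid_spacing_um
    cx, cy = center_um
    dx = np.cos(angle_rad) * separation_um / 2
    dy = np.sin(angle_rad) * separation_um / 2
    tx = np.zeros((ny, nx))
    ty = np.zeros((ny, nx))
    components = []
    for s in (+1.0, -1.0):
        g = np.exp(
            -(((x - cx - s * dx) ** 2 + (y - cy - s * dy) ** 2)
              / (2 * patch_sigma_um**2))
        )
        fx = s * amplitude_Pa * np.cos(angle_rad)
        fy = s * amplitude_Pa * np.sin(angle_rad)
        tx += fx * g
        ty += fy * g
        components.append(
            {"cx": cx + s * dx, "cy": cy + s * dy,
             "sigma": patch_sigma_um, "fx": fx, "fy": fy}
        )
    offset = (float(tx.mean()), float(ty.mean()))
    tx -= offset[0]
    ty -= offset[1]
    return TractionTruth(
        (ny, nx), grid_spacing_um, tx, ty, young_modulus_Pa, poisson_ratio,
        components, offset,
    )


def random_balanced_truth(
    grid_shape: tuple[int, int],
    grid_spacing_um: float,
    young_modulus_Pa: float = 1000.0,
    poisson_ratio: float = 0.45,
    n_dipoles: int = 3,
    amplitude_Pa: tuple[float, float] = (50.0, 200.0),
    patch_sigma_cells: tuple[float, float] = (1.2, 1.8),
    separation_cells: tuple[float, float] = (3.0, 5.0),
    seed: int = 0,
) -> TractionTruth:
    """Random contractile field built from interior Gaussian dipoles.

    Dipoles are confined to the central part of the field so the
    induced displacement decays to near zero at the boundary — the
    regime both the inversion and real fields of view assume.  The tiny
    residual numerical net force is removed by subtracting the grid
    mean.

    When the field is to be sampled through tracked beads rather than
    read off the grid, choose ``patch_sigma_cells`` so the induced
    displacement varies on a scale broader than the mean bead spacing
    — sparse sampling cannot resolve sharper features.
    """
    rng = np.random.default_rng(seed)
    ny, nx = grid_shape
    d = grid_spacing_um
    y, x = np.mgrid[0:ny, 0:nx] * d
    tx = np.zeros((ny, nx))
    ty = np.zeros((ny, nx))
    components = []
    for _ in range(n_dipoles):
        cx = rng.uniform(0.35, 0.65) * nx * d
        cy = rng.uniform(0.35, 0.65) * ny * d
        sep = rng.uniform(*separation_cells) * d
        sig = rng.uniform(*patch_sigma_cells) * d
        amp = rng.uniform(*amplitude_Pa)
        ang = rng.uniform(0, 2 * np.pi)
        dx, dy = np.cos(ang) * sep / 2, np.sin(ang) * sep / 2
        for s in (+1.0, -1.0):
            g = np.exp(
                -(((x - cx - s * dx) ** 2 + (y - cy - s * dy) ** 2)
                  / (2 * sig**2))
            )
            fx = s * amp * np.cos(ang)
            fy = s * amp * np.sin(ang)
            tx += fx * g
            ty += fy * g
            components.append(
                {"cx": cx + s * dx, "cy": cy + s * dy,
                 "sigma": sig, "fx": fx, "fy": fy}
            )
    offset = (float(tx.mean()), float(ty.mean()))
    tx -= offset[0]
    ty -= offset[1]
    return TractionTruth(
        (ny, nx), grid_spacing_um, tx, ty, young_modulus_Pa, poisson_ratio,
        components, offset,
    )


def generate_bead_image_pair(
    truth: TractionTruth,
    bead_density_per_um2: float,
    bead_diameter_um: float,
    photon_noise_sd: float,
    seed: int,
    pixel_size_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Render a stress-free and a deformed bead image for a truth field.

    The reference image scatters Gaussian beads uniformly over the
    field of view; the deformed image translates each bead by the
    forward-model (Boussinesq) displacement at its position.  Beads are
    Gaussian spots with ``sigma = diameter / 2.355`` (the FWHM
    convention) at sub-pixel centres, and additive Gaussian noise of
    the stated SD approximates photon noise.

    Returns ``(reference, deformed, truth_displacement_field)`` where
    the displacement field is sampled on the truth grid.
    """
    rng = np.random.default_rng(seed)
    ny, nx = truth.grid_shape
    d = truth.grid_spacing_um
    if pixel_size_um is None:
        pixel_size_um = d / 4.0
    field_w_um = nx * d
    field_h_um = ny * d
    n_beads = rng.poisson(bead_density_per_um2 * field_w_um * field_h_um)
    if n_beads < 30:
        raise ValueError(
            f"bead density yields only {n_beads} beads; need >= 30 for a "
            "usable displacement field"
        )

    ux, uy = forward_displacement(
        truth.tx, truth.ty, d, truth.substrate, pad_factor=4
    )
    disp = DisplacementField(d, ux, uy)

    positions = rng.uniform(
        [0.0, 0.0], [field_w_um - pixel_size_um, field_h_um - pixel_size_um],
        size=(n_beads, 2),
    )
    from scipy.interpolate import RegularGridInterpolator

    axes = (np.arange(ny) * d, np.arange(nx) * d)
    interp_x = RegularGridInterpolator(
        axes, ux, bounds_error=False, fill_value=None
    )
    interp_y = RegularGridInterpolator(
        axes, uy, bounds_error=False, fill_value=None
    )
    pts = positions[:, ::-1]  # (y, x) order
    bead_disp = np.column_stack([interp_x(pts), interp_y(pts)])

    shape_px = (
        int(round(field_h_um / pixel_size_um)),
        int(round(field_w_um / pixel_size_um)),
    )
    sigma_px = (bead_diameter_um / pixel_size_um) / 2.355
    amplitude = 100.0
    ref = _render_spots(shape_px, positions / pixel_size_um, sigma_px, amplitude)
    deformed = _render_spots(
        shape_px, (positions + bead_disp) / pixel_size_um, sigma_px, amplitude
    )
    if photon_noise_sd > 0:
        ref = ref + rng.normal(0.0, photon_noise_sd, shape_px)
        deformed = deformed + rng.normal(0.0, photon_noise_sd, shape_px)
    return ref, deformed, disp


def _render_spots(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Accumulate Gaussian spots at sub-pixel centres onto a canvas."""
    img = np.zeros(shape)
    h, w = shape
    half = max(2, int(np.ceil(4 * sigma_px)))
    for cx, cy in centers_px:
        x_lo, x_hi = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y_lo, y_hi = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x_lo_c, x_hi_c = max(0, x_lo), min(w, x_hi)
        y_lo_c, y_hi_c = max(0, y_lo), min(h, y_hi)
        if x_lo_c >= x_hi_c or y_lo_c >= y_hi_c:
            continue
        yy, xx = np.mgrid[y_lo_c:y_hi_c, x_lo_c:x_hi_c]
        img[y_lo_c:y_hi_c, x_lo_c:x_hi_c] += amplitude * np.exp(
            -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
        )
    return img


# ---------------------------------------------------------------------------
# Nucleus time-lapses with known decorrelation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusDynamicsTruth:
    """Generative parameters for a decorrelating nucleus time-lapse.

    The pixel intensity decomposes as ``I_t = S + D_t + eps_t`` with a
    static texture ``S`` of variance ``(1 - alpha) sigma^2``, a
    stationary AR(1) dynamic part ``D_t`` of variance ``alpha sigma^2``
    whose lag-k autocorrelation is exactly ``exp(-k dt / tau)``, and
    independent measurement noise of SD ``noise_sd * sigma``.  The
    expected Pearson curve is then ``[(1 - alpha) + alpha exp(-t/tau)]
    / (1 + noise_sd^2)`` — the fit model's family with the noise
    deficit absorbed into its constant offset.
    """

    alpha: float
    tau_min: float
    noise_sd: float
    n_frames: int
    frame_interval_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if not self.tau_min > 0:
            raise ValueError("tau_min must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be positive")

    def expected_pcc(self, lags_min: np.ndarray) -> np.ndarray:
        lags_min = np.asarray(lags_min, dtype=float)
        raw = (1 - self.alpha) + self.alpha * np.exp(-lags_min / self.tau_min)
        return raw / (1 + self.noise_sd**2)


def generate_nucleus_timelapse(
    truth: NucleusDynamicsTruth,
    mask_shape: tuple[int, int] = (24, 24),
    seed: int = 0,
    pixel_size_um: float = 0.21,
    baseline: float = 100.0,
    texture_sd: float = 20.0,
) -> tuple[ImageFrameSeries, np.ndarray]:
    """Simulate one nucleus time-lapse plus its (elliptical) mask.

    The mask is the ellipse inscribed in ``mask_shape`` and must cover
    at least 200 pixels.  Intensities follow the static + AR(1) + noise
    decomposition documented on :class:`NucleusDynamicsTruth`, scaled
    by ``texture_sd`` on top of ``baseline``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = mask_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    mask = ((yy - cy) / (ny / 2)) ** 2 + ((xx - cx) / (nx / 2)) ** 2 <= 1.0
    if mask.sum() < 200:
        raise ValueError(
            f"mask covers only {int(mask.sum())} pixels; need >= 200"
        )

    n_px = int(mask.sum())
    t_frames = truth.n_frames
    a = truth.alpha
    phi = float(np.exp(-truth.frame_interval_min / truth.tau_min))

    static = rng.normal(0.0, np.sqrt(max(1 - a, 0.0)), n_px)
    dynamic = np.zeros((t_frames, n_px))
    if a > 0:
        dynamic[0] = rng.normal(0.0, np.sqrt(a), n_px)
        innov_sd = np.sqrt(a * (1 - phi**2))
        for t in range(1, t_frames):
            dynamic[t] = phi * dynamic[t - 1] + rng.normal(0.0, innov_sd, n_px)
    noise = (
        rng.normal(0.0, truth.noise_sd, (t_frames, n_px))
        if truth.noise_sd > 0
        else np.zeros((t_frames, n_px))
    )

    frames = np.zeros((t_frames, ny, nx), dtype=np.float64)
    for t in range(t_frames):
        frame = np.zeros((ny, nx))
        frame[mask] = baseline + texture_sd * (static + dynamic[t] + noise[t])
        frames[t] = frame
    series = ImageFrameSeries(
        frames, pixel_size_um, truth.frame_interval_min
    )
    return series, mask


# ---------------------------------------------------------------------------
# Spheroid sprouting images
# ---------------------------------------------------------------------------

def generate_sprout_image(
    n_sprouts: int,
    sprout_lengths_um: list[float],
    core_radius_um: float,
    pixel_size_um: float,
    seed: int = 0,
    curvature_per_um: float = 0.0,
    max_retries: int = 25,
) -> tuple[np.ndarray, list[float]]:
    """Render a spheroid core with radiating sprouts of known length.

    Sprouts are thin bright paths starting at the core boundary; with
    nonzero ``curvature_per_um`` each path is a circular arc of the
    stated arc length, otherwise a straight ray.  Sprout angles are
    evenly spaced with jitter; if two rendered sprouts would overlap the
    angles are re-jittered, and persistent overlap raises an error.

    Returns ``(image, truth_lengths_um)``.
    """
    if n_sprouts != len(sprout_lengths_um):
        raise ValueError("need one length per sprout")
    if any(length <= 0 for length in sprout_lengths_um):
        raise ValueError("sprout lengths must be positive")
    rng = np.random.default_rng(seed)

    max_len = max(sprout_lengths_um, default=0.0)
    extent_um = core_radius_um + max_len + 5.0
    half_px = int(np.ceil(extent_um / pixel_size_um))
    size = 2 * half_px + 1
    center = float(half_px)
    core_r_px = core_radius_um / pixel_size_um

    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    img[(yy - center) ** 2 + (xx - center) ** 2 <= core_r_px**2] = 200.0

    if n_sprouts == 0:
        return img, []

    base_angles = 2 * np.pi * np.arange(n_sprouts) / n_sprouts
    jitter_scale = np.pi / max(n_sprouts, 1) * 0.3
    for attempt in range(max_retries):
        angles = base_angles + rng.uniform(
            -jitter_scale, jitter_scale, n_sprouts
        )
        paths = [
            _sprout_path(
                center, core_r_px, ang, length / pixel_size_um,
                curvature_per_um * pixel_size_um,
            )
            for ang, length in zip(angles, sprout_lengths_um)
        ]
        if _paths_disjoint(paths, min_dist_px=6.0):
            break
    else:
        raise RuntimeError(
            f"could not place {n_sprouts} non-overlapping sprouts in "
            f"{max_retries} attempts"
        )

    for path in paths:
        for px, py in path:
            x0, y0 = int(round(px)), int(round(py))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    x, y = x0 + dx, y0 + dy
                    if 0 <= x < size and 0 <= y < size and dx * dx + dy * dy <= 2:
                        img[y, x] = max(img[y, x], 180.0)
    return img, list(sprout_lengths_um)


def _sprout_path(
    center: float,
    start_radius_px: float,
    angle: float,
    length_px: float,
    curvature_per_px: float,
    step_px: float = 0.25,
) -> np.ndarray:
    """Polyline of a sprout: constant-speed arc of the stated length."""
    n_steps = max(2, int(np.ceil(length_px / step_px)))
    s = np.linspace(0.0, length_px, n_steps)
    heading = angle + curvature_per_px * s
    x = center + start_radius_px * np.cos(angle) + np.concatenate(
        [[0.0], np.cumsum(np.diff(s) * np.cos(heading[:-1]))]
    )
    y = center + start_radius_px * np.sin(angle) + np.concatenate(
        [[0.0], np.cumsum(np.diff(s) * np.sin(heading[:-1]))]
    )
    return np.column_stack([x, y])


def _paths_disjoint(paths: list[np.ndarray], min_dist_px: float) -> bool:
    # subsample to ~1 px spacing; with the margin in min_dist_px this is
    # conservative and keeps the pairwise check cheap
    coarse = [p[::4] for p in paths]
    for i in range(len(coarse)):
        for j in range(i + 1, len(coarse)):
            d2 = np.sum(
                (coarse[i][:, None, :] - coarse[j][None, :, :]) ** 2, axis=2
            )
            if d2.min() < min_dist_px**2:
                return False
    return True


# ---------------------------------------------------------------------------
# Foci stacks
# ---------------------------------------------------------------------------

def generate_foci_stack(
    n_nuclei: int,
    foci_counts: list[int],
    min_separation_um: float,
    seed: int = 0,
    pixel_size_um: float = 0.21,
    n_planes: int = 5,
    z_step_um: float = 1.0,
    spot_sigma_um: float = 0.25,
    nucleus_axes_um: tuple[float, float] = (6.0, 4.5),
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Render a two-channel z-stack of nuclei with known foci counts.

    Nuclei are ellipsoids laid out on a tile grid (never touching);
    each carries the requested number of Gaussian foci with all
    pairwise separations at least ``min_separation_um`` in-plane.
    Returns ``(nucleus_stack, foci_stack, truth_counts)`` with stacks
    of shape ``(n_planes, H, W)``.

    Raises if the requested foci cannot be packed into a nucleus at the
    stated separation, naming the offending nucleus.
    """
    if len(foci_counts) != n_nuclei:
        raise ValueError("need one focus count per nucleus")
    rng = np.random.default_rng(seed)

    ax_um, bx_um = nucleus_axes_um
    a_px = ax_um / pixel_size_um
    b_px = bx_um / pixel_size_um
    margin_px = 8
    tile = int(np.ceil(2 * a_px)) + 2 * margin_px
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    h, w = n_rows * tile, n_cols * tile

    sep_px = min_separation_um / pixel_size_um
    sigma_px = spot_sigma_um / pixel_size_um
    zc = (n_planes - 1) / 2
    z_half = max((n_planes - 1) / 2, 1.0)

    nucleus = np.zeros((n_planes, h, w))
    foci = np.zeros((n_planes, h, w))
    truth: list[int] = []

    yy, xx = np.mgrid[0:h, 0:w]
    for idx in range(n_nuclei):
        row, col = divmod(idx, n_cols)
        cy = row * tile + tile / 2
        cx = col * tile + tile / 2
        # ellipsoid: in-plane axes shrink away from the central plane
        for z in range(n_planes):
            shrink2 = 1.0 - ((z - zc) / (z_half + 0.5)) ** 2
            if shrink2 <= 0:
                continue
            ell = ((yy - cy) / (b_px * np.sqrt(shrink2))) ** 2 + (
                (xx - cx) / (a_px * np.sqrt(shrink2))
            ) ** 2 <= 1.0
            nucleus[z][ell] = 150.0

        count = int(foci_counts[idx])
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < count:
            tries += 1
            if tries > 4000:
                raise ValueError(
                    f"cannot place {count} foci at separation "
                    f"{min_separation_um} um inside nucleus {idx}"
                )
            # keep foci well inside the mid-plane ellipse
            fx = cx + rng.uniform(-1, 1) * (a_px - 3 * sigma_px - 2)
            fy = cy + rng.uniform(-1, 1) * (b_px - 3 * sigma_px - 2)
            if ((fy - cy) / (b_px - 3 * sigma_px - 2)) ** 2 + (
                (fx - cx) / (a_px - 3 * sigma_px - 2)
            ) ** 2 > 1.0:
                continue
            if any(np.hypot(fx - px, fy - py) < sep_px for px, py in placed):
                continue
            placed.append((fx, fy))
        truth.append(count)

        for fx, fy in placed:
            fz = rng.uniform(zc - 1, zc + 1)
            x_lo = max(0, int(fx) - 8)
            x_hi = min(w, int(fx) + 9)
            y_lo = max(0, int(fy) - 8)
            y_hi = min(h, int(fy) + 9)
            sub_y, sub_x = np.mgrid[y_lo:y_hi, x_lo:x_hi]
            blob = np.exp(
                -(((sub_x - fx) ** 2 + (sub_y - fy) ** 2) / (2 * sigma_px**2))
            )
            for z in range(n_planes):
                foci[z, y_lo:y_hi, x_lo:x_hi] += (
                    120.0 * np.exp(-((z - fz) ** 2) / 2.0) * blob
                )

    nucleus += rng.normal(0.0, 1.0, nucleus.shape)
    foci += rng.normal(0.0, 1.0, foci.shape)
    return nucleus, foci, truth


# ---------------------------------------------------------------------------
# Gel contraction series
# ---------------------------------------------------------------------------

def generate_gel_series(
    initial_radius_px: float,
    area_fractions: list[float],
) -> tuple[list[np.ndarray], list[float]]:
    """Filled-disk silhouettes whose areas follow the stated fractions.

    Frame ``i`` is a disk of radius ``r0 * sqrt(f_i)`` so its area is
    exactly ``f_i`` times frame 0's, up to pixelation.  Fractions must
    start at 1 and be non-increasing (a gel does not regrow).
    """
    if not area_fractions:
        raise ValueError("need at least one area fraction")
    if abs(area_fractions[0] - 1.0) > 1e-12:
        raise ValueError("first area fraction must be 1.0")
    if any(f > 1.0 or f <= 0.0 for f in area_fractions):
        raise ValueError("area fractions must lie in (0, 1]")
    if any(b > a for a, b in zip(area_fractions, area_fractions[1:])):
        raise ValueError("area fractions must be non-increasing")

    size = 2 * int(np.ceil(initial_radius_px)) + 21
    center = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - center) ** 2 + (xx - center) ** 2
    frames = []
    for f in area_fractions:
        radius = initial_radius_px * np.sqrt(f)
        frame = np.full((size, size), 10.0)
        frame[r2 <= radius**2] = 200.0
        frames.append(frame)
    return frames, list(area_fractions)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    genes: list[str],
    conditions: list[str],
    true_log2_fold_changes: dict[str, dict[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "GAPDH",
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Ct table consistent with stated fold changes at perfect efficiency.

    One Ct unit corresponds to a 2-fold expression difference, so a
    gene with log2 fold change ``f`` in a condition has its Ct lowered
    by ``f`` relative to the reference condition.  The housekeeping
    reference gene is constant across conditions and appended to the
    table if not already among ``genes``.  Gaussian noise of SD
    ``ct_noise_sd`` is added to every measurement.
    """
    if reference_condition is None:
        reference_condition = conditions[0]
    if reference_condition not in conditions:
        raise ValueError(
            f"reference condition {reference_condition!r} not in conditions"
        )
    rng = np.random.default_rng(seed)
    all_genes = list(genes)
    if reference_gene not in all_genes:
        all_genes.append(reference_gene)

    baselines = {
        g: (18.0 if g == reference_gene else rng.uniform(20.0, 28.0))
        for g in all_genes
    }
    rows = []
    for gene in all_genes:
        for cond in conditions:
            if gene == reference_gene or cond == reference_condition:
                log2fc = 0.0
            else:
                log2fc = true_log2_fold_changes.get(gene, {}).get(cond, 0.0)
            for rep in range(n_replicates):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": baselines[gene] - log2fc + noise,
                    }
                )
    return pd.DataFrame(rows)
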