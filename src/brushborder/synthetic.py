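"""Synthetic microscopy inputs with known ground truth.

Every downstream operation in this package quantifies structure that, in the
original experiments, lives in electron or fluorescence micrographs of the
intestinal brush border.  This module generates minimal synthetic stand-ins
with exactly the structure those operations measure:

* hexagonally packed vs. disordered microvillus *tip fields* (point patterns
  on a triangular lattice with controllable spacing, Gaussian positional
  jitter and random dropout), and their rendering as top-view images
  (Gaussian point-spread bumps plus noise);
* TEM-like *cross-section* images of bright elliptical profiles on a dark
  background, optionally fused pairwise into single blobs;
* two-channel *line-scan profiles* of microvilli: a full-length reference
  channel (ezrin-like) and a marker channel that is either tip-localized or
  delocalized;
* *FISH signal tables* containing true bacterial signals plus the two
  false-positive classes excluded by the counting rules (nuclear signals and
  Cy3/green double-positive autofluorescence);
* relative *weight curves* for colitis time courses.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, PlacementError
from .profiles import DEFAULT_SCAN_LENGTH_UM, LineScanProfile

__all__ = [
    "PointPattern",
    "ImageGrid",
    "SimulationConfig",
    "FishSignal",
    "EllipseGroundTruth",
    "WeightCurve",
    "gen_tip_pattern",
    "gen_poisson_pattern",
    "render_topview",
    "gen_cross_sections",
    "gen_line_profiles",
    "gen_fish_field",
    "gen_weight_curves",
]

# triangular-lattice point density is 2 / (sqrt(3) * spacing^2)
TRIANGULAR_DENSITY_FACTOR = 2.0 / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PointPattern:
    """Planar point positions (micrometres) inside a rectangular field."""

    points: np.ndarray  # (n, 2) array of (x, y)
    field_width: float
    field_height: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.field_width <= 0 or self.field_height <= 0:
            raise InvalidParameterError("field dimensions must be positive")
        if pts.size and not np.all(np.isfinite(pts)):
            raise InvalidParameterError("point coordinates must be finite")
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > self.field_width
            or pts[:, 1].max() > self.field_height
        ):
            raise InvalidParameterError("points must lie inside the field")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return self.field_width * self.field_height


@dataclass(frozen=True)
class ImageGrid:
    """2-D (or channel-stacked) non-negative intensity raster.

    ``pixel_size`` is micrometres per pixel; ``origin`` is the physical
    position (x, y) of the image's top-left corner, so pixel (row r, col c)
    has its center at ``origin + (c + 0.5, r + 0.5) * pixel_size``.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=float)
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if pix.ndim not in (2, 3):
            raise InvalidParameterError("pixels must be 2-D or channel-stacked 3-D")
        if not np.all(np.isfinite(pix)) or pix.min(initial=0.0) < 0:
            raise InvalidParameterError("intensities must be finite and non-negative")
        object.__setattr__(self, "pixels", pix)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the tip-field generator and its rendering.

    spacing
        Triangular-lattice constant in micrometres (~0.1 um for tightly
        packed duodenal microvilli).
    jitter_sd
        Isotropic Gaussian displacement sd (um); 0 = perfect lattice.
    dropout_frac
        Independent removal probability per tip, in [0, 1].
    noise_sd
        Additive Gaussian image noise sd, in intensity units of the
        unit-amplitude rendered bumps.
    psf_sigma
        Gaussian point-spread sd of the rendering, um.  Default 0.01
        (10 nm): high-magnification SEM resolves 100-nm-spaced tips
        individually even when positional disorder brings neighbors
        within a few tens of nanometres.
    hard_core
        Minimum tip separation (um) enforced after jitter and dropout by
        dependent thinning (of any closer pair the later point is removed).
        0 disables it.  Microvilli are ~0.1 um thick, so tips of a real
        brush border cannot approach arbitrarily: disordered fields with a
        hard core reproduce the observed combination of *fewer* microvilli
        with *larger* nearest-neighbor distances.
    """

    seed: int
    spacing: float = 0.1
    jitter_sd: float = 0.0
    dropout_frac: float = 0.0
    noise_sd: float = 0.0
    psf_sigma: float = 0.01
    hard_core: float = 0.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        if not 0.0 <= self.dropout_frac <= 1.0:
            raise InvalidParameterError("dropout_frac must be in [0, 1]")
        if self.jitter_sd < 0:
            raise InvalidParameterError("jitter_sd must be non-negative")
        if self.hard_core < 0:
            raise InvalidParameterError("hard_core must be non-negative")


@dataclass(frozen=True)
class FishSignal:
    """One fluorescence in-situ hybridization signal's feature row.

    ``true_class`` is the generator's ground truth: a genuine bacterium, a
    nuclear false positive (Cy3 signal inside a nucleus), or autofluorescent
    feces (bright in both the Cy3 and green channels).
    """

    x: float
    y: float
    cy3_intensity: float
    green_intensity: float
    nuclear_overlap_frac: float
    true_class: str  # bacterium | nuclear_fp | autofluor_fp

    def __post_init__(self) -> None:
        if self.cy3_intensity < 0 or self.green_intensity < 0:
            raise InvalidParameterError("intensities must be non-negative")
        if not 0.0 <= self.nuclear_overlap_frac <= 1.0:
            raise InvalidParameterError("nuclear_overlap_frac must be in [0, 1]")
        if self.true_class not in ("bacterium", "nuclear_fp", "autofluor_fp"):
            raise InvalidParameterError(f"unknown true_class {self.true_class!r}")


@dataclass(frozen=True)
class EllipseGroundTruth:
    """Ground truth for one generated microvillus cross-section ellipse."""

    center_nm: tuple[float, float]
    area_nm2: float
    axis_ratio: float
    angle_rad: float
    fused: bool
    component_id: int


@dataclass(frozen=True)
class WeightCurve:
    """Relative body weight (% of day 0) over a colitis time course."""

    days: np.ndarray
    relative_weight: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        w = np.asarray(self.relative_weight, dtype=float)
        if days.shape != w.shape or days.ndim != 1:
            raise InvalidParameterError("days and relative_weight must be equal-length 1-D")
        if np.any(np.diff(days) <= 0):
            raise InvalidParameterError("days must be strictly increasing")
        if days[0] != 0 or not np.isclose(w[0], 100.0):
            raise InvalidParameterError("day 0 with relative weight 100% must be present")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "relative_weight", w)


# ---------------------------------------------------------------------------
# tip fields


def gen_tip_pattern(
    config: SimulationConfig, field_width: float, field_height: float
) -> PointPattern:
    """Triangular lattice of microvillus tips with jitter and dropout.

    The lattice orientation is randomized per seed (micrographs have
    arbitrary orientation, and the spectral order statistic must be tested
    rotation-invariantly).  Jitter is applied before dropout; jittered
    points leaving the field are clipped back to the boundary minus 1e-6 um.
    """
    a = config.spacing
    if field_width <= 2 * a or field_height <= 2 * a:
        raise InvalidParameterError("field dimensions must exceed 2 x spacing")
    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(0.0, np.pi / 3.0)  # lattice has 60-degree symmetry
    cx, cy = field_width / 2.0, field_height / 2.0
    # cover the circumscribed circle so any rotation fills the field
    radius = np.hypot(field_width, field_height) / 2.0 + a
    row_h = a * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(radius / row_h))
    n_cols = int(np.ceil(radius / a))
    js = np.arange(-n_rows, n_rows + 1)
    is_ = np.arange(-n_cols, n_cols + 1)
    ii, jj = np.meshgrid(is_, js)
    xs = (ii + 0.5 * (jj & 1)) * a
    ys = jj * row_h
    ct, st = np.cos(theta), np.sin(theta)
    px = cx + ct * xs - st * ys
    py = cy + st * xs + ct * ys
    pts = np.column_stack([px.ravel(), py.ravel()])
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= field_width)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= field_height)
    )
    pts = pts[inside]
    if config.jitter_sd > 0:
        pts = pts + rng.normal(0.0, config.jitter_sd, size=pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], 1e-6, field_width - 1e-6)
        pts[:, 1] = np.clip(pts[:, 1], 1e-6, field_height - 1e-6)
    if config.dropout_frac > 0:
        keep = rng.random(pts.shape[0]) >= config.dropout_frac
        pts = pts[keep]
    if config.hard_core > 0 and pts.shape[0] > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        alive = np.ones(pts.shape[0], dtype=bool)
        for i, j in sorted(tree.query_pairs(config.hard_core)):
            if alive[i] and alive[j]:
                alive[max(i, j)] = False
        pts = pts[alive]
    return PointPattern(points=pts, field_width=field_width, field_height=field_height)


def gen_poisson_pattern(
    intensity: float, field_width: float, field_height: float, seed: int
) -> PointPattern:
    """Homogeneous Poisson point pattern of given intensity (points/um^2).

    Serves as the fully disordered null against the lattice generator; its
    nearest-neighbor distance has the closed-form mean 1 / (2 sqrt(lambda)).
    """
    if intensity <= 0:
        raise InvalidParameterError("intensity must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * field_width * field_height)
    pts = np.column_stack(
        [rng.uniform(0, field_width, n), rng.uniform(0, field_height, n)]
    )
    return PointPattern(points=pts, field_width=field_width, field_height=field_height)


def render_topview(
    pattern: PointPattern,
    psf_sigma: float,
    noise_sd: float,
    pixel_size: float,
    seed: int,
    pad: float = 0.0,
) -> ImageGrid:
    """Render a tip field as a top-view image.

    Each tip becomes an isotropic Gaussian bump of sd ``psf_sigma`` and unit
    amplitude; bumps are summed and additive Gaussian noise of sd
    ``noise_sd`` is added and clipped at zero.  ``pad`` extends the image
    beyond the field on every side (the returned grid's ``origin`` is
    ``(-pad, -pad)``) so boundary tips are rendered completely.  Sampling
    must be Nyquist-adequate: ``pixel_size < psf_sigma``.
    """
    if not 0 < pixel_size < psf_sigma:
        raise InvalidParameterError("require 0 < pixel_size < psf_sigma")
    if pad < 0:
        raise InvalidParameterError("pad must be non-negative")
    w = pattern.field_width + 2 * pad
    h = pattern.field_height + 2 * pad
    n_cols = max(1, int(round(w / pixel_size)))
    n_rows = max(1, int(round(h / pixel_size)))
    img = np.zeros((n_rows, n_cols), dtype=float)
    half = int(np.ceil(5.0 * psf_sigma / pixel_size))
    inv2s2 = 1.0 / (2.0 * psf_sigma**2)
    for x, y in pattern.points:
        u = (x + pad) / pixel_size - 0.5  # fractional column of the tip
        v = (y + pad) / pixel_size - 0.5
        c0, c1 = max(0, int(u) - half), min(n_cols, int(u) + half + 1)
        r0, r1 = max(0, int(v) - half), min(n_rows, int(v) + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = np.arange(c0, c1) - u
        rr = np.arange(r0, r1) - v
        img[r0:r1, c0:c1] += np.exp(
            -((rr[:, None] ** 2 + cc[None, :] ** 2) * pixel_size**2) * inv2s2
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return ImageGrid(pixels=np.clip(img, 0.0, None), pixel_size=pixel_size, origin=(-pad, -pad))


# ---------------------------------------------------------------------------
# cross-sections


def _ellipse_coverage(shape, center_px, a_px, b_px, angle, supersample=4):
    """Anti-aliased filled-ellipse coverage raster in [0, 1]."""
    h, w = shape
    cx, cy = center_px
    # bounding window
    r = max(a_px, b_px) + 2
    c0, c1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    r0, r1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    s = supersample
    sub = (np.arange(s) + 0.5) / s
    xs = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel() - 0.5 - cx
    ys = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel() - 0.5 - cy
    ct, st = np.cos(angle), np.sin(angle)
    X, Y = np.meshgrid(xs, ys)
    U = (ct * X + st * Y) / a_px
    V = (-st * X + ct * Y) / b_px
    inside = (U**2 + V**2 <= 1.0).astype(float)
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    out = np.zeros(shape, dtype=float)
    out[r0:r1, c0:c1] = cov
    return out


def gen_cross_sections(
    n: int,
    mean_equiv_diameter: float = 80.0,
    axis_ratio: float = 1.0,
    fusion_prob: float = 0.0,
    image_size: int = 512,
    pixel_size: float = 2.0,
    seed: int = 0,
    diameter_cv: float = 0.08,
    background: float = 100.0,
    foreground: float = 30000.0,
) -> tuple[ImageGrid, list[EllipseGroundTruth]]:
    """TEM-like raster of bright elliptical cross-sections on dark ground.

    ``n`` ellipses of mean equivalent diameter ``mean_equiv_diameter`` (nm)
    and fixed ``axis_ratio`` (major/minor, >= 1) are placed without overlap,
    except that with probability ``fusion_prob`` a pair of ellipses is
    deliberately overlapped into one connected blob (a fusion event), as
    seen when neighboring microvilli coalesce.  Returns the image (pixel
    size converted to micrometres) and per-ellipse ground truth (analytic
    area in nm^2, axis ratio, fusion flag, connected-component id).
    """
    if n < 0:
        raise InvalidParameterError("n must be non-negative")
    if axis_ratio < 1.0:
        raise InvalidParameterError("axis_ratio must be >= 1")
    if not 0.0 <= fusion_prob <= 1.0:
        raise InvalidParameterError("fusion_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ps = pixel_size  # nm per pixel
    cov = np.zeros((image_size, image_size), dtype=float)
    truths: list[EllipseGroundTruth] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius) px

    def semi_axes(d_nm: float) -> tuple[float, float]:
        # preserve equivalent-diameter area: pi (d/2)^2 = pi a b
        a = (d_nm / 2.0) * np.sqrt(axis_ratio)
        return a, (d_nm / 2.0) / np.sqrt(axis_ratio)

    def try_place(radius_px: float, retries: int = 200) -> tuple[float, float]:
        margin = radius_px + 6
        if 2 * margin >= image_size:
            raise PlacementError("objects too large for the field")
        for _ in range(retries):
            cx = rng.uniform(margin, image_size - margin)
            cy = rng.uniform(margin, image_size - margin)
            if all(np.hypot(cx - px, cy - py) > radius_px + pr + 3 for px, py, pr in placed):
                return cx, cy
        raise PlacementError(f"could not place object after {retries} retries")

    comp = 0
    i = 0
    while i < n:
        fuse = (fusion_prob > 0) and (i + 1 < n) and (rng.random() < fusion_prob)
        d1 = mean_equiv_diameter * np.exp(rng.normal(0.0, diameter_cv))
        a1, b1 = semi_axes(d1)
        ang1 = rng.uniform(0, np.pi)
        if fuse:
            d2 = mean_equiv_diameter * np.exp(rng.normal(0.0, diameter_cv))
            a2, b2 = semi_axes(d2)
            ang2 = rng.uniform(0, np.pi)
            # overlap guaranteed: each ellipse contains a disk of its minor axis
            sep = 0.75 * (b1 + b2) / ps
            pair_r = (max(a1, b1) + max(a2, b2)) / ps + sep
            cx, cy = try_place(pair_r)
            phi = rng.uniform(0, 2 * np.pi)
            centers = [
                (cx - 0.5 * sep * np.cos(phi), cy - 0.5 * sep * np.sin(phi)),
                (cx + 0.5 * sep * np.cos(phi), cy + 0.5 * sep * np.sin(phi)),
            ]
            members = [(d1, a1, b1, ang1), (d2, a2, b2, ang2)]
            placed.append((cx, cy, pair_r))
        else:
            r1 = max(a1, b1) / ps
            cx, cy = try_place(r1)
            centers = [(cx, cy)]
            members = [(d1, a1, b1, ang1)]
            placed.append((cx, cy, r1))
        for (ccx, ccy), (_, a, b, ang) in zip(centers, members):
            cov = np.maximum(
                cov, _ellipse_coverage(cov.shape, (ccx, ccy), a / ps, b / ps, ang)
            )
            truths.append(
                EllipseGroundTruth(
                    center_nm=((ccx + 0.5) * ps, (ccy + 0.5) * ps),
                    area_nm2=float(np.pi * a * b),
                    axis_ratio=axis_ratio,
                    angle_rad=float(ang),
                    fused=fuse,
                    component_id=comp,
                )
            )
        comp += 1
        i += 2 if fuse else 1
    pixels = background + (foreground - background) * cov
    return ImageGrid(pixels=pixels, pixel_size=ps / 1000.0), truths


# ---------------------------------------------------------------------------
# line-scan profiles


def gen_line_profiles(
    micro_length: float = 1.0,
    marker_mode: str = "tip",
    tip_peak_sd: float = 0.25,
    noise_sd: float = 0.05,
    n_profiles: int = 1,
    scan_length: float = DEFAULT_SCAN_LENGTH_UM,
    seed: int = 0,
    sample_spacing: float = 0.01,
    edge_sigma: float = 0.05,
    length_cv: float = 0.05,
    center_jitter_sd: float = 0.05,
) -> list[LineScanProfile]:
    """Two-channel line-scan profiles on microvilli of controllable length.

    The reference channel emulates ezrin, present along the whole
    microvillus: a plateau spanning the microvillus length, tilted from 0.85
    at the base to 1.0 at the distal tip (ezrin is distally enriched) and
    smoothed with a Gaussian of sd ``edge_sigma``.  The marker channel is a
    Gaussian peak of sd ``tip_peak_sd`` centered on the distal plateau edge
    (``marker_mode='tip'``, the intact-crosslinking phenotype) or a broad
    bump spread over and beyond the plateau (``marker_mode='delocalized'``,
    the knock-out phenotype).  The distal direction is the increasing scan
    coordinate.  Per-profile biological variability: small lognormal
    amplitude scatter, microvillus-length CV ``length_cv`` and positional
    jitter of the brush border along the scan.
    """
    if micro_length <= 0:
        raise InvalidParameterError("micro_length must be positive")
    if scan_length < micro_length:
        raise InvalidParameterError("scan_length must be >= micro_length")
    if marker_mode not in ("tip", "delocalized"):
        raise InvalidParameterError("marker_mode must be 'tip' or 'delocalized'")
    rng = np.random.default_rng(seed)
    pos = np.arange(0.0, scan_length + 0.5 * sample_spacing, sample_spacing)
    sig_samples = edge_sigma / sample_spacing
    out: list[LineScanProfile] = []
    for _ in range(n_profiles):
        length = micro_length * float(np.exp(rng.normal(0.0, length_cv)))
        length = min(length, scan_length)
        start = (scan_length - length) / 2.0 + rng.normal(0.0, center_jitter_sd)
        start = float(np.clip(start, 0.0, scan_length - length))
        tip = start + length
        amp_ref = float(np.exp(rng.normal(0.0, 0.1)))
        amp_mar = float(np.exp(rng.normal(0.0, 0.1)))
        plateau = np.zeros_like(pos)
        inside = (pos >= start) & (pos <= tip)
        plateau[inside] = 0.85 + 0.15 * (pos[inside] - start) / length
        ref = amp_ref * ndimage.gaussian_filter1d(plateau, sig_samples, mode="constant")
        if marker_mode == "tip":
            mar = amp_mar * np.exp(-((pos - tip) ** 2) / (2.0 * tip_peak_sd**2))
        else:
            center = start + 0.5 * length
            mar = amp_mar * 0.6 * np.exp(-((pos - center) ** 2) / (2.0 * (0.8 * length) ** 2))
        if noise_sd > 0:
            ref = ref + rng.normal(0.0, noise_sd, ref.shape)
            mar = mar + rng.normal(0.0, noise_sd, mar.shape)
        out.append(
            LineScanProfile(
                positions=pos,
                ref_intensity=np.clip(ref, 0.0, None),
                marker_intensity=np.clip(mar, 0.0, None),
            )
        )
    return out


# ---------------------------------------------------------------------------
# FISH fields


def gen_fish_field(
    n_bacteria: int,
    n_nuclear_fp: int,
    n_autofluor_fp: int,
    n_cells: int,
    seed: int = 0,
    field_um: float = 100.0,
) -> tuple[list[FishSignal], int]:
    """Cy3 FISH signal table with true bacteria and both false-positive types.

    True bacteria are Cy3-bright, green-dark and outside nuclei
    (nuclear overlap < 0.1); nuclear false positives overlap nuclei
    (> 0.5); autofluorescent (fecal) false positives are bright in *both*
    channels.  Returns the signal list and the total cell count of the
    field (the invasion-rate denominator).
    """
    for v in (n_bacteria, n_nuclear_fp, n_autofluor_fp, n_cells):
        if v < 0:
            raise InvalidParameterError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    signals: list[FishSignal] = []

    def positions(k):
        return rng.uniform(0.0, field_um, size=(k, 2))

    for (x, y) in positions(n_bacteria):
        signals.append(
            FishSignal(x, y, rng.uniform(150, 250), rng.uniform(0, 20),
                       rng.uniform(0.0, 0.05), "bacterium")
        )
    for (x, y) in positions(n_nuclear_fp):
        signals.append(
            FishSignal(x, y, rng.uniform(100, 200), rng.uniform(0, 30),
                       rng.uniform(0.6, 0.95), "nuclear_fp")
        )
    for (x, y) in positions(n_autofluor_fp):
        signals.append(
            FishSignal(x, y, rng.uniform(150, 250), rng.uniform(100, 250),
                       rng.uniform(0.0, 0.05), "autofluor_fp")
        )
    return signals, n_cells


# ---------------------------------------------------------------------------
# weight curves


def gen_weight_curves(
    n_mice: int,
    slope_pct_per_day: float,
    n_days: int = 10,
    noise_sd_pct: float = 1.0,
    seed: int = 0,
) -> list[WeightCurve]:
    """Relative weight curves declining linearly from 100% at day 0.

    Each mouse's weight on day d > 0 is 100 + slope * d plus Gaussian noise
    of sd ``noise_sd_pct``; day 0 is exactly 100% by definition of relative
    weight.
    """
    if n_mice < 1 or n_days < 1:
        raise InvalidParameterError("need at least one mouse and one day")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days + 1)
    curves = []
    for _ in range(n_mice):
        w = 100.0 + slope_pct_per_day * days + rng.normal(0.0, noise_sd_pct, days.size)
        w[0] = 100.0
        curves.append(WeightCurve(days=days, relative_weight=np.clip(w, 0.0, None)))
    return curves
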