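"""Line-scan extraction, normalization/alignment and 1-D colocalization.

Implements the brush-border line-scan procedure used to localize
intermicrovillar adhesion complex (IMAC) components: fixed-length intensity
profiles are read from two-channel images (reference channel ezrin, which
decorates the whole microvillus; marker channel the protein of interest),
normalized to a maximum of 1, aligned on the position of the reference
maximum, and compared by a rank correlation restricted to samples where the
normalized reference exceeds a threshold (default 0.7).  Groups of
correlation coefficients (e.g. wild-type vs. knock-out line scans) are
compared with the Wilcoxon-Mann-Whitney test.  Apical-marker abundance is
quantified as the trapezoidal area under the profile (AUC), the length of
the fluorescence signal at half maximum, and AUC per unit signal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    CannotAlignError,
    DegenerateLineError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "LineScanProfile",
    "AlignedProfilePair",
    "ColocResult",
    "GroupComparison",
    "extract_line_profile",
    "normalize_align",
    "coloc_coefficient",
    "compare_groups",
    "profile_auc",
    "signal_length",
    "auc_per_length",
    "profile_envelope",
]

#: Physical scan length used throughout, in micrometres.
DEFAULT_SCAN_LENGTH_UM = 4.0
#: Perpendicular averaging width of the line tool, in pixels.
DEFAULT_LINE_WIDTH_PX = 12


@dataclass(frozen=True)
class LineScanProfile:
    """Paired reference/marker intensities sampled along one line scan.

    Positions are in micrometres, strictly increasing and uniformly spaced;
    increasing position is the luminal (distal) direction.
    """

    positions: np.ndarray
    ref_intensity: np.ndarray
    marker_intensity: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ref = np.asarray(self.ref_intensity, dtype=float)
        mar = np.asarray(self.marker_intensity, dtype=float)
        if not (pos.shape == ref.shape == mar.shape) or pos.ndim != 1:
            raise InvalidParameterError("positions and channels must be equal-length 1-D arrays")
        if pos.size < 2:
            raise InvalidParameterError("a profile needs at least two samples")
        steps = np.diff(pos)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise InvalidParameterError("positions must be strictly increasing and uniform")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(ref)) and np.all(np.isfinite(mar))):
            raise InvalidParameterError("profile values must be finite")
        if np.any(ref < 0) or np.any(mar < 0):
            raise InvalidParameterError("intensities must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ref_intensity", ref)
        object.__setattr__(self, "marker_intensity", mar)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class AlignedProfilePair:
    """A profile pair after per-channel normalization and alignment.

    ``offsets`` are micrometres relative to the reference maximum (0 at the
    reference max, first occurrence on ties); both channels are divided by
    their own maximum so ``ref_norm`` attains exactly 1 at offset 0.
    """

    offsets: np.ndarray
    ref_norm: np.ndarray
    marker_norm: np.ndarray


@dataclass(frozen=True)
class ColocResult:
    """Thresholded correlation between the two aligned channels.

    ``coefficient`` is NaN when fewer than 3 samples survive the threshold
    or a retained vector is constant; ``reason`` then says why.
    """

    coefficient: float
    n_used: int
    method: str
    threshold: float
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.coefficient)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney comparison of two coefficient groups."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" or "asymptotic"


# ---------------------------------------------------------------------------
# extraction


def extract_line_profile(
    image,
    endpoints,
    width_px: int = DEFAULT_LINE_WIDTH_PX,
) -> LineScanProfile:
    """Sample a two-channel image along a line with perpendicular averaging.

    Parameters
    ----------
    image : ImageGrid
        Two-channel image (channel 0 = reference, channel 1 = marker) with
        ``pixels`` of shape (2, H, W) and ``pixel_size`` in micrometres.
    endpoints : pair of (x, y) points in micrometres
        Scan start and end; the scan direction (first to second endpoint)
        is the luminal direction.
    width_px : int
        Number of equally spaced perpendicular offsets averaged per sample
        (the "line width" of the line tool), default 12.

    Returns one sample per pixel step along the line, each the mean of
    ``width_px`` bilinear interpolations perpendicular to the line.
    """
    pix = np.asarray(image.pixels, dtype=float)
    if pix.ndim != 3 or pix.shape[0] != 2:
        raise InvalidParameterError("extract_line_profile needs a two-channel image (2, H, W)")
    if width_px < 1:
        raise InvalidParameterError("width_px must be >= 1")
    ps = image.pixel_size
    origin = getattr(image, "origin", (0.0, 0.0))
    (x0, y0), (x1, y1) = endpoints
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length < 2.0 * ps:
        raise DegenerateLineError("endpoints closer than 2 pixels")
    n_steps = int(np.floor(length / ps))
    t = np.linspace(0.0, n_steps * ps, n_steps + 1)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    # perpendicular unit vector; offsets centered on the line, 1 px apart
    vx, vy = -uy, ux
    offs = (np.arange(width_px) - (width_px - 1) / 2.0) * ps
    xs = x0 + t[:, None] * ux + offs[None, :] * vx
    ys = y0 + t[:, None] * uy + offs[None, :] * vy
    # micrometres -> fractional pixel indices (pixel centers at (i + 0.5) * ps)
    cols = (xs - origin[0]) / ps - 0.5
    rows = (ys - origin[1]) / ps - 0.5
    coords = np.stack([rows.ravel(), cols.ravel()])
    chans = []
    for c in range(2):
        samp = ndimage.map_coordinates(pix[c], coords, order=1, mode="nearest")
        chans.append(samp.reshape(xs.shape).mean(axis=1))
    ref, mar = (np.clip(c, 0.0, None) for c in chans)
    return LineScanProfile(positions=t, ref_intensity=ref, marker_intensity=mar)


# ---------------------------------------------------------------------------
# normalization / alignment


def normalize_align(profile: LineScanProfile) -> AlignedProfilePair:
    """Normalize each channel to max 1 and center on the reference maximum.

    The reference maximum position (first occurrence on exact ties) becomes
    offset 0; no resampling is performed.  Raises :class:`CannotAlignError`
    for an all-zero reference channel.
    """
    ref = profile.ref_intensity
    mar = profile.marker_intensity
    ref_max = float(ref.max())
    if ref_max <= 0.0:
        raise CannotAlignError("reference channel has no positive maximum")
    i_max = int(np.argmax(ref))  # first occurrence
    mar_max = float(mar.max())
    mar_norm = mar / mar_max if mar_max > 0 else mar.copy()
    return AlignedProfilePair(
        offsets=profile.positions - profile.positions[i_max],
        ref_norm=ref / ref_max,
        marker_norm=mar_norm,
    )


def profile_envelope(pairs, channel: str = "marker", bin_width: float | None = None) -> pd.DataFrame:
    """Per-offset mean/min/max envelope over a batch of aligned pairs.

    Offsets are binned to ``bin_width`` (default: the median sample spacing
    of the batch) so profiles whose alignment shifted them onto staggered
    grids still aggregate.  Returns a DataFrame with columns
    ``offset, mean, min, max, n``.
    """
    if channel not in ("marker", "ref"):
        raise InvalidParameterError("channel must be 'marker' or 'ref'")
    pairs = list(pairs)
    if not pairs:
        raise InvalidParameterError("need at least one aligned pair")
    if bin_width is None:
        bin_width = float(np.median([np.median(np.diff(p.offsets)) for p in pairs]))
    offs = np.concatenate([p.offsets for p in pairs])
    vals = np.concatenate([getattr(p, f"{channel}_norm") for p in pairs])
    bins = np.round(offs / bin_width).astype(int)
    df = pd.DataFrame({"bin": bins, "value": vals})
    agg = df.groupby("bin")["value"].agg(["mean", "min", "max", "count"]).reset_index()
    agg["offset"] = agg["bin"] * bin_width
    return agg.rename(columns={"count": "n"})[["offset", "mean", "min", "max", "n"]]


# ---------------------------------------------------------------------------
# colocalization


def coloc_coefficient(
    pair: AlignedProfilePair,
    threshold: float = 0.7,
    method: str = "spearman",
    threshold_channel: str = "ref",
) -> ColocResult:
    """Correlation between the channels over above-threshold samples.

    Samples where the normalized reference exceeds ``threshold`` (the
    brush-border region, defined by the full-length reference marker) enter
    the correlation; ``threshold_channel='both'`` additionally requires the
    marker channel to exceed it.  Spearman uses average ranks on ties.
    The coefficient is reported as missing (NaN, with a reason) when fewer
    than 3 samples are retained or a retained vector is constant.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidParameterError("threshold must be in [0, 1)")
    if method not in ("spearman", "pearson"):
        raise InvalidParameterError("method must be 'spearman' or 'pearson'")
    keep = pair.ref_norm > threshold
    if threshold_channel == "both":
        keep &= pair.marker_norm > threshold
    elif threshold_channel != "ref":
        raise InvalidParameterError("threshold_channel must be 'ref' or 'both'")
    r = pair.ref_norm[keep]
    m = pair.marker_norm[keep]
    n_used = int(keep.sum())
    if n_used < 3:
        return ColocResult(np.nan, n_used, method, threshold, reason="fewer than 3 samples above threshold")
    if np.ptp(r) == 0.0 or np.ptp(m) == 0.0:
        return ColocResult(np.nan, n_used, method, threshold, reason="constant retained vector")
    if method == "spearman":
        coef = float(stats.spearmanr(r, m).statistic)
    else:
        coef = float(stats.pearsonr(r, m).statistic)
    return ColocResult(coef, n_used, method, threshold)


def compare_groups(coeffs_a, coeffs_b) -> GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney test between two coefficient groups.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no cross-sample ties, and the tie-corrected normal
    approximation (without continuity correction) otherwise.  Missing (NaN)
    coefficients are dropped; each group needs >= 3 remaining values.
    """
    a = np.asarray([c for c in np.asarray(coeffs_a, dtype=float) if np.isfinite(c)])
    b = np.asarray([c for c in np.asarray(coeffs_b, dtype=float) if np.isfinite(c)])
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 non-missing coefficients")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        how = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        how = "asymptotic"
    return GroupComparison(float(res.statistic), float(res.pvalue), a.size, b.size, how)


# ---------------------------------------------------------------------------
# AUC / signal-length quantification


def profile_auc(positions, intensities) -> float:
    """Trapezoidal area under an intensity profile (intensity * um)."""
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(intensities, dtype=float)
    if pos.size < 2:
        raise InvalidParameterError("AUC needs at least 2 samples")
    return float(np.trapezoid(vals, pos))


def signal_length(positions, intensities, level: float = 0.5) -> float:
    """Extent of the longest contiguous run at or above ``level`` x max.

    Intensities are normalized to the channel maximum; the two boundary
    crossings of the longest run are located by linear interpolation, so a
    rectangular pulse of width w returns exactly w.  Returns 0 when the
    channel never reaches the level (or has no positive maximum).
    """
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(intensities, dtype=float)
    vmax = vals.max(initial=0.0)
    if vmax <= 0.0:
        return 0.0
    norm = vals / vmax
    above = norm >= level
    if not above.any():
        return 0.0
    # contiguous runs of above-level samples
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    best = 0.0
    for s, e in zip(starts, ends):
        left = pos[s]
        if s > 0:
            # interpolate the upward crossing between s-1 and s
            f = (level - norm[s - 1]) / (norm[s] - norm[s - 1])
            left = pos[s - 1] + f * (pos[s] - pos[s - 1])
        right = pos[e]
        if e < pos.size - 1:
            f = (norm[e] - level) / (norm[e] - norm[e + 1])
            right = pos[e] + f * (pos[e + 1] - pos[e])
        best = max(best, right - left)
    return float(best)


def auc_per_length(auc: float, length: float) -> float:
    """AUC normalized to signal length; NaN (missing) for zero length.

    Dividing the area under an apical-marker profile by the length of its
    fluorescence signal converts total signal into signal per unit brush
    border, the normalization that removes microvillus-shortening effects
    from relative protein-level comparisons.
    """
    if length < 0:
        raise InvalidParameterError("length must be non-negative")
    if length == 0:
        return float("nan")
    return float(auc) / float(length)
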