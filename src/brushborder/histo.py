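"""Colitis scoring, FISH bacterial counting, mucus thickness, weight AUC.

Composite colitis score: blinded sub-scores for inflammation (0-3), crypt
damage (0-5) and ulceration (0-3) are summed (max 11) and multiplied by an
affected-area factor (1-4 for quarters of the colon), giving a total of at
most 44.

FISH invasion counting: Cy3-positive signals are counted as bacteria only
if they are not nuclear (negative-control probes produce false positives
inside nuclei) and not green/Cy3 double-positive (fecal autofluorescence);
counted signals are related to the total cell number of the field.

Mucus layer thickness is sampled at arc-length-uniform points along the
epithelial boundary annotation (>= 11 measurements, then averaged), and
weight-loss curves are compared by per-mouse trapezoidal AUC with one-way
ANOVA and Tukey post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

from .errors import (
    InsufficientDataError,
    InvalidAnnotationError,
    InvalidInputError,
    InvalidParameterError,
)
from .sections import Polyline
from .synthetic import FishSignal, WeightCurve

__all__ = [
    "ColitisSubScores",
    "FISH_LABELS",
    "area_multiplier",
    "colitis_score",
    "classify_fish_signal",
    "invasion_rate",
    "layer_thickness",
    "weight_auc_test",
    "WeightAucResult",
]

FISH_LABELS = ("counted", "excluded_nuclear", "excluded_autofluor", "negative")

# default classification cuts; the study never quantified its visual
# "Cy3-positive"/"green-positive" calls, so these are free parameters
DEFAULT_CY3_CUT = 50.0
DEFAULT_GREEN_CUT = 50.0
DEFAULT_NUCLEAR_CUT = 0.3


@dataclass(frozen=True)
class ColitisSubScores:
    """Blinded histopathology sub-scores for one mouse."""

    inflammation: int  # 0-3
    crypt_damage: int  # 0-5
    ulceration: int  # 0-3
    affected_fraction: float  # fraction of the colon affected, [0, 1]

    def __post_init__(self) -> None:
        if not (isinstance(self.inflammation, (int, np.integer)) and 0 <= self.inflammation <= 3):
            raise InvalidInputError("inflammation score must be an integer in 0-3")
        if not (isinstance(self.crypt_damage, (int, np.integer)) and 0 <= self.crypt_damage <= 5):
            raise InvalidInputError("crypt damage score must be an integer in 0-5")
        if not (isinstance(self.ulceration, (int, np.integer)) and 0 <= self.ulceration <= 3):
            raise InvalidInputError("ulceration score must be an integer in 0-3")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise InvalidInputError("affected_fraction must be in [0, 1]")


def area_multiplier(affected_fraction: float) -> int:
    """Affected-area multiplication factor: quarters of the colon -> 1..4.

    Band boundaries are assigned lower-inclusive upward (0.25 -> 1,
    0.50 -> 2, 0.75 -> 3): the rubric's printed bands overlap at the
    quarter boundaries, so a deterministic convention is required.
    """
    if not 0.0 <= affected_fraction <= 1.0:
        raise InvalidInputError("affected_fraction must be in [0, 1]")
    if affected_fraction <= 0.25:
        return 1
    if affected_fraction <= 0.50:
        return 2
    if affected_fraction <= 0.75:
        return 3
    return 4


def colitis_score(sub: ColitisSubScores) -> tuple[int, int]:
    """(raw sum 0-11, total 0-44 = raw sum x area multiplier)."""
    raw = sub.inflammation + sub.crypt_damage + sub.ulceration
    return int(raw), int(raw * area_multiplier(sub.affected_fraction))


# ---------------------------------------------------------------------------
# FISH classification


def classify_fish_signal(
    signal: FishSignal,
    cy3_cut: float = DEFAULT_CY3_CUT,
    green_cut: float = DEFAULT_GREEN_CUT,
    nuclear_cut: float = DEFAULT_NUCLEAR_CUT,
) -> str:
    """Classify one Cy3 signal by the exclusion rules, in decision order.

    1. Cy3 at or below the cut -> ``negative`` (not a signal at all);
    2. nuclear overlap above the cut -> ``excluded_nuclear``;
    3. green channel above the cut -> ``excluded_autofluor``
       (Cy3/green double-positive = fecal autofluorescence);
    4. otherwise ``counted`` as a bacterium.
    """
    if cy3_cut < 0 or green_cut < 0 or nuclear_cut < 0:
        raise InvalidParameterError("cuts must be non-negative")
    if signal.cy3_intensity <= cy3_cut:
        return "negative"
    if signal.nuclear_overlap_frac > nuclear_cut:
        return "excluded_nuclear"
    if signal.green_intensity > green_cut:
        return "excluded_autofluor"
    return "counted"


def invasion_rate(
    signals,
    total_cells: int,
    cy3_cut: float = DEFAULT_CY3_CUT,
    green_cut: float = DEFAULT_GREEN_CUT,
    nuclear_cut: float = DEFAULT_NUCLEAR_CUT,
) -> float:
    """Counted bacteria per total intestinal cell of the field."""
    if total_cells <= 0:
        raise InvalidInputError("total_cells must be positive")
    n_counted = sum(
        1
        for s in signals
        if classify_fish_signal(s, cy3_cut, green_cut, nuclear_cut) == "counted"
    )
    return n_counted / total_cells


# ---------------------------------------------------------------------------
# mucus layer thickness


def layer_thickness(
    inner: Polyline, outer: Polyline, n_samples: int = 11
) -> tuple[np.ndarray, float]:
    """Mucus-layer thickness between two boundary annotations.

    At ``n_samples`` arc-length-uniform points along the inner (epithelial)
    boundary, the distance to the nearest point of the outer (luminal)
    boundary is measured; the per-sample thicknesses and their mean are
    returned.  Point-to-polyline distance is used rather than normal-ray
    casting: it is identical for parallel boundaries and robust to
    annotation jitter.  Properly crossing annotations are rejected.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    inner_ls = LineString(inner.vertices)
    outer_ls = LineString(outer.vertices)
    if inner_ls.crosses(outer_ls):
        raise InvalidAnnotationError("boundary annotations cross each other")
    fracs = np.linspace(0.0, 1.0, n_samples)
    samples = np.array(
        [outer_ls.distance(inner_ls.interpolate(f, normalized=True)) for f in fracs]
    )
    return samples, float(samples.mean())


# ---------------------------------------------------------------------------
# weight-curve AUC comparison


@dataclass(frozen=True)
class WeightAucResult:
    """Per-mouse weight AUCs by group with one-way ANOVA and Tukey HSD."""

    aucs: dict  # group -> np.ndarray of per-mouse AUC (% x days)
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_value


def weight_auc_test(curves_by_group: dict) -> WeightAucResult:
    """Trapezoidal weight AUC per mouse, compared across groups.

    All curves must share the same day grid; at least 2 groups with >= 3
    mice each are required.  The group effect is tested with one-way ANOVA
    and Tukey-style pairwise comparisons (the study's post-hoc tests —
    Tukey, Bonferroni, Dunn — agreed, so one default suffices).
    """
    groups = list(curves_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    ref_days = None
    aucs: dict = {}
    for g in groups:
        curves = list(curves_by_group[g])
        if len(curves) < 3:
            raise InsufficientDataError(f"group {g!r} needs at least 3 mice")
        vals = []
        for c in curves:
            if ref_days is None:
                ref_days = c.days
            elif not np.array_equal(c.days, ref_days):
                raise InvalidInputError("all weight curves must share the same day grid")
            vals.append(float(np.trapezoid(c.relative_weight, c.days)))
        aucs[g] = np.asarray(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_res = stats.f_oneway(*aucs.values())
        tukey = stats.tukey_hsd(*aucs.values())
    rows = []
    for i, ga in enumerate(groups):
        for j in range(i + 1, len(groups)):
            rows.append({"group_a": ga, "group_b": groups[j], "p_value": float(tukey.pvalue[i, j])})
    return WeightAucResult(
        aucs=aucs,
        f_statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        pairwise=pd.DataFrame(rows),
    )
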