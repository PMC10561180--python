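"""File I/O: TIFF images with JSON sidecars, and CSV tables.

Images are written as 16-bit grayscale TIFF with the pixel size (um) and
origin recorded in an adjacent ``<name>.meta.json`` sidecar — sidecars
rather than TIFF tags keep the metadata independent of TIFF dialects.
Point patterns, profiles and FISH tables are CSV with a header row;
coordinates are 0-based micrometres, origin top-left, y increasing
downward.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidParameterError
from .profiles import LineScanProfile
from .synthetic import FishSignal, ImageGrid, PointPattern

__all__ = [
    "save_image",
    "load_image",
    "points_to_csv",
    "points_from_csv",
    "profiles_to_csv",
    "profiles_from_csv",
    "fish_to_csv",
    "fish_from_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_image(image: ImageGrid, path) -> None:
    """Write an ImageGrid as 16-bit TIFF plus a .meta.json sidecar."""
    path = Path(path)
    pix = np.asarray(image.pixels, dtype=float)
    vmax = pix.max(initial=0.0)
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    tifffile.imwrite(path, np.round(pix * scale).astype(np.uint16))
    meta = {
        "pixel_size_um": image.pixel_size,
        "origin_um": list(image.origin),
        "intensity_scale": scale,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_image(path) -> ImageGrid:
    """Read a TIFF and its sidecar back into an ImageGrid."""
    path = Path(path)
    pix = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidParameterError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    scale = meta.get("intensity_scale", 1.0)
    return ImageGrid(
        pixels=pix / scale,
        pixel_size=meta["pixel_size_um"],
        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
    )


def points_to_csv(pattern: PointPattern, path) -> None:
    df = pd.DataFrame(pattern.points, columns=["x_um", "y_um"])
    df.attrs = {}
    header = f"# field_width_um={pattern.field_width} field_height_um={pattern.field_height}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def points_from_csv(path) -> PointPattern:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise InvalidParameterError("points CSV must start with a field-size comment")
        fields = dict(tok.split("=") for tok in first[1:].split())
        df = pd.read_csv(fh)
    return PointPattern(
        points=df[["x_um", "y_um"]].to_numpy(),
        field_width=float(fields["field_width_um"]),
        field_height=float(fields["field_height_um"]),
    )


def profiles_to_csv(profiles, path) -> None:
    rows = []
    for i, p in enumerate(profiles):
        rows.append(
            pd.DataFrame(
                {
                    "profile_id": i,
                    "position_um": p.positions,
                    "ref_intensity": p.ref_intensity,
                    "marker_intensity": p.marker_intensity,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def profiles_from_csv(path) -> list[LineScanProfile]:
    df = pd.read_csv(path)
    out = []
    for _, g in df.groupby("profile_id", sort=True):
        out.append(
            LineScanProfile(
                positions=g["position_um"].to_numpy(),
                ref_intensity=g["ref_intensity"].to_numpy(),
                marker_intensity=g["marker_intensity"].to_numpy(),
            )
        )
    return out


def fish_to_csv(signals, path) -> None:
    pd.DataFrame(
        [
            {
                "x_um": s.x,
                "y_um": s.y,
                "cy3_intensity": s.cy3_intensity,
                "green_intensity": s.green_intensity,
                "nuclear_overlap_frac": s.nuclear_overlap_frac,
                "true_class": s.true_class,
            }
            for s in signals
        ]
    ).to_csv(path, index=False)


def fish_from_csv(path) -> list[FishSignal]:
    df = pd.read_csv(path)
    return [
        FishSignal(
            x=r.x_um,
            y=r.y_um,
            cy3_intensity=r.cy3_intensity,
            green_intensity=r.green_intensity,
            nuclear_overlap_frac=r.nuclear_overlap_frac,
            true_class=r.true_class,
        )
        for r in df.itertuples()
    ]
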