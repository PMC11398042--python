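"""Color-pixel counting and background-artifact detection.

Pixels of decomposed images are credited to palette entries by CIE76
distance (Euclidean distance in CIELAB, sRGB D65 2-degree observer) within
a matching tolerance; counts are normalized by the white-annotated
bone-reference count to give %color pixels.  Colored pixels falling
outside the limb are background artifacts (e.g. hair decomposed like soft
tissue); their fraction of the white reference grades the image group as
mild, moderate, or severe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import closing, disk, remove_small_holes

from .decomposition import ColorMap, DecomposedImageSet, hex_to_rgb
from .phantom import Radiograph

__all__ = [
    "PixelCount",
    "PercentColorResult",
    "ArtifactReport",
    "SEVERITY_THRESHOLDS",
    "mask_standard_region",
    "wedge_polygon",
    "mask_standard_in_set",
    "cie76_delta_e",
    "count_color_pixels",
    "percent_color",
    "detect_artifacts",
    "estimate_limb_mask",
    "results_to_frame",
]

#: Artifact-fraction grading thresholds (fraction of the white reference).
#: These operational cut-offs are configuration, not measured facts:
#: mild (0.005, 0.05], moderate (0.05, 0.20], severe > 0.20.
SEVERITY_THRESHOLDS = (0.005, 0.05, 0.20)


@dataclass(frozen=True)
class PixelCount:
    label: str
    color: str
    count: int
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("pixel count cannot be negative")


@dataclass
class PercentColorResult:
    """Per-step %color pixels against the white (bone) reference count."""

    percents: dict[int, float]
    white_count: int
    exposure: object = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.percents.values()):
            raise ValueError("percentages cannot be negative")


@dataclass
class ArtifactReport:
    """Per-step background-artifact pixels, flags and the group severity."""

    artifact_pixels: dict[int, int]
    fractions: dict[int, float]
    flagged: dict[int, bool]
    severity: str
    n_flagged_steps: int
    white_count: int
    source_id: str = ""

    @property
    def flagged_steps(self) -> list[int]:
        return [s for s, f in self.flagged.items() if f]


def mask_standard_region(image: np.ndarray, region) -> np.ndarray:
    """Paint the polygon region black (#000000): the density standard is
    excluded from counting, and the remaining non-black area becomes the
    counting domain."""
    region = np.asarray(region, dtype=float)
    if region.ndim != 2 or region.shape[0] < 3 or region.shape[1] != 2:
        raise ValueError("region must be a polygon of >= 3 (row, col) vertices")
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    nrow, ncol = arr.shape[:2]
    if (
        (region[:, 0] < 0).any()
        or (region[:, 0] > nrow).any()
        or (region[:, 1] < 0).any()
        or (region[:, 1] > ncol).any()
    ):
        raise ValueError("polygon vertices outside image bounds")
    rr, cc = _draw_polygon(region[:, 0], region[:, 1], shape=(nrow, ncol))
    out = arr.copy()
    out[rr, cc] = 0
    return out


def wedge_polygon(
    layout,
    original_shape: tuple[int, int],
    size: tuple[int, int] | None = None,
    pad: float = 2.0,
) -> np.ndarray:
    """Rectangle polygon covering the density standard's footprints, in the
    coordinates of the (optionally resized) decomposed images."""
    r0 = min(f[0] for f in layout.footprints) - pad
    r1 = max(f[1] for f in layout.footprints) + pad
    c0 = min(f[2] for f in layout.footprints) - pad
    c1 = max(f[3] for f in layout.footprints) + pad
    if size is not None:
        sr = size[1] / original_shape[0]
        sc = size[0] / original_shape[1]
        r0, r1, c0, c1 = r0 * sr, r1 * sr, c0 * sc, c1 * sc
        nrow, ncol = size[1], size[0]
    else:
        nrow, ncol = original_shape
    r0, r1 = max(r0, 0), min(r1, nrow)
    c0, c1 = max(c0, 0), min(c1, ncol)
    return np.array([(r0, c0), (r0, c1), (r1, c1), (r1, c0)], dtype=float)


def mask_standard_in_set(dset: DecomposedImageSet, region) -> DecomposedImageSet:
    """Apply the #000000 standard mask to all eleven images of a set."""
    for step in list(dset.color_images):
        dset.color_images[step] = mask_standard_region(dset.color_images[step], region)
    dset.white_image = mask_standard_region(dset.white_image, region)
    return dset


def _hex_to_lab(code: str) -> np.ndarray:
    rgb = np.asarray(hex_to_rgb(code), dtype=float).reshape(1, 1, 3) / 255.0
    return _skcolor.rgb2lab(rgb)[0, 0]


def cie76_delta_e(c1: str, c2: str) -> float:
    """CIE76 color difference: Euclidean distance in CIELAB.

    Black-white spans exactly 100 (L* 0 vs 100 with a* = b* = 0).
    """
    lab1, lab2 = _hex_to_lab(c1), _hex_to_lab(c2)
    return float(np.sqrt(((lab1 - lab2) ** 2).sum()))


def _image_lab_counts(image: np.ndarray):
    """Unique colors of the counting domain (non-black pixels) with their
    multiplicities and Lab coordinates."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    flat = arr.reshape(-1, 3).astype(np.uint32)
    packed = (flat[:, 0] << 16) | (flat[:, 1] << 8) | flat[:, 2]
    codes, counts = np.unique(packed[packed != 0], return_counts=True)  # non-#000000
    colors = np.stack(
        [(codes >> 16) & 0xFF, (codes >> 8) & 0xFF, codes & 0xFF], axis=1
    ).astype(np.uint8)
    if colors.size == 0:
        return colors, counts, np.empty((0, 3))
    labs = _skcolor.rgb2lab(colors.reshape(-1, 1, 3).astype(float) / 255.0)[:, 0, :]
    return colors, counts, labs


def count_color_pixels(
    image: np.ndarray,
    palette: ColorMap | dict[str, str],
    tolerance: float = 10.0,
    image_id: str = "",
) -> list[PixelCount]:
    """Credit each counting-domain pixel to the nearest palette entry.

    A pixel counts toward the palette entry with the smallest CIE76
    distance, provided that distance is within ``tolerance``; ties go to
    the lowest step index.  Black (#000000) pixels are the masked density
    standard and are excluded from the domain; pixels beyond tolerance
    (e.g. the background sentinel) stay uncounted.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    labels_hex = palette.palette_labels() if isinstance(palette, ColorMap) else dict(palette)
    if not labels_hex:
        raise ValueError("empty palette")
    labels = list(labels_hex)
    pal_lab = np.stack([_hex_to_lab(h) for h in labels_hex.values()])

    colors, counts, labs = _image_lab_counts(image)
    totals = dict.fromkeys(labels, 0)
    if colors.size:
        d = np.sqrt(((labs[:, None, :] - pal_lab[None, :, :]) ** 2).sum(axis=2))
        nearest = d.argmin(axis=1)  # argmin takes the first (lowest index) on ties
        within = d[np.arange(len(colors)), nearest] <= tolerance
        for idx, cnt in zip(nearest[within], counts[within]):
            totals[labels[idx]] += int(cnt)
    return [
        PixelCount(label, labels_hex[label], totals[label], image_id)
        for label in labels
    ]


def percent_color(
    counts: dict[int, int], white_count: int, exposure=None, source_id: str = ""
) -> PercentColorResult:
    """%color pixels per step: 100 * count_s / white_count."""
    if white_count <= 0:
        raise ValueError("white reference count is zero: no bone annotation")
    return PercentColorResult(
        percents={s: 100.0 * c / white_count for s, c in counts.items()},
        white_count=int(white_count),
        exposure=exposure,
        source_id=source_id,
    )


def _white_count(dset: DecomposedImageSet) -> int:
    white_rgb = np.asarray(hex_to_rgb(dset.colormap.white), dtype=np.uint8)
    return int((dset.white_image == white_rgb).all(axis=2).sum())


def detect_artifacts(
    dset: DecomposedImageSet,
    limb_mask: np.ndarray,
    thresholds: tuple[float, float, float] = SEVERITY_THRESHOLDS,
) -> ArtifactReport:
    """Count colored pixels outside the limb per step and grade severity.

    A step is flagged when its artifact fraction (artifact pixels divided
    by the white reference count) exceeds the mild threshold; the group
    severity is the maximum grade over steps.
    """
    limb_mask = np.asarray(limb_mask, dtype=bool)
    if limb_mask.shape != dset.white_image.shape[:2]:
        raise ValueError("limb mask is not aligned to the decomposed images")
    mild, moderate, severe = thresholds
    white = _white_count(dset)
    if white <= 0:
        raise ValueError("white reference count is zero: no bone annotation")

    artifact_pixels, fractions, flagged = {}, {}, {}
    worst = 0.0
    for step, img in dset.color_images.items():
        rgb = np.asarray(hex_to_rgb(dset.colormap.color(step)), dtype=np.uint8)
        colored = (img == rgb).all(axis=2)
        n_out = int((colored & ~limb_mask).sum())
        f = n_out / white
        artifact_pixels[step] = n_out
        fractions[step] = f
        flagged[step] = f > mild
        worst = max(worst, f)

    if worst > severe:
        grade = "severe"
    elif worst > moderate:
        grade = "moderate"
    elif worst > mild:
        grade = "mild"
    else:
        grade = "none"
    return ArtifactReport(
        artifact_pixels=artifact_pixels,
        fractions=fractions,
        flagged=flagged,
        severity=grade,
        n_flagged_steps=sum(flagged.values()),
        white_count=white,
        source_id=dset.source_id,
    )


def estimate_limb_mask(
    radiograph: Radiograph,
    hu_threshold: float = -500.0,
    closing_radius: int = 5,
    exclude_wedge: bool = True,
) -> np.ndarray:
    """Threshold-plus-morphology limb segmentation for real radiographs.

    Pixels denser than ``hu_threshold`` are foreground; the wedge footprint
    (if known) is removed, the mask is closed, small holes are filled, and
    the largest connected component is kept.  Synthetic runs should prefer
    the generator's ground-truth mask.
    """
    from scipy import ndimage

    fg = radiograph.pixels > hu_threshold
    if exclude_wedge and radiograph.wedge_layout is not None:
        for r0, r1, c0, c1 in radiograph.wedge_layout.footprints:
            fg[max(0, r0 - 2) : r1 + 2, max(0, c0 - 2) : c1 + 2] = False
    fg = closing(fg, disk(closing_radius))
    fg = remove_small_holes(fg, max_size=64 * 64)
    labels, n = ndimage.label(fg)
    if n == 0:
        return fg
    sizes = ndimage.sum(fg, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(sizes.argmax()))


def results_to_frame(
    percents: list[PercentColorResult], artifacts: list[ArtifactReport] | None = None
) -> pd.DataFrame:
    """Tidy results: one row per (source, setting, step)."""
    art_by_id = {a.source_id: a for a in artifacts} if artifacts else {}
    rows = []
    for res in percents:
        art = art_by_id.get(res.source_id)
        for step, pct in sorted(res.percents.items()):
            rows.append(
                {
                    "source_id": res.source_id,
                    "kv": getattr(res.exposure, "kv", np.nan),
                    "mas": getattr(res.exposure, "mas", np.nan),
                    "step": step,
                    "percent": pct,
                    "white_count": res.white_count,
                    "artifact_pixels": art.artifact_pixels[step] if art else 0,
                    "flagged": art.flagged[step] if art else False,
                    "severity": art.severity if art else "none",
                }
            )
    return pd.DataFrame(rows)
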