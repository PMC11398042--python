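"""Radiograph decomposition into color-annotated and white-annotated images.

Each relative-density range is painted with its assigned palette color over
a fixed background sentinel, yielding ten color-annotated images per
radiograph; painting the union of all ten ranges white (restricted to the
limb) yields the white-annotated bone-reference image.  All eleven images
are resized to 899x847 with nearest-neighbor interpolation -- any
interpolating kernel would invent colors outside the categorical palette
before pixel counting -- and written as 24-bit uncompressed BMP files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .calibration import CalibrationTable, StepRange
from .phantom import Radiograph

__all__ = [
    "ColorMap",
    "TABLE1_PALETTE",
    "DecomposedImageSet",
    "OUTPUT_SIZE",
    "hex_to_rgb",
    "rgb_to_hex",
    "mask_in_range",
    "white_annotation",
    "decompose",
    "resize_nearest",
    "write_bmp",
    "read_bmp",
    "write_image_set",
]

#: Output raster size, (width, height) in pixels.
OUTPUT_SIZE = (899, 847)


def hex_to_rgb(code: str) -> tuple[int, int, int]:
    code = code.strip()
    if not (code.startswith("#") and len(code) == 7):
        raise ValueError(f"malformed HEX color {code!r}")
    try:
        return tuple(int(code[i : i + 2], 16) for i in (1, 3, 5))
    except ValueError:
        raise ValueError(f"malformed HEX color {code!r}") from None


def rgb_to_hex(rgb) -> str:
    r, g, b = (int(v) for v in rgb)
    return f"#{r:02X}{g:02X}{b:02X}"


@dataclass(frozen=True)
class ColorMap:
    """Step -> HEX palette plus the white/black/background sentinels."""

    step_colors: dict[int, str]
    white: str = "#FFFFFF"
    standard_mask: str = "#000000"
    background: str = "#404040"

    def __post_init__(self) -> None:
        if sorted(self.step_colors) != list(range(1, 11)):
            raise ValueError("palette needs colors for steps 1..10 exactly")
        everything = list(self.step_colors.values()) + [
            self.white,
            self.standard_mask,
            self.background,
        ]
        normalized = [rgb_to_hex(hex_to_rgb(c)) for c in everything]
        if len(set(normalized)) != len(normalized):
            raise ValueError("palette entries must be pairwise distinct")

    def color(self, step: int) -> str:
        return self.step_colors[step]

    def palette_labels(self) -> dict[str, str]:
        """label -> hex for counting: S1..S10 plus 'white'."""
        out = {f"S{s}": c for s, c in self.step_colors.items()}
        out["white"] = self.white
        return out


#: The study palette: colors assigned to wedge steps S1-S10.
TABLE1_PALETTE = ColorMap(
    step_colors={
        1: "#FFFF00",
        2: "#E08000",
        3: "#FF0000",
        4: "#E080C0",
        5: "#800080",
        6: "#0000FF",
        7: "#008000",
        8: "#808000",
        9: "#00FF00",
        10: "#A6CAF0",
    }
)


def _paint(mask: np.ndarray, color_hex: str, background_hex: str) -> np.ndarray:
    out = np.empty(mask.shape + (3,), dtype=np.uint8)
    out[...] = hex_to_rgb(background_hex)
    out[mask] = hex_to_rgb(color_hex)
    return out


def mask_in_range(
    radiograph: Radiograph | np.ndarray,
    rng: StepRange,
    color: str,
    background: str = "#404040",
) -> np.ndarray:
    """RGB raster with `color` wherever min_hu <= HU <= max_hu (closed
    interval, both bounds attained sample values), background elsewhere."""
    hu = radiograph.pixels if isinstance(radiograph, Radiograph) else np.asarray(radiograph)
    mask = (hu >= rng.min_hu) & (hu <= rng.max_hu)
    return _paint(mask, color, background)


def white_annotation(
    radiograph: Radiograph | np.ndarray,
    table: CalibrationTable,
    limb_mask: np.ndarray,
    white: str = "#FFFFFF",
    background: str = "#404040",
) -> np.ndarray:
    """Bone-reference image: white where the HU lies in the union of the ten
    ranges AND the pixel is inside the limb; background elsewhere.

    Restricting the white reference to the limb is what lets background
    artifacts push %color pixels beyond 100%: stray colored background
    pixels inflate the numerator but never the denominator.
    """
    hu = radiograph.pixels if isinstance(radiograph, Radiograph) else np.asarray(radiograph)
    limb_mask = np.asarray(limb_mask, dtype=bool)
    if limb_mask.shape != hu.shape:
        raise ValueError("limb mask shape does not match the radiograph")
    if not limb_mask.any():
        raise ValueError("empty limb mask: no bone-annotation reference")
    union = np.zeros_like(limb_mask)
    for r in table.ranges:
        union |= (hu >= r.min_hu) & (hu <= r.max_hu)
    return _paint(union & limb_mask, white, background)


def resize_nearest(image: np.ndarray, size: tuple[int, int] = OUTPUT_SIZE) -> np.ndarray:
    """Nearest-neighbor resize to (width, height); preserves the palette for
    RGB rasters and boolean masks alike."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        res = Image.fromarray(arr.astype(np.uint8) * 255).resize(size, Image.NEAREST)
        return np.asarray(res) > 127
    return np.asarray(Image.fromarray(arr).resize(size, Image.NEAREST))


@dataclass
class DecomposedImageSet:
    """Ten color-annotated images plus one white-annotated image, resized."""

    color_images: dict[int, np.ndarray]
    white_image: np.ndarray
    colormap: ColorMap
    source_id: str = ""
    exposure: object = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.color_images) != list(range(1, 11)):
            raise ValueError("decomposed set needs color images for steps 1..10")

    def __len__(self) -> int:
        return len(self.color_images) + 1

    def images(self):
        """Yield (name, image) for all eleven rasters, S1..S10 then white."""
        for step in range(1, 11):
            yield f"S{step}", self.color_images[step]
        yield "white", self.white_image


def decompose(
    radiograph: Radiograph,
    table: CalibrationTable,
    colormap: ColorMap = TABLE1_PALETTE,
    limb_mask: np.ndarray | None = None,
    size: tuple[int, int] = OUTPUT_SIZE,
) -> DecomposedImageSet:
    """Full decomposition of one radiograph: 10 color images + 1 white image,
    each resized to ``size`` with nearest-neighbor interpolation."""
    if limb_mask is None:
        limb_mask = radiograph.limb_mask_truth
    if limb_mask is None:
        raise ValueError("decompose needs a limb mask (none attached to radiograph)")
    color_images = {
        r.step: resize_nearest(
            mask_in_range(radiograph, r, colormap.color(r.step), colormap.background),
            size,
        )
        for r in table.ranges
    }
    white = resize_nearest(
        white_annotation(radiograph, table, limb_mask, colormap.white, colormap.background),
        size,
    )
    return DecomposedImageSet(
        color_images=color_images,
        white_image=white,
        colormap=colormap,
        source_id=radiograph.source_id,
        exposure=radiograph.exposure,
    )


def write_bmp(image: np.ndarray, path) -> None:
    """Write an 8-bit RGB raster as 24-bit uncompressed BMP (lossless)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("write_bmp expects an 8-bit RGB (H, W, 3) array")
    Image.fromarray(arr, mode="RGB").save(str(path), format="BMP")


def read_bmp(path) -> np.ndarray:
    """Read a BMP file back as an 8-bit RGB array; rejects other formats."""
    with Image.open(str(path)) as im:
        if im.format != "BMP":
            raise ValueError(f"{path} is not a BMP file (format={im.format})")
        return np.asarray(im.convert("RGB"))


def write_image_set(dset: DecomposedImageSet, outdir, joint: str = "joint") -> list:
    """Write all eleven images as `<joint>_<kv>kV_<mas>mAs_<name>.bmp`."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = dset.exposure
    kv = f"{exp.kv:g}" if exp is not None else "na"
    mas = f"{exp.mas:g}" if exp is not None else "na"
    paths = []
    for name, img in dset.images():
        p = outdir / f"{joint}_{kv}kV_{mas}mAs_{name}.bmp"
        write_bmp(img, p)
        paths.append(p)
    return paths
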