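"""Synthetic radiograph generator for computed digital absorptiometry (CDA).

Renders 2-D projection radiographs of an aluminum step wedge (the density
standard) lying beside a stylized feline knee, on an HU-like gray scale
anchored at air = -1000.  The generative model is monoenergetic
Beer-Lambert attenuation: each pixel accumulates an optical depth
``A = sum_m mu_m(kV) * t_m`` over the materials along its ray, and the
stored value is ``HU = hu_offset + hu_gain * A`` plus quantum noise whose
standard deviation scales as ``1/sqrt(mAs)``.

Tube voltage enters through the per-material attenuation tables (mu falls
with kV, so every wedge step darkens as kV rises); tube current enters
through the noise level and through an empirical dispersion term that
pulls the thin wedge steps down the HU scale at high mAs, emulating the
range scattering seen on overexposed radiographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExposureSetting",
    "WedgeSpec",
    "PhantomModel",
    "TissueStructure",
    "Radiograph",
    "STUDY_PRESETS",
    "CLUTTER_SEVERITIES",
    "default_model",
    "default_wedge",
    "default_knee",
    "effective_mu",
    "render_radiograph",
    "add_background_clutter",
    "write_dicom",
    "read_dicom",
    "write_png16",
]


@dataclass(frozen=True)
class ExposureSetting:
    """X-ray tube setting: voltage (kV) and current-time product (mAs)."""

    kv: float
    mas: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.kv > 0:
            raise ValueError(f"kV must be positive, got {self.kv}")
        if not self.mas > 0:
            raise ValueError(f"mAs must be positive, got {self.mas}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label or f"{self.kv:g} kV; {self.mas:g} mAs"


#: The five tube settings compared in the feline knee study.
STUDY_PRESETS: tuple[ExposureSetting, ...] = (
    ExposureSetting(50, 1.2, "50 kV; 1.2 mAs"),
    ExposureSetting(60, 1.2, "60 kV; 1.2 mAs"),
    ExposureSetting(60, 12, "60 kV; 12 mAs"),
    ExposureSetting(70, 1.2, "70 kV; 1.2 mAs"),
    ExposureSetting(80, 1.2, "80 kV; 1.2 mAs"),
)

CLUTTER_SEVERITIES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class WedgeSpec:
    """Aluminum density standard: 10 steps of strictly increasing thickness.

    ``step_heights_mm[k]`` is the aluminum path length of step S(k+1); S1 is
    the thinnest (lowest attenuation) and S10 the thickest.  ``footprints``
    are per-step axis-aligned rectangles ``(row0, row1, col0, col1)``
    (half-open) in image coordinates.
    """

    step_heights_mm: tuple[float, ...]
    footprints: tuple[tuple[int, int, int, int], ...]
    n_steps: int = 10
    density_g_cm3: float = 2.65
    mass_g: float = 9.39

    def __post_init__(self) -> None:
        if self.n_steps != 10:
            raise ValueError("the density standard has exactly 10 steps")
        if len(self.step_heights_mm) != self.n_steps:
            raise ValueError("need one height per step")
        if len(self.footprints) != self.n_steps:
            raise ValueError("need one footprint per step")
        h = self.step_heights_mm
        if any(b <= a for a, b in zip(h, h[1:])):
            raise ValueError("step heights must increase strictly from S1 to S10")
        if any(t <= 0 for t in h):
            raise ValueError("step heights must be positive")

    def footprint(self, step: int) -> tuple[int, int, int, int]:
        if not 1 <= step <= self.n_steps:
            raise ValueError(f"step must be in 1..{self.n_steps}, got {step}")
        return self.footprints[step - 1]


def default_wedge(
    image_shape: tuple[int, int] = (512, 512),
    heights_mm: tuple[float, ...] | None = None,
) -> WedgeSpec:
    """Default wedge layout: a vertical column of 10 step bands at the left edge.

    The physical standard's per-step heights are not published; the defaults
    (9.0 mm to 19.8 mm in 1.2 mm increments) are free parameters chosen so the
    default attenuation model spans Table-like reference ranges, and make no
    claim to equal the physical block.
    """
    nrow, ncol = image_shape
    if heights_mm is None:
        heights_mm = tuple(9.0 + 1.2 * k for k in range(10))
    band = max(8, (nrow - 2 * (nrow // 12)) // 10)
    top = nrow // 12
    col0, col1 = max(4, ncol // 25), max(16, ncol // 6)
    feet = tuple(
        (top + k * band, top + (k + 1) * band, col0, col1) for k in range(10)
    )
    return WedgeSpec(step_heights_mm=heights_mm, footprints=feet)


@dataclass(frozen=True)
class PhantomModel:
    """Attenuation model mapping material path lengths to HU-like values.

    ``mu_tables`` holds effective linear attenuation coefficients (mm^-1)
    tabulated at tube voltages; intermediate kV is linearly interpolated and
    extrapolation is refused.  ``hu_offset``/``hu_gain`` form the affine map
    from optical depth to HU (zero path -> air = -1000 HU).  Noise is
    Gaussian in HU, sd = ``noise_sd_ref * sqrt(mas_ref / mAs)``, clipped at
    3 sd so air stays within +-3 sd of -1000.  ``dispersion_gain``/``decay``
    parameterize the mAs-driven downward shift of thin aluminum steps.
    """

    mu_tables: dict[str, dict[float, float]] = field(default_factory=dict)
    hu_gain: float = 1000.0
    hu_offset: float = -1000.0
    noise_sd_ref: float = 35.0
    mas_ref: float = 1.2
    dispersion_gain: float = 435.0
    dispersion_decay: float = 1.6
    hair_path_mm: float = 10.0

    def noise_sd(self, mas: float) -> float:
        return self.noise_sd_ref * math.sqrt(self.mas_ref / mas)

    def hu_from_depth(self, depth):
        return self.hu_offset + self.hu_gain * np.asarray(depth, dtype=float)


def default_model() -> PhantomModel:
    """Default attenuation tables, tuned once so the five study presets
    reproduce the published reference-range ordering and magnitudes
    (aluminum S1 at 50 kV; 1.2 mAs lands near 1005 HU)."""
    return PhantomModel(
        mu_tables={
            "air": {50.0: 0.0, 60.0: 0.0, 70.0: 0.0, 80.0: 0.0},
            "aluminum": {50.0: 0.2228, 60.0: 0.1996, 70.0: 0.1327, 80.0: 0.1106},
            "bone": {50.0: 0.2117, 60.0: 0.1896, 70.0: 0.1261, 80.0: 0.1051},
            "soft": {50.0: 0.0458, 60.0: 0.0429, 70.0: 0.0395, 80.0: 0.0376},
            "hair": {50.0: 0.1350, 60.0: 0.1197, 70.0: 0.1160, 80.0: 0.1020},
        }
    )


def effective_mu(material: str, kv: float, model: PhantomModel) -> float:
    """Effective linear attenuation coefficient (mm^-1) at tube voltage kV.

    Linear interpolation between tabulated voltages; no extrapolation.
    Higher kV means a more penetrating beam, so mu falls with kV for every
    solid material.
    """
    try:
        table = model.mu_tables[material]
    except KeyError:
        raise KeyError(f"unknown material {material!r}") from None
    kvs = sorted(table)
    if not kvs[0] <= kv <= kvs[-1]:
        raise ValueError(
            f"kV={kv:g} outside tabulated range [{kvs[0]:g}, {kvs[-1]:g}] "
            f"for {material!r}"
        )
    mu = float(np.interp(kv, kvs, [table[v] for v in kvs]))
    if mu < 0:
        raise ValueError(f"negative mu for {material!r} at {kv:g} kV")
    return mu


@dataclass(frozen=True)
class TissueStructure:
    """Elliptical projected structure with a radial thickness profile.

    ``profile='chord'`` is an ellipsoid chord ``T*sqrt(1-rho^2)`` (soft
    tissue envelope); ``profile='tapered'`` is ``T*(1-rho)^2``, a cusped
    profile whose HU histogram decreases monotonically -- a stylized stand-in
    for the scarcity of thick, dense bone paths in a lateral knee projection.
    """

    material: str
    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (row, col), pixels
    thickness_mm: float
    profile: str = "chord"

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("structure thickness must be positive")
        if self.profile not in ("chord", "tapered"):
            raise ValueError(f"unknown thickness profile {self.profile!r}")

    def thickness_map(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        rho2 = ((rr - self.center[0]) / self.semi_axes[0]) ** 2 + (
            (cc - self.center[1]) / self.semi_axes[1]
        ) ** 2
        inside = rho2 < 1.0
        rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
        if self.profile == "chord":
            t = self.thickness_mm * np.sqrt(1.0 - rho**2)
        else:
            t = self.thickness_mm * (1.0 - rho) ** 2
        return np.where(inside, t, 0.0)


def default_knee(
    image_shape: tuple[int, int] = (512, 512), scale: float = 1.0
) -> list[TissueStructure]:
    """Stylized knee: a soft-tissue ellipse with a tapered bone core.

    ``scale`` varies limb size between subjects (cohort heterogeneity).
    """
    nrow, ncol = image_shape
    center = (nrow * 0.5, ncol * 0.645)
    return [
        TissueStructure("soft", center, (100.0 * scale, 70.0 * scale), 24.0 * scale),
        TissueStructure(
            "bone", center, (65.0 * scale, 42.0 * scale), 16.0 * scale, "tapered"
        ),
    ]


@dataclass
class Radiograph:
    """A rendered (or loaded) radiograph with HU-like pixel values."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    exposure: ExposureSetting
    wedge_layout: WedgeSpec | None = None
    limb_mask_truth: np.ndarray | None = None
    step_truth: dict[int, tuple[float, float]] | None = None
    clutter_mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 64:
            raise ValueError("radiograph must be a 2-D array of at least 64x64")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("radiograph contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _dispersion_weight(t_al: np.ndarray, wedge: WedgeSpec, model: PhantomModel):
    """Weight in [0, 1] of the mAs dispersion shift: 1 at the thinnest step,
    decaying exponentially toward the thickest."""
    t1, t10 = wedge.step_heights_mm[0], wedge.step_heights_mm[-1]
    x = np.clip((np.asarray(t_al, dtype=float) - t1) / (t10 - t1), 0.0, None)
    return np.exp(-model.dispersion_decay * x)


def _dispersion_shift(t_al, wedge: WedgeSpec, exposure: ExposureSetting, model: PhantomModel):
    g = model.dispersion_gain * math.log(exposure.mas / model.mas_ref)
    return g * _dispersion_weight(t_al, wedge, model)


def _wedge_hu(heights, wedge: WedgeSpec, exposure: ExposureSetting, model: PhantomModel):
    """Noise-free HU of aluminum of the given path length(s) at this exposure."""
    mu = effective_mu("aluminum", exposure.kv, model)
    t = np.asarray(heights, dtype=float)
    hu = model.hu_from_depth(mu * t)
    if exposure.mas != model.mas_ref:
        hu = hu - _dispersion_shift(t, wedge, exposure, model)
    return hu


def render_radiograph(
    wedge: WedgeSpec | None,
    tissue: list[TissueStructure] | None,
    exposure: ExposureSetting,
    model: PhantomModel | None = None,
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_spacing_mm: float = 0.2,
    noise: bool = True,
    source_id: str = "",
) -> Radiograph:
    """Render a radiograph of wedge + tissue at one tube setting.

    Deterministic in (specs, seed).  Raises on overlapping or out-of-bounds
    wedge footprints and on non-positive thicknesses.
    """
    model = model or default_model()
    nrow, ncol = image_shape
    depth = np.zeros(image_shape, dtype=float)
    t_al = np.zeros(image_shape, dtype=float)

    if wedge is not None:
        mu_al = effective_mu("aluminum", exposure.kv, model)
        covered = np.zeros(image_shape, dtype=bool)
        for k in range(wedge.n_steps):
            r0, r1, c0, c1 = wedge.footprints[k]
            if not (0 <= r0 < r1 <= nrow and 0 <= c0 < c1 <= ncol):
                raise ValueError(f"footprint of step S{k + 1} outside image bounds")
            if covered[r0:r1, c0:c1].any():
                raise ValueError(f"footprint of step S{k + 1} overlaps another step")
            covered[r0:r1, c0:c1] = True
            t_al[r0:r1, c0:c1] = wedge.step_heights_mm[k]
        depth += mu_al * t_al

    limb_mask = None
    if tissue:
        limb_mask = np.zeros(image_shape, dtype=bool)
        for struct in tissue:
            mu = effective_mu(struct.material, exposure.kv, model)
            tmap = struct.thickness_map(image_shape)
            depth += mu * tmap
            limb_mask |= tmap > 0

    hu = model.hu_from_depth(depth)
    if wedge is not None and exposure.mas != model.mas_ref:
        in_wedge = t_al > 0
        hu = np.where(
            in_wedge, hu - _dispersion_shift(t_al, wedge, exposure, model), hu
        )

    if noise:
        sd = model.noise_sd(exposure.mas)
        rng = np.random.default_rng(seed)
        hu = hu + np.clip(rng.normal(0.0, sd, size=image_shape), -3 * sd, 3 * sd)

    step_truth = None
    if wedge is not None:
        truth = _wedge_hu(np.asarray(wedge.step_heights_mm), wedge, exposure, model)
        step_truth = {k + 1: (float(truth[k]), float(truth[k])) for k in range(10)}

    return Radiograph(
        pixels=hu,
        pixel_spacing_mm=pixel_spacing_mm,
        exposure=exposure,
        wedge_layout=wedge,
        limb_mask_truth=limb_mask,
        step_truth=step_truth,
        source_id=source_id,
    )


#: Filaments drawn per clutter severity grade.
CLUTTER_FILAMENTS = {"mild": 1, "moderate": 4, "severe": 16}


def add_background_clutter(
    radiograph: Radiograph,
    severity: str,
    seed: int,
    model: PhantomModel | None = None,
) -> Radiograph:
    """Overlay hair-like filaments on the background next to the limb.

    Filaments are thin strands of a fixed low-attenuation "hair" material;
    their HU therefore tracks the tube voltage the radiograph was taken
    with, landing inside the low-step (S1-S3) density ranges only for tube
    settings that shift those ranges down toward soft tissue.  The affected
    pixel fraction grows mild < moderate < severe; placement is
    deterministic per seed and never intrudes on the limb or the wedge.
    """
    if severity not in CLUTTER_SEVERITIES:
        raise ValueError(
            f"unknown severity {severity!r}; expected one of {CLUTTER_SEVERITIES}"
        )
    if radiograph.limb_mask_truth is None:
        raise ValueError("clutter requires a limb ground-truth mask")
    model = model or default_model()
    nrow, ncol = radiograph.shape
    rng = np.random.default_rng(seed)

    forbidden = radiograph.limb_mask_truth.copy()
    if radiograph.wedge_layout is not None:
        for r0, r1, c0, c1 in radiograph.wedge_layout.footprints:
            forbidden[max(0, r0 - 4) : r1 + 4, max(0, c0 - 4) : c1 + 4] = True

    rows, cols = np.nonzero(radiograph.limb_mask_truth)
    cr, cc = rows.mean(), cols.mean()
    rad = max(rows.max() - cr, cols.max() - cc)

    clutter = np.zeros((nrow, ncol), dtype=bool)
    n_filaments = CLUTTER_FILAMENTS[severity]
    for _ in range(n_filaments):
        theta = rng.uniform(0, 2 * math.pi)
        dist = rad + rng.uniform(8, 45)
        r = cr + dist * math.sin(theta)
        c = cc + dist * math.cos(theta)
        heading = theta + math.pi / 2 + rng.normal(0, 0.4)
        for _step in range(90):
            heading += rng.normal(0, 0.25)
            r += math.sin(heading)
            c += math.cos(heading)
            ri, ci = int(round(r)), int(round(c))
            if not (1 <= ri < nrow - 1 and 1 <= ci < ncol - 1):
                break
            patch = np.s_[ri - 1 : ri + 2, ci - 1 : ci + 2]
            if forbidden[patch].any():
                continue
            clutter[patch] = True

    mu_hair = effective_mu("hair", radiograph.exposure.kv, model)
    hair_hu = float(model.hu_from_depth(mu_hair * model.hair_path_mm))
    sd = model.noise_sd(radiograph.exposure.mas)
    noise = np.clip(rng.normal(0.0, sd, size=clutter.sum()), -3 * sd, 3 * sd)

    pixels = radiograph.pixels.copy()
    pixels[clutter] = hair_hu + noise
    out = replace(radiograph, pixels=pixels)
    out.clutter_mask = clutter
    return out


# --------------------------------------------------------------------------
# File output


def write_dicom(radiograph: Radiograph, path) -> None:
    """Write a monochrome DICOM whose rescale maps stored values to HU."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CR"
    ds.Rows, ds.Columns = radiograph.shape
    ds.PixelSpacing = [radiograph.pixel_spacing_mm, radiograph.pixel_spacing_mm]
    ds.KVP = radiograph.exposure.kv
    ds.ExposureInmAs = radiograph.exposure.mas
    ds.SeriesDescription = str(radiograph.exposure)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    # unsigned 16-bit storage: shift by the data minimum, undone by the rescale
    intercept = float(np.floor(radiograph.pixels.min()))
    ds.RescaleIntercept = intercept
    ds.RescaleSlope = 1.0
    stored = np.clip(
        np.round(radiograph.pixels - intercept), 0, 65535
    ).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom(path) -> Radiograph:
    """Read a monochrome DICOM back onto the HU scale (applies the rescale)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    hu = ds.pixel_array.astype(float) * float(
        getattr(ds, "RescaleSlope", 1.0)
    ) + float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    exposure = ExposureSetting(
        kv=float(getattr(ds, "KVP", 60.0)),
        mas=float(getattr(ds, "ExposureInmAs", 1.2)),
        label=str(getattr(ds, "SeriesDescription", "")),
    )
    return Radiograph(pixels=hu, pixel_spacing_mm=spacing, exposure=exposure)


def write_png16(radiograph: Radiograph, path) -> None:
    """16-bit grayscale PNG (HU + 1024, clipped to the unsigned range)."""
    from PIL import Image

    stored = np.clip(np.round(radiograph.pixels + 1024.0), 0, 65535).astype(np.uint16)
    Image.fromarray(stored).save(str(path), format="PNG")
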