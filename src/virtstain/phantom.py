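"""Synthetic vessel-phantom generator.

Produces paired images of an artery cross-section — a low-contrast
"unstained" bright-field rendering and three stain-specific colour
renderings (H&E, picrosirius red, orcein) — together with ground-truth
region masks (lumen, neointima, media, elastic laminae).  The phantom
emulates the statistical structure of a balloon-injured rat carotid
section: an annular vessel wall with a thickened neointima, a
smooth-muscle media bounded by thin elastic laminae, optional
eccentricity, nuclear speckle in the cellular layers, and Gaussian
acquisition noise.  It makes every downstream stage (registration,
patching, training, morphometry) testable without any external data.

The renderings are deliberately schematic: palettes are declared
constants chosen to be hue-separable, not fits to real tissue.

Conventions: images are float arrays in [0, 1], shape (H, W, 3); masks
are boolean rasters of the same spatial shape, 0-based row-major with
the origin at the top-left.  Identical spec + seed gives bit-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "StainDomain",
    "VesselPhantomSpec",
    "RegionMasks",
    "RigidTransform",
    "generate_phantom",
    "apply_rigid_deformation",
    "save_phantom",
    "load_phantom",
    "PALETTES",
    "PALETTE_HUE_BANDS",
    "GRAY_BAND",
]


class StainDomain(enum.Enum):
    """The three stain domains: H&E, picrosirius red, orcein."""

    HE = "he"
    PSR = "psr"
    ORCEIN = "orcein"

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(3, dtype=np.float32)
        v[list(StainDomain).index(self)] = 1.0
        return v

    @classmethod
    def from_label(cls, label: "str | StainDomain") -> "StainDomain":
        if isinstance(label, cls):
            return label
        try:
            return cls(label.lower())
        except ValueError:
            raise ValueError(f"unknown stain domain {label!r}; "
                             f"expected one of {[d.value for d in cls]}") from None


# stain palettes (RGB in [0, 1]); hues are separated so a hue histogram
# can attribute an image to its stain: H&E tissue ~310-320 deg (magenta-
# pink), PSR ~350-356 deg (red), orcein ~15-25 deg (brown).
PALETTES: dict[StainDomain, dict[str, tuple[float, float, float]]] = {
    StainDomain.HE: {
        "background": (0.95, 0.94, 0.96),
        "intima": (0.90, 0.45, 0.80),
        "media": (0.82, 0.40, 0.72),
        "laminae": (0.70, 0.42, 0.62),
        "nuclei": (0.36, 0.15, 0.45),
    },
    StainDomain.PSR: {
        "background": (0.96, 0.94, 0.93),
        "intima": (0.88, 0.52, 0.50),
        "media": (0.75, 0.10, 0.15),
        "laminae": (0.80, 0.45, 0.42),
        "nuclei": (0.55, 0.20, 0.22),
    },
    StainDomain.ORCEIN: {
        "background": (0.96, 0.95, 0.93),
        "intima": (0.82, 0.68, 0.56),
        "media": (0.72, 0.55, 0.42),
        "laminae": (0.30, 0.16, 0.09),
        "nuclei": (0.45, 0.32, 0.22),
    },
}

# dominant-tissue hue bands, degrees on the HSV circle (half-open, mod 360)
PALETTE_HUE_BANDS: dict[StainDomain, tuple[float, float]] = {
    StainDomain.HE: (290.0, 340.0),
    StainDomain.PSR: (340.0, 370.0),   # wraps through 0/360
    StainDomain.ORCEIN: (5.0, 45.0),
}

GRAY_BAND = (0.55, 0.85)  # unstained tissue luminance range


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Parametric geometry and noise model of one synthetic cross-section.

    Radial layout from the vessel centre: lumen (radius ``lumen_radius``),
    neointima ring of ``intima_thickness``, media ring of
    ``media_thickness``, then ``lamina_count`` thin elastic laminae spaced
    ``lamina_spacing`` px apart just outside the media.  ``eccentricity``
    in [0, 1) stretches the annulus affinely.  All lengths are pixels;
    ``pixel_size_um`` converts to micrometres downstream.
    """

    canvas_size: int = 1079
    center: tuple[float, float] | None = None      # (row, col); None = canvas centre
    lumen_radius: float = 150.0
    intima_thickness: float = 60.0
    media_thickness: float = 80.0
    lamina_count: int = 2
    lamina_spacing: float = 6.0
    eccentricity: float = 0.0
    noise_sd: float = 0.02
    nuclei_density: float = 4e-4                   # nuclei per px^2 of cellular tissue
    pixel_size_um: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.canvas_size < 16:
            raise ValueError("invalid spec: canvas_size must be >= 16")
        if self.lumen_radius <= 0:
            raise ValueError("invalid spec: lumen_radius must be > 0")
        if self.intima_thickness < 0:
            raise ValueError("invalid spec: intima_thickness must be >= 0")
        if self.media_thickness <= 0:
            raise ValueError("invalid spec: media_thickness must be > 0")
        if self.lamina_count < 0:
            raise ValueError("invalid spec: lamina_count must be >= 0")
        if self.lamina_count and self.lamina_spacing <= 0:
            raise ValueError("invalid spec: lamina_spacing must be > 0 when laminae present")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("invalid spec: eccentricity must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("invalid spec: noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("invalid spec: pixel_size_um must be > 0")
        extent = (self.lumen_radius + self.intima_thickness + self.media_thickness
                  + self.lamina_count * self.lamina_spacing)
        if extent >= self.canvas_size / 2:
            raise ValueError(
                "invalid spec: vessel does not fit the canvas "
                f"(lumen+intima+media+laminae extent {extent:.1f} px >= "
                f"canvas_size/2 = {self.canvas_size / 2:.1f} px)")

    @property
    def centre_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.canvas_size - 1) / 2.0
        return (c, c)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VesselPhantomSpec":
        d = json.loads(text)
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)


@dataclass
class RegionMasks:
    """Boolean rasters for the vessel layers (same shape, pairwise
    disjoint lumen/intima/media; laminae sit outside the media)."""

    lumen: np.ndarray
    intima: np.ndarray
    media: np.ndarray
    laminae: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in (self.lumen, self.intima, self.media, self.laminae)}
        if len(shapes) != 1:
            raise ValueError(f"masks must share one shape, got {shapes}")
        for a, b, name in ((self.lumen, self.intima, "lumen/intima"),
                           (self.lumen, self.media, "lumen/media"),
                           (self.intima, self.media, "intima/media")):
            if np.any(a & b):
                raise ValueError(f"masks {name} overlap")

    @property
    def shape(self):
        return self.lumen.shape

    @property
    def tissue(self) -> np.ndarray:
        """Vessel-wall tissue: intima, media and laminae."""
        return self.intima | self.media | self.laminae

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"lumen": self.lumen, "intima": self.intima,
                "media": self.media, "laminae": self.laminae}


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, counter-clockwise about the image centre)
    followed by a translation in pixels: ``tx`` along columns, ``ty``
    along rows.  Maps moving-frame points into the fixed frame."""

    rotation_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.tx == 0.0 and self.ty == 0.0

    def inverse(self) -> "RigidTransform":
        th = math.radians(-self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        # p' = R p + t  =>  p = R^-1 (p' - t)
        tx = -(c * self.tx - s * self.ty)
        ty = -(s * self.tx + c * self.ty)
        return RigidTransform(-self.rotation_deg, tx, ty)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        tx = c * other.tx - s * other.ty + self.tx
        ty = s * other.tx + c * other.ty + self.ty
        return RigidTransform(self.rotation_deg + other.rotation_deg, tx, ty)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rotation_deg, self.tx, self.ty)


def apply_rigid_deformation(image: np.ndarray, transform: RigidTransform,
                            order: int = 1, cval: float | None = None) -> np.ndarray:
    """Resample ``image`` under ``transform`` (rotate about the centre,
    then translate), constant fill outside the field of view.

    Emulates the rigid misalignment introduced between imaging an
    unstained section and re-imaging it after chemical staining.  The
    identity transform returns the input unchanged (bit-exact).  With
    ``cval=None`` the fill value is the image's corner median (an
    estimate of the background).
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
        squeeze = True
    elif img.ndim == 3:
        squeeze = False
    else:
        raise ValueError(f"expected a 2-D or (H, W, C) image, got shape {image.shape}")
    if transform.is_identity:
        out = img.copy()
        return out[:, :, 0] if squeeze else out

    if cval is None:
        corners = np.concatenate([img[:3, :3].reshape(-1, img.shape[2]),
                                  img[:3, -3:].reshape(-1, img.shape[2]),
                                  img[-3:, :3].reshape(-1, img.shape[2]),
                                  img[-3:, -3:].reshape(-1, img.shape[2])])
        cval_c = np.median(corners, axis=0)
    else:
        cval_c = np.full(img.shape[2], cval, dtype=np.float64)

    h, w = img.shape[:2]
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = math.radians(transform.rotation_deg)
    # forward map in (row, col): [row', col'] = R [row, col] + [ty, tx]
    # ndimage pulls: input_coord = A @ output_coord + offset = inverse map
    c, s = math.cos(th), math.sin(th)
    # rotation by +theta in (x=col, y=row): x' = cx - sy, y' = sx + cy,
    # written as a matrix on (row, col) coordinates
    rot_rc = np.array([[c, s], [-s, c]])
    a_inv = rot_rc.T
    t = np.array([transform.ty, transform.tx])
    offset = centre - a_inv @ (centre + t)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch], a_inv, offset=offset, order=order,
            mode="constant", cval=cval_c[ch])
    return out[:, :, 0] if squeeze else out


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _luminance(img: np.ndarray) -> np.ndarray:
    return 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]


def _region_masks(spec: VesselPhantomSpec) -> RegionMasks:
    n = spec.canvas_size
    cy, cx = spec.centre_rc
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    s = math.sqrt(1.0 - spec.eccentricity)
    rho = np.hypot(dx * s, dy / s)

    r1 = spec.lumen_radius
    r2 = r1 + spec.intima_thickness
    r3 = r2 + spec.media_thickness
    lumen = rho < r1
    intima = (rho >= r1) & (rho < r2)
    media = (rho >= r2) & (rho < r3)
    laminae = np.zeros_like(lumen)
    if spec.lamina_count:
        width = min(2.0, 0.8 * spec.lamina_spacing)
        for k in range(spec.lamina_count):
            centre_r = r3 + (k + 0.5) * spec.lamina_spacing
            laminae |= np.abs(rho - centre_r) < width / 2.0
    return RegionMasks(lumen=lumen, intima=intima, media=media, laminae=laminae)


def _render_stain(spec: VesselPhantomSpec, masks: RegionMasks,
                  domain: StainDomain,
                  nuclei_rc: np.ndarray) -> np.ndarray:
    pal = PALETTES[domain]
    n = spec.canvas_size
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = pal["background"]
    for region in ("intima", "media", "laminae"):
        img[getattr(masks, region)] = pal[region]
    # nuclear speckle in the cellular layers (small dark disks)
    if len(nuclei_rc):
        rr, cc = np.mgrid[-2:3, -2:3]
        disk = (rr ** 2 + cc ** 2) <= 4
        drr, dcc = rr[disk], cc[disk]
        col = np.array(pal["nuclei"])
        for r0, c0 in nuclei_rc:
            pr = (r0 + drr).clip(0, n - 1)
            pc = (c0 + dcc).clip(0, n - 1)
            img[pr, pc] = col
    return img


def generate_phantom(spec: VesselPhantomSpec
                     ) -> tuple[np.ndarray, dict[StainDomain, np.ndarray], RegionMasks]:
    """Generate one phantom: the unstained rendering, the three stained
    renderings, and the ground-truth region masks.

    The unstained image is the luminance channel of the (noiseless) H&E
    rendering remapped into the narrow gray band [0.55, 0.85] — visible
    but low-contrast tissue — plus Gaussian noise of ``spec.noise_sd``.
    Each stained rendering gets an independent noise draw.  All images
    are pixel-aligned; misalignment is added separately with
    :func:`apply_rigid_deformation`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masks = _region_masks(spec)

    # nuclei positions: Poisson-scattered over the cellular layers
    cellular = masks.intima | masks.media
    idx = np.flatnonzero(cellular)
    nuclei_rc = np.empty((0, 2), dtype=np.int64)
    if len(idx) and spec.nuclei_density > 0:
        count = rng.poisson(spec.nuclei_density * len(idx))
        if count:
            chosen = rng.choice(idx, size=min(count, len(idx)), replace=False)
            nuclei_rc = np.stack(np.unravel_index(chosen, masks.shape), axis=1)

    stained: dict[StainDomain, np.ndarray] = {}
    he_clean = None
    for domain in StainDomain:
        img = _render_stain(spec, masks, domain, nuclei_rc)
        if domain is StainDomain.HE:
            he_clean = img
        noisy = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        stained[domain] = np.clip(noisy, 0.0, 1.0)

    lum = _luminance(he_clean)
    lo, hi = float(lum.min()), float(lum.max())
    g0, g1 = GRAY_BAND
    if hi - lo < 1e-9:
        gray = np.full_like(lum, (g0 + g1) / 2.0)
    else:
        gray = g0 + (lum - lo) / (hi - lo) * (g1 - g0)
    unstained = np.repeat(gray[:, :, None], 3, axis=2)
    unstained = unstained + rng.normal(0.0, spec.noise_sd, size=unstained.shape)
    unstained = np.clip(unstained, 0.0, 1.0)
    return unstained, stained, masks


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def save_image(path: Path | str, img: np.ndarray) -> None:
    """Write a float [0, 1] image as 8-bit PNG or TIFF by extension."""
    path = Path(path)
    arr = _to_uint8(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def load_image(path: Path | str) -> np.ndarray:
    """Read an image file to float [0, 1], shape (H, W, 3)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = arr.astype(np.float64) / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr[:, :, :3]


def save_phantom(out_dir: Path | str, spec: VesselPhantomSpec, *,
                 fmt: str = "png") -> dict[str, Path]:
    """Generate and write one phantom: unstained + stained images, masks
    as 0/255 single-channel PNGs, and a JSON sidecar with the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unstained, stained, masks = generate_phantom(spec)
    paths: dict[str, Path] = {}
    paths["unstained"] = out_dir / f"unstained.{fmt}"
    save_image(paths["unstained"], unstained)
    for domain, img in stained.items():
        paths[domain.value] = out_dir / f"{domain.value}.{fmt}"
        save_image(paths[domain.value], img)
    for name, mask in masks.as_dict().items():
        p = out_dir / f"mask_{name}.png"
        Image.fromarray((mask.astype(np.uint8) * 255)).save(p)
        paths[f"mask_{name}"] = p
    sidecar = out_dir / "spec.json"
    sidecar.write_text(spec.to_json())
    paths["spec"] = sidecar
    return paths


def load_phantom(in_dir: Path | str
                 ) -> tuple[np.ndarray, dict[StainDomain, np.ndarray], RegionMasks,
                            VesselPhantomSpec]:
    in_dir = Path(in_dir)
    spec = VesselPhantomSpec.from_json((in_dir / "spec.json").read_text())
    unstained = load_image(next(in_dir.glob("unstained.*")))
    stained = {d: load_image(next(in_dir.glob(f"{d.value}.*"))) for d in StainDomain}
    masks = RegionMasks(**{
        name: np.asarray(Image.open(in_dir / f"mask_{name}.png")) > 127
        for name in ("lumen", "intima", "media", "laminae")})
    return unstained, stained, masks, spec
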