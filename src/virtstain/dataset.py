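"""Dataset preparation: registration, patch extraction, filtering, splits.

Builds registered, filtered, patch-level training/testing datasets from
whole-slide image (WSI) pairs.  The pipeline mirrors the acquisition
workflow: the unstained section is imaged, chemically stained, and
re-imaged; staining rigidly misaligns the two fields of view, so the
unstained (moving) WSI is co-registered to the stained (fixed) WSI
before the pair is cropped into overlapping square patches, patches
without enough vessel tissue are removed, and the survivors are split
into train/test sets.

Registration is rigid (rotation + translation) and multimodal: the two
images differ in contrast and colour, so the similarity metric is
mutual information on a 64-bin joint grey-level histogram.  The search
is a coarse stage (rotation grid, per-rotation translation proposed by
phase correlation at reduced resolution) followed by Nelder-Mead
refinement of (rotation, tx, ty) at full resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import RegionMasks, RigidTransform, StainDomain, apply_rigid_deformation

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "RegistrationResult",
    "ImagePatchPair",
    "TrainingDataset",
    "register_rigid",
    "mutual_information",
    "crop_patches",
    "tissue_fraction",
    "filter_patches",
    "split_dataset",
    "write_manifest",
    "read_manifest",
    "prepare_wsi_pair",
]

DEFAULT_TISSUE_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class ImagePatchPair:
    """A registered (unstained x, stained y) patch pair.

    ``x`` is the network input, ``y`` the ground-truth stained patch.
    ``origin`` is the 0-based (row, col) of the patch's top-left corner
    in the source WSI; the patch occupies the half-open window
    [origin, origin + size).
    """

    x: np.ndarray
    y: np.ndarray
    stain: StainDomain
    origin: tuple[int, int]
    source_id: str
    tissue_fraction: float = float("nan")

    def __post_init__(self):
        if self.x.shape != self.y.shape:
            raise ValueError(f"x/y shape mismatch: {self.x.shape} vs {self.y.shape}")

    @property
    def size(self) -> int:
        return self.x.shape[0]


@dataclass
class TrainingDataset:
    pairs: list[ImagePatchPair]
    split: str                      # "train" or "test"
    stain: StainDomain

    def __post_init__(self):
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass(frozen=True)
class RegistrationConfig:
    rotation_range_deg: float = 10.0
    rotation_step_deg: float = 1.0
    max_translation_px: float = 32.0
    bins: int = 64
    coarse_downsample: int = 4
    refine_maxiter: int = 200
    metric_floor: float = 0.15      # quality gate: nats of MI after registration


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric: float                   # mutual information (nats) after alignment
    converged: bool
    warped: np.ndarray | None = None


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """MI (nats) between two grayscale images on a joint histogram."""
    a = _to_gray(a).ravel()
    b = _to_gray(b).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def register_rigid(moving: np.ndarray, fixed: np.ndarray,
                   config: RegistrationConfig | None = None,
                   return_warped: bool = True) -> RegistrationResult:
    """Recover the rigid transform aligning ``moving`` onto ``fixed``.

    Maximises mutual information; see the module docstring for the
    search strategy.  Optimizer failure never passes silently: the
    result carries ``converged=False`` with the best transform found.
    """
    from scipy import optimize
    from skimage.registration import phase_cross_correlation
    from skimage.transform import rescale

    cfg = config or RegistrationConfig()
    if moving.shape[:2] != fixed.shape[:2]:
        raise ValueError(f"moving/fixed shapes differ: {moving.shape} vs {fixed.shape}")
    g_mov = _to_gray(moving)
    g_fix = _to_gray(fixed)

    ds = cfg.coarse_downsample
    small_mov = rescale(g_mov, 1.0 / ds, anti_aliasing=True)
    small_fix = rescale(g_fix, 1.0 / ds, anti_aliasing=True)

    def mi_at(params, mov, fix, scale=1.0):
        rot, tx, ty = params
        t = RigidTransform(rot, tx, ty)
        warped = apply_rigid_deformation(mov, t, order=1)
        return mutual_information(warped, fix, cfg.bins)

    # coarse: rotation grid; translation per rotation from phase correlation
    best = (-np.inf, (0.0, 0.0, 0.0))
    rots = np.arange(-cfg.rotation_range_deg, cfg.rotation_range_deg + 1e-9,
                     cfg.rotation_step_deg)
    for rot in rots:
        rotated = apply_rigid_deformation(small_mov, RigidTransform(rot, 0, 0), order=1)
        shift, _, _ = phase_cross_correlation(small_fix, rotated,
                                              upsample_factor=4, normalization=None)
        ty, tx = float(shift[0]) * ds, float(shift[1]) * ds
        if abs(tx) > cfg.max_translation_px or abs(ty) > cfg.max_translation_px:
            tx = np.clip(tx, -cfg.max_translation_px, cfg.max_translation_px)
            ty = np.clip(ty, -cfg.max_translation_px, cfg.max_translation_px)
        score = mi_at((rot, tx / ds, ty / ds), small_mov, small_fix)
        if score > best[0]:
            best = (score, (float(rot), tx, ty))
    x0 = np.array(best[1])

    # refine at full resolution
    res = optimize.minimize(
        lambda p: -mi_at(p, g_mov, g_fix), x0, method="Nelder-Mead",
        options={"maxiter": cfg.refine_maxiter, "xatol": 0.02, "fatol": 1e-6})
    candidates = [tuple(res.x), tuple(x0)]
    scored = [(mi_at(p, g_mov, g_fix), p) for p in candidates]
    metric, params = max(scored, key=lambda t: t[0])
    transform = RigidTransform(*[float(v) for v in params])
    converged = bool(res.success) and metric >= cfg.metric_floor

    warped = None
    if return_warped:
        warped = apply_rigid_deformation(np.asarray(moving, dtype=np.float64), transform)
    return RegistrationResult(transform=transform, metric=float(metric),
                              converged=converged, warped=warped)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def tissue_fraction(patch_y: np.ndarray, mask_patch: np.ndarray | None = None) -> float:
    """Fraction of the patch covered by vessel tissue (intima + media).

    With a ground-truth mask patch (phantom path) the fraction is exact.
    Otherwise a colour heuristic on the stained patch: "non-background"
    pixels have saturation > 0.08 or luminance < 0.85.
    """
    if mask_patch is not None:
        return float(np.mean(mask_patch))
    img = np.asarray(patch_y, dtype=np.float64)
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
    lum = 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]
    return float(np.mean((sat > 0.08) | (lum < 0.85)))


def crop_patches(x_wsi: np.ndarray, y_wsi: np.ndarray, n_patches: int,
                 patch_size: int, seed: int, *, stain: StainDomain = StainDomain.HE,
                 source_id: str = "wsi", masks: RegionMasks | np.ndarray | None = None
                 ) -> list[ImagePatchPair]:
    """Randomly crop ``n_patches`` overlapping patch pairs from a WSI pair.

    The same origin is applied to x and y; every patch lies fully inside
    the WSI (half-open window).  Deterministic per seed.
    """
    if x_wsi.shape[:2] != y_wsi.shape[:2]:
        raise ValueError(f"WSI pair shapes differ: {x_wsi.shape} vs {y_wsi.shape}")
    h, w = x_wsi.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds WSI size {h}x{w}")
    tissue = None
    if masks is not None:
        tissue = masks.intima | masks.media if isinstance(masks, RegionMasks) else masks
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - patch_size + 1, size=n_patches)
    cols = rng.integers(0, w - patch_size + 1, size=n_patches)
    pairs = []
    for r, c in zip(rows, cols):
        r, c = int(r), int(c)
        sl = (slice(r, r + patch_size), slice(c, c + patch_size))
        frac = tissue_fraction(y_wsi[sl], tissue[sl] if tissue is not None else None)
        pairs.append(ImagePatchPair(
            x=np.ascontiguousarray(x_wsi[sl]), y=np.ascontiguousarray(y_wsi[sl]),
            stain=stain, origin=(r, c), source_id=source_id, tissue_fraction=frac))
    return pairs


def filter_patches(pairs: Sequence[ImagePatchPair],
                   tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD
                   ) -> list[ImagePatchPair]:
    """Keep the pairs whose tissue fraction reaches the threshold
    (removes patches without intima and media); ordering preserved."""
    return [p for p in pairs if p.tissue_fraction >= tissue_threshold]


def split_dataset(pairs: Sequence[ImagePatchPair], n_train: int, n_test: int,
                  seed: int, *, group_by_source: bool = True
                  ) -> tuple[TrainingDataset, TrainingDataset]:
    """Split patch pairs into disjoint train/test sets of exact sizes.

    By default patches from one source WSI never straddle the split
    (overlapping crops of the same slide would otherwise leak between
    train and test): whole WSIs are assigned to the test side first,
    then to train, and each side is trimmed to the requested size.
    """
    pairs = list(pairs)
    if n_train < 0 or n_test < 0:
        raise ValueError("split sizes must be >= 0")
    if n_train + n_test > len(pairs):
        raise ValueError(
            f"insufficient pairs: requested {n_train}+{n_test}={n_train + n_test}, "
            f"available {len(pairs)}")
    stain = pairs[0].stain if pairs else StainDomain.HE
    rng = np.random.default_rng(seed)

    if not group_by_source:
        order = rng.permutation(len(pairs))
        test_idx = list(order[:n_test])
        train_idx = list(order[n_test:n_test + n_train])
    else:
        sources: dict[str, list[int]] = {}
        for i, p in enumerate(pairs):
            sources.setdefault(p.source_id, []).append(i)
        keys = sorted(sources)
        rng.shuffle(keys)
        test_idx: list[int] = []
        train_idx: list[int] = []
        for k in keys:
            if len(test_idx) < n_test:
                test_idx.extend(sources[k])
            else:
                train_idx.extend(sources[k])
        if len(test_idx) < n_test or len(train_idx) < n_train:
            raise ValueError(
                f"cannot form WSI-grouped splits of sizes ({n_train}, {n_test}) "
                f"from {len(pairs)} pairs across {len(keys)} sources")
        test_idx = test_idx[:n_test]
        train_idx = train_idx[:n_train]

    train = TrainingDataset([pairs[i] for i in sorted(train_idx)], "train", stain)
    test = TrainingDataset([pairs[i] for i in sorted(test_idx)], "test", stain)
    return train, test


# ---------------------------------------------------------------------------
# manifest + end-to-end preparation
# ---------------------------------------------------------------------------

def write_manifest(path: Path | str, datasets: Sequence[TrainingDataset],
                   patch_dir: Path | str | None = None) -> None:
    """Write a JSON-lines manifest (one record per patch pair); when
    ``patch_dir`` is given, also write the patch images as PNGs."""
    from .phantom import save_image
    path = Path(path)
    if patch_dir is not None:
        patch_dir = Path(patch_dir)
        patch_dir.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for ds in datasets:
            for i, p in enumerate(ds.pairs):
                rec = {"source_id": p.source_id, "origin": list(p.origin),
                       "stain": p.stain.value, "split": ds.split,
                       "tissue_fraction": round(p.tissue_fraction, 6)}
                if patch_dir is not None:
                    stem = f"{ds.split}_{p.stain.value}_{i:05d}"
                    xp = patch_dir / f"{stem}_x.png"
                    yp = patch_dir / f"{stem}_y.png"
                    save_image(xp, p.x)
                    save_image(yp, p.y)
                    rec["x_path"] = str(xp)
                    rec["y_path"] = str(yp)
                fh.write(json.dumps(rec) + "\n")


def read_manifest(path: Path | str) -> dict[str, TrainingDataset]:
    """Load a manifest written by :func:`write_manifest` (with patches)."""
    from .phantom import load_image
    buckets: dict[str, list[ImagePatchPair]] = {"train": [], "test": []}
    stain = StainDomain.HE
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        stain = StainDomain.from_label(rec["stain"])
        pair = ImagePatchPair(
            x=load_image(rec["x_path"]), y=load_image(rec["y_path"]),
            stain=stain, origin=tuple(rec["origin"]),
            source_id=rec["source_id"], tissue_fraction=rec["tissue_fraction"])
        buckets[rec["split"]].append(pair)
    return {split: TrainingDataset(pairs, split, stain)
            for split, pairs in buckets.items()}


def prepare_wsi_pair(unstained: np.ndarray, stained: np.ndarray, *,
                     n_patches: int = 25, patch_size: int = 500, seed: int = 0,
                     stain: StainDomain = StainDomain.HE, source_id: str = "wsi",
                     masks: RegionMasks | None = None,
                     registration: RegistrationConfig | None = None,
                     tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
                     skip_registration: bool = False
                     ) -> tuple[list[ImagePatchPair], RegistrationResult | None]:
    """Register one WSI pair, crop patches, filter by tissue content.

    Returns the filtered patch pairs and the registration result (None
    if registration was skipped).  A pair whose post-registration metric
    falls below the configured floor is flagged (``converged=False``),
    the automatic counterpart of visually rejecting deformed slides.
    """
    reg = None
    if skip_registration:
        warped = np.asarray(unstained, dtype=np.float64)
    else:
        reg = register_rigid(unstained, stained, registration)
        warped = reg.warped
    pairs = crop_patches(warped, stained, n_patches, patch_size, seed,
                         stain=stain, source_id=source_id, masks=masks)
    return filter_patches(pairs, tissue_threshold), reg
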