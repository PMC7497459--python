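"""Shared fixtures: phantoms and (session-scoped) scaled-down training runs.

The training fixtures are deliberately small — 64 x 64 patches, reduced
channel counts, tens of epochs — so the whole suite runs on one CPU in
minutes while still exercising the full adversarial loop.
"""

from __future__ import annotations

import numpy as np
import pytest

import virtstain as vs
from virtstain.cgan import DiscriminatorConfig, GeneratorConfig
from virtstain.dataset import crop_patches, filter_patches
from virtstain.multistain import MultiStainConfig, train_multistain
from virtstain.training import TrainConfig, train


# ---------------------------------------------------------------------------
# helpers (importable from tests via conftest)
# ---------------------------------------------------------------------------

def dominant_hue(img: np.ndarray, sat_thresh: float = 0.10) -> float | None:
    """Mode of the hue histogram (degrees) over saturated pixels."""
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0)
    mask = sat > sat_thresh
    if mask.sum() < 20:
        return None
    r, g, b = img[..., 0][mask], img[..., 1][mask], img[..., 2][mask]
    mxv = np.maximum(np.maximum(r, g), b)
    mnv = np.minimum(np.minimum(r, g), b)
    d = mxv - mnv
    hue = np.zeros_like(mxv)
    m = (mxv == r) & (d > 0)
    hue[m] = (60 * ((g - b) / d) % 360)[m]
    m = (mxv == g) & (d > 0)
    hue[m] = ((60 * ((b - r) / d) + 120) % 360)[m]
    m = (mxv == b) & (d > 0)
    hue[m] = ((60 * ((r - g) / d) + 240) % 360)[m]
    h, edges = np.histogram(hue, bins=72, range=(0, 360))
    return float(edges[np.argmax(h)] + 2.5)


def hue_in_band(h: float | None, band: tuple[float, float]) -> bool:
    if h is None:
        return False
    lo, hi = band
    return bool(lo <= h < hi or lo <= h + 360 < hi)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def he_phantom():
    """A mid-size phantom with all layers present."""
    spec = vs.VesselPhantomSpec(canvas_size=256, lumen_radius=45, intima_thickness=22,
                                media_thickness=30, lamina_count=2, lamina_spacing=5,
                                seed=9)
    unstained, stained, masks = vs.generate_phantom(spec)
    return spec, unstained, stained, masks


@pytest.fixture(scope="session")
def registration_phantom():
    """Larger eccentric phantom for registration tests."""
    spec = vs.VesselPhantomSpec(canvas_size=512, lumen_radius=80, intima_thickness=40,
                                media_thickness=55, lamina_count=2, lamina_spacing=6,
                                eccentricity=0.15, seed=21)
    unstained, stained, masks = vs.generate_phantom(spec)
    return spec, unstained, stained, masks


def _patch_pairs(n_wsi=2, n_per=20, size=64, seed=7):
    pairs = []
    rng = np.random.default_rng(seed)
    for i in range(n_wsi):
        spec = vs.VesselPhantomSpec(canvas_size=256, lumen_radius=45 + 5 * i,
                                    intima_thickness=22, media_thickness=30,
                                    lamina_count=2, lamina_spacing=5,
                                    eccentricity=0.1 * i, seed=100 + i)
        u, st, masks = vs.generate_phantom(spec)
        ps = crop_patches(u, st[vs.StainDomain.HE], n_per, size,
                          int(rng.integers(2 ** 31)), source_id=f"wsi{i}", masks=masks)
        pairs.extend(filter_patches(ps, 0.10))
    return pairs


SMALL_GEN = GeneratorConfig(n_levels=6, base_channels=16)
SMALL_DISC = DiscriminatorConfig(base_channels=16)


@pytest.fixture(scope="session")
def cgan_toy_run():
    """Paired cGAN trained on 20 phantom pairs at 64 x 64 for 30 epochs."""
    pairs = _patch_pairs()
    train_pairs, test_pairs = pairs[:20], pairs[20:26]
    ds = vs.TrainingDataset(train_pairs, "train", vs.StainDomain.HE)
    gen, hist = train(ds, SMALL_GEN, SMALL_DISC, TrainConfig(epochs=30, seed=7),
                      test_pairs=test_pairs)
    return gen, hist, train_pairs, test_pairs


@pytest.fixture(scope="session")
def overfit_run():
    """Single-pair overfit: 500 alternating update pairs."""
    pairs = _patch_pairs(n_wsi=1, n_per=10, seed=5)
    pair = max(pairs, key=lambda p: p.tissue_fraction)
    ds = vs.TrainingDataset([pair], "train", vs.StainDomain.HE)
    gen, hist = train(ds, SMALL_GEN, SMALL_DISC, TrainConfig(epochs=500, seed=11))
    return gen, hist, pair


def _multistain_datasets(n_per):
    spec = vs.VesselPhantomSpec(canvas_size=256, lumen_radius=45, intima_thickness=22,
                                media_thickness=30, lamina_count=2, lamina_spacing=5,
                                seed=9)
    u, st, masks = vs.generate_phantom(spec)
    datasets = {}
    for d in vs.StainDomain:
        ps = filter_patches(crop_patches(u, st[d], 14, 64, 123, stain=d, masks=masks),
                            0.10)
        ps = sorted(ps, key=lambda p: -p.tissue_fraction)[:n_per]
        datasets[d] = vs.TrainingDataset(ps, "train", d)
    return datasets


@pytest.fixture(scope="session")
def multistain_toy_run():
    """Multi-domain model: 10 pairs per stain, 64 x 64, 30 epochs."""
    datasets = _multistain_datasets(10)
    cfg = MultiStainConfig(gen=SMALL_GEN, disc=SMALL_DISC, epochs=30, seed=5)
    gen, disc, hist = train_multistain(datasets, cfg)
    return gen, disc, hist, datasets


@pytest.fixture(scope="session")
def multistain_overfit_run():
    """Overfit toy: 3 high-tissue pairs per stain, 60 epochs."""
    datasets = _multistain_datasets(3)
    cfg = MultiStainConfig(gen=SMALL_GEN, disc=SMALL_DISC, epochs=60, seed=5)
    gen, disc, hist = train_multistain(datasets, cfg)
    return gen, disc, hist, datasets
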