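"""Dataset preparation: cropping, filtering, splitting, rigid registration."""

import numpy as np
import pytest

import virtstain as vs
from virtstain.dataset import (RegistrationConfig, crop_patches, filter_patches,
                               read_manifest, register_rigid, split_dataset,
                               tissue_fraction, write_manifest)
from virtstain.phantom import RigidTransform, apply_rigid_deformation

from conftest import jaccard


def _wsi_pair(h=1079, w=1079, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((h, w, 3))
    y = rng.random((h, w, 3))
    return x, y


class TestCropPatches:
    def test_25_patches_of_500_from_1079_wsi(self):
        x, y = _wsi_pair()
        pairs = crop_patches(x, y, 25, 500, seed=3)
        assert len(pairs) == 25
        for p in pairs:
            assert p.x.shape == (500, 500, 3)
            assert p.y.shape == (500, 500, 3)
            r, c = p.origin
            assert 0 <= r and r + 500 <= 1079
            assert 0 <= c and c + 500 <= 1079
            # same window applied to x and y
            assert np.array_equal(p.x, x[r:r + 500, c:c + 500])
            assert np.array_equal(p.y, y[r:r + 500, c:c + 500])

    def test_patch_equal_to_wsi_has_origin_zero(self):
        x, y = _wsi_pair(500, 500)
        pairs = crop_patches(x, y, 5, 500, seed=1)
        assert all(p.origin == (0, 0) for p in pairs)

    def test_deterministic_per_seed(self):
        x, y = _wsi_pair(300, 300)
        a = crop_patches(x, y, 10, 64, seed=9)
        b = crop_patches(x, y, 10, 64, seed=9)
        assert [p.origin for p in a] == [p.origin for p in b]
        c = crop_patches(x, y, 10, 64, seed=10)
        assert [p.origin for p in a] != [p.origin for p in c]

    def test_oversized_patch_rejected(self):
        x, y = _wsi_pair(100, 100)
        with pytest.raises(ValueError, match="patch_size"):
            crop_patches(x, y, 1, 101, seed=0)


class TestFilterPatches:
    def test_pure_background_removed_and_tissue_retained(self, he_phantom):
        spec, unstained, stained, masks = he_phantom
        he = stained[vs.StainDomain.HE]
        # hand-placed windows: a corner (background) and the media ring
        bg = crop_patches(unstained, he, 1, 40, seed=0, masks=masks)[0]
        bg_pair = type(bg)(x=unstained[:40, :40], y=he[:40, :40],
                           stain=vs.StainDomain.HE, origin=(0, 0), source_id="w",
                           tissue_fraction=tissue_fraction(
                               he[:40, :40], (masks.intima | masks.media)[:40, :40]))
        rows, cols = np.nonzero(masks.media)
        r, c = rows[len(rows) // 2], cols[len(cols) // 2]
        r0, c0 = max(0, r - 8), max(0, c - 8)
        med_pair = type(bg)(x=unstained[r0:r0 + 16, c0:c0 + 16],
                            y=he[r0:r0 + 16, c0:c0 + 16],
                            stain=vs.StainDomain.HE, origin=(r0, c0), source_id="w",
                            tissue_fraction=tissue_fraction(
                                he[r0:r0 + 16, c0:c0 + 16],
                                (masks.intima | masks.media)[r0:r0 + 16, c0:c0 + 16]))
        kept = filter_patches([bg_pair, med_pair], 0.10)
        assert kept == [med_pair]

    def test_five_percent_tissue_removed_at_ten_percent_threshold(self, he_phantom):
        """Ground-truth mask fraction is the oracle for the filter."""
        spec, unstained, stained, masks = he_phantom
        he = stained[vs.StainDomain.HE]
        tissue = masks.intima | masks.media
        pairs = crop_patches(unstained, he, 300, 48, seed=4, masks=masks)
        low = [p for p in pairs if p.tissue_fraction < 0.08]
        assert low, "sampling produced no low-tissue patch"
        kept = filter_patches(pairs, 0.10)
        assert all(p.tissue_fraction >= 0.10 for p in kept)
        assert not (set(id(p) for p in low) & set(id(p) for p in kept))
        # ordering preserved
        idx = {id(p): i for i, p in enumerate(pairs)}
        assert [idx[id(p)] for p in kept] == sorted(idx[id(p)] for p in kept)

    def test_color_heuristic_matches_mask_fraction(self, he_phantom):
        """Without masks, the saturation/luminance heuristic finds tissue."""
        spec, unstained, stained, masks = he_phantom
        he = stained[vs.StainDomain.HE]
        frac_heur = tissue_fraction(he)
        frac_true = float((masks.intima | masks.media).mean())
        assert abs(frac_heur - frac_true) < 0.10


class TestSplitDataset:
    def _pairs(self, n_sources=80, per_source=25):
        pairs = []
        for s in range(n_sources):
            for i in range(per_source):
                pairs.append(vs.ImagePatchPair(
                    x=np.zeros((4, 4, 3)), y=np.zeros((4, 4, 3)),
                    stain=vs.StainDomain.HE, origin=(0, i),
                    source_id=f"wsi{s:03d}", tissue_fraction=1.0))
        return pairs

    def test_1800_200_split_sizes_and_disjointness(self):
        pairs = self._pairs()
        train, test = split_dataset(pairs, 1800, 200, seed=0)
        assert len(train) == 1800 and len(test) == 200
        train_ids = {(p.source_id, p.origin) for p in train}
        test_ids = {(p.source_id, p.origin) for p in test}
        assert not train_ids & test_ids

    def test_no_source_straddles_the_split(self):
        pairs = self._pairs(n_sources=10, per_source=10)
        train, test = split_dataset(pairs, 70, 30, seed=1)
        assert not ({p.source_id for p in train} & {p.source_id for p in test})

    def test_zero_test_split(self):
        pairs = self._pairs(n_sources=4, per_source=5)
        train, test = split_dataset(pairs, 20, 0, seed=0)
        assert len(train) == 20 and len(test) == 0

    def test_same_seed_identical_membership(self):
        pairs = self._pairs(n_sources=8, per_source=5)
        a = split_dataset(pairs, 25, 15, seed=3)
        b = split_dataset(pairs, 25, 15, seed=3)
        for da, db in zip(a, b):
            assert [(p.source_id, p.origin) for p in da] == \
                   [(p.source_id, p.origin) for p in db]

    def test_insufficient_pairs_rejected_with_counts(self):
        pairs = self._pairs(n_sources=2, per_source=5)
        with pytest.raises(ValueError, match="10"):
            split_dataset(pairs, 9, 2, seed=0)

    def test_pipeline_conserves_pairs(self):
        pairs = self._pairs(n_sources=6, per_source=5)
        train, test = split_dataset(pairs, 25, 5, seed=2)
        assert len(train) + len(test) == len(pairs)


class TestRegistration:
    def test_identity_recovered(self, registration_phantom):
        _, _, stained, _ = registration_phantom
        he = stained[vs.StainDomain.HE]
        res = register_rigid(he, he, RegistrationConfig(coarse_downsample=2))
        assert abs(res.transform.rotation_deg) < 0.1
        assert abs(res.transform.tx) < 0.2 and abs(res.transform.ty) < 0.2

    def test_known_rotation_translation_recovered(self, registration_phantom):
        _, unstained, stained, _ = registration_phantom
        true = RigidTransform(5.0, 10.0, -7.0)
        moving = apply_rigid_deformation(unstained, true.inverse())
        res = register_rigid(moving, stained[vs.StainDomain.HE],
                             RegistrationConfig(coarse_downsample=2))
        assert res.converged
        assert abs(res.transform.rotation_deg - 5.0) < 0.5
        assert abs(res.transform.tx - 10.0) < 1.0
        assert abs(res.transform.ty + 7.0) < 1.0

    def test_pure_translation_recovered(self, registration_phantom):
        _, unstained, stained, _ = registration_phantom
        true = RigidTransform(0.0, 3.0, 4.0)
        moving = apply_rigid_deformation(unstained, true.inverse())
        res = register_rigid(moving, stained[vs.StainDomain.HE],
                             RegistrationConfig(coarse_downsample=2))
        assert abs(res.transform.rotation_deg) < 0.3
        assert abs(res.transform.tx - 3.0) < 0.5
        assert abs(res.transform.ty - 4.0) < 0.5

    def test_registration_restores_tissue_overlap(self, registration_phantom):
        """Residual criterion: warped tissue Jaccard >= 0.95 vs fixed."""
        spec, unstained, stained, masks = registration_phantom
        true = RigidTransform(4.0, -8.0, 6.0)
        moving = apply_rigid_deformation(unstained, true.inverse())
        res = register_rigid(moving, stained[vs.StainDomain.HE],
                             RegistrationConfig(coarse_downsample=2))
        tissue = (masks.intima | masks.media).astype(float)
        tissue_moving = apply_rigid_deformation(tissue, true.inverse(), cval=0.0)
        tissue_back = apply_rigid_deformation(tissue_moving, res.transform, cval=0.0)
        assert jaccard(tissue_back > 0.5, tissue > 0.5) >= 0.95


def test_manifest_round_trip(tmp_path, he_phantom):
    spec, unstained, stained, masks = he_phantom
    pairs = crop_patches(unstained, stained[vs.StainDomain.HE], 6, 64, seed=1,
                         masks=masks, source_id="p0")
    train, test = split_dataset(pairs, 4, 2, seed=0, group_by_source=False)
    write_manifest(tmp_path / "m.jsonl", [train, test], tmp_path / "patches")
    loaded = read_manifest(tmp_path / "m.jsonl")
    assert len(loaded["train"]) == 4 and len(loaded["test"]) == 2
    got = loaded["train"].pairs[0]
    src = train.pairs[0]
    assert got.origin == src.origin
    assert np.abs(got.x - src.x).max() <= 1.0 / 255.0 + 1e-9
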