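"""Project store: object derivation, patch extraction geometry, exports."""

import numpy as np
import pandas as pd
import pytest

import bulklabel as bl
from bulklabel.project import crop_centered

CFG = dict(name="t", patch_size=64, class_names=["x", "y"])


def _project(**overrides):
    return bl.Project(":memory:", bl.ProjectConfig(**{**CFG, **overrides}))


def _blank(h, w):
    return np.zeros((h, w, 3), dtype=np.uint8), np.zeros((h, w), dtype=np.uint16)


class TestImportImage:
    def test_empty_mask_yields_no_objects(self):
        p = _project()
        img, mask = _blank(50, 50)
        assert p.import_image("a", img, mask) == []

    def test_shape_mismatch_rejected(self):
        p = _project()
        img, _ = _blank(50, 50)
        _, mask = _blank(40, 50)
        with pytest.raises(ValueError):
            p.import_image("a", img, mask)

    def test_square_centroid_closed_form(self):
        p = _project()
        img, mask = _blank(40, 40)
        mask[10:20, 10:20] = 1
        (obj,) = p.import_image("a", img, mask)
        assert obj.centroid == (14.5, 14.5)
        assert obj.area == 100
        assert obj.bbox == (10, 10, 20, 20)

    def test_centroids_match_brute_force_pixel_scan(self):
        rng = np.random.default_rng(4)
        img, mask = _blank(120, 120)
        for inst in range(1, 26):
            r, c = rng.integers(5, 110, size=2)
            h, w = rng.integers(3, 9, size=2)
            mask[r:r + h, c:c + w] = inst  # later rectangles may overwrite
        p = _project()
        objects = p.import_image("a", img, mask)
        present = set(np.unique(mask)[1:].tolist())
        assert {o.instance_id for o in objects} == present
        for obj in objects:
            pix = np.argwhere(mask == obj.instance_id)
            assert np.allclose(obj.centroid, pix.mean(axis=0))
            assert obj.area == len(pix)


class TestPatchExtraction:
    def test_interior_patch_covers_expected_window(self):
        img = np.arange(200 * 200 * 3, dtype=np.uint32).reshape(200, 200, 3)
        img = (img % 251).astype(np.uint8)
        patch = crop_centered(img, (100.0, 100.0), 64)
        assert np.array_equal(patch, img[68:132, 68:132])
        # the rounded centroid sits at patch index (32, 32)
        assert np.array_equal(patch[32, 32], img[100, 100])

    def test_corner_object_is_zero_padded(self):
        img = np.full((100, 100, 3), 200, dtype=np.uint8)
        patch = crop_centered(img, (0.0, 0.0), 64)
        assert (patch[:32, :] == 0).all()
        assert (patch[:, :32] == 0).all()
        assert (patch[32:, 32:] == 200).all()

    def test_full_roi_patch_is_the_roi(self):
        """An object centered in a 256x256 ROI with patch size 256 yields a
        patch pixel-identical to the ROI."""
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(256, 256, 3), dtype=np.uint8)
        mask = np.zeros((256, 256), dtype=np.uint16)
        mask[118:138, 118:138] = 1  # centroid (127.5, 127.5) -> rounds to 128
        p = _project(patch_size=256)
        p.import_image("roi", img, mask)
        (rec,) = p.extract_patches()
        assert np.array_equal(rec.patch, img)

    def test_extraction_is_idempotent_and_bijective(self, dataset):
        from conftest import make_project
        p = make_project(dataset)
        first = p.extract_patches()
        second = p.extract_patches()
        assert len(first) == len(p.get_objects())
        for a, b in zip(first, second):
            assert a.key == b.key
            assert np.array_equal(a.patch, b.patch)

    def test_oversized_patch_is_allowed(self):
        img = np.full((20, 20, 3), 7, dtype=np.uint8)
        patch = crop_centered(img, (10.0, 10.0), 64)
        assert patch.shape == (64, 64, 3)
        assert patch.sum() == img.sum()


class TestContextPatch:
    def _one_object_project(self, corner=False):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(300, 300, 3), dtype=np.uint8)
        mask = np.zeros((300, 300), dtype=np.uint16)
        if corner:
            mask[0:4, 0:4] = 1
        else:
            mask[148:153, 148:153] = 1
        p = _project(patch_size=64)
        p.import_image("a", img, mask)
        p.extract_patches()
        return p, img

    def test_same_size_equals_training_patch(self):
        p, _ = self._one_object_project()
        (rec,) = p.get_patches()
        ctx = p.get_context_patch(rec.key, 64)
        assert np.array_equal(ctx, rec.patch)

    def test_center_of_context_is_training_patch(self):
        p, _ = self._one_object_project()
        (rec,) = p.get_patches()
        ctx = p.get_context_patch(rec.key, 256)
        assert np.array_equal(ctx[96:160, 96:160], rec.patch)

    def test_corner_padding_consistent_with_extraction(self):
        p, img = self._one_object_project(corner=True)
        (obj,) = p.get_objects()
        ctx = p.get_context_patch(obj.key, 256)
        assert np.array_equal(ctx, crop_centered(img, obj.centroid, 256))

    def test_smaller_than_patch_size_rejected(self):
        p, _ = self._one_object_project()
        with pytest.raises(ValueError):
            p.get_context_patch(("a", 1), 32)


class TestLabelMaskExport:
    def _project_with_two_objects(self):
        img, mask = _blank(60, 60)
        mask[5:15, 5:15] = 1
        mask[30:40, 30:44] = 2
        p = _project(patch_size=16)
        p.import_image("a", img, mask)
        p.extract_patches()
        return p, mask

    def test_unlabeled_objects_render_black(self):
        p, mask = self._project_with_two_objects()
        rendered, table = p.export_label_masks()
        assert (rendered["a"] == 0).all()
        assert len(table) == 0

    def test_single_label_paints_exact_footprint(self):
        p, mask = self._project_with_two_objects()
        p.apply_label_event([("a", 1)], 1, timestamp=1.0, source="single")
        rendered, table = p.export_label_masks()
        color = np.array(p.config.colors[1], dtype=np.uint8)
        out = rendered["a"]
        assert (out[mask == 1] == color).all()
        assert (out[mask != 1] == 0).all()
        assert len(table) == 1

    def test_export_reimport_round_trip(self, tmp_path):
        p, mask = self._project_with_two_objects()
        p.apply_label_event([("a", 1)], 2, timestamp=1.0, source="single")
        p.apply_label_event([("a", 2)], "unsure", timestamp=2.0, source="single")
        _, table = p.export_label_masks(tmp_path)
        loaded = pd.read_csv(tmp_path / "labels.csv", dtype={"label": str})
        fresh, _ = self._project_with_two_objects()
        fresh.import_labels(loaded)
        _, table2 = fresh.export_label_masks()
        pd.testing.assert_frame_equal(table.reset_index(drop=True),
                                      table2.reset_index(drop=True))


def test_model_checkpoint_stored_in_project(dataset, pretrained):
    from conftest import make_project
    import bulklabel as blm
    p = make_project(dataset)
    p.save_checkpoint("encoder", pretrained.to_bytes())
    restored = blm.ModelState.from_bytes(p.load_checkpoint("encoder"))
    probe = [r.patch for r in p.get_patches()[:10]]
    assert np.array_equal(blm.compute_features(pretrained, probe),
                          blm.compute_features(restored, probe))
    with pytest.raises(KeyError):
        p.load_checkpoint("missing")


def test_config_yaml_round_trip(tmp_path):
    cfg = bl.ProjectConfig(name="uc", patch_size=32,
                           class_names=["gs", "ss", "none"],
                           special_labels=("unsure",))
    cfg.to_yaml(tmp_path / "c.yaml")
    loaded = bl.ProjectConfig.from_yaml(tmp_path / "c.yaml")
    assert loaded == cfg


def test_reopening_project_restores_config(tmp_path):
    path = tmp_path / "p.db"
    p = bl.Project(path, bl.ProjectConfig(**CFG))
    p.close()
    reopened = bl.Project(path)
    assert reopened.config.class_names == ["x", "y"]
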