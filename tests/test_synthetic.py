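"""Generator tests: determinism, manifest bookkeeping, cue conflict, and the
shape/texture separability guarantees that make the cue-conflict battery
meaningful."""

import json

import numpy as np
import pytest

from blurlab.synthetic import (CueConflictSpec, DatasetManifest, SceneParams,
                               default_class_specs, generate_cue_conflict_set,
                               generate_dataset, render_object_image)


class TestRendering:
    def test_render_is_deterministic(self):
        cls = default_class_specs(4)[2]
        scene = SceneParams.draw(123, 64)
        a = render_object_image(cls, scene)
        b = render_object_image(cls, scene)
        assert np.array_equal(a, b)

    def test_image_range_and_shape(self):
        cls = default_class_specs(2)[0]
        img = render_object_image(cls, SceneParams.draw(5, 48), image_size=48)
        assert img.shape == (48, 48, 3)
        assert img.dtype == np.float32
        assert img.min() >= 0 and img.max() <= 1

    def test_object_fully_inside_frame_at_scale_bounds(self):
        cls = default_class_specs(2)[1]
        for seed in range(10):
            _, mask = render_object_image(cls, SceneParams.draw(seed, 64),
                                          return_mask=True)
            border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
            assert border.max() == 0.0  # no object pixel touches the border

    def test_texture_spectrum_peaks_at_class_frequency(self):
        # FFT-peak oracle: the interior of a rendered object is the class
        # plaid, so its spectrum peaks at the class carrier frequency.
        cls = default_class_specs(16)[1]  # square shape, freq 8 cycles/image
        scene = SceneParams((0.0, 0.0), 0.0, 0.95, seed=9)
        img, mask = render_object_image(cls, scene, return_mask=True)
        patch = img[16:48, 16:48, 0]          # fully inside the square
        assert mask[16:48, 16:48].min() == 1.0
        f = np.abs(np.fft.fftshift(np.fft.fft2(patch - patch.mean())))
        yy, xx = np.mgrid[0:32, 0:32]
        r = np.hypot(yy - 16, xx - 16)
        peak_r = r.ravel()[np.argmax(f.ravel())]
        # crop is half the image side, so the expected radius is freq/2
        assert abs(peak_r - cls.freq / 2) <= 1.5


class TestDataset:
    def test_sizing_and_balance(self, tiny_dataset):
        ds = tiny_dataset
        assert ds.train_images.shape == (48, 32, 32, 3)
        assert ds.test_images.shape == (24, 32, 32, 3)
        counts = ds.manifest.counts()
        assert all(v == 12 for v in counts["train"].values())
        assert all(v == 6 for v in counts["test"].values())

    def test_16_class_100_per_class_yields_1600_test_images(self):
        # manifest-level check of the reference test-set sizing
        n_classes, n_test = 16, 100
        records = [{"split": "test", "class_id": c}
                   for c in range(n_classes) for _ in range(n_test)]
        m = DatasetManifest(n_classes, 64, 0, [str(c) for c in range(16)],
                            records)
        assert sum(m.counts()["test"].values()) == 1600

    def test_minimal_two_class_dataset(self):
        ds = generate_dataset(n_classes=2, n_train=1, n_test=1, image_size=32,
                              master_seed=3)
        assert len(ds.train_images) == 2
        assert set(ds.train_labels) == {0, 1}

    def test_regeneration_same_seed_identical(self):
        a = generate_dataset(n_classes=3, n_train=2, n_test=1, image_size=32,
                             master_seed=7)
        b = generate_dataset(n_classes=3, n_train=2, n_test=1, image_size=32,
                             master_seed=7)
        assert a.manifest.hash() == b.manifest.hash()
        assert np.array_equal(a.train_images, b.train_images)
        c = generate_dataset(n_classes=3, n_train=2, n_test=1, image_size=32,
                             master_seed=8)
        assert not np.array_equal(a.train_images, c.train_images)

    def test_train_test_scene_seeds_disjoint(self, tiny_dataset):
        seeds = {"train": set(), "test": set()}
        for r in tiny_dataset.manifest.records:
            seeds[r["split"]].add(r["scene_seed"])
        assert not seeds["train"] & seeds["test"]

    def test_manifest_json_round_trip(self, tiny_dataset):
        m = tiny_dataset.manifest
        again = DatasetManifest.from_json(m.to_json())
        assert again.to_json() == m.to_json()
        assert json.loads(m.to_json())["n_classes"] == 4

    def test_save_load_round_trip(self, tiny_dataset, tmp_path):
        tiny_dataset.save(tmp_path / "d")
        back = type(tiny_dataset).load(tmp_path / "d")
        assert np.array_equal(back.train_labels, tiny_dataset.train_labels)
        # 8-bit PNG quantization only
        assert np.abs(back.train_images - tiny_dataset.train_images).max() <= 1 / 255

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_dataset(n_classes=1)
        with pytest.raises(ValueError):
            generate_dataset(n_classes=4, n_train=0)


class TestCueConflict:
    def test_pair_grid_sizing(self):
        classes = default_class_specs(4)
        cc = generate_cue_conflict_set(classes, n_per_pair=2, image_size=32)
        assert len(cc) == 4 * 3 * 2
        assert (cc.shape_labels != cc.texture_labels).all()
        per_shape = np.bincount(cc.shape_labels)
        assert (per_shape == 6).all()

    def test_reference_sizing_formula(self):
        # 16 classes x 15 partners x 5 per ordered pair = 1,200 images
        assert 16 * 15 * 5 == 1200

    def test_two_class_minimal(self):
        cc = generate_cue_conflict_set(default_class_specs(2), n_per_pair=1,
                                       image_size=32)
        assert len(cc) == 2

    def test_equal_labels_rejected(self):
        with pytest.raises(ValueError):
            CueConflictSpec(shape_class=3, texture_class=3)

    def test_silhouette_matches_pure_shape_render(self):
        # mask-equality oracle: a cue-conflict render shares its silhouette
        # with the pure shape-class render under the same scene
        classes = default_class_specs(4)
        scene = SceneParams.draw(77, 64)
        _, mask_pure = render_object_image(classes[1], scene, return_mask=True)
        _, mask_cc = render_object_image(classes[1], scene,
                                         texture_of=classes[3],
                                         return_mask=True)
        assert np.array_equal(mask_pure, mask_cc)


class TestSeparability:
    """Pilot linear classifiers: shape alone and texture alone both carry
    class information, so cue-conflict decisions can meaningfully split."""

    def test_silhouettes_separable_by_shape_alone(self, tiny_dataset):
        from sklearn.linear_model import LogisticRegression

        from blurlab.stimuli import lowpass

        ds = tiny_dataset

        def silhouettes(images):
            # blur away the texture (sigma 2 kills both carrier frequencies),
            # then downscale: what remains is the bright silhouette
            smooth = lowpass(images, 2.0).mean(axis=3)
            n = len(images)
            return smooth.reshape(n, 8, 4, 8, 4).mean(axis=(2, 4)).reshape(n, -1)

        clf = LogisticRegression(max_iter=2000)
        clf.fit(silhouettes(ds.train_images), ds.train_labels)
        acc = clf.score(silhouettes(ds.test_images), ds.test_labels)
        n, p0 = len(ds.test_labels), 1.0 / ds.n_classes
        assert acc > p0 + 2.33 * np.sqrt(p0 * (1 - p0) / n)  # above chance, p<.01

    def test_texture_patches_separable_by_texture_alone(self, tiny_dataset):
        from sklearn.linear_model import LogisticRegression

        ds = tiny_dataset
        # central patch lies inside the object at these scene scale bounds
        def patches(images):
            p = images[:, 12:20, 12:20, 0]
            f = np.abs(np.fft.fft2(p - p.mean(axis=(1, 2), keepdims=True)))
            return f.reshape(len(p), -1)

        clf = LogisticRegression(max_iter=2000)
        clf.fit(patches(ds.train_images), ds.train_labels)
        acc = clf.score(patches(ds.test_images), ds.test_labels)
        n, p0 = len(ds.test_labels), 1.0 / ds.n_classes
        assert acc > p0 + 2.33 * np.sqrt(p0 * (1 - p0) / n)
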