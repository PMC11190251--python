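"""Shared fixtures: one synthetic study dataset and one pre-trained encoder,
built once per test session because contrastive training is the expensive
step everything downstream reuses."""

import numpy as np
import pytest

import bulklabel as bl

# Study conditions shared by the learning/efficiency tests: 300 objects in
# 3 well-separated classes, 32-px patches, a tiny encoder pooled to 16 px.
ENCODER_SPEC = bl.EncoderSpec(patch_size=32, encoder_size=16, feature_dim=48,
                              hidden_dim=96, projection_dim=24)
TRAIN_CFG = bl.TrainConfig(seed=3, epochs_pretrain=20, epochs_finetune=8)
CLASS_NAMES = ["alpha", "beta", "gamma"]


@pytest.fixture(scope="session")
def dataset():
    """(images, masks, truth) for the default 300-object, 3-class spec."""
    return bl.generate_dataset(bl.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def truth_map(dataset):
    _, _, truth = dataset
    return {(str(r.image_id), int(r.instance_id)): int(r.class_id)
            for r in truth.itertuples()}


def make_project(dataset, path=":memory:"):
    images, masks, _ = dataset
    cfg = bl.ProjectConfig(name="study", patch_size=32, class_names=CLASS_NAMES)
    project = bl.Project(path, cfg)
    for i, (img, mask) in enumerate(zip(images, masks)):
        project.import_image(f"img_{i:03d}", img, mask)
    project.extract_patches()
    return project


@pytest.fixture()
def project(dataset):
    return make_project(dataset)


@pytest.fixture(scope="session")
def patches(dataset):
    """Training patches in (image_id, instance_id) order."""
    proj = make_project(dataset)
    records = proj.get_patches()
    keys = [r.key for r in records]
    return keys, [r.patch for r in records]


@pytest.fixture(scope="session")
def pretrained(patches):
    """Self-supervised model state on the study patches."""
    _, imgs = patches
    return bl.train_selfsupervised(imgs, ENCODER_SPEC, TRAIN_CFG, n_classes=3)


@pytest.fixture(scope="session")
def true_labels(patches, truth_map):
    keys, _ = patches
    return np.asarray([truth_map[k] for k in keys])
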