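import numpy as np
import pytest

from granulenet.backbone import BackboneSpec, build_backbone
from granulenet.synthetic import SynthParams, generate_dataset


@pytest.fixture(scope="session")
def tiny_extractor():
    return build_backbone(BackboneSpec.tiny(), init="random", seed=7)


@pytest.fixture(scope="session")
def full_extractor():
    # ~1.5 s to build; shared by the shape and montage tests.
    return build_backbone(BackboneSpec.full(), init="random", seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 low-noise tiny-frame images (20 per class), masks retained."""
    return generate_dataset(20, SynthParams.tiny(), seed=7, keep_masks=True)


@pytest.fixture(scope="session")
def tiny_pipeline_models(tiny_extractor, tiny_dataset):
    """(improved_scorer, trained conventional model) fitted on tiny_dataset."""
    from granulenet.conventional import TrainConfig, train_conventional
    from granulenet.pipeline import make_improved_scorer
    from granulenet.svm_head import fit_svm

    feats = np.stack([tiny_extractor.extract(s).flat for s in tiny_dataset])
    labels = np.array([s.y for s in tiny_dataset])
    svm = fit_svm(feats, labels)
    scorer = make_improved_scorer(tiny_extractor, svm)
    conventional = train_conventional(
        tiny_dataset, tiny_extractor.spec,
        TrainConfig(learning_rate=1e-2, batch_size=4, epochs=10, seed=7),
        extractor=tiny_extractor)
    return scorer, conventional


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
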