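import numpy as np
import pandas as pd
import pytest

import protaxsound as ps
from protaxsound.pipeline import PipelineConfig, prepare_clip, train_bundle


@pytest.fixture(scope="session")
def library():
    return ps.generate_species_library(5, seed=1)


@pytest.fixture(scope="session")
def noiseless_clip(library):
    clip, rois = ps.synthesize_clip(library[0], duration=1.5, noise_level=0.0, seed=3)
    return clip, rois


@pytest.fixture(scope="session")
def tiny_cfg():
    return PipelineConfig(rf_trees=100, cnn_epochs=8, inner_folds=2)


@pytest.fixture(scope="session")
def tiny_dataset():
    return ps.generate_dataset(3, 6, noise_level=0.05, seed=2)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset, tiny_cfg):
    samples, rows = [], []
    for clip, row in zip(tiny_dataset.clips, tiny_dataset.metadata.to_dict("records")):
        s = prepare_clip(clip, tiny_cfg, row["file"], species=row["species_id"])
        if s is not None:
            samples.append(s)
            rows.append(row)
    return samples, pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_prepared, tiny_cfg):
    samples, meta = tiny_prepared
    return train_bundle(samples, meta, tiny_cfg, seed=5)
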