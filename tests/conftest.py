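"""Shared fixtures: synthetic recordings and a pipeline feature table.

Everything is generated at test time from seeds; the expensive session-scoped
fixtures are built lazily, only when a requesting test actually runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dusqa.config import PipelineConfig
from dusqa.features import extract_features, features_to_frame
from dusqa.synthetic import SynthSpec, make_dataset, synth_recording


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """One 60-s high-SNR recording with ground truth."""
    return synth_recording(SynthSpec(duration_s=60.0, snr_db=20.0, seed=11))


@pytest.fixture(scope="session")
def pipeline_features(cfg) -> pd.DataFrame:
    """Feature table of a strongly separated 6-subject synthetic dataset.

    Each subject's 60-s record mixes high-SNR (good) and low-SNR (poor) 15-s
    blocks, so every subject contributes segments of both classes; labels come
    from the simulated annotators through the consensus rule.
    """
    recordings, segments = make_dataset(n_subjects=6, records_per_subject=1,
                                        duration_s=60.0, seed=7)
    by_record: dict[str, list] = {}
    for s in segments:
        by_record.setdefault(s.record_id, []).append(s)
    frames = []
    for rec, _truth in recordings:
        fvs, _beats = extract_features(rec, cfg, by_record[rec.record_id])
        frames.append(features_to_frame(fvs))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
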