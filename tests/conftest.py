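"""Shared fixtures: a small labeled dataset and surrogates trained on it.

Everything is generated at run time from fixed seeds; no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibusynth.dataset import (
    LabeledDataset,
    SamplingConfig,
    build_dataset,
    sample_inputs,
    split_dataset,
)
from ibusynth.kinetics import INPUT_NAMES
from ibusynth.surrogate import GradientBoostedSurrogate


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """600 simulator-labeled rows (log-uniform, fixed seed)."""
    inputs = sample_inputs(SamplingConfig(n_samples=600, seed=20240901))
    return build_dataset(inputs)


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    return split_dataset(small_dataset, seed=11)


@pytest.fixture(scope="session")
def small_surrogates(small_splits) -> dict[str, GradientBoostedSurrogate]:
    """One default-hyperparameter surrogate per output, fit on the train split."""
    train, _, _ = small_splits
    models = {}
    for tgt in ("y1", "y2", "y3"):
        models[tgt] = GradientBoostedSurrogate(target=tgt, random_state=0).fit(
            train.inputs, train.outputs[tgt]
        )
    return models


def make_synthetic_dataset(
    inputs: pd.DataFrame, outputs: pd.DataFrame, censored=None
) -> LabeledDataset:
    """Hand-built LabeledDataset (synthetic labels, no simulation)."""
    n = len(inputs)
    cens = pd.Series([False] * n) if censored is None else pd.Series(censored)
    return LabeledDataset(
        inputs=inputs.reset_index(drop=True),
        outputs=outputs.reset_index(drop=True),
        censored=cens.reset_index(drop=True),
        provenance={"synthetic": True},
    )


def random_bounded_inputs(n: int, seed: int) -> pd.DataFrame:
    """Uniform-in-log random design rows inside the documented bounds."""
    return sample_inputs(SamplingConfig(n_samples=n, seed=seed))
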