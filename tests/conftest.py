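import numpy as np
import pytest

import eegintent as ei
from eegintent.features import extract_feature_table
from eegintent.preprocess import epoch_question, preprocess_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def build_feature_table(
    n_subjects,
    n_insider,
    n_conflict,
    duration,
    intent_effect=0.0,
    scenario_effect=0.0,
    seed=0,
    channels=None,
    yes_prob=0.5,
):
    """Full synthetic pipeline (clean signals, no artifacts) to a feature table."""
    design = ei.make_design(
        n_subjects,
        n_insider,
        n_conflict,
        yes_prob_by_type={"insider": yes_prob, "conflict": yes_prob},
        dropout_prob=0.0,
        seed=seed,
    )
    effects = ei.EffectSpec(
        intent_effect=intent_effect,
        scenario_effect=scenario_effect,
        artifacts=ei.ArtifactConfig.none(),
    )
    epochs = []
    for rec in ei.synthesize_experiment(design, effects, seed, duration=duration):
        epochs.extend(epoch_question(preprocess_recording(rec)))
    return extract_feature_table(epochs, channels=channels)


@pytest.fixture(scope="session")
def strong_intent_table():
    """Two subjects, ten 30 s insider questions each, strong intent effect."""
    return build_feature_table(
        2, 10, 0, duration=30.0, intent_effect=1.0, seed=3, channels=["F3", "Fz", "F4"]
    )


@pytest.fixture(scope="session")
def clean_30s_recording():
    design = ei.make_design(1, 1, 0, yes_prob_by_type={"insider": 1.0},
                            dropout_prob=0.0, seed=0)
    effects = ei.EffectSpec(artifacts=ei.ArtifactConfig.none())
    rec = next(ei.synthesize_experiment(design, effects, seed=0, duration=30.0))
    return preprocess_recording(rec)
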