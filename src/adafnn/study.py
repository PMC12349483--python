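"""Frozen model and training settings for the synthetic study.

These are the package's equivalent of a tuned per-dataset configuration
table: a small architecture scaled to the synthetic problem (J=200, F<=8)
rather than the full-scale signals, with the optimizer protocol fixed at
its defaults (Adam, learning rate 1e-4, at most 500 epochs, patience 20).
Tests and the acceptance script both import from here so every experiment
runs the same conditions.
"""

from __future__ import annotations

from .model import (
    BasisLayerSpec,
    ClassifierHeadSpec,
    MicroNetworkSpec,
    ModelSpec,
)
from .regularization import RegularizationConfig
from .training import TrainingConfig

# small-capacity settings for the synthetic study
STUDY_K = 4
STUDY_MICRO_WIDTHS = (16, 8)
STUDY_MLP_WIDTHS = (32, 16)
STUDY_DROPOUT = 0.20
STUDY_LAMBDA1 = 1.0
STUDY_LAMBDA2 = 0.05
STUDY_KR1 = 2
STUDY_KR2 = 3
STUDY_BATCH = 16


def study_model_spec(F: int, K: int = STUDY_K) -> ModelSpec:
    """The small Multi-AdaFNN used throughout the synthetic experiments."""
    return ModelSpec(
        basis=BasisLayerSpec(K, F, MicroNetworkSpec(STUDY_MICRO_WIDTHS),
                             layer_norm=False),
        head=ClassifierHeadSpec(hidden_widths=STUDY_MLP_WIDTHS,
                                dropout_rate=STUDY_DROPOUT),
    )


def study_training_config(seed: int, K: int = STUDY_K) -> TrainingConfig:
    """Optimizer protocol at its defaults plus the study regularization."""
    return TrainingConfig(
        seed=seed,
        batch_size=STUDY_BATCH,
        dropout_rate=STUDY_DROPOUT,
        reg=RegularizationConfig(lambda1=STUDY_LAMBDA1, lambda2=STUDY_LAMBDA2,
                                 kR1=min(STUDY_KR1, K),
                                 kR2=min(STUDY_KR2, max(K, 2)),
                                 subsample_seed=seed),
    )
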