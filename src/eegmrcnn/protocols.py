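"""Canonical study conditions used by the examples and validation runs.

The full clinical-scale protocol (41 vs 34 subjects, 10 min recordings,
filters 32/64/64, 200 training epochs) is far beyond a single-CPU desk run,
so the package also fixes one *scaled demo protocol* whose results are
quoted in the documentation: 20+20 subjects, 48 s of recording each (12
four-second epochs per subject), a planted beta-band power ratio of 1.8
between groups, MRCNN models with filter counts divided by 8, and shortened
training. These are package-level constants so that every test, script and
README example refers to the same conditions.
"""

from __future__ import annotations

from .data import BANDS
from .models import ModelSpec
from .synth import CohortSpec
from .train_eval import TrainConfig

__all__ = [
    "demo_cohort_spec",
    "demo_model_spec",
    "demo_train_config",
    "DEMO_BETA_RATIO",
    "DEMO_TRAIN_EPOCHS",
    "DEMO_RANKING_TRAIN_EPOCHS",
]

#: Planted group ratio of total beta-band power in the demo cohort.
DEMO_BETA_RATIO = 1.8

#: Training epochs per fold for the demo classification run.
DEMO_TRAIN_EPOCHS = 30

#: Shorter schedule used when many replicate runs are compared.
DEMO_RANKING_TRAIN_EPOCHS = 12


def demo_cohort_spec(seed: int, n_per_group: int = 20,
                     duration_s: float = 48.0,
                     beta_ratio: float = DEMO_BETA_RATIO) -> CohortSpec:
    """Two balanced groups differing only in beta-band power."""
    return CohortSpec(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        duration_s=duration_s,
        band_effects=((BANDS["beta"], beta_ratio),),
        seed=seed,
    )


def demo_model_spec(architecture: str = "MRCNN_RSE") -> ModelSpec:
    """The architecture at 1/8 filter width (CPU-trainable in minutes)."""
    return ModelSpec(architecture=architecture).scaled(8)


def demo_train_config(seed: int) -> TrainConfig:
    """The standard schedule (batch 32, warmup to 1e-3, decay to 5e-4,
    weight decay 1e-3, 5 folds) with the run's seed."""
    return TrainConfig(seed=seed)
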