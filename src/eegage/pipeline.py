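"""End-to-end convenience wrappers: recording -> features -> model-ready table.

These helpers chain the preprocessing, montage, segmentation and feature
stages with their default configurations; each stage remains individually
usable.  Cohort extraction is streaming (one recording in memory at a time)
so full-length cohorts stay well within desk-scale memory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_subject
from .preprocess import PreprocessConfig, preprocess, segment_epochs, to_bipolar
from .recording import RawRecording
from .simulate import SyntheticCohortSpec, simulate_subject

__all__ = ["subject_features", "simulate_cohort_features"]


def subject_features(rec: RawRecording,
                     pre_cfg: PreprocessConfig | None = None,
                     feat_cfg: FeatureConfig | None = None,
                     epoch_len: float = 60.0,
                     overlap: float = 0.5) -> dict[str, float]:
    """Preprocess, re-montage, epoch and extract one subject's features."""
    pre_cfg = pre_cfg or PreprocessConfig()
    rec = preprocess(rec, pre_cfg)
    if pre_cfg.montage_mode == "bipolar":
        rec = to_bipolar(rec, pre_cfg.bipolar_pairs)
    epochs = segment_epochs(rec, epoch_len, overlap)
    return extract_subject(epochs, feat_cfg)


def simulate_cohort_features(spec: SyntheticCohortSpec,
                             pre_cfg: PreprocessConfig | None = None,
                             feat_cfg: FeatureConfig | None = None,
                             epoch_len: float = 60.0,
                             overlap: float = 0.5) -> pd.DataFrame:
    """Simulate a cohort and extract its FeatureTable, streaming per subject.

    Returns a DataFrame indexed by subject_id whose first columns are
    ``age`` and ``sex`` followed by the named features.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(spec.age_lo, spec.age_hi, spec.n_subjects)
    sexes = np.array(["F", "M"] * spec.n_subjects)[: spec.n_subjects]
    rng.shuffle(sexes)
    child_seeds = rng.integers(0, 2 ** 31 - 1, spec.n_subjects)

    rows, index = [], []
    for i in range(spec.n_subjects):
        rec, _ = simulate_subject(spec, float(ages[i]), int(child_seeds[i]),
                                  sex=str(sexes[i]))
        rows.append(subject_features(rec, pre_cfg, feat_cfg, epoch_len, overlap))
        index.append(f"sub-{i:03d}")
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    table.insert(0, "sex", sexes)
    table.insert(0, "age", ages)
    return table
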