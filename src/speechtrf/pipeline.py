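"""End-to-end protocol: full-vs-reduced fits and the group-level report.

Ties the layers together the way the study design prescribes: for every
subject and source, fit the full predictor battery and a reduced model
omitting the feature under investigation with a shared partition/basis/
step, take the per-source quality-index difference as that feature's
improvement map, then run the ROI, lateralization and language analyses
over subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import TRFBasis, make_basis
from .boosting import DEFAULT_STEP, cross_validated_fit
from .simulate import StudyData
from .sourcespace import GroupDataset
from .stats import (
    language_regression,
    lateralization_index,
    pairwise_language_ttests,
    roi_summary,
)

__all__ = [
    "FEATURE_REGISTRY",
    "validate_feature",
    "improvement_dataset",
    "hemisphere_summary",
    "li_table",
]

# Feature names follow the context-level x measure grid of the analysis;
# cohort entropy does not exist at the sublexical level (no word cohort).
CONTEXT_LEVELS = ("sublexical", "lexical", "sentence")
MEASURES = ("surprisal", "cohort_entropy", "phoneme_entropy")
FEATURE_REGISTRY = tuple(
    f"{level}_{measure}"
    for level in CONTEXT_LEVELS
    for measure in MEASURES
    if not (level == "sublexical" and measure == "cohort_entropy")
) + ("word_onset", "phoneme_onset", "gammatone_envelope", "gammatone_onset")


def validate_feature(name: str) -> str:
    if name == "sublexical_cohort_entropy":
        raise ValueError("cohort entropy is not defined at the sublexical level")
    if name not in FEATURE_REGISTRY:
        raise ValueError(f"unknown feature {name!r}; known: {FEATURE_REGISTRY}")
    return name


def improvement_dataset(
    study: StudyData,
    feature: str,
    k: int = 4,
    step: float = DEFAULT_STEP,
    basis: TRFBasis | None = None,
) -> GroupDataset:
    """Per-subject improvement maps for one feature (full minus reduced q).

    Both fits share the partition, basis and step; responses of all
    sources are fit per subject.  Returns a GroupDataset of Delta quality
    index per (subject, source).
    """
    validate_feature(feature)
    names = [t.name for t in study.tracks]
    if feature not in names:
        raise ValueError(f"study has no track named {feature!r}")
    reduced = [t for t in study.tracks if t.name != feature]
    if basis is None:
        basis = make_basis(fs=study.spec.fs)
    n_subj = len(study.labels)
    maps = np.empty((n_subj, study.space.n_sources))
    for i in range(n_subj):
        full = cross_validated_fit(study.tracks, study.responses[i], k, step, basis)
        red = cross_validated_fit(reduced, study.responses[i], k, step, basis)
        maps[i] = full.quality - red.quality
    return GroupDataset(maps, list(study.labels), study.space)


def hemisphere_summary(
    ds: GroupDataset, baseline: str = "English"
) -> dict[str, pd.DataFrame]:
    """ROI t-tests, language regression and pairwise tests per hemisphere."""
    out: dict[str, pd.DataFrame] = {}
    for hemi in ("L", "R"):
        mask = ds.space.hemisphere == hemi
        if ds.roi is not None:
            mask = mask & ds.roi
        values = ds.values[:, mask].mean(axis=1)
        out[f"roi_{hemi}"] = roi_summary(ds, mask)
        if len(set(ds.labels)) >= 2:
            out[f"regression_{hemi}"] = language_regression(
                values, ds.labels, baseline
            )
            out[f"pairwise_{hemi}"] = pairwise_language_ttests(values, ds.labels)
    return out


def li_table(ds: GroupDataset) -> pd.DataFrame:
    """Per-subject lateralization index of hemispheric improvement strengths."""
    left = ds.space.hemisphere == "L"
    right = ds.space.hemisphere == "R"
    if ds.roi is not None:
        left = left & ds.roi
        right = right & ds.roi
    L = ds.values[:, left].mean(axis=1)
    R = ds.values[:, right].mean(axis=1)
    li = lateralization_index(L, R)
    return pd.DataFrame(
        {"subject": np.arange(len(li)), "language": ds.labels,
         "strength_L": L, "strength_R": R, "li": li}
    )
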