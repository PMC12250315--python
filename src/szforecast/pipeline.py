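"""End-to-end glue: synthetic cohort -> labeled, featurized subjects.

Chains the standard stages — bipolar montage derivation, 0.1-20 Hz
band-pass + 40 Hz resampling, rater-consensus events, seizure merging,
epoch labeling with right-censor exclusion, and QEEG featurization — into
the :class:`~szforecast.forecaster.SubjectFeatures` objects the forecaster
and alarm evaluator consume.
"""

from __future__ import annotations

import numpy as np

from .eeg_io import MontageSpec, Recording, consensus_events, default_montage_8ch, preprocess
from .features import FeatureSpec, featurize
from .forecaster import SubjectFeatures
from .labeling import (
    EPOCH_LEN_S,
    exclude_right_censored,
    label_epochs,
    merge_close_seizures,
)
from .synthetic import SyntheticSubject


def prepare_subject(
    rec: Recording,
    ann_or_events,
    montage: MontageSpec | None = None,
    feature_spec: FeatureSpec | None = None,
    sph_s: float = 180.0,
    sop_s: float = 420.0,
    consensus_k: int | None = None,
    epoch_len_s: float = EPOCH_LEN_S,
    preprocessed: bool = False,
) -> SubjectFeatures:
    """Montage, preprocess, label and featurize one subject.

    ``ann_or_events`` is an :class:`AnnotationSet` (consensus threshold
    ``consensus_k``, default 2 for multi-rater sets, 1 for a single rater)
    or an explicit event list.  The censoring horizon is SPH + SOP.
    """
    montage = montage or default_montage_8ch()
    feature_spec = feature_spec or FeatureSpec()
    if hasattr(ann_or_events, "masks"):
        k = consensus_k
        if k is None:
            k = 2 if ann_or_events.n_raters >= 2 else 1
        raw_events = consensus_events(ann_or_events, k=k)
    else:
        raw_events = list(ann_or_events)
    events = merge_close_seizures(raw_events, sph_s)

    from .eeg_io import derive_bipolar_montage

    if not preprocessed:
        rec = preprocess(derive_bipolar_montage(rec, montage))
    epochs = label_epochs(rec, events, epoch_len_s=epoch_len_s)
    epochs = exclude_right_censored(epochs, events, sph_s + sop_s,
                                    record_end_s=rec.duration_s)
    fset = featurize(epochs, rec, montage, feature_spec)
    return SubjectFeatures(
        subject_id=rec.subject_id,
        epochs=epochs,
        fset=fset,
        events=events,
        raw_events=raw_events,
        has_seizures=len(raw_events) > 0,
        record_end_s=rec.duration_s,
    )


def prepare_cohort(
    cohort: list[SyntheticSubject],
    montage: MontageSpec | None = None,
    feature_spec: FeatureSpec | None = None,
    sph_s: float = 180.0,
    sop_s: float = 420.0,
) -> list[SubjectFeatures]:
    return [
        prepare_subject(
            s.recording, s.annotations, montage, feature_spec, sph_s, sop_s
        )
        for s in cohort
    ]


def adjacent_trend_fraction(
    grid, value_col: str, along: str, other: str, increasing: bool
) -> float:
    """Fraction of adjacent grid-cell pairs (along one axis, other axis
    fixed) whose values move in the stated direction (ties count as
    conforming)."""
    ok = 0
    total = 0
    for _, sub in grid.groupby(other):
        sub = sub.sort_values(along)
        vals = sub[value_col].to_numpy()
        d = np.diff(vals)
        d = d[np.isfinite(d)]
        total += len(d)
        ok += int((d >= -1e-12).sum()) if increasing else int((d <= 1e-12).sum())
    return ok / total if total else float("nan")
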