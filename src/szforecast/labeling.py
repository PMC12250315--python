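"""Epoch segmentation and state labeling.

Recordings are cut into fixed, non-overlapping 20 s epochs and each epoch is
assigned one of four states relative to the (merged) seizure events:

* **ictal** — the epoch overlaps a seizure;
* **preictal** — every second of the epoch lies within [onset - 360 s,
  onset - 60 s) of some seizure (and outside every exclusion zone);
* **interictal** — every second lies outside all seizure-adjacent zones
  (at least 60 s after the previous offset and 360 s before the next
  onset);
* **excluded** — everything else (near-onset and post-seizure buffer
  zones, boundary-straddling epochs, right-censored record tails).

The preictal window takes precedence over the nominal interictal window so
the two classes are disjoint: interictal ends a full 360 s before the next
onset, keeping near-onset data out of the negative class.

Seizures closer than the SPH are merged into a single event before labeling
and alarm scoring.  Epochs whose look-ahead horizon extends past the end of
the recording with no intervening seizure are right-censored (the outcome is
unknowable) and excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eeg_io import MontageSpec, Recording

LABELS = ("ictal", "preictal", "interictal", "excluded")

#: defaults, in seconds: preictal window [onset-360, onset-60), 60 s
#: post-seizure buffer, interictal clear zone ending 360 s before next onset
PREICTAL_START_S = 360.0
PREICTAL_END_S = 60.0
POST_SZ_BUFFER_S = 60.0
EPOCH_LEN_S = 20.0


def merge_close_seizures(
    events: list[tuple[float, float]], sph_s: float
) -> list[tuple[float, float]]:
    """Merge successive seizures whose gap is strictly less than the SPH.

    Seizures that follow the previous one within less than the SPH cannot be
    warned about independently; they are treated as a single seizure event
    spanning both.  Idempotent; a gap of exactly ``sph_s`` is not merged.
    """
    if not events:
        return []
    ev = sorted(events)
    merged = [ev[0]]
    for onset, offset in ev[1:]:
        prev_onset, prev_offset = merged[-1]
        if onset < prev_offset:
            raise ValueError("events overlap; merge or fix annotations first")
        if onset - prev_offset < sph_s:
            merged[-1] = (prev_onset, max(offset, prev_offset))
        else:
            merged.append((onset, offset))
    return merged


def label_epochs(
    rec: Recording,
    events: list[tuple[float, float]],
    epoch_len_s: float = EPOCH_LEN_S,
    preictal_start_s: float = PREICTAL_START_S,
    preictal_end_s: float = PREICTAL_END_S,
    post_sz_buffer_s: float = POST_SZ_BUFFER_S,
    pre_sz_clear_s: float = PREICTAL_START_S,
) -> pd.DataFrame:
    """Assign a state label to every epoch of a recording.

    Returns a DataFrame with columns ``subject_id, start_s, epoch_len_s,
    label, censored`` covering the recording in order with non-overlapping
    epochs.  ``pre_sz_clear_s`` is the distance before the next onset at
    which the interictal window closes; it defaults to the preictal window
    start so that the two classes are disjoint.

    State precedence per second (the 1 Hz annotation resolution): ictal,
    then the near-onset/post-seizure exclusion zones, then preictal (the
    union over events' windows — consecutive seizures' windows may abut),
    then interictal.  An epoch is ictal if it contains any ictal second,
    preictal/interictal only if every second carries that state, excluded
    otherwise.  Raises if events overlap (callers must merge first).
    """
    ev = sorted(events)
    for (a0, b0), (a1, _) in zip(ev, ev[1:]):
        if a1 < b0:
            raise ValueError("overlapping events; call merge_close_seizures first")
    duration = rec.duration_s
    n_epochs = int(np.floor(duration / epoch_len_s + 1e-9))
    starts = np.arange(n_epochs) * epoch_len_s

    n_sec = int(np.ceil(duration))
    sec = np.arange(n_sec, dtype=float)
    ictal_m = np.zeros(n_sec, dtype=bool)
    near_m = np.zeros(n_sec, dtype=bool)
    pre_m = np.zeros(n_sec, dtype=bool)
    clear = max(pre_sz_clear_s, preictal_start_s)
    for onset, offset in ev:
        ictal_m |= (sec + 1 > onset) & (sec < offset)
        near_m |= (sec >= onset - preictal_end_s) & (sec < onset)
        near_m |= (sec >= offset) & (sec < offset + post_sz_buffer_s)
        if clear > preictal_start_s:  # extra clear zone before the window
            near_m |= (sec >= onset - clear) & (sec < onset - preictal_start_s)
        pre_m |= (sec >= onset - preictal_start_s) & (sec < onset - preictal_end_s)
    # precedence: ictal > exclusion zones > preictal > interictal
    ICT, NEAR, PRE, INTER = 3, 2, 1, 0
    sec_state = np.zeros(n_sec, dtype=np.int8)
    sec_state[pre_m] = PRE
    sec_state[near_m] = NEAR
    sec_state[ictal_m] = ICT

    labels = []
    for s in starts:
        block = sec_state[int(round(s)) : int(round(s + epoch_len_s))]
        if (block == ICT).any():
            labels.append("ictal")
        elif (block == PRE).all():
            labels.append("preictal")
        elif (block == INTER).all():
            labels.append("interictal")
        else:
            labels.append("excluded")
    return pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "start_s": starts,
            "epoch_len_s": epoch_len_s,
            "label": pd.Categorical(labels, categories=list(LABELS)),
            "censored": False,
        }
    )


def exclude_right_censored(
    epochs: pd.DataFrame,
    events: list[tuple[float, float]],
    horizon_s: float,
    record_end_s: float | None = None,
) -> pd.DataFrame:
    """Flag epochs whose look-ahead horizon runs past the end of the record.

    A non-ictal epoch with look-ahead window
    ``[epoch_end, epoch_end + horizon_s)`` extending strictly past the
    record end — with no seizure onset between the epoch end and the record
    end to settle the outcome — has an unknowable label and is excluded.
    ``horizon_s`` should equal SPH + SOP of the evaluation in use.
    """
    if horizon_s < 0:
        raise ValueError("horizon_s must be non-negative")
    out = epochs.copy()
    if horizon_s == 0:
        return out
    if record_end_s is None:
        record_end_s = float(
            (epochs["start_s"] + epochs["epoch_len_s"]).max()
        )
    onsets = np.array([on for on, _ in events])
    ends = out["start_s"].to_numpy() + out["epoch_len_s"].to_numpy()
    past_end = ends + horizon_s > record_end_s + 1e-9
    if len(onsets):
        settles = np.array(
            [np.any((onsets >= e) & (onsets < record_end_s)) for e in ends]
        )
    else:
        settles = np.zeros(len(ends), dtype=bool)
    censor = past_end & ~settles & (out["label"].to_numpy() != "ictal")
    out.loc[censor, "label"] = "excluded"
    out.loc[censor, "censored"] = True
    return out


def augment_transpositions(
    rec: Recording, spec: MontageSpec
) -> list[Recording]:
    """Left-right, front-back and doubly-flipped copies of a montaged
    recording.

    Each copy permutes the derivation rows by the corresponding involution
    (the front-back flip also applies the per-derivation polarity sign of a
    longitudinal chain).  Intended for training folds only; augmented copies
    keep the parent ``subject_id`` so fold assignment follows the parent.
    """
    n = rec.n_channels
    if len(spec.derivations) != n:
        raise ValueError("montage spec does not match recording channel count")

    def apply(perm: list[int], signs: list[int]) -> Recording:
        sig = rec.signal[perm] * np.asarray(signs)[perm, None]
        return Recording(
            subject_id=rec.subject_id,
            channel_labels=list(rec.channel_labels),
            fs=rec.fs,
            signal=sig,
            start_time_s=rec.start_time_s,
        )

    lr = spec.left_right_map
    fb = spec.front_back_map
    ones = [1] * n
    fb_signs = list(spec.front_back_signs)
    both = [fb[lr[i]] for i in range(n)]  # LR after FB
    return [
        apply(lr, ones),
        apply(fb, fb_signs),
        apply(both, fb_signs),
    ]
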