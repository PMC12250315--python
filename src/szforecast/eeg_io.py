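"""EEG containers, EDF round-trip, bipolar montage derivation and preprocessing.

The pipeline operates on :class:`Recording` (channels x samples, microvolts),
multi-rater :class:`AnnotationSet` objects (1 Hz binary seizure masks), and a
:class:`MontageSpec` describing bipolar derivations together with the
left-right pairing and the two transposition maps used for training-data
augmentation.

All intervals are half-open ``[onset, offset)`` in seconds from record start.
"""

from __future__ import annotations

import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: channel-name patterns treated as non-EEG and dropped on EDF read
_NON_EEG_RE = re.compile(r"(ECG|EKG|EMG|EOG|RESP|SAO2|SPO2|PULSE|CO2)", re.I)


@dataclass
class Recording:
    """Multichannel EEG block.

    Attributes
    ----------
    subject_id : str
    channel_labels : list of str
        Electrode names (e.g. ``"C3"``) or bipolar derivation names
        (e.g. ``"C3-O1"``) after montage derivation.
    fs : float
        Sampling rate in Hz.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    start_time_s : float
        Offset of the first sample from the nominal record start.
    """

    subject_id: str
    channel_labels: list[str]
    fs: float
    signal: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.subject_id,
            list(self.channel_labels),
            self.fs,
            self.signal.copy(),
            self.start_time_s,
        )


@dataclass
class MontageSpec:
    """Bipolar montage plus symmetry maps.

    ``derivations`` is an ordered list of ``(anode, cathode)`` electrode-label
    pairs.  ``left_right_pairs`` lists homologous derivation index pairs
    (left index, right index); midline derivations are listed in
    ``midline``.  ``left_right_map`` and ``front_back_map`` are involutive
    permutations of derivation indices; ``front_back_signs`` carries the
    per-derivation polarity (+1/-1) that a front-back electrode flip induces
    on a longitudinal bipolar chain.
    """

    derivations: list[tuple[str, str]]
    left_right_pairs: list[tuple[int, int]]
    left_right_map: list[int]
    front_back_map: list[int]
    front_back_signs: list[int] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.derivations)
        if not self.front_back_signs:
            self.front_back_signs = [1] * n
        for name, perm in (
            ("left_right_map", self.left_right_map),
            ("front_back_map", self.front_back_map),
        ):
            if sorted(perm) != list(range(n)):
                raise ValueError(f"{name} is not a permutation of 0..{n - 1}")
            if any(perm[perm[i]] != i for i in range(n)):
                raise ValueError(f"{name} is not an involution")
        seen: set[int] = set()
        for left, right in self.left_right_pairs:
            if left in seen or right in seen:
                raise ValueError("a derivation appears in more than one left-right pair")
            seen.update((left, right))

    @property
    def derivation_labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.derivations]

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "derivations": [list(d) for d in self.derivations],
            "left_right_pairs": [list(p) for p in self.left_right_pairs],
            "left_right_map": list(self.left_right_map),
            "front_back_map": list(self.front_back_map),
            "front_back_signs": list(self.front_back_signs),
            "midline": list(self.midline),
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MontageSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            derivations=[tuple(d) for d in data["derivations"]],
            left_right_pairs=[tuple(p) for p in data["left_right_pairs"]],
            left_right_map=list(data["left_right_map"]),
            front_back_map=list(data["front_back_map"]),
            front_back_signs=list(data.get("front_back_signs", [])),
            midline=list(data.get("midline", [])),
        )


def default_montage_8ch() -> MontageSpec:
    """Longitudinal bipolar montage over the 8-electrode 10-20 subset
    Fp1/Fp2, C3/C4, T3/T4, O1/O2 (two parasagittal + two temporal chains).

    Derivation order::

        0 Fp1-C3   1 C3-O1   2 Fp2-C4   3 C4-O2
        4 Fp1-T3   5 T3-O1   6 Fp2-T4   7 T4-O2

    Left-right flip swaps each left derivation with its right homologue.
    Front-back flip swaps the anterior and posterior derivation within each
    chain and reverses polarity (Fp1-C3 maps to O1-C3 = -(C3-O1)).
    """
    derivations = [
        ("Fp1", "C3"), ("C3", "O1"), ("Fp2", "C4"), ("C4", "O2"),
        ("Fp1", "T3"), ("T3", "O1"), ("Fp2", "T4"), ("T4", "O2"),
    ]
    left_right_pairs = [(0, 2), (1, 3), (4, 6), (5, 7)]
    left_right_map = [2, 3, 0, 1, 6, 7, 4, 5]
    front_back_map = [1, 0, 3, 2, 5, 4, 7, 6]
    front_back_signs = [-1] * 8
    return MontageSpec(
        derivations=derivations,
        left_right_pairs=left_right_pairs,
        left_right_map=left_right_map,
        front_back_map=front_back_map,
        front_back_signs=front_back_signs,
    )


@dataclass
class AnnotationSet:
    """Per-rater seizure masks at 1 Hz.

    ``masks`` has shape (n_raters, n_seconds); entry 1 marks a second the
    rater annotated as seizure.
    """

    masks: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=int)
        if self.masks.ndim != 2:
            raise ValueError("masks must be 2-D (raters x seconds)")

    @property
    def n_raters(self) -> int:
        return self.masks.shape[0]

    @property
    def n_seconds(self) -> int:
        return self.masks.shape[1]

    def events(self, consensus_k: int = 2) -> list[tuple[float, float]]:
        return consensus_events(self, k=consensus_k)


def consensus_events(ann: AnnotationSet, k: int = 2) -> list[tuple[float, float]]:
    """Maximal runs of seconds where at least ``k`` raters mark seizure.

    Returns sorted, non-overlapping ``(onset_s, offset_s)`` half-open
    intervals.  Antitone in ``k``: raising the threshold can only shrink
    events.
    """
    if not 1 <= k <= ann.n_raters:
        raise ValueError(f"k={k} outside [1, {ann.n_raters}]")
    agree = (ann.masks.sum(axis=0) >= k).astype(int)
    padded = np.concatenate([[0], agree, [0]])
    edges = np.flatnonzero(np.diff(padded))
    onsets, offsets = edges[0::2], edges[1::2]
    return [(float(a), float(b)) for a, b in zip(onsets, offsets)]


def events_to_masks(
    events: list[tuple[float, float]], n_seconds: int
) -> np.ndarray:
    """Rasterize half-open event intervals onto a 1 Hz binary mask."""
    mask = np.zeros(n_seconds, dtype=int)
    for onset, offset in events:
        lo = max(0, int(np.floor(onset)))
        hi = min(n_seconds, int(np.ceil(offset)))
        mask[lo:hi] = 1
    return mask


# ---------------------------------------------------------------------------
# EDF round trip
# ---------------------------------------------------------------------------

def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as plain 16-bit EDF, one data record per second.

    Physical ranges are per-channel (data min/max, symmetric guard band);
    amplitudes therefore round-trip within one 16-bit quantization step of
    the channel's physical span.  Requires an integer sampling rate.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    total = n_records * fs
    sig = np.zeros((n_ch, total))
    sig[:, : rec.n_samples] = rec.signal

    phys_min, phys_max = [], []
    scaled = np.empty_like(sig, dtype=np.int16)
    for i in range(n_ch):
        lo, hi = float(sig[i].min()), float(sig[i].max())
        span = max(hi - lo, 1e-6)
        lo -= 0.01 * span
        hi += 0.01 * span
        phys_min.append(lo)
        phys_max.append(hi)
        scaled[i] = np.round(
            (sig[i] - lo) / (hi - lo) * (32767 - (-32768)) + (-32768)
        ).astype(np.int16)

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * n_ch), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        (16, [pad(lbl, 16) for lbl in rec.channel_labels]),
        (80, [pad("", 80)] * n_ch),
        (8, [pad("uV", 8)] * n_ch),
        (8, [pad(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)]),
        (8, [pad(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)]),
        (8, [pad("-32768", 8)] * n_ch),
        (8, [pad("32767", 8)] * n_ch),
        (80, [pad("", 80)] * n_ch),
        (8, [pad(str(fs), 8)] * n_ch),
        (32, [pad("", 32)] * n_ch),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for _, col in fields:
            fh.write(b"".join(col))
        for r in range(n_records):
            block = scaled[:, r * fs : (r + 1) * fs]
            fh.write(struct.pack(f"<{n_ch * fs}h", *block.reshape(-1)))


def read_edf(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EDF file into a Recording, keeping EEG channels only.

    Non-EEG channels (ECG/EMG/respiration and the like, identified by label)
    are dropped with a logged warning.  Mixed sampling rates are resolved by
    MNE's reader (resampled to the highest common rate on load).
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    except Exception as exc:  # pragma: no cover - error path
        raise OSError(f"cannot parse {path} as EDF: {exc}") from exc
    labels = list(raw.ch_names)
    keep = [i for i, lbl in enumerate(labels) if not _NON_EEG_RE.search(lbl)]
    dropped = [labels[i] for i in range(len(labels)) if i not in keep]
    if dropped:
        logger.warning("dropping non-EEG channels %s from %s", dropped, path.name)
    data = raw.get_data(picks=keep) * 1e6  # MNE loads volts; convert to uV
    return Recording(
        subject_id=subject_id or path.stem,
        channel_labels=[labels[i] for i in keep],
        fs=float(raw.info["sfreq"]),
        signal=data,
    )


# ---------------------------------------------------------------------------
# Montage derivation and preprocessing
# ---------------------------------------------------------------------------

def derive_bipolar_montage(rec: Recording, spec: MontageSpec) -> Recording:
    """Form bipolar derivations ``anode - cathode`` sample-wise.

    Output channel order follows ``spec.derivations``; labels become
    ``"A-C"`` strings.
    """
    if len(set(spec.derivations)) != len(spec.derivations):
        raise ValueError("duplicate derivation in montage spec")
    index = {lbl: i for i, lbl in enumerate(rec.channel_labels)}
    rows = []
    for anode, cathode in spec.derivations:
        for lbl in (anode, cathode):
            if lbl not in index:
                raise KeyError(f"electrode {lbl!r} not present in recording")
        rows.append(rec.signal[index[anode]] - rec.signal[index[cathode]])
    return Recording(
        subject_id=rec.subject_id,
        channel_labels=spec.derivation_labels,
        fs=rec.fs,
        signal=np.array(rows),
        start_time_s=rec.start_time_s,
    )


def preprocess(
    rec: Recording,
    low_hz: float = 0.1,
    high_hz: float = 20.0,
    target_fs: float = 40.0,
) -> Recording:
    """Zero-phase band-pass (0.1-20 Hz default) then polyphase resample to
    40 Hz.

    A 4th-order Butterworth is applied forward-backward (zero phase) so that
    filtering does not shift preictal timing.  When the upper band edge
    coincides with Nyquist the band-pass degrades to a high-pass (the band
    is already limited).  Output duration is preserved within one sample.
    """
    if rec.fs < 2 * high_hz:
        raise ValueError(
            f"fs={rec.fs} cannot honor the {low_hz}-{high_hz} Hz band "
            f"(need fs >= {2 * high_hz})"
        )
    nyq = rec.fs / 2.0
    if high_hz >= nyq * (1 - 1e-9):
        sos = sps.butter(4, low_hz / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(4, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)

    if abs(rec.fs - target_fs) < 1e-9:
        out = filtered
        out_fs = rec.fs
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
        out_fs = target_fs
    return Recording(
        subject_id=rec.subject_id,
        channel_labels=list(rec.channel_labels),
        fs=out_fs,
        signal=out,
        start_time_s=rec.start_time_s,
    )


def read_annotation_csv(path: str | Path) -> dict[str, dict[int, list[tuple[float, float]]]]:
    """Read a sidecar annotation CSV (subject, rater, onset_s, offset_s)."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, dict[int, list[tuple[float, float]]]] = {}
    for (subject, rater), grp in df.groupby(["subject", "rater"]):
        out.setdefault(str(subject), {})[int(rater)] = [
            (float(a), float(b)) for a, b in zip(grp["onset_s"], grp["offset_s"])
        ]
    return out


def write_annotation_csv(
    path: str | Path, per_subject: dict[str, AnnotationSet]
) -> None:
    """Write per-rater events for a cohort as CSV (subject, rater, onset_s, offset_s)."""
    import pandas as pd

    rows = []
    for subject, ann in per_subject.items():
        for r in range(ann.n_raters):
            single = AnnotationSet(ann.masks[r : r + 1])
            for onset, offset in consensus_events(single, k=1):
                rows.append((subject, r, onset, offset))
    pd.DataFrame(rows, columns=["subject", "rater", "onset_s", "offset_s"]).to_csv(
        path, index=False
    )
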