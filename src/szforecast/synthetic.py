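"""Synthetic neonatal-like EEG cohorts with seizures and a plantable
preictal signature.

The generator exists so that every downstream stage (preprocessing,
labeling, QEEG features, sequence classification, alarm evaluation,
calibration) has a signal whose ground truth is known and tunable:

* background: 1/f-weighted Gaussian noise, with inter-channel correlation
  that is higher for homologous left/right electrode pairs than for
  non-homologous pairs;
* seizures: amplitude-ramped rhythmic discharges (sinusoid with a frequency
  chirp, 3 Hz slowing toward 1.5 Hz), durations lognormal with configurable
  median (default 74 s, matching the cohort statistics the generator
  emulates);
* preictal signature: over the ``preictal_span`` seconds before each onset,
  a linear ramp adds 8-20 Hz band power and inflates variance, scaled by
  ``preictal_strength``.  Strength 0 makes preictal and interictal segments
  statistically exchangeable, giving a null cohort for control experiments.

Everything is reproducible bit-exactly from ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .eeg_io import AnnotationSet, Recording, events_to_masks

#: 10-20 electrode subset used at the default channel count; left/right
#: homologous partners are adjacent.
_PAIRED_LABELS = ["Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2",
                  "F3", "F4", "P3", "P4", "F7", "F8", "T5", "T6"]


@dataclass
class SynthConfig:
    """Cohort generation parameters.

    Defaults describe the reduced-scale study cohort: 12 subjects, half
    with seizures, one hour of 8-channel EEG each, seizure durations
    lognormal with median 74 s, a 300 s preictal span, three raters.
    """

    n_subjects: int = 12
    seizure_subject_fraction: float = 0.5
    record_duration: float = 3600.0
    fs: float = 64.0
    n_channels: int = 8
    seizures_min: int = 2
    seizures_max: int = 6
    seizure_duration_median: float = 74.0
    seizure_duration_sigma: float = 0.7
    min_gap_s: float = 360.0
    preictal_strength: float = 0.0
    preictal_span: float = 300.0
    n_raters: int = 3
    rater_noise: float = 0.0
    background_std_uv: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels % 2 != 0 or self.n_channels <= 0:
            raise ValueError("n_channels must be a positive even number")
        if self.n_channels > len(_PAIRED_LABELS):
            raise ValueError(f"n_channels must be <= {len(_PAIRED_LABELS)}")
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        if self.fs < 40:
            raise ValueError("fs must be >= 40 Hz")
        if not 0 <= self.seizure_subject_fraction <= 1:
            raise ValueError("seizure_subject_fraction must lie in [0,1]")
        if self.preictal_strength < 0:
            raise ValueError("preictal_strength must be non-negative")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")

    @property
    def channel_labels(self) -> list[str]:
        return _PAIRED_LABELS[: self.n_channels]


@dataclass
class GroundTruth:
    """Per-subject planted events and preictal windows (half-open seconds)."""

    seizure_events: list[tuple[float, float]]
    planted_preictal_windows: list[tuple[float, float]]
    preictal_strength: float

    def __post_init__(self) -> None:
        ev = sorted(self.seizure_events)
        for (a0, b0), (a1, _) in zip(ev, ev[1:]):
            if a1 < b0:
                raise ValueError("seizure events overlap")
        self.seizure_events = ev


def _subject_rng(config: SynthConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(subject_index)])
    )


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude-weighted Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.ones_like(freqs)
    nz = freqs > 0
    weight[nz] = 1.0 / np.sqrt(freqs[nz])
    weight[0] = 0.0  # no DC
    x = np.fft.irfft(spec * weight, n=n)
    return x / x.std()


def generate_background(config: SynthConfig, subject_index: int) -> Recording:
    """Generate one subject's multichannel 1/f background.

    Each channel mixes a global source, a per-homologous-pair source and an
    independent component, so homologous left/right channels correlate more
    strongly than non-homologous ones.  Amplitudes are scaled to
    ``background_std_uv`` microvolts.
    """
    config.validate()
    rng = _subject_rng(config, subject_index)
    n = int(round(config.record_duration * config.fs))
    n_ch = config.n_channels
    global_src = _pink_noise(rng, n, config.fs)
    pair_srcs = [_pink_noise(rng, n, config.fs) for _ in range(n_ch // 2)]
    sig = np.empty((n_ch, n))
    # weights: corr(homologous) = a^2+b^2 ~ 0.58, corr(other) = a^2 ~ 0.25
    a, b = 0.5, 0.575
    c = np.sqrt(1 - a**2 - b**2)
    for ch in range(n_ch):
        own = _pink_noise(rng, n, config.fs)
        sig[ch] = a * global_src + b * pair_srcs[ch // 2] + c * own
    sig *= config.background_std_uv
    return Recording(
        subject_id=f"S{subject_index:03d}",
        channel_labels=config.channel_labels,
        fs=config.fs,
        signal=sig,
    )


def _draw_events(
    rng: np.random.Generator, config: SynthConfig, n_events: int
) -> list[tuple[float, float]]:
    """Place non-overlapping events with at least ``min_gap_s`` spacing.

    Onsets are sampled by distributing the slack uniformly between events;
    the first onset is kept clear of the first ``preictal_span`` so the
    planted window fits, and the last offset clear of the record end.
    """
    durations = []
    for _ in range(n_events):
        d = config.seizure_duration_median * np.exp(
            config.seizure_duration_sigma * rng.standard_normal()
        )
        durations.append(float(np.clip(d, 10.0, 300.0)))
    lead = config.preictal_span + 60.0
    tail = 60.0
    occupied = sum(durations) + (n_events - 1) * config.min_gap_s
    slack = config.record_duration - lead - tail - occupied
    if slack < 0:
        raise ValueError(
            f"{n_events} seizures (total {occupied:.0f} s + margins) do not fit "
            f"in a {config.record_duration:.0f} s record with "
            f"min_gap_s={config.min_gap_s}"
        )
    cuts = np.sort(rng.uniform(0, slack, size=n_events))
    events = []
    t = lead
    for i, dur in enumerate(durations):
        onset = t + cuts[i] - (cuts[i - 1] if i else 0.0) + (config.min_gap_s if i else 0.0)
        onset = float(np.round(onset))
        events.append((onset, float(np.round(onset + dur))))
        t = events[-1][1]
    return events


def inject_seizures(
    rec: Recording, config: SynthConfig, subject_index: int | None = None,
    n_events: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """Superimpose seizure discharges (and the optional preictal signature).

    Each seizure is an amplitude-ramped sinusoid whose frequency chirps from
    3 Hz down to 1.5 Hz, added to every channel with channel-specific phase.
    If ``preictal_strength > 0`` a linear ramp over each planted window
    [onset - preictal_span, onset) adds 8-20 Hz noise power and inflates
    variance proportionally to the strength.
    """
    config.validate()
    idx = subject_index if subject_index is not None else 0
    rng = _subject_rng(config, 10_000 + idx)
    if n_events is None:
        n_events = int(rng.integers(config.seizures_min, config.seizures_max + 1))
    out = rec.copy()
    events = _draw_events(rng, config, n_events)
    fs = rec.fs
    amp = 2.5 * config.background_std_uv
    for onset, offset in events:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        i1 = min(i1, rec.n_samples)
        t = np.arange(i1 - i0) / fs
        dur = max(t[-1], 1e-9) if len(t) else 1.0
        freq = 3.0 - 1.5 * t / dur  # chirp 3 -> 1.5 Hz
        phase = 2 * np.pi * np.cumsum(freq) / fs
        envelope = np.minimum(1.0, np.minimum(t, dur - t) / 5.0).clip(0.05)
        for ch in range(rec.n_channels):
            out.signal[ch, i0:i1] += amp * envelope * np.sin(
                phase + rng.uniform(0, 2 * np.pi)
            )

    windows = []
    for onset, _ in events:
        start = max(0.0, onset - config.preictal_span)
        windows.append((start, onset))

    if config.preictal_strength > 0:
        sos = sps.butter(4, [8 / (fs / 2), min(20 / (fs / 2), 0.99)],
                         btype="bandpass", output="sos")
        for start, end in windows:
            i0, i1 = int(round(start * fs)), int(round(end * fs))
            ramp = np.linspace(0, 1, i1 - i0, endpoint=False)
            gain = 1.0 + 0.10 * config.preictal_strength * ramp
            hf_amp = 0.25 * config.background_std_uv * config.preictal_strength
            for ch in range(rec.n_channels):
                hf = sps.sosfilt(sos, rng.standard_normal(i1 - i0))
                hf /= max(hf.std(), 1e-12)
                out.signal[ch, i0:i1] = (
                    out.signal[ch, i0:i1] * gain + hf_amp * ramp * hf
                )

    truth = GroundTruth(
        seizure_events=events,
        planted_preictal_windows=windows,
        preictal_strength=config.preictal_strength,
    )
    return out, truth


def synth_annotations(
    truth: GroundTruth, config: SynthConfig, subject_index: int | None = None
) -> AnnotationSet:
    """Per-rater 1 Hz masks: ground truth with independent boundary jitter.

    Each rater's onset and offset are shifted by an integer number of
    seconds drawn uniformly from [-rater_noise, rater_noise]; zero noise
    reproduces the truth exactly for every rater.  Jittered events never
    collapse below 1 s or leave the record.
    """
    config.validate()
    idx = subject_index if subject_index is not None else 0
    rng = _subject_rng(config, 20_000 + idx)
    n_seconds = int(np.ceil(config.record_duration))
    masks = np.zeros((config.n_raters, n_seconds), dtype=int)
    jmax = int(round(config.rater_noise))
    for r in range(config.n_raters):
        events = []
        for onset, offset in truth.seizure_events:
            if jmax > 0:
                onset = onset + rng.integers(-jmax, jmax + 1)
                offset = offset + rng.integers(-jmax, jmax + 1)
            onset = float(np.clip(onset, 0, n_seconds - 1))
            offset = float(np.clip(max(offset, onset + 1), 1, n_seconds))
            events.append((onset, offset))
        masks[r] = events_to_masks(events, n_seconds)
    return AnnotationSet(masks)


@dataclass
class SyntheticSubject:
    recording: Recording
    truth: GroundTruth
    annotations: AnnotationSet
    has_seizures: bool


def generate_subject(
    config: SynthConfig, subject_index: int, with_seizures: bool
) -> SyntheticSubject:
    rec = generate_background(config, subject_index)
    if with_seizures:
        rec, truth = inject_seizures(rec, config, subject_index)
    else:
        truth = GroundTruth([], [], config.preictal_strength)
    ann = synth_annotations(truth, config, subject_index)
    return SyntheticSubject(rec, truth, ann, with_seizures)


def generate_cohort(config: SynthConfig) -> list[SyntheticSubject]:
    """Generate the full cohort; the first ``round(fraction * n)`` subjects
    (in a seed-determined shuffled order) carry seizures."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 999]))
    n_sz = int(round(config.seizure_subject_fraction * config.n_subjects))
    flags = np.zeros(config.n_subjects, dtype=bool)
    flags[:n_sz] = True
    rng.shuffle(flags)
    return [
        generate_subject(config, i, bool(flags[i]))
        for i in range(config.n_subjects)
    ]


def write_cohort(cohort: list[SyntheticSubject], out_dir: str | Path) -> None:
    """Write EDFs, a sidecar annotation CSV and a ground-truth JSON."""
    from .eeg_io import write_annotation_csv, write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    anns = {}
    truths = {}
    for subj in cohort:
        sid = subj.recording.subject_id
        write_edf(subj.recording, out / f"{sid}.edf")
        anns[sid] = subj.annotations
        truths[sid] = {
            "seizure_events": subj.truth.seizure_events,
            "planted_preictal_windows": subj.truth.planted_preictal_windows,
            "preictal_strength": subj.truth.preictal_strength,
        }
    write_annotation_csv(out / "annotations.csv", anns)
    (out / "ground_truth.json").write_text(json.dumps(truths, indent=1))


def config_from_yaml(path: str | Path) -> SynthConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return SynthConfig(**data)
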