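"""SPH/SOP alarm system and its time-point evaluation metrics.

An alarm triggered at time ``t`` opens a warning lasting SPH + SOP: the
seizure prediction horizon (SPH) is the guaranteed lead time before the
seizure occurrence period (SOP), the window in which the predicted seizure
is expected.  The alarm is a **true positive** iff some (merged) seizure
onsets within ``[t + SPH, t + SPH + SOP)``; otherwise it is a false
positive.  A seizure whose onset is covered by no alarm's occurrence period
is a false negative.  While a warning is active no new alarm can trigger;
the next trigger is eligible at the first epoch after expiry.

All time-based metrics are counted on the 20-s epoch grid:

* sensitivity — two variants: the time-point form (true-alarm time over
  all time points in alarm states associated with seizures, crediting each
  missed seizure with the trigger window ``[onset - SPH - SOP,
  onset - SPH)`` a correct alarm would have occupied) and the event-level
  form (fraction of seizures whose onset fell inside a warning's
  occurrence period); sweeps use the event-level form as TPR/recall;
* corrected time-in-warning — (warning time − true-alarm time) /
  (total time − true-alarm time);
* precision — true-alarm time / all alarm time;
* FDR — false-positive alarms per hour of evaluable monitoring.

Threshold sweeps trace these metrics over a dense probability-threshold
grid; AUROC integrates TPR (sensitivity) against FPR (corrected TIW) by
trapezoid, AUPRC integrates precision against recall step-wise to avoid
optimistic bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forecaster import PredictionTrace
from .labeling import merge_close_seizures

STATE_NONE, STATE_FALSE, STATE_TRUE = 0, 1, 2


@dataclass
class AlarmConfig:
    sph_s: float = 180.0
    sop_s: float = 420.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.sph_s < 0:
            raise ValueError("sph_s must be >= 0")
        if self.sop_s <= 0:
            raise ValueError("sop_s must be > 0")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class AlarmTrack:
    """Alarms plus per-time-point states on the evaluable epoch grid."""

    cfg: AlarmConfig
    times: np.ndarray  # evaluable grid points (epoch end times), sorted
    epoch_len_s: float
    alarms: list[tuple[float, str]]  # (trigger time, "true_positive"/"false_positive")
    state: np.ndarray  # int8 per grid point
    events: list[tuple[float, float]]
    fn_onsets: list[float]

    @property
    def n_alarms(self) -> int:
        return len(self.alarms)

    @property
    def n_false_alarms(self) -> int:
        return sum(1 for _, o in self.alarms if o == "false_positive")


@dataclass
class ConfusionTally:
    tp_time_s: float
    fp_time_s: float
    tn_time_s: float
    fn_count: int
    missed_credit_time_s: float
    total_time_s: float
    n_alarms: int
    n_false_alarms: int
    n_seizures: int

    @property
    def time_in_true_alarm_s(self) -> float:
        return self.tp_time_s


def evaluable_mask(
    trace: PredictionTrace,
    events: list[tuple[float, float]],
    horizon_s: float,
    record_end_s: float | None = None,
) -> np.ndarray:
    """Non-burn-in grid points that are not right-censored at this horizon."""
    if record_end_s is None:
        record_end_s = float(trace.epoch_end_times_s[-1])
    t = trace.epoch_end_times_s
    mask = ~trace.burn_in_mask
    past = t + horizon_s > record_end_s + 1e-9
    onsets = np.array([on for on, _ in events])
    if len(onsets):
        settles = np.array(
            [np.any((onsets >= u) & (onsets < record_end_s)) for u in t]
        )
    else:
        settles = np.zeros(len(t), dtype=bool)
    return mask & ~(past & ~settles)


def raise_alarms(
    trace: PredictionTrace,
    cfg: AlarmConfig,
    events: list[tuple[float, float]],
    premerged: bool = False,
) -> AlarmTrack:
    """Threshold the probability trace into SPH/SOP alarms.

    Events are merged with :func:`merge_close_seizures` at the SPH unless
    ``premerged``.  A new alarm triggers at the first evaluable grid point
    with probability strictly above threshold and no active warning.
    """
    if not 0 <= cfg.threshold <= 1:
        raise ValueError("threshold outside [0, 1]")
    ev = events if premerged else merge_close_seizures(events, cfg.sph_s)
    onsets = np.array([on for on, _ in ev])
    horizon = cfg.sph_s + cfg.sop_s
    keep = evaluable_mask(trace, ev, horizon)
    times = trace.epoch_end_times_s[keep]
    probs = trace.preictal_prob[keep]

    alarms: list[tuple[float, str]] = []
    state = np.zeros(len(times), dtype=np.int8)
    above = np.flatnonzero(probs > cfg.threshold)
    pos = 0
    while pos < len(above):
        i = above[pos]
        t = times[i]
        is_tp = bool(
            len(onsets)
            and np.any((onsets >= t + cfg.sph_s) & (onsets < t + horizon))
        )
        alarms.append((float(t), "true_positive" if is_tp else "false_positive"))
        j = int(np.searchsorted(times, t + horizon, side="left"))
        state[i:j] = STATE_TRUE if is_tp else STATE_FALSE
        pos = int(np.searchsorted(above, j, side="left"))

    covered = np.zeros(len(onsets), dtype=bool)
    for t, outcome in alarms:
        if outcome == "true_positive":
            covered |= (onsets >= t + cfg.sph_s) & (onsets < t + horizon)
    fn_onsets = [float(o) for o in onsets[~covered]]
    return AlarmTrack(
        cfg=cfg,
        times=times,
        epoch_len_s=float(np.median(np.diff(times))) if len(times) > 1 else 20.0,
        alarms=alarms,
        state=state,
        events=ev,
        fn_onsets=fn_onsets,
    )


def tally(track: AlarmTrack) -> ConfusionTally:
    """Count grid time in each alarm state plus missed-seizure credit."""
    dt = track.epoch_len_s
    tp = float((track.state == STATE_TRUE).sum()) * dt
    fp = float((track.state == STATE_FALSE).sum()) * dt
    total = float(len(track.times)) * dt
    missed = 0.0
    cfg = track.cfg
    for onset in track.fn_onsets:
        lo, hi = onset - cfg.sph_s - cfg.sop_s, onset - cfg.sph_s
        missed += float(((track.times >= lo) & (track.times < hi)).sum()) * dt
    return ConfusionTally(
        tp_time_s=tp,
        fp_time_s=fp,
        tn_time_s=total - tp - fp,
        fn_count=len(track.fn_onsets),
        missed_credit_time_s=missed,
        total_time_s=total,
        n_alarms=track.n_alarms,
        n_false_alarms=track.n_false_alarms,
        n_seizures=len(track.events),
    )


def _sum_tallies(tallies: list[ConfusionTally]) -> ConfusionTally:
    return ConfusionTally(
        tp_time_s=sum(t.tp_time_s for t in tallies),
        fp_time_s=sum(t.fp_time_s for t in tallies),
        tn_time_s=sum(t.tn_time_s for t in tallies),
        fn_count=sum(t.fn_count for t in tallies),
        missed_credit_time_s=sum(t.missed_credit_time_s for t in tallies),
        total_time_s=sum(t.total_time_s for t in tallies),
        n_alarms=sum(t.n_alarms for t in tallies),
        n_false_alarms=sum(t.n_false_alarms for t in tallies),
        n_seizures=sum(t.n_seizures for t in tallies),
    )


def sensitivity(t: ConfusionTally) -> float:
    """Time-point sensitivity; NaN (missing) when no seizure-associated
    alarm time exists to score against.

    The denominator is all time points in alarm states associated with
    seizures: true-alarm time plus, for each missed seizure, the trigger
    window a correct alarm would have occupied.  See
    :func:`seizure_sensitivity` for the event-level variant used in
    threshold sweeps.
    """
    denom = t.tp_time_s + t.missed_credit_time_s
    if denom <= 0:
        return float("nan")
    return t.tp_time_s / denom


def seizure_sensitivity(t: ConfusionTally) -> float:
    """Event-level sensitivity: fraction of (merged) seizures whose onset
    fell inside some warning's occurrence period.

    This is the operative definition in the seizure-prediction-
    characteristic literature; NaN (missing) when the record holds no
    seizures.
    """
    if t.n_seizures == 0:
        return float("nan")
    return (t.n_seizures - t.fn_count) / t.n_seizures


def corrected_tiw(t: ConfusionTally) -> float:
    """(warning time − true-alarm time) / (total time − true-alarm time)."""
    denom = t.total_time_s - t.time_in_true_alarm_s
    if denom <= 0:
        raise ValueError("degenerate timeline: no time outside true alarms")
    return (t.tp_time_s + t.fp_time_s - t.time_in_true_alarm_s) / denom


def precision(t: ConfusionTally) -> float:
    denom = t.tp_time_s + t.fp_time_s
    if denom <= 0:
        return float("nan")
    return t.tp_time_s / denom


def fdr_per_hour(track: AlarmTrack, total_time_s: float | None = None) -> float:
    """False-positive alarms per evaluable hour."""
    if total_time_s is None:
        total_time_s = len(track.times) * track.epoch_len_s
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    return track.n_false_alarms / (total_time_s / 3600.0)


# ---------------------------------------------------------------------------
# threshold sweeps and SPH x SOP grids
# ---------------------------------------------------------------------------

def _as_pairs(
    traces, events
) -> list[tuple[PredictionTrace, list[tuple[float, float]]]]:
    if isinstance(traces, PredictionTrace):
        return [(traces, events)]
    if isinstance(events, dict):
        return [(tr, events[tr.subject_id]) for tr in traces]
    return list(zip(traces, events))


def _threshold_grid(pairs, n_grid: int = 101, include_observed: bool = True) -> np.ndarray:
    grid = np.linspace(0, 1, n_grid)
    if include_observed:
        obs = np.concatenate(
            [tr.preictal_prob[~tr.burn_in_mask] for tr, _ in pairs]
        )
        grid = np.union1d(grid, np.unique(obs[np.isfinite(obs)]))
    return grid


@dataclass
class SweepResult:
    curves: pd.DataFrame  # per-threshold pooled metrics
    auroc: float
    auprc: float
    prevalence: float
    flagged_degenerate: bool = False


def prevalence_time_fraction(pairs, cfg: AlarmConfig) -> float:
    """Positive-class prevalence on the time-point scale: the fraction of
    evaluable grid time inside some seizure's correct-trigger window
    ``[onset - SPH - SOP, onset - SPH)``."""
    pos = 0
    total = 0
    for trace, events in pairs:
        ev = merge_close_seizures(events, cfg.sph_s)
        keep = evaluable_mask(trace, ev, cfg.sph_s + cfg.sop_s)
        times = trace.epoch_end_times_s[keep]
        total += len(times)
        in_win = np.zeros(len(times), dtype=bool)
        for onset, _ in ev:
            in_win |= (times >= onset - cfg.sph_s - cfg.sop_s) & (
                times < onset - cfg.sph_s
            )
        pos += int(in_win.sum())
    return pos / total if total else float("nan")


def threshold_sweep(
    traces,
    cfg: AlarmConfig,
    events,
    n_grid: int = 101,
    include_observed: bool = True,
) -> SweepResult:
    """Pooled alarm metrics across a dense threshold grid.

    ``traces`` may be a single trace or a list; ``events`` correspondingly
    a single event list, a list of lists, or a dict keyed by subject ID.
    TPR/FPR and precision/recall are computed from the pooled (micro-
    averaged) tallies at each threshold.
    """
    pairs = _as_pairs(traces, events)
    if not pairs:
        raise ValueError("no prediction traces supplied")
    thresholds = _threshold_grid(pairs, n_grid, include_observed)
    merged = [
        (tr, merge_close_seizures(ev, cfg.sph_s)) for tr, ev in pairs
    ]
    rows = []
    for th in thresholds:
        c = AlarmConfig(cfg.sph_s, cfg.sop_s, float(th))
        tallies = [
            tally(raise_alarms(tr, c, ev, premerged=True)) for tr, ev in merged
        ]
        tot = _sum_tallies(tallies)
        fpr = (
            corrected_tiw(tot)
            if tot.total_time_s > tot.time_in_true_alarm_s
            else float("nan")
        )
        rows.append(
            {
                "threshold": float(th),
                "tpr": seizure_sensitivity(tot),
                "tp_sensitivity": sensitivity(tot),
                "fpr": fpr,
                "precision": precision(tot),
                "fdr_per_hour": (
                    tot.n_false_alarms / (tot.total_time_s / 3600.0)
                    if tot.total_time_s > 0
                    else float("nan")
                ),
                "tp_time_s": tot.tp_time_s,
                "fp_time_s": tot.fp_time_s,
                "fn_count": tot.fn_count,
                "n_alarms": tot.n_alarms,
            }
        )
    curves = pd.DataFrame(rows)
    prev = prevalence_time_fraction(pairs, cfg)

    probs = np.concatenate([tr.preictal_prob[~tr.burn_in_mask] for tr, _ in pairs])
    degenerate = np.unique(probs[np.isfinite(probs)]).size < 2
    if degenerate:
        return SweepResult(curves, 0.5, prev, prev, flagged_degenerate=True)

    ok = curves.dropna(subset=["tpr", "fpr"])
    fpr = np.concatenate([[0.0], ok["fpr"].to_numpy()[::-1], [1.0]])
    tpr = np.concatenate([[0.0], ok["tpr"].to_numpy()[::-1], [1.0]])
    order = np.argsort(fpr, kind="stable")
    auroc = float(np.trapezoid(tpr[order], fpr[order]))

    # step-wise AP scanned from high to low threshold; alarm dynamics can
    # make event recall locally non-monotone, so integrate over its
    # cumulative-max envelope (keeps the area within [0, 1])
    pr = curves.dropna(subset=["tpr", "precision"]).sort_values(
        "threshold", ascending=False
    )
    rec = np.maximum.accumulate(np.concatenate([[0.0], pr["tpr"].to_numpy()]))
    prec = pr["precision"].to_numpy()
    auprc = float(np.sum(np.diff(rec) * prec)) if len(pr) else float("nan")
    return SweepResult(curves, auroc, auprc, prev)


def grid_sweep(
    traces,
    events,
    sph_grid_s=tuple(range(60, 421, 60)),
    sop_grid_s=tuple(range(60, 421, 60)),
    n_grid: int = 41,
) -> pd.DataFrame:
    """AUROC/AUPRC/TIW over the SPH x SOP grid, pooled across subjects.

    Returns a tidy frame keyed by (sph_s, sop_s), one row per cell, for
    heatmap plotting.  Events are re-merged and right-censoring re-derived
    per cell.  Cell values are invariant to subject order (micro-averaged
    pooling).
    """
    pairs = _as_pairs(traces, events)
    trs = [tr for tr, _ in pairs]
    evs = [ev for _, ev in pairs]
    rows = []
    for sph in sph_grid_s:
        for sop in sop_grid_s:
            cfg = AlarmConfig(float(sph), float(sop), 0.5)
            res = threshold_sweep(trs, cfg, evs, n_grid=n_grid,
                                  include_observed=False)
            ok = res.curves.dropna(subset=["tpr"])
            tiw_mid = float("nan")
            if len(ok):
                # corrected TIW at the threshold closest to 80% sensitivity
                idx = (ok["tpr"] - 0.8).abs().idxmin()
                tiw_mid = float(ok.loc[idx, "fpr"])
            rows.append(
                {
                    "sph_s": float(sph),
                    "sop_s": float(sop),
                    "auroc": res.auroc,
                    "auprc": res.auprc,
                    "prevalence": res.prevalence,
                    "tiw_at_80sens": tiw_mid,
                }
            )
    return pd.DataFrame(rows)
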