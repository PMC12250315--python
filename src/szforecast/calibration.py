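"""Probabilistic quality of prediction traces: reliability, ECE, BSS.

The reliability table bins predicted probabilities into equal-width bins on
[0, 1] (default 10, last bin closed) and compares mean confidence with the
empirical positive fraction per bin.  Expected Calibration Error (ECE) is
the count-weighted mean absolute confidence/accuracy gap.  The Brier Skill
Score (BSS) compares the model's Brier score with the climatology
reference — the constant forecast at the positive-class prevalence, whose
Brier score is p̄(1 − p̄); positive BSS means the model beats climatology.

For horizon-based scoring an epoch at time t is positive iff a seizure
onsets within [t + SPH, t + SPH + SOP); the BSS grid re-derives these
labels per (SPH, SOP) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alarms import evaluable_mask, _as_pairs
from .forecaster import PredictionTrace
from .labeling import merge_close_seizures


@dataclass
class CalibrationTable:
    n_bins: int
    confidence: np.ndarray  # mean predicted probability per bin (NaN if empty)
    accuracy: np.ndarray  # empirical positive fraction per bin (NaN if empty)
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        edges = np.linspace(0, 1, self.n_bins + 1)
        return pd.DataFrame(
            {
                "bin_low": edges[:-1],
                "bin_high": edges[1:],
                "confidence": self.confidence,
                "accuracy": self.accuracy,
                "count": self.counts,
            }
        )


def reliability(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> CalibrationTable:
    """Equal-width reliability table; bin i is [i/n, (i+1)/n), last closed."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels length mismatch")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probs outside [0, 1]")
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    conf = np.full(n_bins, np.nan)
    acc = np.full(n_bins, np.nan)
    occupied = counts > 0
    sums_p = np.bincount(idx, weights=probs, minlength=n_bins)
    sums_y = np.bincount(idx, weights=labels.astype(float), minlength=n_bins)
    conf[occupied] = sums_p[occupied] / counts[occupied]
    acc[occupied] = sums_y[occupied] / counts[occupied]
    return CalibrationTable(n_bins, conf, acc, counts)


def ece(table: CalibrationTable) -> float:
    """Count-weighted mean |accuracy − confidence|; missing if no data."""
    n = table.counts.sum()
    if n == 0:
        return float("nan")
    occ = table.counts > 0
    return float(
        np.sum(table.counts[occ] * np.abs(table.accuracy[occ] - table.confidence[occ]))
        / n
    )


def brier_score(probs: np.ndarray, labels: np.ndarray) -> float:
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, float)
    return float(np.mean((probs - labels) ** 2))


def brier_skill_score(probs: np.ndarray, labels: np.ndarray) -> float:
    """BSS = 1 − BS/BS_ref with the climatology (prevalence) reference.

    Missing (NaN) for single-class labels, where the reference Brier score
    p̄(1 − p̄) vanishes.
    """
    labels = np.asarray(labels, float)
    p_bar = labels.mean()
    bs_ref = p_bar * (1 - p_bar)
    if bs_ref == 0:
        return float("nan")
    return 1.0 - brier_score(probs, labels) / bs_ref


def horizon_labels(
    trace: PredictionTrace,
    events: list[tuple[float, float]],
    sph_s: float,
    sop_s: float,
    premerged: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(probs, labels) on the evaluable grid for one horizon.

    A grid point t is positive iff a (merged) seizure onsets within
    [t + SPH, t + SPH + SOP); right-censored points are dropped.
    """
    ev = events if premerged else merge_close_seizures(events, sph_s)
    keep = evaluable_mask(trace, ev, sph_s + sop_s)
    times = trace.epoch_end_times_s[keep]
    probs = trace.preictal_prob[keep]
    onsets = np.array([on for on, _ in ev])
    labels = np.zeros(len(times), dtype=int)
    for onset in onsets:
        labels |= ((times + sph_s <= onset) & (onset < times + sph_s + sop_s)).astype(int)
    return probs, labels


def calibration_report(
    traces, events, sph_s: float, sop_s: float, n_bins: int = 10
) -> dict:
    """Pooled reliability/ECE/Brier/BSS at one horizon across subjects."""
    pairs = _as_pairs(traces, events)
    ps, ys = [], []
    for tr, ev in pairs:
        p, y = horizon_labels(tr, ev, sph_s, sop_s)
        ps.append(p)
        ys.append(y)
    probs = np.concatenate(ps)
    labels = np.concatenate(ys)
    table = reliability(probs, labels, n_bins)
    return {
        "table": table,
        "ece": ece(table),
        "brier": brier_score(probs, labels),
        "bss": brier_skill_score(probs, labels),
        "prevalence": float(labels.mean()),
        "n": int(labels.size),
    }


def bss_grid(
    traces,
    events,
    sph_grid_s=tuple(range(60, 421, 60)),
    sop_grid_s=tuple(list(range(60, 421, 60)) + [600]),
) -> pd.DataFrame:
    """BSS (and ECE) per (SPH, SOP) cell, pooled across subjects.

    Cells whose horizon labels are single-class report missing values.
    """
    pairs = _as_pairs(traces, events)
    rows = []
    for sph in sph_grid_s:
        for sop in sop_grid_s:
            ps, ys = [], []
            for tr, ev in pairs:
                p, y = horizon_labels(tr, ev, float(sph), float(sop))
                ps.append(p)
                ys.append(y)
            probs = np.concatenate(ps)
            labels = np.concatenate(ys)
            rows.append(
                {
                    "sph_s": float(sph),
                    "sop_s": float(sop),
                    "bss": brier_skill_score(probs, labels),
                    "ece": ece(reliability(probs, labels)),
                    "prevalence": float(labels.mean()),
                }
            )
    return pd.DataFrame(rows)
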