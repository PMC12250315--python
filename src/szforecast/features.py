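"""QEEG feature extraction per 20-s epoch.

Three feature families, computed on the bipolar-montaged, preprocessed
(0.1-20 Hz, 40 Hz) signal:

1. **Asymmetry indices of statistical moments** — for each homologous
   left/right derivation pair, the normalized difference
   ``(L - R) / (|L| + |R| + delta)`` of six summary statistics (mean,
   standard deviation, excess kurtosis, skew, 10th and 90th percentiles).
   Bounded in [-1, 1], scale-free and antisymmetric under a left-right
   channel transposition.
2. **Power spectral features** — Welch band powers per derivation in the
   conventional delta/theta/alpha/beta bands truncated at the 20 Hz filter
   edge; absolute (log10) and/or relative (fraction of total 0.5-20 Hz
   power).
3. **Recurrence quantification analysis (RQA)** — per derivation, the
   signal is downsampled, time-delay embedded with (m, tau), and a
   recurrence matrix is thresholded at ``radius_fraction * std(epoch)``;
   recurrence rate (RR), determinism (DET), laminarity (LAM) and mean
   diagonal line length (L) are reported, with the main diagonal excluded
   (Theiler window 1).

Column order is fixed and documented in :func:`feature_names`: asymmetry
block, then spectral block, then RQA block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .eeg_io import MontageSpec, Recording

logger = logging.getLogger(__name__)

STAT_NAMES = ("mean", "std", "kurtosis", "skew", "p10", "p90")
RQA_NAMES = ("RR", "DET", "LAM", "L")
ASYM_DELTA = 1e-12

DEFAULT_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 20.0))


@dataclass
class FeatureSpec:
    """Feature extraction parameters (all configurable stand-ins)."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    spectral_mode: str = "both"  # absolute | relative | both
    rqa_m: int = 3
    rqa_tau: int = 1
    rqa_radius_fraction: float = 0.2
    rqa_downsample: int = 2
    rqa_line_min: int = 2
    rqa_theiler: int = 1

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not (0 <= lo < hi <= 20.0):
                raise ValueError(f"band ({lo},{hi}) outside [0, 20] Hz")
        bands = sorted(self.bands)
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi:
                raise ValueError("bands overlap")
        if self.spectral_mode not in ("absolute", "relative", "both"):
            raise ValueError(f"bad spectral_mode {self.spectral_mode!r}")
        if self.rqa_radius_fraction <= 0 or self.rqa_m < 1 or self.rqa_tau < 1:
            raise ValueError("invalid RQA parameters")

    @property
    def spectral_kinds(self) -> tuple[str, ...]:
        return {
            "absolute": ("abs",),
            "relative": ("rel",),
            "both": ("abs", "rel"),
        }[self.spectral_mode]


# ---------------------------------------------------------------------------
# per-family primitives
# ---------------------------------------------------------------------------

def summary_stats(x: np.ndarray) -> np.ndarray:
    """(mean, population std, excess kurtosis, skew, p10, p90) of a signal.

    Constant signals get kurtosis = skew = 0 by convention (flagged via
    logger), never NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return _summary_stats_batch(x[None, :])[0]


def _summary_stats_batch(X: np.ndarray) -> np.ndarray:
    """Vectorized summary stats: X (n, samples) -> (n, 6)."""
    mean = X.mean(axis=1)
    std = X.std(axis=1)  # population normalization
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-signal path
        kurt = spstats.kurtosis(X, axis=1, fisher=True, bias=True)
        skew = spstats.skew(X, axis=1, bias=True)
    degenerate = ~np.isfinite(kurt) | ~np.isfinite(skew)
    if degenerate.any():
        logger.debug("constant epochs: kurtosis/skew set to 0 for %d epochs",
                     int(degenerate.sum()))
        kurt = np.where(np.isfinite(kurt), kurt, 0.0)
        skew = np.where(np.isfinite(skew), skew, 0.0)
    p10 = np.percentile(X, 10, axis=1)  # linear interpolation
    p90 = np.percentile(X, 90, axis=1)
    return np.column_stack([mean, std, kurt, skew, p10, p90])


def asymmetry_index(left_val: float, right_val: float) -> float:
    """Normalized left-right difference (L - R) / (|L| + |R| + delta).

    Bounded in [-1, 1]; antisymmetric in its arguments; the small delta
    guards the zero denominator.
    """
    return float(
        (left_val - right_val)
        / (abs(left_val) + abs(right_val) + ASYM_DELTA)
    )


def _asymmetry_batch(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    return (left - right) / (np.abs(left) + np.abs(right) + ASYM_DELTA)


def spectral_features(
    x: np.ndarray, fs: float, spec: FeatureSpec | None = None
) -> np.ndarray:
    """Welch band powers of one epoch; see :func:`_spectral_batch`."""
    spec = spec or FeatureSpec()
    return _spectral_batch(np.asarray(x, float)[None, :], fs, spec)[0]


def _spectral_batch(X: np.ndarray, fs: float, spec: FeatureSpec) -> np.ndarray:
    """Band powers for X (n, samples) -> (n, n_bands * n_kinds).

    Welch with 4 s segments, 50% overlap; band power integrates the PSD
    over the band.  Relative powers divide by total 0.5-20 Hz power, so
    they sum to 1 when the bands tile that range; an all-zero epoch gets
    uniform 1/n_bands relative power (flagged).
    """
    n = X.shape[1]
    nperseg = min(n, int(round(4 * fs)))
    freqs, psd = sps.welch(X, fs=fs, nperseg=nperseg, axis=-1)
    df = freqs[1] - freqs[0]
    band_power = np.empty((X.shape[0], len(spec.bands)))
    for b, (lo, hi) in enumerate(spec.bands):
        sel = (freqs >= lo) & (freqs < hi)
        band_power[:, b] = psd[:, sel].sum(axis=1) * df
    total_sel = (freqs >= 0.5) & (freqs < 20.0)  # half-open, matches band edges
    total = psd[:, total_sel].sum(axis=1) * df

    cols = []
    for kind in spec.spectral_kinds:
        if kind == "abs":
            cols.append(np.log10(band_power + 1e-12))
        else:
            zero = total <= 0
            if zero.any():
                logger.debug("all-zero epochs in relative mode: %d", int(zero.sum()))
            safe_total = np.where(zero, 1.0, total)
            rel = band_power / safe_total[:, None]
            rel[zero] = 1.0 / len(spec.bands)
            cols.append(rel)
    return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# RQA
# ---------------------------------------------------------------------------

def _embed_batch(X: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: X (n, s) -> (n, s-(m-1)tau, m)."""
    n_pts = X.shape[1] - (m - 1) * tau
    if n_pts < 2:
        raise ValueError("signal too short to embed")
    return np.stack([X[:, k * tau : k * tau + n_pts] for k in range(m)], axis=-1)


def _recurrence_batch(V: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Boolean recurrence matrices for embedded batch V (n, N, m)."""
    sq = (V**2).sum(axis=2)
    G = V @ V.transpose(0, 2, 1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * G
    np.maximum(d2, 0.0, out=d2)
    return d2 <= (eps**2)[:, None, None]


def _line_stats_fast(R: np.ndarray, offsets: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Points-in-lines(>=2) and line counts along one direction.

    ``offsets`` is (di, dj): (1, 1) for diagonal lines, (1, 0) for vertical
    lines.  Returns per-matrix (points_in_long_lines, n_long_lines) for
    line_min = 2.
    """
    di, dj = offsets
    nxt = np.zeros_like(R)
    prv = np.zeros_like(R)
    if dj:
        nxt[:, :-di, :-dj] = R[:, di:, dj:]
        prv[:, di:, dj:] = R[:, :-di, :-dj]
    else:
        nxt[:, :-di, :] = R[:, di:, :]
        prv[:, di:, :] = R[:, :-di, :]
    in_line = R & (nxt | prv)
    starts = R & nxt & ~prv
    return in_line.sum(axis=(1, 2)), starts.sum(axis=(1, 2))


def _line_stats_general(
    R: np.ndarray, offsets: tuple[int, int], line_min: int
) -> tuple[np.ndarray, np.ndarray]:
    """Run-length statistics along diagonals or verticals for any line_min."""
    B, N, _ = R.shape
    points = np.zeros(B, dtype=np.int64)
    counts = np.zeros(B, dtype=np.int64)
    di, dj = offsets
    for b in range(B):
        lines: list[np.ndarray] = []
        if dj:
            lines = [np.diagonal(R[b], off) for off in range(-N + 1, N)]
        else:
            lines = [R[b][:, j] for j in range(N)]
        for line in lines:
            padded = np.concatenate([[0], line.astype(np.int8), [0]])
            edges = np.flatnonzero(np.diff(padded))
            lengths = edges[1::2] - edges[0::2]
            long = lengths[lengths >= line_min]
            points[b] += long.sum()
            counts[b] += long.size
    return points, counts


def rqa_features(x: np.ndarray, spec: FeatureSpec | None = None) -> np.ndarray:
    """(RR, DET, LAM, L) of one epoch signal; see module docstring.

    A constant (zero-variance) signal returns the degenerate convention
    RR = DET = LAM = 1 with L equal to the longest off-diagonal line.
    """
    spec = spec or FeatureSpec()
    return _rqa_batch(np.asarray(x, float)[None, :], spec)[0]


def _rqa_batch(X: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """RQA for a batch of epoch signals X (n, samples) -> (n, 4)."""
    ds = max(1, int(spec.rqa_downsample))
    Y = X[:, ::ds]
    eps = spec.rqa_radius_fraction * X.std(axis=1)
    degenerate = eps <= 0
    eps = np.where(degenerate, np.inf, eps)
    V = _embed_batch(Y, spec.rqa_m, spec.rqa_tau)
    N = V.shape[1]
    if N < 50:
        raise ValueError(
            f"embedded trajectory has {N} < 50 points; reduce downsampling"
        )
    R = _recurrence_batch(V, eps)
    idx = np.arange(N)
    theiler = np.abs(idx[:, None] - idx[None, :]) >= max(1, spec.rqa_theiler)
    R &= theiler

    n_rec = R.sum(axis=(1, 2))
    denom_rr = N * N - theiler.size + theiler.sum()  # pairs outside Theiler band
    rr = n_rec / denom_rr

    if spec.rqa_line_min == 2:
        p_diag, n_diag = _line_stats_fast(R, (1, 1))
        p_vert, _ = _line_stats_fast(R, (1, 0))
    else:
        p_diag, n_diag = _line_stats_general(R, (1, 1), spec.rqa_line_min)
        p_vert, _ = _line_stats_general(R, (1, 0), spec.rqa_line_min)

    with np.errstate(invalid="ignore", divide="ignore"):
        det = np.where(n_rec > 0, p_diag / np.maximum(n_rec, 1), 0.0)
        lam = np.where(n_rec > 0, p_vert / np.maximum(n_rec, 1), 0.0)
        mean_len = np.where(n_diag > 0, p_diag / np.maximum(n_diag, 1), 0.0)

    if degenerate.any():
        logger.debug("degenerate constant epochs in RQA: %d", int(degenerate.sum()))
        det = np.where(degenerate, 1.0, det)
        lam = np.where(degenerate, 1.0, lam)
        rr = np.where(degenerate, 1.0, rr)
    return np.column_stack([rr, det, lam, mean_len])


# ---------------------------------------------------------------------------
# full featurization
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Feature matrix plus the cached per-derivation statistics needed to
    derive augmented (channel-transposed) feature views exactly."""

    X: np.ndarray  # (n_epochs, n_features)
    names: list[str]
    deriv_stats: np.ndarray  # (n_epochs, n_derivations, 6)
    spectral: np.ndarray  # (n_epochs, n_derivations, n_spectral_per_deriv)
    rqa: np.ndarray  # (n_epochs, n_derivations, 4)
    montage: MontageSpec = field(repr=False, default=None)
    spec: FeatureSpec = field(repr=False, default=None)


def feature_names(montage: MontageSpec, spec: FeatureSpec) -> list[str]:
    """Fixed feature column order.

    Asymmetry block (per left-right pair x 6 stats), spectral block (per
    derivation x kind x band) and RQA block (per derivation x 4 measures).
    """
    labels = montage.derivation_labels
    names = []
    for left, right in montage.left_right_pairs:
        for stat in STAT_NAMES:
            names.append(f"asym[{labels[left]}|{labels[right]}]_{stat}")
    for d, lbl in enumerate(labels):
        for kind in spec.spectral_kinds:
            for lo, hi in spec.bands:
                names.append(f"pow_{kind}[{lbl}]_{lo:g}-{hi:g}Hz")
    for lbl in labels:
        for rq in RQA_NAMES:
            names.append(f"rqa[{lbl}]_{rq}")
    return names


def _assemble(
    deriv_stats: np.ndarray,
    spectral: np.ndarray,
    rqa: np.ndarray,
    montage: MontageSpec,
) -> np.ndarray:
    asym_cols = [
        _asymmetry_batch(deriv_stats[:, left, :], deriv_stats[:, right, :])
        for left, right in montage.left_right_pairs
    ]
    n_ep = deriv_stats.shape[0]
    blocks = []
    if asym_cols:
        blocks.append(np.concatenate(asym_cols, axis=1))
    blocks.append(spectral.reshape(n_ep, -1))
    blocks.append(rqa.reshape(n_ep, -1))
    return np.concatenate(blocks, axis=1)


def featurize(
    epochs: pd.DataFrame,
    rec: Recording,
    montage: MontageSpec,
    spec: FeatureSpec | None = None,
    rqa_chunk: int = 64,
) -> FeatureSet:
    """Compute the full feature matrix for every epoch of one subject.

    ``rec`` must already be montaged (channels = derivations) and
    preprocessed to the nominal 40 Hz.  Every epoch gets features —
    including excluded and ictal ones, which are needed for continuous
    prediction traces — and is masked for training elsewhere.
    """
    spec = spec or FeatureSpec()
    fs = rec.fs
    n_deriv = rec.n_channels
    if n_deriv != len(montage.derivations):
        raise ValueError("recording channel count does not match montage")
    starts = epochs["start_s"].to_numpy()
    lens = epochs["epoch_len_s"].to_numpy()
    n_samp = int(round(lens[0] * fs))
    i0 = np.round(starts * fs).astype(int)
    if np.any(i0 + n_samp > rec.n_samples):
        raise ValueError("an epoch extends past the end of the recording")
    idx = i0[:, None] + np.arange(n_samp)[None, :]

    n_ep = len(epochs)
    deriv_stats = np.empty((n_ep, n_deriv, 6))
    n_spec_cols = len(spec.spectral_kinds) * len(spec.bands)
    spectral = np.empty((n_ep, n_deriv, n_spec_cols))
    rqa = np.empty((n_ep, n_deriv, 4))
    for d in range(n_deriv):
        E = rec.signal[d][idx]  # (n_ep, n_samp)
        deriv_stats[:, d, :] = _summary_stats_batch(E)
        spectral[:, d, :] = _spectral_batch(E, fs, spec)
        for lo in range(0, n_ep, rqa_chunk):
            sl = slice(lo, min(lo + rqa_chunk, n_ep))
            rqa[sl, d, :] = _rqa_batch(E[sl], spec)

    X = _assemble(deriv_stats, spectral, rqa, montage)
    return FeatureSet(
        X=X,
        names=feature_names(montage, spec),
        deriv_stats=deriv_stats,
        spectral=spectral,
        rqa=rqa,
        montage=montage,
        spec=spec,
    )


_SIGN_FLIP = np.array([-1.0, 1.0, 1.0, -1.0, -1.0, -1.0])  # mean,std,kurt,skew,p10,p90
_P10, _P90 = 4, 5


def _transform_stats(stats: np.ndarray, sign: int) -> np.ndarray:
    """Summary stats of ``sign * x`` given the stats of ``x`` (exact)."""
    if sign == 1:
        return stats
    out = stats * _SIGN_FLIP
    out[..., [_P10, _P90]] = out[..., [_P90, _P10]]  # -p90 becomes new p10
    return out


def transposed_feature_view(fset: FeatureSet, perm: list[int], signs: list[int]) -> np.ndarray:
    """Feature matrix of the channel-transposed recording, derived exactly
    from the cached per-derivation blocks.

    Row ``i`` of the flipped recording equals ``signs[perm[i]] *
    original_row[perm[i]]``; summary statistics transform analytically
    under negation, and spectral/RQA features are sign-invariant, so the
    flipped feature matrix is a deterministic column transform.  Verified
    against re-featurizing the flipped signal in the test suite.
    """
    perm = np.asarray(perm)
    stats = fset.deriv_stats[:, perm, :].copy()
    for j, src in enumerate(perm):
        if signs[src] == -1:
            stats[:, j, :] = _transform_stats(fset.deriv_stats[:, src, :], -1)
    spectral = fset.spectral[:, perm, :]
    rqa = fset.rqa[:, perm, :]
    return _assemble(stats, spectral, rqa, fset.montage)


def augmented_feature_views(fset: FeatureSet) -> list[np.ndarray]:
    """The three transposition-augmented feature matrices (left-right,
    front-back, both), matching :func:`szforecast.labeling.augment_transpositions`."""
    m = fset.montage
    n = len(m.derivations)
    ones = [1] * n
    lr, fb = list(m.left_right_map), list(m.front_back_map)
    both = [fb[lr[i]] for i in range(n)]
    return [
        transposed_feature_view(fset, lr, ones),
        transposed_feature_view(fset, fb, m.front_back_signs),
        transposed_feature_view(fset, both, m.front_back_signs),
    ]
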