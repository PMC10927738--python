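"""Frame-level acoustic features and per-segment reduction.

The classic front end computes 16 base features per 25 ms frame (10 ms
hop): zero-crossing rate, spectral entropy, log-energy and 13 MFCCs,
plus their regression deltas — 32 values per frame.  A pluggable latent
embedder adds a 1,024-dimensional representation per frame.  Each
segment's frames-by-features matrix is reduced to a single row by
taking the first principal-component loading (the dominant direction of
frame-to-frame covariation), so one segment contributes one observation.
Feature scaling is fold-aware: the z-scoring parameters are fitted on
the training and validation folds only and applied unchanged to test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import FeatureTable, Fold

WIN_S = 0.025
OVERLAP_S = 0.015
N_MFCC = 13
N_MEL_FILTERS = 26
N_ENTROPY_BANDS = 16
PRE_EMPHASIS = 0.97

CLASSIC_BASE_NAMES = (
    ["ac_zcr", "ac_spectral_entropy", "ac_log_energy"]
    + [f"ac_mfcc{i:02d}" for i in range(1, N_MFCC + 1)]
)
CLASSIC_NAMES = CLASSIC_BASE_NAMES + [f"{n}_delta" for n in CLASSIC_BASE_NAMES]


def normalize_amplitude(samples: np.ndarray) -> np.ndarray:
    """Peak-normalise a waveform to +/-1 full scale.

    All-silent input is returned unchanged with a warning (there is no
    peak to scale by).
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot normalize an empty waveform")
    peak = np.max(np.abs(samples))
    if peak == 0.0:
        warnings.warn("all-zero waveform left unchanged by normalization")
        return samples
    return samples / peak


def frame_signal(
    samples: np.ndarray,
    sample_rate: int,
    win_s: float = WIN_S,
    overlap_s: float = OVERLAP_S,
) -> np.ndarray:
    """Slice a waveform into overlapping analysis frames.

    Returns an (n_frames, win) matrix with hop = win - overlap (10 ms at
    the defaults).  The trailing partial frame is dropped; input shorter
    than one window yields a single zero-padded frame (with a warning).
    """
    if win_s <= overlap_s:
        raise ValueError(f"window ({win_s}s) must exceed overlap ({overlap_s}s)")
    samples = np.asarray(samples, dtype=np.float64)
    win = int(round(win_s * sample_rate))
    hop = int(round((win_s - overlap_s) * sample_rate))
    if len(samples) < win:
        warnings.warn("input shorter than one analysis window; zero-padding")
        return np.pad(samples, (0, win - len(samples)))[None, :]
    n_frames = (len(samples) - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return samples[idx]


def _hz_to_mel(hz):
    return 2595.0 * np.log10(1.0 + np.asarray(hz, dtype=float) / 700.0)


def _mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank over the one-sided spectrum (0..Nyquist)."""
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2.0), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    fb = np.zeros((n_filters, n_bins))
    for m in range(1, n_filters + 1):
        left, centre, right = bins[m - 1], bins[m], bins[m + 1]
        if centre > left:
            fb[m - 1, left:centre] = (np.arange(left, centre) - left) / (centre - left)
        if right > centre:
            fb[m - 1, centre:right] = (right - np.arange(centre, right)) / (right - centre)
    return fb


def _power_spectra(frames: np.ndarray) -> np.ndarray:
    """Hamming-windowed one-sided power spectra of pre-emphasised frames."""
    emphasised = frames.copy()
    emphasised[:, 1:] -= PRE_EMPHASIS * frames[:, :-1]
    windowed = emphasised * np.hamming(frames.shape[1])
    spectrum = rfft(windowed, axis=1)
    return np.abs(spectrum) ** 2


def classic_frame_features(frames: np.ndarray, sample_rate: int) -> np.ndarray:
    """The 16 base features per frame: ZCR, spectral entropy, log-energy, MFCC 1-13.

    ZCR is the fraction of adjacent-sample sign changes.  Spectral
    entropy is the Shannon entropy (bits) of the normalised power
    spectrum, coarse-grained into 16 equal-width bands: banding
    stabilises the single-frame periodogram (whose raw per-bin entropy
    sits well below the flat-spectrum limit even for white noise), so a
    flat spectrum approaches log2(16).  MFCCs use a 26-filter mel bank
    and an orthonormal DCT-II, keeping coefficients 1-13 (the
    energy-like c0 is dropped in favour of the explicit log-energy
    column).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[1] < 2:
        raise ValueError("frames must contain at least 2 samples")
    eps = np.finfo(np.float64).tiny

    signs = np.sign(frames)
    signs[signs == 0] = 1.0
    zcr = (np.abs(np.diff(signs, axis=1)) > 0).sum(axis=1) / (frames.shape[1] - 1)

    # entropy from the raw periodogram (no pre-emphasis tilt, no window)
    raw_power = np.abs(rfft(frames, axis=1)) ** 2
    n_bands = min(N_ENTROPY_BANDS, raw_power.shape[1])
    band_power = np.stack(
        [chunk.sum(axis=1) for chunk in np.array_split(raw_power, n_bands, axis=1)],
        axis=1,
    )
    p_norm = band_power / np.maximum(band_power.sum(axis=1, keepdims=True), eps)
    entropy = -(p_norm * np.log2(np.maximum(p_norm, eps))).sum(axis=1)

    power = _power_spectra(frames)

    log_energy = np.log((frames ** 2).sum(axis=1) + eps)

    fb = mel_filterbank(N_MEL_FILTERS, frames.shape[1], sample_rate)
    mel_energy = np.log(np.maximum(power @ fb.T, eps))
    mfcc = dct(mel_energy, type=2, norm="ortho", axis=1)[:, 1:N_MFCC + 1]

    return np.column_stack([zcr, entropy, log_energy, mfcc])


def delta_features(matrix: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression deltas over +/-``width`` frames with edge replication.

    d_t = sum_k k (x_{t+k} - x_{t-k}) / (2 sum_k k^2); single-frame input
    has no temporal context and returns zeros.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    n = matrix.shape[0]
    if n == 1:
        return np.zeros_like(matrix)
    padded = np.pad(matrix, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, width + 1))
    out = np.zeros_like(matrix)
    for k in range(1, width + 1):
        out += k * (padded[width + k:width + k + n] - padded[width - k:width - k + n])
    return out / denom


def reduce_segment(matrix: np.ndarray) -> np.ndarray:
    """Collapse a frames-by-features matrix to one row per segment.

    Multi-frame segments return the first principal-component loading of
    the column-centred matrix: the unit-norm feature-space direction of
    dominant frame-to-frame covariation, sign-fixed so its largest-
    magnitude element is positive.  Single-frame segments have no
    temporal covariation and return the raw frame values.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if matrix.shape[0] == 1:
        return matrix[0].copy()
    centred = matrix - matrix.mean(axis=0, keepdims=True)
    if not np.any(centred):
        return np.zeros(matrix.shape[1])
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    loading = vt[0]
    sign = np.sign(loading[np.argmax(np.abs(loading))])
    return loading * (sign if sign != 0 else 1.0)


class LatentEmbedder:
    """Interface contract for per-frame latent speech representations.

    Implementations map a waveform to a frames-by-``output_dimension``
    matrix, deterministically for a given input, with a constant output
    dimension across calls.
    """

    name: str = "latent"
    output_dimension: int = 1024

    def transform(self, samples: np.ndarray, sample_rate: int) -> np.ndarray:
        raise NotImplementedError


class SyntheticEmbedder(LatentEmbedder):
    """Deterministic stand-in embedder: seeded random projection of frame spectra.

    Synthetic by construction — it learns nothing and models nothing; it
    exists so the 1,024-dimensional latent pathway (column counts, PCA
    reduction, scaling, classification) is exercised end-to-end without
    any pretrained network.  Frame power spectra (log1p-compressed) are
    projected through a fixed Gaussian matrix drawn from ``seed`` and
    squashed with tanh; the projection depends only on (seed, n_bins),
    so identical audio yields identical embeddings.
    """

    def __init__(self, output_dimension: int = 1024, seed: int = 1234):
        self.name = "synthetic"
        self.output_dimension = int(output_dimension)
        self.seed = int(seed)
        self._projections: dict[int, np.ndarray] = {}

    def _projection(self, n_bins: int) -> np.ndarray:
        if n_bins not in self._projections:
            rng = np.random.default_rng([self.seed, n_bins])
            self._projections[n_bins] = rng.standard_normal(
                (n_bins, self.output_dimension)
            ) / np.sqrt(n_bins)
        return self._projections[n_bins]

    def transform(self, samples: np.ndarray, sample_rate: int) -> np.ndarray:
        frames = frame_signal(samples, sample_rate)
        spectra = np.log1p(_power_spectra(frames))
        return np.tanh(spectra @ self._projection(spectra.shape[1]))


def classic_segment_matrix(samples: np.ndarray, sample_rate: int) -> np.ndarray:
    """Frames x 32 classic matrix (16 base + 16 deltas) for one segment."""
    frames = frame_signal(samples, sample_rate)
    base = classic_frame_features(frames, sample_rate)
    return np.hstack([base, delta_features(base)])


def segment_acoustic_vector(
    samples: np.ndarray,
    sample_rate: int,
    embedder: LatentEmbedder | None = None,
) -> tuple[np.ndarray, list[str]]:
    """One 32- (or 1,056-) dimensional acoustic row for a segment's audio."""
    classic = reduce_segment(classic_segment_matrix(samples, sample_rate))
    names = list(CLASSIC_NAMES)
    if embedder is None:
        return classic, names
    latent = reduce_segment(embedder.transform(samples, sample_rate))
    names += [f"emb_{i:04d}" for i in range(embedder.output_dimension)]
    return np.concatenate([classic, latent]), names


class FoldAwareScaler(BaseEstimator, TransformerMixin):
    """Per-column z-scoring fitted on the train+validation folds only.

    Guards against leakage: fitting on rows tagged TEST raises.  Columns
    with zero variance in the fit folds are centred only and recorded in
    ``constant_columns_``.
    """

    def __init__(self, fit_folds: tuple[Fold, ...] = (Fold.TRAIN, Fold.VALIDATION)):
        self.fit_folds = fit_folds

    def fit(self, table: FeatureTable, y=None) -> "FoldAwareScaler":
        folds = {Fold(f) for f in self.fit_folds}
        if Fold.TEST in folds:
            raise ValueError("refusing to fit scaling parameters on TEST rows")
        fit_rows = table.rows_in(*folds)
        if len(fit_rows.values) == 0:
            raise ValueError(f"no rows in fit folds {sorted(f.value for f in folds)}")
        self.mean_ = fit_rows.values.mean(axis=0)
        sd = fit_rows.values.std(axis=0, ddof=0)
        self.constant_columns_ = list(sd.index[sd == 0.0])
        self.scale_ = sd.replace(0.0, 1.0)
        self.columns_ = list(table.values.columns)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if list(table.values.columns) != self.columns_:
            raise ValueError("column set differs from the one the scaler was fitted on")
        scaled = (table.values - self.mean_) / self.scale_
        return FeatureTable(scaled, table.fold_of_row, table.labels)
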