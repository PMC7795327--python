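"""Multiscale acoustic feature extraction for fixed-length event excerpts.

Each analysis window length yields an 81-channel per-frame block:

* 25 spectral channels — the four standardized moments of the spectral
  distribution, zero-crossing rate, entropy, flatness, roughness,
  irregularity, four spectral-flux variants, brightness above 100/200/400/
  800 Hz with the 400/100 and 800/100 brightness ratios, rolloff at
  95/75/25/5% with the 5/95 (outlier) and 25/75 (interquartile) rolloff
  ratios;
* 26 MFCC channels — the first 13 mel-frequency cepstral coefficients and
  their first-order temporal differences;
* 30 melodic channels — pitch, inharmonicity and voicing curves (raw plus
  100/250/500/1000 ms centered moving averages), computed on the raw signal
  and on a 400 Hz high-passed version.

Five statistics (mean, sample standard deviation, median, min, max) collapse
each channel over frames, giving 405 values per window length and 2430 for
the default six-length grid (16-512 ms).  Channel names follow the
``{stat}_{feature}_{window_ms}`` scheme, e.g. ``std_melinharm250ms_32``.

Conventions for quantities the literature leaves open are documented on the
individual functions (roughness uses summed Sethares dissonance over
spectral peak pairs; irregularity is the squared successive-peak-amplitude
difference normalized by total squared peak amplitude; entropy is Shannon
entropy of the normalized spectrum divided by log of the bin count).
Silent-frame guards make every channel a total function: ratios with a
denominator below 1e-12 are defined as 0, and unvoiced frames carry pitch 0.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.fft import dct
from scipy.signal import butter, get_window, medfilt, sosfiltfilt

from .exceptions import ValidationError
from .tf import (
    WINDOW_KINDS,
    STFTConfig,
    TFImage,
    frame_signal,
    mel_filterbank,
    stft_spectrogram,
)

EPS = 1e-12
DEFAULT_WINDOWS_MS = (16, 32, 64, 128, 256, 512)
STAT_NAMES = ("mean", "std", "median", "min", "max")

SPECTRAL_NAMES = [
    "speccentroid",
    "specspread",
    "specskewness",
    "speckurtosis",
    "speczcr",
    "specentropy",
    "specflatness",
    "specroughness",
    "specirregularity",
    "specflux",
    "specfluxinc",
    "specfluxhalfwave",
    "specfluxmedian",
    "specbright100",
    "specbright200",
    "specbright400",
    "specbright800",
    "specbright4ratio",
    "specbright8ratio",
    "specrolloff95",
    "specrolloff75",
    "specrolloff25",
    "specrolloff05",
    "specrolloffOutRatio",
    "specrolloffIQRatio",
]
MFCC_NAMES = [f"mfcc{i}" for i in range(1, 14)] + [f"deltamfcc{i}" for i in range(1, 14)]
_SMOOTH_MS = (100, 250, 500, 1000)
_SMOOTH_TOKENS = ("100ms", "250ms", "500ms", "1s")
MELODIC_NAMES = [
    f"mel{base}{hf}{tok}"
    for hf in ("", "HF")
    for base in ("pitch", "inharm", "voicing")
    for tok in ("",) + _SMOOTH_TOKENS
]
FEATURE_BASE_NAMES = SPECTRAL_NAMES + MFCC_NAMES + MELODIC_NAMES
assert len(FEATURE_BASE_NAMES) == 81


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    ok = den > EPS
    out[ok] = num[ok] / den[ok]
    return out


def _frame_peaks(col: np.ndarray, rel_threshold: float = 0.05, max_peaks: int = 12):
    """Indices and amplitudes of the strongest local spectral maxima."""
    if col.size < 3:
        return np.empty(0, dtype=int), np.empty(0)
    interior = (col[1:-1] > col[:-2]) & (col[1:-1] >= col[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return idx, col[idx]
    amp = col[idx]
    keep = amp >= rel_threshold * amp.max()
    idx, amp = idx[keep], amp[keep]
    if idx.size > max_peaks:
        top = np.argsort(amp)[-max_peaks:]
        order = np.sort(top)
        idx, amp = idx[order], amp[order]
    return idx, amp


@lru_cache(maxsize=64)
def _triu_idx(n: int):
    return np.triu_indices(n, k=1)


def _sethares_roughness(freqs: np.ndarray, amps: np.ndarray) -> float:
    """Summed pairwise sensory dissonance (Plomp-Levelt curve, Sethares fit)."""
    if freqs.size < 2:
        return 0.0
    iu = _triu_idx(freqs.size)
    f1, f2 = freqs[iu[0]], freqs[iu[1]]
    df = np.abs(f1 - f2)
    s = 0.24 / (0.0207 * np.minimum(f1, f2) + 18.96)
    d = np.exp(-3.5 * s * df) - np.exp(-5.75 * s * df)
    return float(np.sum(amps[iu[0]] * amps[iu[1]] * d))


def _irregularity(amps: np.ndarray) -> float:
    """Squared difference of successive peak amplitudes over total squared amplitude."""
    if amps.size < 2:
        return 0.0
    den = float(np.sum(amps**2))
    return float(np.sum(np.diff(amps) ** 2) / den) if den > EPS else 0.0


def extract_spectral_features(
    spec: TFImage, frames: np.ndarray | None = None
) -> np.ndarray:
    """25 spectral channels per frame (rows ordered as ``SPECTRAL_NAMES``).

    ``frames`` are the time-domain frames aligned with the spectrogram; when
    supplied, the zero-crossing rate is counted on them, otherwise it falls
    back to the spectral estimate 2 x centroid (exact for a sinusoid).
    """
    S = np.asarray(spec.values, dtype=np.float64)
    if S.size == 0:
        raise ValidationError("empty spectrogram")
    freqs = np.asarray(spec.freqs, dtype=np.float64)
    nbins, T = S.shape
    E = S**2

    tot_mag = S.sum(axis=0)
    p = _safe_ratio(S, tot_mag[None, :].repeat(nbins, axis=0))
    centroid = (freqs[:, None] * p).sum(axis=0)
    spread = np.sqrt(((freqs[:, None] - centroid[None, :]) ** 2 * p).sum(axis=0))
    z = _safe_ratio(freqs[:, None] - centroid[None, :], spread[None, :].repeat(nbins, axis=0))
    skew = (z**3 * p).sum(axis=0)
    kurt = np.where(spread > EPS, (z**4 * p).sum(axis=0) - 3.0, 0.0)

    if frames is not None:
        signs = np.signbit(frames)
        crossings = (signs[:, 1:] != signs[:, :-1]).sum(axis=1)
        zcr = crossings * spec.rate / frames.shape[1]
    else:
        zcr = 2.0 * centroid

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = np.where(tot_mag > EPS, -plogp.sum(axis=0) / np.log(nbins), 0.0)

    log_gm = np.where(S > EPS, np.log(np.maximum(S, EPS)), np.log(EPS)).mean(axis=0)
    flatness = np.where(tot_mag > EPS, np.exp(log_gm) / np.maximum(S.mean(axis=0), EPS), 0.0)

    roughness = np.zeros(T)
    irregularity = np.zeros(T)
    for t in range(T):
        idx, amp = _frame_peaks(S[:, t])
        roughness[t] = _sethares_roughness(freqs[idx], amp)
        irregularity[t] = _irregularity(amp)

    dS = np.diff(S, axis=1)
    flux = np.concatenate([[0.0], np.sqrt((dS**2).sum(axis=0))])
    flux_inc = np.concatenate([[0.0], np.clip(dS, 0.0, None).sum(axis=0)])
    flux_hw = np.concatenate([[0.0], np.sqrt((np.clip(dS, 0.0, None) ** 2).sum(axis=0))])
    k_med = min(5, T if T % 2 == 1 else T - 1)
    flux_med = medfilt(flux, kernel_size=k_med) if T > 2 else flux.copy()

    tot_e = E.sum(axis=0)
    bright = {}
    for cut in (100, 200, 400, 800):
        bright[cut] = _safe_ratio(E[freqs >= cut].sum(axis=0), tot_e)
    b4ratio = _safe_ratio(bright[400], bright[100])
    b8ratio = _safe_ratio(bright[800], bright[100])

    cum = np.cumsum(E, axis=0)
    roll = {}
    for pct in (95, 75, 25, 5):
        target = pct / 100.0 * tot_e
        idx = np.argmax(cum >= target[None, :] - EPS, axis=0)
        roll[pct] = np.where(tot_e > EPS, freqs[idx], 0.0)
    out_ratio = _safe_ratio(roll[5], roll[95])
    iq_ratio = _safe_ratio(roll[25], roll[75])

    return np.vstack(
        [
            centroid,
            spread,
            skew,
            kurt,
            zcr,
            entropy,
            flatness,
            roughness,
            irregularity,
            flux,
            flux_inc,
            flux_hw,
            flux_med,
            bright[100],
            bright[200],
            bright[400],
            bright[800],
            b4ratio,
            b8ratio,
            roll[95],
            roll[75],
            roll[25],
            roll[5],
            out_ratio,
            iq_ratio,
        ]
    )


def extract_mfcc_features(spec: TFImage, n_mels: int = 64) -> np.ndarray:
    """13 MFCCs (log mel energies -> orthonormal DCT-II, coefficients 1..13)
    plus 13 first-order temporal differences (first-frame delta = 0)."""
    S = np.asarray(spec.values, dtype=np.float64)
    if S.size == 0:
        raise ValidationError("empty spectrogram")
    fb = mel_filterbank(n_mels, spec.freqs)
    logE = np.log(fb @ S + 1e-10)
    coeffs = dct(logE, type=2, axis=0, norm="ortho")[1:14]
    deltas = np.concatenate([np.zeros((13, 1)), np.diff(coeffs, axis=1)], axis=1)
    return np.vstack([coeffs, deltas])


def pitch_curve(
    wave: np.ndarray,
    cfg: STFTConfig = STFTConfig(window_kind="hamming"),
    rate: float = 4000.0,
    f_min: float = 60.0,
    f_max: float = 1600.0,
    voicing_threshold: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame pitch, voicing and inharmonicity curves.

    Pitch is estimated from the product of the frame's real cepstrum and
    autocorrelation over the candidate lag range (a cepstral-autocorrelation
    detector), then refined on the quadratically interpolated spectral peak
    nearest the candidate.  The ceiling is 1600 Hz, the highest fundamental
    reported for wheezes; the 60 Hz floor is raised to ``2*rate/W`` when the
    analysis window cannot hold a full period at the nominal floor.

    Voicing is the fraction of spectral energy captured by a harmonic comb
    at the estimated pitch; frames whose voicing falls below the threshold
    (and silent frames) are marked unvoiced with pitch encoded as 0.
    Inharmonicity is the energy-weighted deviation of spectral peaks from
    integer multiples of the pitch, normalized to [0, 1] (0 for unvoiced
    frames so every channel stays total).
    """
    wave = np.asarray(wave, dtype=np.float64)
    w = cfg.window_samples(rate)
    nfft = cfg.fft_size(rate)
    f_min_eff = max(f_min, 2.0 * rate / w)
    q_min = max(2, int(np.ceil(rate / f_max)))
    q_max = int(np.floor(rate / f_min_eff))
    if q_max <= q_min:
        raise ValidationError(
            f"window of {w} samples too short for pitch analysis up to {f_max} Hz"
        )
    frames = frame_signal(wave, w, cfg.hop_samples(rate))
    win = get_window(WINDOW_KINDS[cfg.window_kind], w, fftbins=True)
    X = np.fft.rfft(frames * win, n=nfft, axis=1)
    mag = np.abs(X)
    power = mag**2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)

    cep = np.fft.irfft(np.log(mag + 1e-10), n=nfft, axis=1)
    acorr = np.fft.irfft(power, n=nfft, axis=1)

    T = frames.shape[0]
    pitch = np.zeros(T)
    voicing = np.zeros(T)
    inharm = np.zeros(T)
    tot_e = power.sum(axis=1)
    bin_hz = rate / nfft

    for t in range(T):
        if tot_e[t] < 1e-14:
            continue
        lag_score = cep[t, q_min : q_max + 1] * np.maximum(acorr[t, q_min : q_max + 1], 0.0)
        q = q_min + int(np.argmax(lag_score))
        f0 = rate / q
        # refine on the nearest interpolated spectral peak
        lo = int(np.floor(0.8 * f0 / bin_hz))
        hi = int(np.ceil(1.25 * f0 / bin_hz))
        lo, hi = max(lo, 1), min(hi, mag.shape[1] - 2)
        if hi > lo:
            j = lo + int(np.argmax(mag[t, lo : hi + 1]))
            a, b, c = mag[t, j - 1], mag[t, j], mag[t, j + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if abs(denom) > EPS else 0.0
            cand = (j + np.clip(delta, -0.5, 0.5)) * bin_hz
            if f_min_eff * 0.9 <= cand <= f_max:
                f0 = cand
        f0 = float(np.clip(f0, f_min_eff, f_max))

        harmonics = np.arange(1, int(rate / 2 // f0) + 1) * f0
        comb = np.zeros(mag.shape[1], dtype=bool)
        for h in harmonics:
            j = int(round(h / bin_hz))
            comb[max(j - 1, 0) : j + 2] = True
        v = float(power[t, comb].sum() / tot_e[t])
        if v < voicing_threshold:
            voicing[t] = v
            continue
        pitch[t] = f0
        voicing[t] = v
        idx, amp = _frame_peaks(mag[t])
        if idx.size:
            pk_f = freqs[idx]
            dev = np.abs(pk_f / f0 - np.round(pk_f / f0))  # in [0, 0.5] periods
            e = amp**2
            inharm[t] = float(np.sum(e * 2 * dev) / np.sum(e))
    return pitch, voicing, inharm


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge count-normalization."""
    if width <= 1:
        return x.copy()
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def extract_melodic_features(
    wave: np.ndarray, cfg: STFTConfig = STFTConfig(window_kind="hamming"), rate: float = 4000.0
) -> np.ndarray:
    """30 melodic channels per frame (rows ordered as ``MELODIC_NAMES``).

    {pitch, inharmonicity, voicing} x {raw, 100, 250, 500, 1000 ms centered
    moving average}, on the raw signal and on a 400 Hz high-passed version
    (removing the normal breathing sounds, whose energy is negligible above
    400 Hz).
    """
    hop_s = cfg.hop_samples(rate) / rate
    sos = butter(4, 400.0, btype="highpass", fs=rate, output="sos")
    hp = sosfiltfilt(sos, np.asarray(wave, dtype=np.float64))
    rows = []
    for sig in (wave, hp):
        pitch, voicing, inharm = pitch_curve(sig, cfg, rate)
        for curve in (pitch, inharm, voicing):
            rows.append(curve)
            for dur_ms in _SMOOTH_MS:
                width = max(1, int(round(dur_ms / 1000.0 / hop_s)))
                rows.append(_moving_average(curve, width))
    return np.vstack(rows)


def extract_frame_block(
    wave: np.ndarray, cfg: STFTConfig, rate: float = 4000.0
) -> np.ndarray:
    """Full 81 x T per-frame block for one analysis window length."""
    spec = stft_spectrogram(wave, cfg, rate)
    frames = frame_signal(wave, cfg.window_samples(rate), cfg.hop_samples(rate))
    block = np.vstack(
        [
            extract_spectral_features(spec, frames=frames),
            extract_mfcc_features(spec),
            extract_melodic_features(wave, cfg, rate),
        ]
    )
    assert block.shape[0] == 81
    return block


def summarize_statistics(block: np.ndarray) -> np.ndarray:
    """Collapse an (n_channels, T) block to n_channels x 5 statistics.

    Statistics are computed over the frame axis in the order mean, sample
    standard deviation (0 for a single frame), median, min, max; the result
    is flattened channel-major and is invariant to frame permutations.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[1] < 1:
        raise ValidationError("block must be (channels, T) with T >= 1")
    std = block.std(axis=1, ddof=1) if block.shape[1] > 1 else np.zeros(block.shape[0])
    stats = np.stack(
        [
            block.mean(axis=1),
            std,
            np.median(block, axis=1),
            block.min(axis=1),
            block.max(axis=1),
        ],
        axis=1,
    )
    return stats.ravel()


def feature_names(windows_ms=DEFAULT_WINDOWS_MS) -> list[str]:
    """Canonical ordered channel names: windows x features x statistics."""
    return [
        f"{stat}_{base}_{int(w)}"
        for w in windows_ms
        for base in FEATURE_BASE_NAMES
        for stat in STAT_NAMES
    ]


def extract_feature_vector(
    wave: np.ndarray,
    windows_ms=DEFAULT_WINDOWS_MS,
    window_kind: str = "hamming",
    rate: float = 4000.0,
) -> np.ndarray:
    """2430-dimensional event descriptor (for the default six-window grid).

    Concatenates the 405 summary statistics (81 channels x 5 statistics) of
    every analysis window length.  The Hamming window is the default for
    feature extraction.  Use :func:`feature_names` for the matching header.
    """
    parts = []
    for w in windows_ms:
        cfg = STFTConfig(window_kind=window_kind, window_ms=float(w))
        parts.append(summarize_statistics(extract_frame_block(wave, cfg, rate)))
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise ValidationError("feature vector contains non-finite values")
    return vec


def features_to_frame(vectors, windows_ms=DEFAULT_WINDOWS_MS, index=None):
    """Stack event feature vectors into a DataFrame with the canonical
    2430-name header (write with ``.to_csv`` / ``.to_parquet``)."""
    import pandas as pd

    return pd.DataFrame(np.atleast_2d(vectors), columns=feature_names(windows_ms), index=index)


__all__ = [
    "SPECTRAL_NAMES",
    "features_to_frame",
    "MFCC_NAMES",
    "MELODIC_NAMES",
    "FEATURE_BASE_NAMES",
    "STAT_NAMES",
    "DEFAULT_WINDOWS_MS",
    "extract_spectral_features",
    "extract_mfcc_features",
    "pitch_curve",
    "extract_melodic_features",
    "extract_frame_block",
    "summarize_statistics",
    "feature_names",
    "extract_feature_vector",
]
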