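"""Time-frequency representations: spectrogram and mel spectrogram.

Frame convention: no edge padding, hop = window * (1 - overlap); with the
canonical settings (2.0 s excerpt at 4000 Hz, 32 ms window, 75% overlap,
512-point transform) this yields exactly 247 frames and 257 one-sided bins.
Windows shorter than the transform length are zero-padded to it.  The
spectrogram is a magnitude (not power) spectrogram; logarithmic compression
happens only inside the MFCC computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .exceptions import ValidationError

WINDOW_KINDS = {
    "hamming": "hamming",
    "blackman_harris": "blackmanharris",
    "rectangular": "boxcar",
}


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings.

    ``window_ms`` is the analysis window length in milliseconds (the study
    grid is 16, 32, 64, 128, 256 and 512 ms), ``overlap`` the fractional
    window overlap, and ``n_fft`` the transform length (raised to the window
    length when a long window would not fit).
    """

    window_kind: str = "blackman_harris"
    window_ms: float = 32.0
    n_fft: int = 512
    overlap: float = 0.75

    def __post_init__(self) -> None:
        if self.window_kind not in WINDOW_KINDS:
            raise ValidationError(f"window_kind must be one of {sorted(WINDOW_KINDS)}")
        if not (0 <= self.overlap < 1):
            raise ValidationError("overlap must be in [0, 1)")
        if self.window_ms <= 0 or self.n_fft <= 0:
            raise ValidationError("window_ms and n_fft must be > 0")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def hop_samples(self, rate: float) -> int:
        return max(1, int(round(self.window_samples(rate) * (1 - self.overlap))))

    def fft_size(self, rate: float) -> int:
        w = self.window_samples(rate)
        n = self.n_fft
        while n < w:  # long windows get a matching power-of-two transform
            n *= 2
        return n


@dataclass
class TFImage:
    """Normalized or raw time-frequency magnitude image.

    ``values`` has shape (frequency-or-mel bands, time frames); ``freqs``
    holds bin center frequencies in Hz (linear scale) or band indices (mel
    scale); ``times`` holds frame-center times in seconds.  The serialized
    axis order, e.g. for CNN input, is (channel, time, frequency) so the
    canonical 2 s images are 1 x 247 x 257 and 1 x 247 x 64.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    scale: str = "linear"  # or "mel"
    rate: float = 4000.0

    def as_tensor(self) -> np.ndarray:
        """(1, time, frequency) view used as CNN input."""
        return self.values.T[np.newaxis, :, :]


def frame_count(n_samples: int, window: int, hop: int) -> int:
    """Number of frames with no edge padding: floor((L - W)/H) + 1."""
    if n_samples < window:
        raise ValidationError(f"signal ({n_samples}) shorter than window ({window})")
    return (n_samples - window) // hop + 1


def frame_signal(wave: np.ndarray, window: int, hop: int) -> np.ndarray:
    """(n_frames, window) view of the signal, no padding."""
    wave = np.asarray(wave, dtype=np.float64)
    n = frame_count(wave.size, window, hop)
    return sliding_window_view(wave, window)[:: hop][:n]


def stft_spectrogram(wave: np.ndarray, cfg: STFTConfig = STFTConfig(), rate: float = 4000.0) -> TFImage:
    """Magnitude spectrogram of a waveform under the given STFT settings."""
    wave = np.asarray(wave, dtype=np.float64)
    w = cfg.window_samples(rate)
    hop = cfg.hop_samples(rate)
    nfft = cfg.fft_size(rate)
    frames = frame_signal(wave, w, hop)
    win = get_window(WINDOW_KINDS[cfg.window_kind], w, fftbins=True)
    mags = np.abs(np.fft.rfft(frames * win, n=nfft, axis=1)).T  # (bins, frames)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    times = (np.arange(frames.shape[0]) * hop + w / 2) / rate
    return TFImage(values=mags, freqs=freqs, times=times, scale="linear", rate=rate)


def hz_to_mel(f):
    """Perceptual mel scale: m = 2595 * log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValidationError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, freqs: np.ndarray, fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank matrix of shape (n_mels, n_bins).

    Band centers are uniform on the mel scale between ``fmin`` and ``fmax``
    (Nyquist by default); triangles are area-unnormalized.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if fmax is None:
        fmax = float(freqs[-1])
    if n_mels < 1:
        raise ValidationError("n_mels must be >= 1")
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (freqs - lo) / max(ctr - lo, 1e-12)
        falling = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        if not fb[i].any():  # guarantee no empty band at coarse bin spacing
            fb[i, np.argmin(np.abs(freqs - ctr))] = 1.0
    return fb


def mel_spectrogram(spec: TFImage, n_mels: int = 64) -> TFImage:
    """Apply a triangular mel filterbank to a linear-scale magnitude image."""
    if spec.scale != "linear":
        raise ValidationError("mel_spectrogram expects a linear-scale image")
    if n_mels > spec.freqs.size:
        raise ValidationError(f"n_mels={n_mels} exceeds {spec.freqs.size} frequency bins")
    fb = mel_filterbank(n_mels, spec.freqs)
    return TFImage(
        values=fb @ spec.values,
        freqs=np.arange(n_mels, dtype=np.float64),
        times=spec.times,
        scale="mel",
        rate=spec.rate,
    )


def normalize_image(img: TFImage) -> TFImage:
    """Min-max normalize an image to [0, 1]; constant images map to zeros."""
    v = img.values
    if not np.all(np.isfinite(v)):
        raise ValidationError("image contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return TFImage(values=out, freqs=img.freqs, times=img.times, scale=img.scale, rate=img.rate)


def save_image(path, img: TFImage) -> None:
    """Serialize a TF image as an NPZ archive with axis metadata."""
    np.savez(
        path,
        values=img.values,
        freqs=img.freqs,
        times=img.times,
        scale=np.array(img.scale),
        rate=np.array(img.rate),
    )


def load_image(path) -> TFImage:
    with np.load(path, allow_pickle=False) as data:
        return TFImage(
            values=data["values"],
            freqs=data["freqs"],
            times=data["times"],
            scale=str(data["scale"]),
            rate=float(data["rate"]),
        )


__all__ = [
    "STFTConfig",
    "TFImage",
    "save_image",
    "load_image",
    "frame_count",
    "frame_signal",
    "stft_spectrogram",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_spectrogram",
    "normalize_image",
]
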