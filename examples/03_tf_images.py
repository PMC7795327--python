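"""Compute the two time-frequency images used by the convolutional models.

A 2 s excerpt at 4 kHz analyzed with a 32 ms Blackman-Harris window, 75%
overlap and a 512-point transform yields a 1 x 247 x 257 spectrogram; a
64-band triangular mel filterbank reduces it to 1 x 247 x 64.  Both are
min-max normalized to [0, 1] per image.
"""

import numpy as np

from arslab.events import ExcerptPolicy, excerpt_event
from arslab.synth import SynthConfig, synth_recording
from arslab.tf import STFTConfig, mel_spectrogram, normalize_image, stft_spectrogram

# a clean-event configuration (high SNR) so the tone is visible in the image
rec, events = synth_recording(SynthConfig(snr_db=10.0, seed=3), "P001", "P001_R01")
wheeze = next(e for e in events if e.label == "wheeze")
wave = excerpt_event(rec, wheeze, ExcerptPolicy(max_len=2.0))
print(f"excerpt: {wave.size} samples ({wave.size / rec.rate:.1f} s)")

spec = normalize_image(stft_spectrogram(wave, STFTConfig(), rec.rate))
mel = normalize_image(mel_spectrogram(stft_spectrogram(wave, STFTConfig(), rec.rate), 64))
print("spectrogram tensor:", spec.as_tensor().shape)   # (1, 247, 257)
print("mel spectrogram tensor:", mel.as_tensor().shape)  # (1, 247, 64)
peak_bin = int(np.argmax(spec.values.sum(axis=1)))
print(f"dominant frequency ~ {spec.freqs[peak_bin]:.0f} Hz")
# The dominant bin sits at the wheeze fundamental (100-1000 Hz range).
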