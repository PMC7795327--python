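import numpy as np
import pytest

from arslab.io_rsd import AnnotatedEvent, AudioRecording


@pytest.fixture()
def tone_recording():
    """10 s, 4 kHz recording containing a 500 Hz tone, for excerpt tests."""
    rate = 4000.0
    t = np.arange(int(10 * rate)) / rate
    x = 0.1 * np.sin(2 * np.pi * 500 * t)
    return AudioRecording(x, rate, participant_id="P1", recording_id="R1")


@pytest.fixture()
def small_corpus():
    """Tiny synthetic corpus shared across experiment-level tests."""
    from arslab.io_rsd import DatasetManifest, ManifestEntry, make_split
    from arslab.synth import SynthConfig, synth_corpus
    from arslab.experiments import Corpus

    cfg = SynthConfig(
        n_participants=6,
        recordings_per_participant=2,
        recording_duration=12.0,
        crackle_rate=3,
        wheeze_rate=2,
        seed=42,
    )
    recs = synth_corpus(cfg)
    manifest = DatasetManifest(
        [ManifestEntry(r.recording_id, r.participant_id, "", "") for r, _ in recs], {}
    )
    split = make_split(manifest, test_fraction=0.34, seed=3)
    return Corpus(recs, split)
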