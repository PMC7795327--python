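"""Demonstrate the duration confound with a duration-only classifier.

A decision tree that sees nothing but each event's annotated duration is
nearly perfect when the negative class has fixed 50/150 ms durations — the
task leaks the label through duration alone — and collapses to the
majority-class rate when negatives are duration-matched via the Burr models.
"""

from arslab.experiments import Corpus, ExperimentConfig, run_experiment
from arslab.io_rsd import DatasetManifest, ManifestEntry, make_split
from arslab.synth import SynthConfig, synth_corpus

config = SynthConfig(
    n_participants=8, recordings_per_participant=2, recording_duration=15.0,
    crackle_rate=4, wheeze_rate=2, seed=6,
)
recordings = synth_corpus(config)
manifest = DatasetManifest(
    [ManifestEntry(r.recording_id, r.participant_id, "", "") for r, _ in recordings], {}
)
corpus = Corpus(recordings, make_split(manifest, test_fraction=0.3, seed=6))

for mode in ("fixed", "variable"):
    cfg = ExperimentConfig(
        train_mode=mode, test_mode=mode, task="3class",
        classifier="duration_only", n_seeds=1, master_seed=0,
    )
    report = run_experiment(cfg, corpus)
    print(f"{mode:9s} negatives: duration-only 3-class accuracy = "
          f"{report.mean_accuracy:.3f}  (test events: {report.event_log['test']})")
# Typical output: ~0.99 with fixed negatives vs ~0.55 with Burr-matched
# negatives — the gap is performance explained by duration leakage alone,
# not by any acoustic property of the sounds.
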