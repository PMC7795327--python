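"""Rank features with MRMR and train a tuned classifier.

MRMR orders channels by the mutual-information quotient of relevance over
redundancy; the classifier's hyperparameters are tuned by a Gaussian-process
sequential search on a stratified validation split of the training data.
"""

import numpy as np

from arslab.events import ExcerptPolicy, excerpt_event, generate_variable_rge
from arslab.features import extract_feature_vector, feature_names
from arslab.selection import mrmr_rank, optimize_and_fit, select_subset
from arslab.synth import SynthConfig, synth_corpus

config = SynthConfig(
    n_participants=4, recordings_per_participant=2, recording_duration=12.0,
    crackle_rate=3, wheeze_rate=2, snr_db=0.0, seed=5,
)
X, y = [], []
for rec, ars in synth_corpus(config):
    rge = generate_variable_rge(rec, ars, 3, 2, seed=5)
    for ev in ars + rge:
        wave = excerpt_event(rec, ev, ExcerptPolicy())
        X.append(extract_feature_vector(wave, windows_ms=(32, 128)))
        y.append("other" if ev.label.startswith("other") else ev.label)
X, y = np.vstack(X), np.array(y)
print(f"{X.shape[0]} events x {X.shape[1]} features, classes {sorted(set(y))}")

ranking = mrmr_rank(X, y, names=feature_names((32, 128)), top_k=10)
top10 = select_subset(ranking, 10)
print("top MRMR channels:")
for idx in top10[:5]:
    print(f"  {ranking.names[idx]}")

result = optimize_and_fit("svm_rbf", X[:, top10], y, budget=10, seed=0)
print(f"tuned config: {({k: round(v, 4) for k, v in result.params.items()})}")
print(f"validation accuracy of best config: {result.best_score:.3f}")
# The selected channels typically include melodic voicing/pitch statistics
# (wheezes are harmonic) and flux/brightness statistics (crackles are
# transient); validation accuracy well above 1/3 shows real acoustic signal.
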