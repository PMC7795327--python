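"""Generate the negative ("other") class in both experiment modes.

Fixed mode produces events of exactly 50 and 150 ms — a duration signature a
classifier can exploit.  Variable mode draws durations from truncated Burr
Type XII models fitted to the annotated crackle/wheeze duration
distributions, so negatives are duration-matched to positives.
"""

import numpy as np

from arslab.events import generate_fixed_rge, generate_variable_rge
from arslab.synth import SynthConfig, synth_recording

rec, ars = synth_recording(SynthConfig(seed=2), "P001", "P001_R01")
print(f"recording: {rec.duration:.1f} s with {len(ars)} adventitious events")

fixed = generate_fixed_rge(rec, ars, {0.050: 4, 0.150: 2}, seed=7)
print("fixed-mode durations (s):", sorted(round(e.duration, 3) for e in fixed))

variable = generate_variable_rge(rec, ars, n_crackle_like=4, n_wheeze_like=2, seed=7)
for e in sorted(variable, key=lambda e: e.label):
    print(f"  {e.label:13s} {e.duration * 1000:7.1f} ms")
# otherCrackle durations stay below 100 ms and otherWheeze durations below
# 2 s (draws beyond the ceilings are discarded by the truncated sampler);
# none of the generated events overlaps an annotated adventitious event.
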