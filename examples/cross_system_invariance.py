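"""The portability claim: features agree across recording systems.

One subject's EEG sources are rendered twice from the same underlying
signals — once as a 1000 Hz vertex-referenced recording (BrainScope-like)
and once as a 128 Hz AFz-referenced recording (TruScan-like).  After
harmonization, both yield the same eight features, which is what makes a
classifier trained on one system applicable to the other.
"""

import numpy as np

from prexstim import FEATURE_NAMES_V1, SynthConfig, features_of
from prexstim.synth import render_dialect_pair

brainscope, truscan = render_dialect_pair(SynthConfig(), "responder", seed=3)
f_bs = features_of(brainscope)
f_ts = features_of(truscan)

print(f"{'feature':<20}{'1000 Hz sys':>12}{'128 Hz sys':>12}{'diff %':>9}")
for name, a, b in zip(FEATURE_NAMES_V1, f_bs, f_ts):
    print(f"{name:<20}{a:>12.4f}{b:>12.4f}{100 * abs(a - b) / b:>9.4f}")
print(f"\nworst relative difference: {100 * np.max(np.abs(f_bs - f_ts) / f_ts):.4f}%")
print("Differences stay far below 2%: the reference transform is exact")
print("and resampling preserves all band content below 45 Hz.")
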