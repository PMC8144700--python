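"""Generate a small synthetic EEG cohort and write it to disk as EDF+.

Each subject is 670 s of 19-channel protocol-structured EEG (rest, eyes
opening/closing, photic stimulation, hyperventilation) with a planted
class effect: responders react more strongly in four of the eight
predictor cells.  Files land in ./cohort_demo/ together with sidecar
event tables and a manifest.
"""

from prexstim import SynthConfig, generate_cohort
from prexstim.synth import DIALECT_TRUSCAN

config = SynthConfig(
    n_responders=3,
    n_nonresponders=2,
    dialect=DIALECT_TRUSCAN,  # 128 Hz, Fz/Fp1/Fp2-average reference
    source_rate=128.0,        # render at the dialect's native rate
    seed=7,
)

manifest = generate_cohort(config, "cohort_demo")
print(manifest.to_string(index=False))
print("\nEach row is one EDF recording; 'label' is the ground-truth VNS")
print("response class the generator planted, 'seed' reproduces the file.")
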