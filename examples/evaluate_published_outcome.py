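"""Reproduce the published external-validation report.

The validation cohort had eight subjects: six real-life responders (two
of whom the model missed) and two non-responders (both correct).  The
evaluation module turns that outcome into the reported metrics, and the
bundled cohort table reproduces the published descriptive statistics.
"""

from prexstim.datasets import load_validation_cohort, validation_outcomes
from prexstim.evaluation import confusion_matrix, fisher_exact, performance

truth = validation_outcomes()
pred = list(truth)
missed = [i for i, t in enumerate(truth) if t == "responder"][-2:]
for i in missed:
    pred[i] = "non-responder"

counts = confusion_matrix(pred, truth)
acc, sens, spec = performance(counts).rounded()
print(f"confusion: TP={counts.tp} FP={counts.fp} FN={counts.fn} TN={counts.tn}")
print(f"accuracy {acc}%, sensitivity {sens}%, specificity {spec}%")

cohort = load_validation_cohort()
ages = cohort["age_onset"]
print(f"\nage at epilepsy onset: median {ages.median():.0f}, "
      f"range {ages.min()}-{ages.max()}")
print(f"valproate use: {cohort['VPA'].sum()} of {len(cohort)} subjects")
print(f"levetiracetam vs 36/60 in training: Fisher p = "
      f"{fisher_exact([[36, 24], [0, 8]]):.3f}")
print(f"valproate vs 14/60 in training: Fisher p = "
      f"{fisher_exact([[14, 46], [5, 3]]):.3f}")
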