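"""Bundled reference tables.

The validation-cohort table lists the eight externally-recorded VNS
patients (demographics, treatment and real-life outcome) as published;
it drives the worked evaluation example and the cohort statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Antiepileptic drugs appearing in either cohort's treatment columns.
DRUGS = (
    "BRV", "CBZ", "CLB", "CLZ", "ESL", "GBP", "LCM", "LEV",
    "LTG", "PGB", "PHE", "PHT", "PRM", "TPM", "VPA", "ZNS",
)


def load_validation_cohort(expand_drugs: bool = True) -> pd.DataFrame:
    """The eight-subject validation cohort table.

    With ``expand_drugs`` the comma-separated treatment column is expanded
    into one 0/1 indicator column per drug.
    """
    ref = resources.files("prexstim.data") / "validation_cohort.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    if expand_drugs:
        for drug in DRUGS:
            table[drug] = [
                int(drug in str(t).split(",")) for t in table["treatment"]
            ]
    return table


def validation_outcomes() -> list[str]:
    """Real-life outcomes of the validation cohort, in subject order."""
    table = load_validation_cohort(expand_drugs=False)
    return [
        "responder" if str(v).lower() == "yes" else "non-responder"
        for v in table["responder"]
    ]
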