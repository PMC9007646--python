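"""Shared plumbing for the numbered analysis scripts.

Each script reads its inputs from the results/ workspace written by the
earlier steps, so the whole analysis can be reproduced file by file.
"""

from pathlib import Path

import pandas as pd

from spongecerna.cohort import collapse_duplicates, stratify_risk
from spongecerna.diffexpr import size_factors
from spongecerna.io import read_clinical, read_expression
from spongecerna.pipeline import normalized_log2

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
INPUTS = RESULTS / "inputs"


def load_expression(rna_class: str):
    m = read_expression(INPUTS / f"counts_{rna_class.lower()}.tsv", rna_class)
    return collapse_duplicates(m)


def load_clinical_stratified() -> pd.DataFrame:
    return stratify_risk(read_clinical(INPUTS / "clinical.tsv"))


def load_logexpr(rna_class: str) -> pd.DataFrame:
    m = load_expression(rna_class)
    return normalized_log2(m, size_factors(m))


def group_samples(clin: pd.DataFrame, group: str) -> list[str]:
    return list(clin.loc[clin["risk_group"] == group, "sample_id"])
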