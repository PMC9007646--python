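"""Negative-binomial differential expression, high- vs low-risk, per RNA class.

Median-of-ratios normalization, method-of-moments dispersion, Wald test,
BH adjustment; genes called at FDR < 0.01 and |log2FC| > 1.
"""

import pandas as pd
from _workspace import RESULTS, load_clinical_stratified, load_expression

from spongecerna.config import RunConfig
from spongecerna.diffexpr import call_de, nb_wald_test, size_factors

out = RESULTS / "de"
out.mkdir(parents=True, exist_ok=True)
config = RunConfig(seed=1)

clin = load_clinical_stratified()
groups = pd.Series(clin["risk_group"].to_numpy(), index=clin["sample_id"])

for cls in ("mRNA", "lncRNA", "miRNA"):
    m = load_expression(cls)
    called = call_de(nb_wald_test(m, groups, size_factors(m)), config)
    called.sort_values("gene").to_csv(out / f"de_{cls.lower()}.tsv", sep="\t",
                                      index=False, float_format="%.8g")
    n_up = int((called["direction"] == "up").sum())
    n_down = int((called["direction"] == "down").sum())
    print(f"{cls}: {n_up} up, {n_down} down of {len(called)} genes "
          f"(FDR<{config.de_fdr}, |log2FC|>{config.de_lfc})")
print("volcano-ready tables written to results/de/")
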