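"""Build the per-risk-group sponge networks from the DE genes.

Candidate lncRNA-mRNA pairs share >= 1 targeting miRNA; pairs are kept
at M >= 3 shared miRNAs, hypergeometric p < 0.01, positive Pearson
correlation and BH-adjusted correlation p < 0.05 within each group.
"""

import pandas as pd
from _workspace import INPUTS, RESULTS, group_samples, load_clinical_stratified, load_logexpr

from spongecerna.config import RunConfig
from spongecerna.io import read_expression, read_interactions, write_json
from spongecerna.sponge import build_group_network, candidate_pairs, mirna_universe

out = RESULTS / "sponge"
out.mkdir(parents=True, exist_ok=True)
config = RunConfig(seed=1)

clin = load_clinical_stratified()
lnc_edges = read_interactions(INPUTS / "interactions_mirna_lncrna.tsv")
mrna_edges = read_interactions(INPUTS / "interactions_mirna_mrna.tsv")
mirna_ids = read_expression(INPUTS / "counts_mirna.tsv", "miRNA").genes

de_lnc = pd.read_csv(RESULTS / "de" / "de_lncrna.tsv", sep="\t")
de_mrna = pd.read_csv(RESULTS / "de" / "de_mrna.tsv", sep="\t")
de_lnc_set = set(de_lnc.loc[de_lnc["direction"] != "ns", "gene"])
de_mrna_set = set(de_mrna.loc[de_mrna["direction"] != "ns", "gene"])

universe = mirna_universe(lnc_edges, mrna_edges, mirna_ids)
pairs = candidate_pairs(lnc_edges, mrna_edges, universe,
                        lnc_genes=de_lnc_set, mrna_genes=de_mrna_set)
print(f"miRNA universe: {len(universe)}; candidate DE pairs sharing >=1 miRNA: {len(pairs)}")

log_lnc = load_logexpr("lncRNA")
log_mrna = load_logexpr("mRNA")
for grp in ("high", "low"):
    net = build_group_network(pairs, log_lnc, log_mrna,
                              group_samples(clin, grp), grp, config)
    net.write(out / f"sponge_{grp}.edges.tsv")
    write_json(net.summary(), out / f"sponge_{grp}.summary.json")
    s = net.summary()
    print(f"{grp}-risk network: {s['n_edges']} sponge edges over "
          f"{s['n_lncrna']} lncRNAs and {s['n_mrna']} mRNAs")
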