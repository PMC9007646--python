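"""Score the causal effect of each sponge lncRNA on its paired mRNA.

Adjustment-set regression on standardized log-expression with the pair's
shared miRNAs as covariates; the signed Wald statistic is the effect
score.  Edge strength is also tested with Fisher's z correlation p.
"""

from _workspace import RESULTS, group_samples, load_clinical_stratified, load_logexpr

from spongecerna.causal import positive_fraction, score_network
from spongecerna.config import RunConfig
from spongecerna.sponge import SpongeNetwork

out = RESULTS / "causal"
out.mkdir(parents=True, exist_ok=True)
config = RunConfig(seed=1)

clin = load_clinical_stratified()
log_lnc = load_logexpr("lncRNA")
log_mrna = load_logexpr("mRNA")
log_mir = load_logexpr("miRNA")

for grp in ("high", "low"):
    net = SpongeNetwork.read(RESULTS / "sponge" / f"sponge_{grp}.edges.tsv", grp)
    scored = score_network(net, log_lnc, log_mrna, log_mir,
                           group_samples(clin, grp), config)
    scored.sort_values(["lncrna", "mrna"]).to_csv(
        out / f"causal_{grp}.tsv", sep="\t", index=False, float_format="%.8g")
    pos = positive_fraction(scored)
    if len(scored):
        lo, hi = scored["score"].min(), scored["score"].max()
        print(f"{grp}-risk: {len(scored)} edges scored, range [{lo:.2f}, {hi:.2f}], "
              f"{pos['n_positive']} positive ({100 * pos['fraction']:.1f}%), "
              f"{int(scored['retained'].sum())} retained at adj p<{config.causal_adj_p}")
    else:
        print(f"{grp}-risk: no edges to score")
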