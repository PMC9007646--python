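"""Gene-set over-representation of the sponge-network mRNAs.

Hypergeometric ORA of the mRNAs in either group network against the
supplied gene sets, BH-adjusted, with clusterProfiler-style k/n ratios.
"""

from _workspace import INPUTS, RESULTS

from spongecerna.enrichment import ora_test
from spongecerna.io import read_expression, read_gmt
from spongecerna.sponge import SpongeNetwork

out = RESULTS / "enrichment"
out.mkdir(parents=True, exist_ok=True)

sets = read_gmt(INPUTS / "gene_sets.gmt")
universe = set(read_expression(INPUTS / "counts_mrna.tsv", "mRNA").genes)
query = set()
for grp in ("high", "low"):
    net = SpongeNetwork.read(RESULTS / "sponge" / f"sponge_{grp}.edges.tsv", grp)
    query |= set(net.mrnas)

res = ora_test(query, sets, universe)
res.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
sig = res[res["p_adjust"] < 0.05]
print(f"tested {len(res)} gene sets against {len(query)} network mRNAs; "
      f"{len(sig)} enriched at adjusted p<0.05")
for _, row in sig.head(5).iterrows():
    print(f"  {row['term_id']}: {row['gene_ratio']} hits, "
          f"adj p = {row['p_adjust']:.3g}")
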