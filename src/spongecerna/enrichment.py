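"""Gene-set over-representation analysis (ORA) of network mRNAs.

Hypergeometric enrichment of a query gene list against user-supplied
gene sets (GMT), sharing its tail kernel with the sponge shared-miRNA
test.  Ratios are reported in the "k/n" string form conventional for
pathway tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spongecerna.diffexpr import bh_adjust
from spongecerna.stats import hypergeom_tail

MIN_SET_SIZE = 3


def ora_test(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    descriptions: dict[str, str] | None = None,
    qvalue: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    The universe is restricted to genes annotated in at least one set;
    for each term with >= 3 universe genes and >= 1 query hit,
    p = P(X >= k) with X ~ Hypergeom(N annotated, K in set, n query
    annotated).  BH adjustment across tested terms; ``qvalue="storey"``
    additionally scales by a pi0 estimate at lambda = 0.5.
    """
    if not universe:
        raise ValueError("empty universe")
    descriptions = descriptions or {}
    annotated = set().union(*sets.values()) & universe if sets else set()
    if not annotated:
        raise ValueError("no annotated genes in the universe")
    query_ann = query & annotated
    n_universe = len(annotated)
    n_query = len(query_ann)

    rows = []
    for term in sorted(sets):
        members = sets[term] & annotated
        k_set = len(members)
        hits = sorted(query_ann & members)
        k = len(hits)
        if k_set < MIN_SET_SIZE or k < 1:
            continue
        p = hypergeom_tail(k, n_universe, k_set, n_query)
        rows.append({
            "term_id": term,
            "description": descriptions.get(term, term),
            "gene_ratio": f"{k}/{n_query}",
            "bg_ratio": f"{k_set}/{n_universe}",
            "p": p,
            "count": k,
            "hit_genes": ";".join(hits),
        })
    out = pd.DataFrame(rows, columns=["term_id", "description", "gene_ratio",
                                      "bg_ratio", "p", "count", "hit_genes"])
    if out.empty:
        out["p_adjust"] = pd.Series(dtype=float)
        out["q_value"] = pd.Series(dtype=float)
        return out
    out["p_adjust"] = bh_adjust(out["p"].to_numpy())
    if qvalue == "storey":
        lam = 0.5
        pi0 = min(1.0, float((out["p"] > lam).mean()) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / len(out))
        out["q_value"] = np.minimum(out["p_adjust"] * pi0, 1.0)
    else:
        out["q_value"] = out["p_adjust"]
    return out.sort_values(["p_adjust", "term_id"]).reset_index(drop=True)
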