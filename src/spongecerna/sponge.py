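"""Per-risk-group sponge (ceRNA) network construction.

Candidate lncRNA-mRNA pairs are those sharing at least one targeting
miRNA.  A pair enters the network when (i) the shared-miRNA count M is at
least the configured minimum (M > 2 by default), (ii) the hypergeometric
tail probability of sharing that many miRNAs is below the threshold,
(iii) the pair is positively correlated in the group's normalized
log-expression and (iv) the BH-adjusted correlation p is below its
threshold.  Correlations are computed within each risk group separately,
yielding one network per group.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from spongecerna.config import RunConfig
from spongecerna.diffexpr import bh_adjust
from spongecerna.stats import hypergeom_tail


def shared_mirna_test(
    lnc_targets: set[str], mrna_targets: set[str], universe: set[str]
) -> dict[str, float]:
    """Shared-miRNA count M and its hypergeometric upper-tail probability.

    Tests whether the two genes share more targeting miRNAs than expected
    from drawing their target sets independently from the universe.
    M = 0 gives p = 1.
    """
    if not universe:
        raise ValueError("miRNA universe is empty")
    if not lnc_targets <= universe or not mrna_targets <= universe:
        raise ValueError("target sets must be contained in the universe")
    m = len(lnc_targets & mrna_targets)
    p = hypergeom_tail(m, len(universe), len(lnc_targets), len(mrna_targets))
    return {"m": m, "hyper_p": p}


def mirna_universe(
    lnc_edges: pd.DataFrame,
    mrna_edges: pd.DataFrame,
    expressed_mirnas: Iterable[str] | None = None,
) -> set[str]:
    """miRNAs appearing in either interaction table, optionally intersected
    with the measured miRNA matrix."""
    universe = set(lnc_edges["miRNA_id"]) | set(mrna_edges["miRNA_id"])
    if expressed_mirnas is not None:
        universe &= set(expressed_mirnas)
    return universe


def candidate_pairs(
    lnc_edges: pd.DataFrame,
    mrna_edges: pd.DataFrame,
    universe: set[str],
    lnc_genes: Iterable[str] | None = None,
    mrna_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """All (lncRNA, mRNA) pairs sharing >= 1 universe miRNA, with M and hyper_p.

    ``lnc_genes`` / ``mrna_genes`` restrict the pair universe (typically to
    the differentially expressed genes).
    """
    uni = sorted(universe)
    if not uni:
        raise ValueError("miRNA universe is empty")
    uni_idx = {m: i for i, m in enumerate(uni)}

    def _membership(edges: pd.DataFrame, keep: set[str] | None) -> tuple[list[str], np.ndarray]:
        sel = edges[edges["miRNA_id"].isin(uni_idx)]
        if keep is not None:
            sel = sel[sel["target_id"].isin(keep)]
        genes = sorted(sel["target_id"].unique())
        g_idx = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((len(genes), len(uni)), dtype=np.int32)
        for mi, ti in zip(sel["miRNA_id"], sel["target_id"]):
            mat[g_idx[ti], uni_idx[mi]] = 1
        return genes, mat

    lnc_keep = set(lnc_genes) if lnc_genes is not None else None
    mrna_keep = set(mrna_genes) if mrna_genes is not None else None
    lncs, lmat = _membership(lnc_edges, lnc_keep)
    mrnas, mmat = _membership(mrna_edges, mrna_keep)
    if not lncs or not mrnas:
        return pd.DataFrame(columns=["lncrna", "mrna", "shared_m", "n_mirna_lnc",
                                     "n_mirna_mrna", "universe_n", "hyper_p", "shared_set"])

    shared = lmat @ mmat.T
    k_lnc = lmat.sum(axis=1)
    k_mrna = mmat.sum(axis=1)
    li, mi = np.nonzero(shared)
    m = shared[li, mi]
    n_uni = len(uni)
    p = sps.hypergeom.sf(m - 1, n_uni, k_lnc[li], k_mrna[mi])

    uni_arr = np.array(uni)
    shared_sets = [
        ";".join(uni_arr[(lmat[i] & mmat[j]).astype(bool)]) for i, j in zip(li, mi)
    ]
    return pd.DataFrame({
        "lncrna": [lncs[i] for i in li],
        "mrna": [mrnas[j] for j in mi],
        "shared_m": m.astype(int),
        "n_mirna_lnc": k_lnc[li].astype(int),
        "n_mirna_mrna": k_mrna[mi].astype(int),
        "universe_n": n_uni,
        "hyper_p": p,
        "shared_set": shared_sets,
    })


def sponge_correlation(
    pairs: pd.DataFrame,
    logexpr_lnc: pd.DataFrame,
    logexpr_mrna: pd.DataFrame,
    samples: Iterable[str],
) -> pd.DataFrame:
    """Pearson r and BH-adjusted two-sided p per candidate pair, one group.

    Expression frames are gene x sample on the log2(normalized + 1) scale.
    Zero-variance genes yield NaN r and a ``dropped`` flag.
    """
    samples = [s for s in samples]
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples in the group")
    out = pairs.copy()
    if out.empty:
        for col in ("pearson_r", "corr_p", "corr_p_adj"):
            out[col] = pd.Series(dtype=float)
        out["dropped"] = pd.Series(dtype=bool)
        return out

    lx = logexpr_lnc.loc[out["lncrna"], samples].to_numpy(dtype=float)
    mx = logexpr_mrna.loc[out["mrna"], samples].to_numpy(dtype=float)
    lx_c = lx - lx.mean(axis=1, keepdims=True)
    mx_c = mx - mx.mean(axis=1, keepdims=True)
    l_sd = np.sqrt((lx_c**2).sum(axis=1))
    m_sd = np.sqrt((mx_c**2).sum(axis=1))
    valid = (l_sd > 0) & (m_sd > 0)
    r = np.full(len(out), np.nan)
    num = (lx_c * mx_c).sum(axis=1)
    r[valid] = num[valid] / (l_sd[valid] * m_sd[valid])
    r = np.clip(r, -1.0, 1.0)

    p = np.full(len(out), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), n - 2)
    p = np.clip(p, 0.0, 1.0)

    out["pearson_r"] = r
    out["corr_p"] = p
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid] = bh_adjust(p[valid])
    out["corr_p_adj"] = adj
    out["dropped"] = ~valid
    return out


def filter_pairs(pairs: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Keep pairs with M >= minimum, hyper_p < threshold, r > 0 and
    BH-adjusted correlation p < threshold."""
    config = config or RunConfig()
    keep = (
        (pairs["shared_m"] >= config.sponge_min_shared)
        & (pairs["hyper_p"] < config.sponge_p)
        & (pairs["pearson_r"] > 0)
        & (pairs["corr_p_adj"] < config.corr_adj_p)
        & ~pairs["dropped"].fillna(False).astype(bool)
    )
    return pairs[keep.fillna(False)].reset_index(drop=True)


@dataclasses.dataclass
class SpongeNetwork:
    """Sponge network for one risk group: lncRNA-mRNA edges plus the
    shared-miRNA memberships behind each edge."""

    edges: pd.DataFrame  # columns lncrna, mrna, pearson_r, shared_m, hyper_p, shared_set
    group: str

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["lncrna"], self.edges["mrna"]))

    @property
    def lncrnas(self) -> list[str]:
        return sorted(self.edges["lncrna"].unique())

    @property
    def mrnas(self) -> list[str]:
        return sorted(self.edges["mrna"].unique())

    def sponge_degree(self) -> pd.Series:
        """Sponge-edge degree of every lncRNA in the network."""
        return self.edges["lncrna"].value_counts().sort_index()

    def graph(self, include_mirnas: bool = False) -> nx.Graph:
        g = nx.Graph()
        for lnc in self.lncrnas:
            g.add_node(lnc, node_type="lncRNA")
        for mr in self.mrnas:
            g.add_node(mr, node_type="mRNA")
        for row in self.edges.itertuples():
            g.add_edge(row.lncrna, row.mrna, weight=float(row.pearson_r))
            if include_mirnas:
                for mir in str(row.shared_set).split(";"):
                    if mir:
                        g.add_node(mir, node_type="miRNA")
                        g.add_edge(row.lncrna, mir, membership=True)
                        g.add_edge(row.mrna, mir, membership=True)
        return g

    def summary(self) -> dict:
        return {
            "group": self.group,
            "n_lncrna": len(self.lncrnas),
            "n_mrna": len(self.mrnas),
            "n_edges": int(len(self.edges)),
        }

    def write(self, path: str | Path) -> None:
        cols = ["lncrna", "mrna", "pearson_r", "shared_m", "hyper_p",
                "corr_p", "corr_p_adj", "shared_set"]
        present = [c for c in cols if c in self.edges.columns]
        out = self.edges[present].sort_values(["lncrna", "mrna"]).reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read(cls, path: str | Path, group: str) -> "SpongeNetwork":
        return cls(pd.read_csv(path, sep="\t"), group)


def build_sponge_network(passing_pairs: pd.DataFrame, group: str) -> SpongeNetwork:
    """Assemble the network from pairs that already passed every filter."""
    edges = passing_pairs.sort_values(["lncrna", "mrna"]).reset_index(drop=True)
    return SpongeNetwork(edges=edges, group=group)


def build_group_network(
    pairs: pd.DataFrame,
    logexpr_lnc: pd.DataFrame,
    logexpr_mrna: pd.DataFrame,
    group_samples: Iterable[str],
    group: str,
    config: RunConfig | None = None,
) -> SpongeNetwork:
    """Candidate pairs -> correlations -> filters -> network, for one group."""
    tested = sponge_correlation(pairs, logexpr_lnc, logexpr_mrna, group_samples)
    return build_sponge_network(filter_pairs(tested, config), group)
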