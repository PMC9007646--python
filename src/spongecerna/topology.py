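"""Network topology: hub selection, group comparison, scale-free check, MCL.

Hubs are the top fraction of lncRNAs by sponge-edge degree.  The two
group networks are compared on unordered (lncRNA, mRNA) edge sets:
similarity = |conserved| / min(|E_high|, |E_low|), and hub dissimilarity
= 1 - |shared hubs| / min(|hubs_high|, |hubs_low|).  Modules are found
with Markov clustering (expansion / inflation on the column-stochastic
sponge adjacency).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from spongecerna.sponge import SpongeNetwork


def select_hubs(net: SpongeNetwork, fraction: float = 0.20) -> dict:
    """Top ceil(fraction * n_lncRNA) lncRNAs by sponge-edge degree.

    Ties at the cutoff degree are broken by lexicographic node ID and the
    expansion is reported (``tie`` flag plus the tied IDs).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    deg = net.sponge_degree()
    if deg.empty:
        return {"hubs": [], "k": 0, "tie": False, "tied_ids": []}
    k = int(np.ceil(fraction * len(deg)))
    ordered = deg.sort_values(ascending=False, kind="stable")
    # stable sort on (-degree, id): value_counts().sort_index() pre-sorts IDs
    cutoff_degree = ordered.iloc[k - 1]
    tied = sorted(deg.index[deg == cutoff_degree])
    chosen = list(ordered.index[:k])
    tie = len(tied) > sum(1 for h in chosen if deg[h] == cutoff_degree)
    return {"hubs": sorted(chosen), "k": k, "tie": tie,
            "tied_ids": tied if tie else []}


@dataclasses.dataclass
class NetworkComparison:
    conserved_edges: set[tuple[str, str]]
    differential_edges_high: set[tuple[str, str]]
    differential_edges_low: set[tuple[str, str]]
    sim_edges: float
    hubs_high: list[str]
    hubs_low: list[str]
    hubs_shared: list[str]
    differential_hubs_high: list[str]
    hub_dissimilarity: float

    def to_dict(self) -> dict:
        return {
            "n_conserved_edges": len(self.conserved_edges),
            "n_differential_edges_high": len(self.differential_edges_high),
            "n_differential_edges_low": len(self.differential_edges_low),
            "sim_edges": self.sim_edges,
            "hubs_high": self.hubs_high,
            "hubs_low": self.hubs_low,
            "hubs_shared": self.hubs_shared,
            "differential_hubs_high": self.differential_hubs_high,
            "hub_dissimilarity": self.hub_dissimilarity,
        }


def compare_networks(
    net_high: SpongeNetwork,
    net_low: SpongeNetwork,
    hubs_high: list[str],
    hubs_low: list[str],
) -> NetworkComparison:
    """Conserved/differential edges and hub overlap between the two groups."""
    def _pairs(net: SpongeNetwork) -> set[tuple[str, str]]:
        return {tuple(sorted(p)) for p in net.pair_set()}

    e_high, e_low = _pairs(net_high), _pairs(net_low)
    conserved = e_high & e_low
    denom = min(len(e_high), len(e_low))
    sim = len(conserved) / denom if denom else float("nan")
    h_high, h_low = set(hubs_high), set(hubs_low)
    shared = h_high & h_low
    hub_denom = min(len(h_high), len(h_low))
    dissim = 1.0 - len(shared) / hub_denom if hub_denom else float("nan")
    return NetworkComparison(
        conserved_edges=conserved,
        differential_edges_high=e_high - e_low,
        differential_edges_low=e_low - e_high,
        sim_edges=sim,
        hubs_high=sorted(h_high),
        hubs_low=sorted(h_low),
        hubs_shared=sorted(shared),
        differential_hubs_high=sorted(h_high - h_low),
        hub_dissimilarity=dissim,
    )


def scale_free_fit(net: SpongeNetwork, n_bins: int = 10) -> dict:
    """Power-law check: regress log10 P(k) on log10 k over log-binned degrees.

    Degrees pool lncRNA and mRNA sponge-edge degrees.  Fewer than five
    distinct degree values gives an NA result (flagged), not an error.
    """
    g = net.graph()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    na = {"slope": float("nan"), "r_squared": float("nan"), "ok": False}
    if degrees.size == 0 or len(np.unique(degrees[degrees > 0])) < 5:
        return na
    degrees = degrees[degrees > 0]
    edges = np.logspace(np.log10(degrees.min()), np.log10(degrees.max() + 1), n_bins + 1)
    hist, bin_edges = np.histogram(degrees, bins=edges)
    widths = np.diff(bin_edges)
    centers = np.sqrt(bin_edges[:-1] * bin_edges[1:])
    dens = hist / (widths * degrees.size)
    keep = dens > 0
    if keep.sum() < 3:
        return na
    x, y = np.log10(centers[keep]), np.log10(dens[keep])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"slope": float(slope), "r_squared": r2, "ok": True}


def mcl_cluster(
    net: SpongeNetwork | None = None,
    inflation: float = 2.0,
    adjacency: pd.DataFrame | None = None,
    max_iter: int = 200,
    prune: float = 1e-6,
    tol: float = 1e-8,
) -> dict:
    """Markov clustering of the sponge graph (or an explicit adjacency).

    Self-loops are set to each node's maximum incident weight, columns are
    normalized, then expansion (matrix square) and inflation (elementwise
    power + renormalize) alternate, pruning entries below 1e-6, until the
    maximum elementwise change is below 1e-8 or 200 iterations.  Modules
    are read off the attractor rows; a node appearing in several modules
    goes to the one with the larger flow (ties lexicographic by module
    representative).  Returns ``assignment`` (node -> module id),
    ``modules`` (module id -> sorted nodes) and a ``converged`` flag.
    """
    if adjacency is not None:
        nodes = list(adjacency.index)
        a = adjacency.to_numpy(dtype=float)
    else:
        g = net.graph()
        nodes = sorted(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w = abs(float(data.get("weight", 1.0)))
            a[idx[u], idx[v]] = w
            a[idx[v], idx[u]] = w
    n = len(nodes)
    if n == 0:
        return {"assignment": {}, "modules": {}, "converged": True}
    if (a < 0).any():
        raise ValueError("edge weights must be nonnegative")

    incident_max = a.max(axis=0)
    np.fill_diagonal(a, np.where(incident_max > 0, incident_max, 1.0))

    def _normalize(m: np.ndarray) -> np.ndarray:
        s = m.sum(axis=0)
        s[s == 0] = 1.0
        return m / s

    m = _normalize(a)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune] = 0.0
        m = _normalize(m)
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break

    # attractor rows (nonzero diagonal) define modules; node joins the
    # attractor giving it the most flow
    attractors = np.flatnonzero(np.diag(m) > prune)
    if attractors.size == 0:
        attractors = np.array([int(np.argmax(np.diag(m)))])
    # merge attractors that share a module (overlapping support)
    parent = {int(i): int(i) for i in attractors}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in attractors:
        for j in attractors:
            if i < j and (m[i] > prune).astype(bool) @ (m[j] > prune).astype(bool):
                parent[find(int(j))] = find(int(i))

    assignment: dict[str, int] = {}
    for v in range(n):
        flows = m[attractors, v]
        if flows.max() <= 0:
            # isolated or fully pruned column: its own singleton module
            assignment[nodes[v]] = -(v + 1)
            continue
        best = attractors[np.flatnonzero(flows == flows.max())]
        chosen = find(int(min(best)))
        assignment[nodes[v]] = chosen

    # relabel modules 0..K-1 ordered by their lexicographically first member
    members: dict[int, list[str]] = {}
    for v, mod in assignment.items():
        members.setdefault(mod, []).append(v)
    ordered = sorted(members.values(), key=lambda vs: min(vs))
    modules = {k: sorted(vs) for k, vs in enumerate(ordered)}
    final = {v: k for k, vs in modules.items() for v in vs}
    return {"assignment": final, "modules": modules, "converged": converged}
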