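"""End-to-end pipeline over a synthetic cohort.

simulate -> preprocess/stratify -> differential expression per RNA class
-> per-group sponge networks -> causal scoring -> hubs, comparison and
modules -> survival screen of differential hubs -> ORA of network mRNAs.
All outputs are plain TSV/JSON written in deterministic order; two runs
with the same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from spongecerna import causal, cohort, diffexpr, enrichment, sponge, survival, topology
from spongecerna.config import RunConfig
from spongecerna.io import write_json
from spongecerna.synthetic import SimParams, SyntheticCohort, simulate_cohort, truth_eval


def normalized_log2(counts, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the expression scale used for all
    correlations, causal scores and survival splits."""
    return np.log2(counts.values.div(factors, axis=1) + 1.0)


def run_pipeline(
    params: SimParams | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    data: SyntheticCohort | None = None,
) -> dict:
    """Run every stage; optionally write all result tables under ``outdir``.

    Returns a dict with the per-stage objects plus recovery metrics
    against the planted ground truth.
    """
    params = params or SimParams()
    config = config or RunConfig(seed=params.seed)
    data = data or simulate_cohort(params)
    out: dict = {"params": params, "config": config, "data": data}

    if outdir is not None:
        outdir = Path(outdir)
        for sub in ("inputs", "cohort", "de", "sponge", "causal",
                    "topology", "survival", "enrichment"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        data.write(outdir / "inputs")

    # ---- cohort: stratify and summarize
    clin = cohort.stratify_risk(data.clinical, config.wbc_cutoff)
    groups = pd.Series(clin["risk_group"].to_numpy(), index=clin["sample_id"])
    table1 = cohort.cohort_summary(clin)
    out["clinical"] = clin
    out["table1"] = table1
    if outdir is not None:
        clin.to_csv(outdir / "cohort" / "clinical_stratified.tsv", sep="\t",
                    index=False, float_format="%.8g")
        table1.to_csv(outdir / "cohort" / "table1.tsv", sep="\t",
                      index=False, float_format="%.8g")

    # ---- differential expression per RNA class
    de_called: dict[str, pd.DataFrame] = {}
    logexpr: dict[str, pd.DataFrame] = {}
    factors: dict[str, pd.Series] = {}
    for cls, m in data.expression.items():
        collapsed = cohort.collapse_duplicates(m)
        f = diffexpr.size_factors(collapsed)
        res = diffexpr.nb_wald_test(collapsed, groups, f)
        called = diffexpr.call_de(res, config)
        de_called[cls] = called
        factors[cls] = f
        logexpr[cls] = normalized_log2(collapsed, f)
        if outdir is not None:
            called.sort_values("gene").to_csv(
                outdir / "de" / f"de_{cls.lower()}.tsv", sep="\t",
                index=False, float_format="%.8g")
    out["de"] = de_called
    out["logexpr"] = logexpr
    out["size_factors"] = factors

    de_lnc = set(de_called["lncRNA"].loc[de_called["lncRNA"]["direction"] != "ns", "gene"])
    de_mrna = set(de_called["mRNA"].loc[de_called["mRNA"]["direction"] != "ns", "gene"])

    # ---- sponge networks per risk group
    universe = sponge.mirna_universe(
        data.interactions["mirna_lncrna"], data.interactions["mirna_mrna"],
        expressed_mirnas=data.expression["miRNA"].genes)
    candidates = sponge.candidate_pairs(
        data.interactions["mirna_lncrna"], data.interactions["mirna_mrna"],
        universe, lnc_genes=de_lnc, mrna_genes=de_mrna)
    out["candidates"] = candidates

    networks: dict[str, sponge.SpongeNetwork] = {}
    for grp in ("high", "low"):
        samples = list(clin.loc[clin["risk_group"] == grp, "sample_id"])
        networks[grp] = sponge.build_group_network(
            candidates, logexpr["lncRNA"], logexpr["mRNA"], samples, grp, config)
        if outdir is not None:
            networks[grp].write(outdir / "sponge" / f"sponge_{grp}.edges.tsv")
            write_json(networks[grp].summary(),
                       outdir / "sponge" / f"sponge_{grp}.summary.json")
    out["networks"] = networks

    # ---- causal scoring per group
    causal_edges: dict[str, pd.DataFrame] = {}
    for grp in ("high", "low"):
        samples = list(clin.loc[clin["risk_group"] == grp, "sample_id"])
        scored = causal.score_network(
            networks[grp], logexpr["lncRNA"], logexpr["mRNA"], logexpr["miRNA"],
            samples, config)
        causal_edges[grp] = scored
        if outdir is not None:
            scored.sort_values(["lncrna", "mrna"]).to_csv(
                outdir / "causal" / f"causal_{grp}.tsv", sep="\t",
                index=False, float_format="%.8g")
    out["causal"] = causal_edges
    out["positive_fraction"] = {g: causal.positive_fraction(causal_edges[g])
                                for g in ("high", "low")}

    # ---- topology: hubs, comparison, scale-free, modules
    hubs = {g: topology.select_hubs(networks[g], config.hub_fraction)
            for g in ("high", "low")}
    comparison = topology.compare_networks(
        networks["high"], networks["low"], hubs["high"]["hubs"], hubs["low"]["hubs"])
    modules = {g: topology.mcl_cluster(networks[g]) for g in ("high", "low")}
    out["hubs"] = hubs
    out["comparison"] = comparison
    out["modules"] = modules
    out["scale_free"] = {g: topology.scale_free_fit(networks[g]) for g in ("high", "low")}
    if outdir is not None:
        write_json(comparison.to_dict(), outdir / "topology" / "comparison.json")
        for g in ("high", "low"):
            pd.DataFrame({"hub": hubs[g]["hubs"]}).to_csv(
                outdir / "topology" / f"hubs_{g}.tsv", sep="\t", index=False)
            assign = modules[g]["assignment"]
            pd.DataFrame(sorted(assign.items()), columns=["node", "module"]).to_csv(
                outdir / "topology" / f"modules_{g}.tsv", sep="\t", index=False)

    # ---- survival screen of the high-risk hub set
    records = clin.set_index("sample_id")[["os_time", "os_event"]].rename(
        columns={"os_time": "time", "os_event": "event"})
    screened_set = hubs["high"]["hubs"]
    screen = survival.screen_hubs(logexpr["lncRNA"], screened_set, records, config)
    out["screen"] = screen
    if outdir is not None:
        screen.to_csv(outdir / "survival" / "screen.tsv", sep="\t",
                      index=False, float_format="%.8g")

    retained = causal_edges["high"][causal_edges["high"]["retained"]]
    all_samples = list(clin["sample_id"])
    out["hub_mrna_corr"] = survival.hub_mrna_correlation(
        logexpr["lncRNA"], logexpr["mRNA"], retained, all_samples)
    if outdir is not None:
        out["hub_mrna_corr"].to_csv(outdir / "survival" / "hub_mrna_correlation.tsv",
                                    sep="\t", index=False, float_format="%.8g")

    # ---- enrichment of network mRNAs
    network_mrnas = set(networks["high"].mrnas) | set(networks["low"].mrnas)
    mrna_universe = set(data.expression["mRNA"].genes)
    try:
        enrich = enrichment.ora_test(network_mrnas, data.gene_sets, mrna_universe)
    except ValueError:
        enrich = pd.DataFrame()
    out["enrichment"] = enrich
    if outdir is not None:
        enrich.to_csv(outdir / "enrichment" / "enrichment.tsv", sep="\t",
                      index=False, float_format="%.8g")

    # ---- recovery metrics vs planted truth
    truth = data.truth
    inferred_pairs = networks["high"].pair_set() | networks["low"].pair_set()
    de_inferred = de_lnc | de_mrna
    metrics = {
        "de": truth_eval(de_inferred, truth.de_set(("mRNA", "lncRNA"))),
        "sponge_pairs": truth_eval(inferred_pairs, truth.pair_set()),
        "n_edges_high": len(networks["high"].edges),
        "n_edges_low": len(networks["low"].edges),
        "sim_edges": comparison.sim_edges,
        "hub_dissimilarity": comparison.hub_dissimilarity,
        "positive_fraction_high": out["positive_fraction"]["high"]["fraction"],
        "screen_passing_fraction": screen.attrs.get("passing_fraction", float("nan")),
    }
    out["metrics"] = metrics
    if outdir is not None:
        write_json(metrics, outdir / "metrics.json")
    return out
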