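"""Synthetic two-risk-group cohort generator with planted ground truth.

Emulates the study design the pipeline targets: a pediatric-leukemia-like
cohort of two WBC-defined risk groups with negative-binomial RNA-seq count
matrices (mRNA, lncRNA, miRNA), miRNA->target interaction tables, a
clinical table with survival endpoints, and gene sets — all with planted
structure the pipeline should recover:

* differentially expressed genes with a fixed |log2FC| between groups;
* sponge triplets: a lncRNA and an mRNA that share a set of targeting
  miRNAs and are positively co-expressed through a shared latent miRNA
  activity that represses both (and raises the miRNAs);
* prognostic hub lncRNAs loading on a latent risk axis that drives an
  exponential survival hazard.

Counts are NB draws with variance mu + alpha*mu^2 around per-group means
times per-sample library factors.  The sponge coupling coefficient is
solved per pair from the delta-method relation between the latent weight
and the target Pearson correlation on the log scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from spongecerna.io import ExpressionMatrix, write_clinical, write_expression, write_gmt, write_interactions

LN2 = math.log(2.0)
# baseline abundance: log2 means ~ Normal(5, 2); triplet members use
# Normal(6, 1) so the correlation target stays reachable under NB noise
BASE_LOG2_MEAN = (5.0, 2.0)
TRIPLET_LOG2_MEAN = (6.0, 1.0)
MIRNA_LATENT_WEIGHT = 0.3       # ln-scale response of a shared miRNA to its triplet latent
HUB_LOADING_CORR = 0.8          # target corr between a prognostic hub and the risk axis
MEDIAN_EVENT_YEARS = 3.3        # sets the exponential baseline hazard scale


@dataclasses.dataclass
class SimParams:
    n_low: int = 169
    n_high: int = 92
    n_mrna: int = 2000
    n_lncrna: int = 600
    n_mirna: int = 150
    frac_de: float = 0.10
    lfc_de: float = 1.5
    nb_dispersion: float = 0.2
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    n_triplets: int = 50
    shared_mirnas_per_triplet: int = 4
    rho_sponge: float = 0.7
    background_edge_prob: float = 0.01
    n_prognostic_hubs: int = 10
    beta_hazard: float = 0.7
    censor_frac: float = 0.3
    wbc_cutoff: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_sponge < 1.0:
            raise ValueError(f"rho_sponge must be in (-1, 1), got {self.rho_sponge}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError(f"frac_de must be in [0, 1], got {self.frac_de}")
        for name in ("n_low", "n_high", "n_mrna", "n_lncrna", "n_mirna",
                     "n_triplets", "shared_mirnas_per_triplet"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.shared_mirnas_per_triplet > self.n_mirna:
            raise ValueError("shared_mirnas_per_triplet exceeds the miRNA universe")
        if self.n_triplets * self.shared_mirnas_per_triplet > self.n_mirna * self.n_lncrna:
            raise ValueError("infeasible: more planted triplet edges than possible pairs")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna):
            raise ValueError("n_triplets exceeds available distinct lncRNAs/mRNAs")
        if self.n_prognostic_hubs > self.n_lncrna:
            raise ValueError("n_prognostic_hubs exceeds the lncRNA count")
        if not 0.0 <= self.censor_frac < 1.0:
            raise ValueError(f"censor_frac must be in [0, 1), got {self.censor_frac}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")


@dataclasses.dataclass
class GroundTruth:
    """Manifest of everything the generator planted."""

    de_genes: pd.DataFrame            # columns gene, rna_class, log2fc
    triplets: list[dict]              # {"lncrna", "mrna", "mirnas": [...]}
    prognostic_hubs: list[dict]       # {"gene", "beta"}
    lib_factors: pd.Series

    def pair_set(self) -> set[tuple[str, str]]:
        """Planted sponge pairs as unordered-comparable (lncRNA, mRNA) tuples."""
        return {(t["lncrna"], t["mrna"]) for t in self.triplets}

    def de_set(self, rna_classes: Sequence[str] = ("mRNA", "lncRNA")) -> set[str]:
        sel = self.de_genes["rna_class"].isin(rna_classes)
        return set(self.de_genes.loc[sel, "gene"])

    def hub_set(self) -> set[str]:
        return {h["gene"] for h in self.prognostic_hubs}

    def to_json(self, path: str | Path) -> None:
        obj = {
            "de_genes": self.de_genes.to_dict(orient="records"),
            "triplets": self.triplets,
            "prognostic_hubs": self.prognostic_hubs,
            "lib_factors": {k: float(v) for k, v in self.lib_factors.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            de_genes=pd.DataFrame(obj["de_genes"], columns=["gene", "rna_class", "log2fc"]),
            triplets=obj["triplets"],
            prognostic_hubs=obj["prognostic_hubs"],
            lib_factors=pd.Series(obj["lib_factors"]),
        )


@dataclasses.dataclass
class SyntheticCohort:
    expression: dict[str, ExpressionMatrix]
    interactions: dict[str, pd.DataFrame]   # keys "mirna_mrna", "mirna_lncrna"
    clinical: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: GroundTruth
    params: SimParams

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cls, m in self.expression.items():
            write_expression(m, outdir / f"counts_{cls.lower()}.tsv")
        write_interactions(self.interactions["mirna_mrna"], outdir / "interactions_mirna_mrna.tsv")
        write_interactions(self.interactions["mirna_lncrna"], outdir / "interactions_mirna_lncrna.tsv")
        write_clinical(self.clinical, outdir / "clinical.tsv")
        write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        self.truth.to_json(outdir / "truth.json")


def sponge_coupling_weight(rho: float, noise_var1: float, noise_var2: float) -> float:
    """Latent weight c (ln scale) so two genes sharing -c*a reach Pearson rho.

    Solves rho = c^2 / sqrt((c^2 + v1)(c^2 + v2)) for c^2 (quadratic root).
    """
    if rho <= 0.0:
        return 0.0
    r2 = rho * rho
    s = noise_var1 + noise_var2
    prod = noise_var1 * noise_var2
    a = 1.0 - r2
    disc = (r2 * s) ** 2 + 4.0 * a * r2 * prod
    c2 = (r2 * s + math.sqrt(disc)) / (2.0 * a)
    return math.sqrt(c2)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + alpha*mu^2 (Poisson if alpha=0)."""
    mu = np.maximum(mu, 1e-12)
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    # gamma-Poisson mixture keeps full vectorization for array means
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def solve_censor_horizon(rates: np.ndarray, censor_frac: float) -> float:
    """Uniform(0, c) censoring horizon hitting an expected censoring fraction.

    For T ~ Exp(rate) and C ~ Uniform(0, c), P(censored) averaged over the
    per-sample rates equals censor_frac.
    """
    if censor_frac <= 0.0:
        return float("inf")
    rates = np.asarray(rates, dtype=float)

    def frac(c: float) -> float:
        return float(np.mean((1.0 - np.exp(-rates * c)) / (rates * c))) - censor_frac

    lo, hi = 1e-6, 1e6
    return float(optimize.brentq(frac, lo, hi, xtol=1e-10))


def simulate_survival(
    x: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    h0: float | None = None,
    censor_frac: float = 0.3,
) -> pd.DataFrame:
    """Exponential survival times with hazard h0*exp(beta*x), uniform censoring.

    ``x`` is the per-sample covariate (used as given; standardize upstream if a
    per-SD hazard ratio is wanted).  Returns columns time and event.
    """
    x = np.asarray(x, dtype=float)
    if h0 is None:
        h0 = LN2 / MEDIAN_EVENT_YEARS
    rates = h0 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / rates)
    if censor_frac <= 0.0:
        return pd.DataFrame({"time": t_event, "event": np.ones(x.size, dtype=int)})
    horizon = solve_censor_horizon(rates, censor_frac)
    t_cens = rng.uniform(0.0, horizon, size=x.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def _simulate_clinical_covariates(
    rng: np.random.Generator, n_low: int, n_high: int, cutoff: float
) -> pd.DataFrame:
    """Ages, gender, WBC and fusion flags with Table-1-like group rates.

    WBC is drawn from two log-normals truncated at the cutoff so the group
    labels reproduce the stratification rule exactly.
    """
    n = n_low + n_high
    age = np.clip(rng.normal(7.9, 5.3, size=n), 0.03, None)
    gender = np.where(rng.random(n) < 0.51, "male", "female")

    def trunc_lognormal(mean_ln, sd_ln, size, low=None, high=None):
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.lognormal(mean_ln, sd_ln, size=size)
            ok = np.ones(draw.size, dtype=bool)
            if low is not None:
                ok &= draw >= low
            if high is not None:
                ok &= draw < high
            take = draw[ok][: size - filled]
            out[filled : filled + take.size] = take
            filled += take.size
        return out

    wbc = np.concatenate([
        trunc_lognormal(math.log(12.0), 0.8, n_low, high=cutoff),
        trunc_lognormal(math.log(90.0), 0.5, n_high, low=cutoff),
    ])
    group = np.array(["low"] * n_low + ["high"] * n_high)
    # per-group fusion prevalences on the scale of a B-precursor ALL cohort
    fusion_rates = {
        "bcr_abl1": (0.0, 0.054),
        "etv6_runx1": (0.112, 0.022),
        "tcf3_hlf": (0.089, 0.076),
        "tcf3_pbx1": (0.089, 0.076),
        "trisomy_4_10": (0.083, 0.076),
    }
    clin = pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": age,
        "gender": gender,
        "wbc": wbc,
        "risk_group_true": group,
    })
    for col, (p_lo, p_hi) in fusion_rates.items():
        p = np.where(group == "low", p_lo, p_hi)
        clin[col] = (rng.random(n) < p).astype(int)
    return clin


def simulate_cohort(params: SimParams | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort (see module docstring)."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_low + params.n_high
    alpha = params.nb_dispersion

    mrna_ids = [f"MRNA{i + 1:05d}" for i in range(params.n_mrna)]
    lnc_ids = [f"LNC{i + 1:05d}" for i in range(params.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(params.n_mirna)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    is_high = np.array([False] * params.n_low + [True] * params.n_high)

    base_log2 = {
        "mRNA": rng.normal(*BASE_LOG2_MEAN, size=params.n_mrna),
        "lncRNA": rng.normal(*BASE_LOG2_MEAN, size=params.n_lncrna),
        "miRNA": rng.normal(*BASE_LOG2_MEAN, size=params.n_mirna),
    }

    # ---- plant DE genes (balanced up/down, fixed |log2FC| in the high group)
    de_records = []
    de_effect = {
        "mRNA": np.zeros(params.n_mrna),
        "lncRNA": np.zeros(params.n_lncrna),
        "miRNA": np.zeros(params.n_mirna),
    }
    ids_by_class = {"mRNA": mrna_ids, "lncRNA": lnc_ids, "miRNA": mir_ids}
    de_index: dict[str, np.ndarray] = {}
    for cls, ids in ids_by_class.items():
        n_de = int(round(params.frac_de * len(ids)))
        idx = rng.choice(len(ids), size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        rng.shuffle(signs)
        de_effect[cls][idx] = signs * params.lfc_de
        de_index[cls] = idx
        for i, s in zip(idx, signs):
            de_records.append({"gene": ids[i], "rna_class": cls,
                              "log2fc": float(s * params.lfc_de)})
    de_genes = pd.DataFrame(de_records, columns=["gene", "rna_class", "log2fc"])

    # ---- choose triplet members (from the DE pool when it is large enough,
    # so a DE-restricted network can recover them)
    def _triplet_pool(cls: str) -> np.ndarray:
        idx = de_index[cls]
        if idx.size >= params.n_triplets:
            return idx
        return np.arange(len(ids_by_class[cls]))

    trip_lnc = rng.choice(_triplet_pool("lncRNA"), size=params.n_triplets, replace=False)
    trip_mrna = rng.choice(_triplet_pool("mRNA"), size=params.n_triplets, replace=False)
    base_log2["lncRNA"][trip_lnc] = rng.normal(*TRIPLET_LOG2_MEAN, size=params.n_triplets)
    base_log2["mRNA"][trip_mrna] = rng.normal(*TRIPLET_LOG2_MEAN, size=params.n_triplets)

    triplets = []
    latent = rng.standard_normal((params.n_triplets, n))
    lnc_latent_log2 = np.zeros((params.n_lncrna, n))
    mrna_latent_log2 = np.zeros((params.n_mrna, n))
    mir_latent_log2 = np.zeros((params.n_mirna, n))
    for t in range(params.n_triplets):
        i_l, i_m = trip_lnc[t], trip_mrna[t]
        mirs = rng.choice(params.n_mirna, size=params.shared_mirnas_per_triplet, replace=False)
        mu_l = 2.0 ** base_log2["lncRNA"][i_l]
        mu_m = 2.0 ** base_log2["mRNA"][i_m]
        v_l = 1.0 / mu_l + alpha
        v_m = 1.0 / mu_m + alpha
        c = sponge_coupling_weight(params.rho_sponge, v_l, v_m)
        a = latent[t]
        lnc_latent_log2[i_l] += -(c / LN2) * a
        mrna_latent_log2[i_m] += -(c / LN2) * a
        mir_latent_log2[mirs] += (MIRNA_LATENT_WEIGHT / LN2) * a
        triplets.append({
            "lncrna": lnc_ids[i_l],
            "mrna": mrna_ids[i_m],
            "mirnas": sorted(mir_ids[j] for j in mirs),
        })

    # ---- prognostic hubs load on a latent risk axis u
    hub_pool = trip_lnc if params.n_prognostic_hubs <= trip_lnc.size else np.arange(params.n_lncrna)
    hub_idx = rng.choice(hub_pool, size=params.n_prognostic_hubs, replace=False)
    u = rng.standard_normal(n)
    prognostic_hubs = []
    for i in hub_idx:
        mu_h = 2.0 ** base_log2["lncRNA"][i]
        v_h = 1.0 / mu_h + alpha
        c_u = HUB_LOADING_CORR * math.sqrt(v_h / (1.0 - HUB_LOADING_CORR**2))
        lnc_latent_log2[i] += (c_u / LN2) * u
        prognostic_hubs.append({"gene": lnc_ids[i], "beta": float(params.beta_hazard)})

    # ---- assemble per-sample log2 means and draw NB counts
    lib = rng.uniform(*params.lib_size_range, size=n)
    counts: dict[str, ExpressionMatrix] = {}
    latent_by_class = {"mRNA": mrna_latent_log2, "lncRNA": lnc_latent_log2,
                       "miRNA": mir_latent_log2}
    for cls, ids in ids_by_class.items():
        log2_mu = base_log2[cls][:, None] + latent_by_class[cls]
        log2_mu = log2_mu + np.where(is_high, de_effect[cls][:, None], 0.0)
        mu = (2.0 ** log2_mu) * lib[None, :]
        x = _nb_draw(rng, mu, alpha)
        counts[cls] = ExpressionMatrix(
            pd.DataFrame(x, index=pd.Index(ids, name="gene"), columns=sample_ids), cls
        )

    # ---- interaction tables: planted triplet edges plus background noise
    def _edge_table(target_ids: list[str], planted: set[tuple[str, str]]) -> pd.DataFrame:
        mask = rng.random((params.n_mirna, len(target_ids))) < params.background_edge_prob
        edges = {(mir_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(mask))}
        edges |= planted
        rows = sorted(edges)
        return pd.DataFrame(rows, columns=["miRNA_id", "target_id"])

    planted_mrna = {(m, t["mrna"]) for t in triplets for m in t["mirnas"]}
    planted_lnc = {(m, t["lncrna"]) for t in triplets for m in t["mirnas"]}
    interactions = {
        "mirna_mrna": _edge_table(mrna_ids, planted_mrna),
        "mirna_lncrna": _edge_table(lnc_ids, planted_lnc),
    }

    # ---- survival driven by the observed hub-expression axis
    clin = _simulate_clinical_covariates(rng, params.n_low, params.n_high, params.wbc_cutoff)
    hub_expr = np.log2(counts["lncRNA"].values.to_numpy()[hub_idx] / lib[None, :] + 1.0)
    z = (hub_expr - hub_expr.mean(axis=1, keepdims=True)) / np.maximum(
        hub_expr.std(axis=1, keepdims=True), 1e-12
    )
    risk_axis = z.mean(axis=0)
    sd = risk_axis.std()
    risk_axis = risk_axis / sd if sd > 0 else risk_axis
    os_tab = simulate_survival(risk_axis, params.beta_hazard, rng,
                               censor_frac=params.censor_frac)
    efs_tab = simulate_survival(risk_axis, params.beta_hazard, rng,
                                h0=1.5 * LN2 / MEDIAN_EVENT_YEARS,
                                censor_frac=params.censor_frac)
    clin["os_time"] = os_tab["time"].to_numpy()
    clin["os_event"] = os_tab["event"].to_numpy()
    clin["efs_time"] = np.minimum(efs_tab["time"].to_numpy(), clin["os_time"])
    clin["efs_event"] = np.where(efs_tab["time"].to_numpy() <= clin["os_time"],
                                 efs_tab["event"].to_numpy(), clin["os_event"])

    # ---- gene sets: background sets plus two seeded with triplet mRNAs
    gene_sets: dict[str, set[str]] = {}
    for k in range(20):
        size = int(rng.integers(10, 51))
        members = rng.choice(params.n_mrna, size=size, replace=False)
        gene_sets[f"SET{k + 1:02d}"] = {mrna_ids[j] for j in members}
    trip_mrna_ids = [t["mrna"] for t in triplets]
    for k in range(2):
        seed_n = max(len(trip_mrna_ids) // 2, 1)
        seeded = set(rng.choice(trip_mrna_ids, size=seed_n, replace=False))
        fill = rng.choice(params.n_mrna, size=15, replace=False)
        gene_sets[f"PLANTED_SET{k + 1}"] = seeded | {mrna_ids[j] for j in fill}

    truth = GroundTruth(
        de_genes=de_genes,
        triplets=triplets,
        prognostic_hubs=prognostic_hubs,
        lib_factors=pd.Series(lib, index=sample_ids),
    )
    return SyntheticCohort(
        expression=counts,
        interactions=interactions,
        clinical=clin,
        gene_sets=gene_sets,
        truth=truth,
        params=params,
    )


def truth_eval(inferred, truth) -> dict[str, float]:
    """Set-overlap precision/recall/F1; pairs are compared unordered.

    An empty truth set leaves recall (and F1) NaN rather than raising.
    """
    def _norm(items):
        out = set()
        for it in items:
            if isinstance(it, (tuple, list)) and len(it) == 2:
                out.add(tuple(sorted(it)))
            else:
                out.add(it)
        return out

    inf_set, tru_set = _norm(inferred), _norm(truth)
    tp = len(inf_set & tru_set)
    precision = tp / len(inf_set) if inf_set else float("nan")
    recall = tp / len(tru_set) if tru_set else float("nan")
    if precision != precision or recall != recall or (precision + recall) == 0:
        f1 = float("nan") if (recall != recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "n_inferred": len(inf_set), "n_truth": len(tru_set)}
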