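"""Causal-effect scoring of sponge lncRNAs on their paired mRNAs.

Under the ceRNA model the miRNAs shared by a sponge pair are the common
causes of both transcripts, so adjusting for them identifies the direct
lncRNA -> mRNA effect.  Each retained network edge is scored by the
signed Wald statistic of the lncRNA coefficient in the linear model

    z(mRNA) ~ z(lncRNA) + z(shared miRNA_1) + ... + z(shared miRNA_M)

on standardized log-expression, an unbounded signed effect scale.  Edge
strength is additionally tested with Fisher's asymptotic z-transform
p-value on the pair correlation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from spongecerna.config import RunConfig
from spongecerna.diffexpr import bh_adjust
from spongecerna.sponge import SpongeNetwork

COLLINEAR_COND = 1e8


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance input")
    return (x - x.mean()) / sd


def causal_score(
    lnc_expr: np.ndarray,
    mrna_expr: np.ndarray,
    shared_mirna_expr: np.ndarray | None = None,
) -> dict[str, float]:
    """Signed Wald statistic of the lncRNA effect after miRNA adjustment.

    ``shared_mirna_expr`` has one row per shared miRNA (may be None/empty).
    Near-collinear miRNA covariates (design condition number above 1e8)
    are dropped in decreasing-|correlation-with-lncRNA| order and the
    result flagged.  Returns score, effect_p, df and the flag.
    """
    y = _zscore(np.asarray(mrna_expr, dtype=float))
    x = _zscore(np.asarray(lnc_expr, dtype=float))
    n = y.size
    covars: list[np.ndarray] = []
    if shared_mirna_expr is not None and len(shared_mirna_expr) > 0:
        for row in np.atleast_2d(np.asarray(shared_mirna_expr, dtype=float)):
            sd = row.std(ddof=0)
            if sd > 0:
                covars.append((row - row.mean()) / sd)
    if n < len(covars) + 4:
        raise ValueError("too few samples for the adjustment set")

    dropped = 0
    while True:
        design = np.column_stack([np.ones(n), x, *covars])
        if covars and np.linalg.cond(design) > COLLINEAR_COND:
            # drop the miRNA most correlated with the lncRNA first
            cors = [abs(np.corrcoef(x, c)[0, 1]) for c in covars]
            covars.pop(int(np.argmax(cors)))
            dropped += 1
            continue
        break

    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - design.shape[1]
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = math.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-300))
    score = float(coef[1] / se)
    p = 2.0 * float(sps.t.sf(abs(score), df))
    return {"score": score, "effect_p": min(p, 1.0), "df": df,
            "dropped_covariates": dropped}


def fisher_cor_pvalue(r: float, n: int) -> float:
    """Fisher z-transform asymptotic two-sided p for a Pearson correlation.

    z = atanh(r) * sqrt(n - 3); p = 2 * (1 - Phi(|z|)).  |r| = 1 gives 0.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    z = math.atanh(r) * math.sqrt(n - 3)
    return 2.0 * float(sps.norm.sf(abs(z)))


def score_network(
    net: SpongeNetwork,
    logexpr_lnc: pd.DataFrame,
    logexpr_mrna: pd.DataFrame,
    logexpr_mirna: pd.DataFrame,
    samples: list[str],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every network edge; BH-adjust the regression p-values.

    Returns a CausalEdge table (lncrna, mrna, score, effect_p, effect_p_adj,
    fisher_p, positive, retained) sorted by edge.  ``retained`` applies the
    adjusted-p cutoff from the config.
    """
    config = config or RunConfig()
    n = len(samples)
    rows = []
    for row in net.edges.itertuples():
        lx = logexpr_lnc.loc[row.lncrna, samples].to_numpy(dtype=float)
        mx = logexpr_mrna.loc[row.mrna, samples].to_numpy(dtype=float)
        mirs = [m for m in str(row.shared_set).split(";") if m and m in logexpr_mirna.index]
        madj = logexpr_mirna.loc[mirs, samples].to_numpy(dtype=float) if mirs else None
        try:
            res = causal_score(lx, mx, madj)
        except ValueError:
            rows.append({"lncrna": row.lncrna, "mrna": row.mrna, "score": np.nan,
                         "effect_p": np.nan, "fisher_p": np.nan, "degenerate": True})
            continue
        r = float(np.corrcoef(lx, mx)[0, 1])
        rows.append({
            "lncrna": row.lncrna, "mrna": row.mrna,
            "score": res["score"], "effect_p": res["effect_p"],
            "fisher_p": fisher_cor_pvalue(max(min(r, 1.0), -1.0), n),
            "degenerate": False,
        })
    out = pd.DataFrame(rows, columns=["lncrna", "mrna", "score", "effect_p",
                                      "fisher_p", "degenerate"])
    adj = np.full(len(out), np.nan)
    ok = ~out["effect_p"].isna()
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(out.loc[ok, "effect_p"].to_numpy())
    out["effect_p_adj"] = adj
    out["positive"] = out["score"] > 0
    out["retained"] = (out["effect_p_adj"] < config.causal_adj_p).fillna(False)
    return out


def positive_fraction(edges: pd.DataFrame) -> dict[str, float]:
    """Count and fraction of edges with a positive causal score."""
    scores = edges["score"].dropna()
    if scores.empty:
        return {"n_positive": 0, "fraction": float("nan")}
    n_pos = int((scores > 0).sum())
    return {"n_positive": n_pos, "fraction": n_pos / len(scores)}
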