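"""Two-group negative-binomial differential expression.

A DESeq-style analysis implemented from first principles: median-of-ratios
size factors, gene-wise method-of-moments NB dispersion (variance
mu + alpha*mu^2, no shrinkage), a Wald test on the log2 fold change via
the delta method, and Benjamini-Hochberg adjustment within each RNA
class.  Genes are called up/down only when both the FDR and the absolute
log2 fold-change thresholds are met.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from spongecerna.config import RunConfig
from spongecerna.io import ExpressionMatrix

PSEUDO_MEAN = 0.5  # epsilon added to group means before taking the fold change


def size_factors(counts: ExpressionMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample).

    Each sample's factor is the median, over genes with a positive
    geometric mean, of that sample's count divided by the gene's
    geometric mean across samples.  ``pseudo_reference=True`` adds one
    pseudocount when no gene is positive in every sample.
    """
    x = counts.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if pseudo_reference:
        x = x + 1.0
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "re-run with pseudo_reference=True"
        )
    ref = np.exp(np.mean(np.log(x[all_positive]), axis=1))
    ratios = x[all_positive] / ref[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor; matrix too sparse")
    return pd.Series(factors, index=counts.samples, name="size_factor")


def _mom_dispersion(q: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene."""
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in group_idx:
        n_k = idx.size
        mu_k = q[:, idx].mean(axis=1)
        s2_k = q[:, idx].var(axis=1, ddof=1)
        num += (n_k - 1) * (s2_k - mu_k)
        den += (n_k - 1) * mu_k**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    # negative MoM estimates mean under-Poisson sampling noise: treat as Poisson
    alpha = np.where(alpha < 0, 0.0, np.maximum(alpha, 1e-8))
    alpha[den == 0] = 0.0
    return alpha


def nb_wald_test(
    counts: ExpressionMatrix,
    groups: pd.Series,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of high- vs low-group expression.

    ``groups`` maps sample IDs to "low"/"high"; both groups need at least
    two samples.  Returns a table with base_mean, log2fc (high vs low),
    se_lfc, wald_p and BH-adjusted fdr.  Genes with zero counts in both
    groups get p = 1, log2fc = 0 and ``all_zero=True``.
    """
    groups = pd.Series(groups)
    labels = set(groups.unique())
    if labels != {"low", "high"}:
        raise ValueError(f"groups must be exactly {{'low','high'}}, got {sorted(labels)}")
    if factors is None:
        factors = size_factors(counts)
    samples = [s for s in counts.samples if s in groups.index]
    x = counts.values[samples].to_numpy(dtype=float)
    f = factors.loc[samples].to_numpy(dtype=float)
    q = x / f[None, :]
    g = groups.loc[samples].to_numpy()
    idx_low = np.flatnonzero(g == "low")
    idx_high = np.flatnonzero(g == "high")
    if idx_low.size < 2 or idx_high.size < 2:
        raise ValueError("each group needs at least two samples")

    mu_low = q[:, idx_low].mean(axis=1)
    mu_high = q[:, idx_high].mean(axis=1)
    alpha = _mom_dispersion(q, [idx_low, idx_high])

    ml = mu_low + PSEUDO_MEAN
    mh = mu_high + PSEUDO_MEAN
    log2fc = np.log2(mh / ml)
    # delta method on log2 of the shifted group means
    var_low = (mu_low + alpha * mu_low**2) / idx_low.size
    var_high = (mu_high + alpha * mu_high**2) / idx_high.size
    se = np.sqrt(var_low / ml**2 + var_high / mh**2) / np.log(2.0)

    all_zero = (mu_low == 0) & (mu_high == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    wald_p = 2.0 * sps.norm.sf(np.abs(z))
    wald_p = np.where(all_zero | (se == 0), 1.0, wald_p)
    log2fc = np.where(all_zero, 0.0, log2fc)

    out = pd.DataFrame(
        {
            "gene": counts.genes,
            "rna_class": counts.rna_class,
            "base_mean": q.mean(axis=1),
            "log2fc": log2fc,
            "se_lfc": se,
            "wald_p": np.clip(wald_p, 0.0, 1.0),
            "all_zero": all_zero,
        }
    )
    out["fdr"] = bh_adjust(out["wald_p"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_de(results: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Apply the FDR and |log2FC| thresholds, adding direction and -log10 FDR.

    direction is "up" iff fdr < de_fdr and log2fc > de_lfc, "down" iff
    fdr < de_fdr and log2fc < -de_lfc, "ns" otherwise.
    """
    config = config or RunConfig()
    out = results.copy()
    sig = out["fdr"] < config.de_fdr
    out["direction"] = np.select(
        [sig & (out["log2fc"] > config.de_lfc), sig & (out["log2fc"] < -config.de_lfc)],
        ["up", "down"],
        default="ns",
    )
    with np.errstate(divide="ignore"):
        out["neg_log10_fdr"] = -np.log10(np.maximum(out["fdr"], 1e-300))
    return out


def de_gene_sets(called: pd.DataFrame) -> dict[str, set[str]]:
    """Up-/down-regulated gene sets from a ``call_de`` table."""
    return {
        "up": set(called.loc[called["direction"] == "up", "gene"]),
        "down": set(called.loc[called["direction"] == "down", "gene"]),
    }
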