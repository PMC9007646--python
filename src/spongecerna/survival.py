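"""Survival screening of differential hub lncRNAs.

Kaplan-Meier product-limit estimation with Greenwood standard errors,
the two-group log-rank test, Cox proportional hazards by Newton-Raphson
on the Breslow partial likelihood, and the hub screen itself: each hub
is median-dichotomized, compared by log-rank, and its hazard ratio taken
from a univariate Cox fit on the stratum indicator.  A hub passes when
the log-rank p and hazard-ratio thresholds are both met.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from spongecerna.causal import fisher_cor_pvalue
from spongecerna.config import RunConfig

MAX_ABS_BETA = 20.0  # divergence guard for monotone partial likelihoods


def _as_arrays(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if (time < 0).any():
        raise ValueError("times must be nonnegative")
    if np.isnan(time).any():
        raise ValueError("missing times are not allowed")
    return time, event


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival curve over the distinct event times.

    Returns columns time, n_risk, n_event, survival and greenwood_se;
    S(0) = 1 is included as the first row.  With no events the curve is
    identically 1 and ``all_censored`` is set in ``DataFrame.attrs``.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    time, event = _as_arrays(records)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = [{"time": 0.0, "n_risk": time.size, "n_event": 0,
             "survival": 1.0, "greenwood_se": 0.0}]
    s = 1.0
    gw = 0.0
    for t in np.unique(time[event == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
        se = s * math.sqrt(gw) if s > 0 else 0.0
        rows.append({"time": float(t), "n_risk": n_risk, "n_event": d,
                     "survival": s, "greenwood_se": se})
    out = pd.DataFrame(rows)
    out.attrs["all_censored"] = bool(event.sum() == 0)
    return out


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict[str, float]:
    """Two-group log-rank test (chi-square with one degree of freedom).

    No events in either group gives chi2 = 0, p = 1 by convention.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = _as_arrays(records_a)
    tb, eb = _as_arrays(records_b)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if times.size == 0:
        return {"chi2": 0.0, "p": 1.0}
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var <= 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = o_minus_e**2 / var
    return {"chi2": float(chi2), "p": float(sps.chi2.sf(chi2, 1))}


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Cox proportional hazards via Newton-Raphson, Breslow tie handling.

    ``records`` needs columns time, event and the covariates.  Returns
    beta, se, hr (per covariate, as Series), per-sample risk scores
    exp(x'beta), and a ``diverged`` flag set when a monotone likelihood
    pushes |beta| past 20.
    """
    time, event = _as_arrays(records)
    if event.sum() == 0:
        raise ValueError("need at least one event")
    x = records[covariates].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    if (x.std(axis=0) == 0).any():
        bad = [c for c, s in zip(covariates, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s), non-identifiable: {bad}")

    center = x.mean(axis=0)
    xc = x - center
    p = xc.shape[1]
    beta = np.zeros(p)
    diverged = False

    order = np.argsort(-time, kind="stable")  # decreasing time for cumulative sums
    t_sorted = time[order]
    e_sorted = event[order]
    x_sorted = xc[order]
    event_times = np.unique(time[event == 1])

    for _ in range(max_iter):
        eta = x_sorted @ beta
        w = np.exp(np.clip(eta, -500, 500))
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * x_sorted, axis=0)
        s2 = np.cumsum(w[:, None, None] * (x_sorted[:, :, None] * x_sorted[:, None, :]), axis=0)
        score = np.zeros(p)
        info = np.zeros((p, p))
        for t in event_times:
            at_risk = np.searchsorted(-t_sorted, -t, side="right") - 1
            d_mask = (t_sorted == t) & (e_sorted == 1)
            d = int(d_mask.sum())
            xbar = s1[at_risk] / s0[at_risk]
            score += x_sorted[d_mask].sum(axis=0) - d * xbar
            info += d * (s2[at_risk] / s0[at_risk] - np.outer(xbar, xbar))
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            diverged = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) >= MAX_ABS_BETA:
            beta = np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA)
            diverged = True
            break

    eta = xc @ beta
    se = np.sqrt(np.maximum(np.diag(np.linalg.pinv(info)), 0.0))
    return {
        "beta": pd.Series(beta, index=covariates),
        "se": pd.Series(se, index=covariates),
        "hr": pd.Series(np.exp(beta), index=covariates),
        "risk_scores": pd.Series(np.exp(eta), index=records.index),
        "diverged": diverged,
    }


def screen_hubs(
    expr: pd.DataFrame,
    hubs: list[str],
    records: pd.DataFrame,
    config: RunConfig | None = None,
    split: str = "median",
) -> pd.DataFrame:
    """Per-hub survival screen on median-dichotomized expression.

    ``expr`` is gene x sample log-expression; ``records`` is indexed by
    sample with columns time and event.  Each hub's samples are split at
    the median (or lower/upper quartile with ``split="quartile"``), the
    strata compared by log-rank, and the hazard ratio (high vs low
    stratum) taken from a univariate Cox fit on the stratum indicator.
    Hubs whose split leaves an empty stratum are skipped with a flag.
    """
    config = config or RunConfig()
    samples = [s for s in records.index if s in expr.columns]
    rec = records.loc[samples]
    rows = []
    for gene in hubs:
        if gene not in expr.index:
            raise KeyError(f"hub {gene!r} not in expression matrix")
        vals = expr.loc[gene, samples].to_numpy(dtype=float)
        if split == "median":
            cut = float(np.median(vals))
        elif split == "quartile":
            cut = float(np.quantile(vals, 0.75))
        else:
            raise ValueError(f"unknown split rule {split!r}")
        high = vals > cut
        if high.all() or not high.any():
            rows.append({"gene": gene, "logrank_chi2": np.nan, "logrank_p": np.nan,
                         "hazard_ratio": np.nan, "significant": False, "skipped": True})
            continue
        lr = logrank_test(rec[~high], rec[high])
        hr = np.nan
        try:
            fit = cox_fit(rec.assign(stratum=high.astype(float)), ["stratum"])
            hr = float(fit["hr"]["stratum"])
        except ValueError:
            pass
        rows.append({
            "gene": gene,
            "logrank_chi2": lr["chi2"],
            "logrank_p": lr["p"],
            "hazard_ratio": hr,
            "significant": bool(
                lr["p"] < config.survival_p and not np.isnan(hr) and hr > config.survival_hr
            ),
            "skipped": False,
        })
    out = pd.DataFrame(rows, columns=["gene", "logrank_chi2", "logrank_p",
                                      "hazard_ratio", "significant", "skipped"])
    out = out.sort_values("logrank_p", na_position="last").reset_index(drop=True)
    tested = out[~out["skipped"]]
    out.attrs["passing_fraction"] = (
        float(tested["significant"].mean()) if len(tested) else float("nan")
    )
    return out


def hub_mrna_correlation(
    expr_lnc: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    edges: pd.DataFrame,
    samples: list[str],
    r_threshold: float = 0.55,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Pearson r with Fisher's asymptotic p per retained causal edge.

    Flags pairs with r strictly above the threshold and p below it.
    Zero-variance genes give an NA row.
    """
    n = len(samples)
    rows = []
    for row in edges.itertuples():
        lx = expr_lnc.loc[row.lncrna, samples].to_numpy(dtype=float)
        mx = expr_mrna.loc[row.mrna, samples].to_numpy(dtype=float)
        if lx.std() == 0 or mx.std() == 0:
            rows.append({"lncrna": row.lncrna, "mrna": row.mrna,
                         "pearson_r": np.nan, "fisher_p": np.nan, "flagged": False})
            continue
        r = float(np.clip(np.corrcoef(lx, mx)[0, 1], -1.0, 1.0))
        p = fisher_cor_pvalue(r, n)
        rows.append({"lncrna": row.lncrna, "mrna": row.mrna, "pearson_r": r,
                     "fisher_p": p, "flagged": bool(r > r_threshold and p < p_threshold)})
    return pd.DataFrame(rows, columns=["lncrna", "mrna", "pearson_r",
                                       "fisher_p", "flagged"])
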