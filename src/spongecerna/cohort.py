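"""Cohort preprocessing and baseline-characteristics statistics.

Covers: collapsing replicated gene IDs by averaging, applying the
sample exclusion criteria (complete expression data, WBC, fusion flags
and overall-survival follow-up required), WBC-based risk stratification
(count >= cutoff is high risk, ties inclusive), and a baseline
characteristics table comparing the two risk groups — Welch's t for
continuous variables and the Yates-corrected chi-square for categorical
ones, with Fisher's exact test available as an alternative.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from spongecerna.io import ExpressionMatrix

FUSION_COLUMNS = ("bcr_abl1", "etv6_runx1", "tcf3_hlf", "tcf3_pbx1", "trisomy_4_10")


def collapse_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace rows sharing a gene ID by their arithmetic mean per sample.

    Output gene order is first occurrence.
    """
    if not m.values.index.duplicated().any():
        return ExpressionMatrix(m.values.copy(), m.rna_class)
    order = m.values.index.drop_duplicates()
    collapsed = m.values.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(collapsed, m.rna_class)


def apply_exclusions(
    clin: pd.DataFrame, available: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep samples present in every assay with complete WBC, fusion and OS data.

    ``available`` maps an assay name (e.g. "mRNA", "miRNA") to the sample IDs
    it covers.  Returns the retained table and per-criterion exclusion counts
    (a sample failing several criteria is counted under each).
    """
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=clin.index)
    for assay, ids in available.items():
        present = clin["sample_id"].isin(set(ids))
        counts[f"no_{assay}_data"] = int((~present).sum())
        keep &= present
    for crit, cols in [
        ("missing_wbc", ["wbc"]),
        ("missing_fusion", [c for c in FUSION_COLUMNS if c in clin.columns]),
        ("missing_os", ["os_time", "os_event"]),
    ]:
        cols = [c for c in cols if c in clin.columns]
        # a criterion whose columns are absent from the table cannot exclude
        ok = clin[cols].notna().all(axis=1) if cols else pd.Series(True, index=clin.index)
        counts[crit] = int((~ok).sum())
        keep &= ok
    return clin[keep].reset_index(drop=True), counts


def stratify_risk(clin: pd.DataFrame, cutoff: float = 50.0) -> pd.DataFrame:
    """Assign risk_group = high where WBC >= cutoff, low otherwise."""
    if "wbc" not in clin.columns or clin["wbc"].isna().any():
        raise ValueError("WBC must be present for all samples; run apply_exclusions first")
    out = clin.copy()
    out["risk_group"] = np.where(out["wbc"] >= cutoff, "high", "low")
    return out


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict[str, float]:
    """Welch's unequal-variance t-test from per-group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0.0:
        # degenerate: no sampling variance at all
        p = 1.0 if mean1 == mean2 else 0.0
        return {"t": 0.0 if mean1 == mean2 else math.inf, "df": float(n1 + n2 - 2), "p": p}
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return {"t": float(t), "df": float(df), "p": min(p, 1.0)}


def chi2_yates(table2x2) -> dict[str, float]:
    """Yates-continuity-corrected chi-square on a 2x2 table (df = 1).

    A zero row or column margin gives p = 1 by convention.
    """
    tab = np.asarray(table2x2, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return {"chi2": 0.0, "p": 1.0}
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=True)
    return {"chi2": float(chi2), "p": float(p)}


def fisher_exact(table2x2) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable as observed)."""
    tab = np.asarray(table2x2, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(tab, alternative="two-sided")[1])


CONTINUOUS_COLUMNS = ("age", "wbc", "os_time", "efs_time")


def cohort_summary(
    clin: pd.DataFrame, categorical_test: str = "yates"
) -> pd.DataFrame:
    """Baseline-characteristics table comparing the two risk groups.

    Continuous rows report mean (SD), median [min, max] and missing counts
    per group with a Welch p from the raw values; categorical rows report
    counts (%) with a Yates chi-square p (or Fisher exact when
    ``categorical_test="fisher"``).  With fewer than two groups every p is NA.
    """
    if "risk_group" not in clin.columns:
        raise ValueError("clinical table must be stratified (risk_group column)")
    groups = sorted(clin["risk_group"].unique())
    two = len(groups) == 2
    glo = clin[clin["risk_group"] == "low"]
    ghi = clin[clin["risk_group"] == "high"]
    rows = []

    def _cont_stats(x: pd.Series) -> dict:
        v = x.dropna().to_numpy(dtype=float)
        if v.size == 0:
            return {"mean": np.nan, "sd": np.nan, "median": np.nan, "min": np.nan,
                    "max": np.nan, "n": 0, "missing": int(x.isna().sum())}
        return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)), "min": float(v.min()), "max": float(v.max()),
                "n": int(v.size), "missing": int(x.isna().sum())}

    for col in CONTINUOUS_COLUMNS:
        if col not in clin.columns:
            continue
        lo, hi = _cont_stats(glo[col]), _cont_stats(ghi[col])
        p = np.nan
        if two and lo["n"] >= 2 and hi["n"] >= 2:
            p = welch_t_from_summary(lo["mean"], lo["sd"], lo["n"],
                                     hi["mean"], hi["sd"], hi["n"])["p"]
        rows.append({"variable": col, "kind": "continuous",
                     "low_mean": lo["mean"], "low_sd": lo["sd"],
                     "high_mean": hi["mean"], "high_sd": hi["sd"],
                     "low_median": lo["median"], "high_median": hi["median"],
                     "low_missing": lo["missing"], "high_missing": hi["missing"],
                     "p": p})

    cat_cols = [("gender", lambda s: s == "male")]
    cat_cols += [(c, lambda s: s.astype(bool)) for c in FUSION_COLUMNS if c in clin.columns]
    for col, pos in cat_cols:
        if col not in clin.columns:
            continue
        lo_yes = int(pos(glo[col].dropna()).sum())
        lo_no = int(glo[col].notna().sum()) - lo_yes
        hi_yes = int(pos(ghi[col].dropna()).sum())
        hi_no = int(ghi[col].notna().sum()) - hi_yes
        p = np.nan
        if two:
            tab = [[lo_yes, hi_yes], [lo_no, hi_no]]
            p = fisher_exact(tab) if categorical_test == "fisher" else chi2_yates(tab)["p"]
        rows.append({"variable": col, "kind": "categorical",
                     "low_yes": lo_yes, "low_no": lo_no,
                     "high_yes": hi_yes, "high_no": hi_no,
                     "low_pct": 100.0 * lo_yes / max(lo_yes + lo_no, 1),
                     "high_pct": 100.0 * hi_yes / max(hi_yes + hi_no, 1),
                     "p": p})

    out = pd.DataFrame(rows)
    out.attrs["n_low"] = len(glo)
    out.attrs["n_high"] = len(ghi)
    out.attrs["n_total"] = len(clin)
    return out
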