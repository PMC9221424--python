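"""Rank-based cohort statistics.

Two nonparametric primitives drive the whole statistical layer:

* Spearman's rank correlation for continuous and ordinal clinical variables
  against analyte rates, with an exact permutation p-value at small n and a
  t-approximation otherwise;
* the two-sample Wilcoxon rank-sum (Mann-Whitney U) test for categorical
  variables and the tumor-vs-donor comparison, with the exact null
  distribution at small combined n (no ties) and a tie- and
  continuity-corrected normal approximation otherwise.

Significance is declared at p <= 0.05 on raw p-values (no multiple-testing
correction by default; Benjamini-Hochberg is available as an option).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: Declared orderings for ordinal clinical variables; Spearman on ordinals
#: requires a fixed order.
ORDINAL_ENCODINGS: dict[str, dict] = {
    "smoking": {"never": 0, "former": 1, "current": 2},
    "pt_stage": {"pTa": 0, "pTis": 0, "pT1": 1, "pT2": 2, "pT3": 3, "pT4": 4},
    "grade": {"low": 0, "high": 1},
}


def encode_ordinal(values: pd.Series, name: str) -> pd.Series:
    """Map an ordinal variable to its declared integer encoding; numeric
    ordinals (CCI score, ASA) pass through unchanged."""
    if name in ORDINAL_ENCODINGS:
        return values.map(ORDINAL_ENCODINGS[name]).astype(float)
    return pd.to_numeric(values)


# --------------------------------------------------------------------------
# Spearman rank correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "permutation" | "t_approx"

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


def spearman_rho(x, y, exact_n_max: int = 9) -> SpearmanResult | None:
    """Spearman correlation with midrank ties.

    rho is the Pearson correlation of average ranks. The two-sided p-value is
    exact by enumeration over all n! rank permutations for n <= ``exact_n_max``
    and otherwise uses the t-approximation with n-2 degrees of freedom.
    Returns ``None`` for a constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_n_max:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]                      # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        num = ryc @ rxc
        denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((ryc**2).sum(axis=1))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, n=n, method="permutation")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho=rho, p=0.0, n=n, method="t_approx")
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho=rho, p=float(min(1.0, p)), n=n, method="t_approx")


# --------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney U
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    u: float       # U statistic of the first sample
    z: float       # signed standardized statistic (positive: a tends larger)
    p: float
    n1: int
    n2: int
    method: str    # "exact" | "normal_approx"

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


def _u_null_pmf(m: int, n: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic over 0..m*n.

    Counting recurrence on the largest remaining rank: with i "a" values and
    j "b" values left, count(i, j, u) = count(i-1, j, u-j) + count(i, j-1, u)
    (the top rank is an "a", contributing j exceeded pairs, or a "b")."""
    size = m * n + 1
    # dp[j] holds count(i, j, .) for the current i
    dp = [np.zeros(size) for _ in range(n + 1)]
    for j in range(n + 1):
        dp[j][0] = 1.0  # i = 0: only u = 0
    for i in range(1, m + 1):
        prev = dp
        dp = [np.zeros(size) for _ in range(n + 1)]
        dp[0][0] = 1.0  # j = 0: only u = 0
        for j in range(1, n + 1):
            shifted = np.zeros(size)
            shifted[j:] = prev[j][: size - j]
            dp[j] = shifted + dp[j - 1]
    counts = dp[n]
    return counts / counts.sum()


def rank_sum_test(a, b, exact_total_max: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    U is the Mann-Whitney statistic of ``a`` (number of (a, b) pairs with
    a > b, counting ties half). The p-value is exact, from the full null
    distribution of U, when the combined sample size is at most
    ``exact_total_max`` and there are no ties; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction is
    used. ``z`` is reported signed, positive when ``a`` tends larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = float(ranks[:m].sum())
    u = r_a - m * (m + 1) / 2.0
    mu = m * n / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    # signed z with tie and continuity corrections (also reported in exact mode)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = m * n / 12.0 * ((m + n + 1) - tie_term / ((m + n) * (m + n - 1)))
    sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
    if sigma > 0:
        cc = 0.5 if u != mu else 0.0
        z = (u - mu - math.copysign(cc, u - mu)) / sigma
    else:
        z = 0.0

    if not has_ties and (m + n) <= exact_total_max:
        pmf = _u_null_pmf(m, n)
        u_int = int(round(u))
        lo, hi = min(u_int, m * n - u_int), max(u_int, m * n - u_int)
        p = float(pmf[: lo + 1].sum() + pmf[hi:].sum())
        p = min(1.0, p)
        return RankSumResult(u=u, z=z, p=p, n1=m, n2=n, method="exact")
    p = float(min(1.0, 2 * sps.norm.sf(abs(z)))) if sigma > 0 else 1.0
    return RankSumResult(u=u, z=z, p=p, n1=m, n2=n, method="normal_approx")


# --------------------------------------------------------------------------
# Cohort comparison and clinical correlation
# --------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(0, 1)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def compare_cohorts(utuc: pd.DataFrame, nd: pd.DataFrame,
                    categories: list[str] | None = None,
                    bh_correction: bool = False) -> pd.DataFrame:
    """Per-category rank-sum comparison of two cohorts' events/mL tables.

    Inputs are per-sample rate tables (one column per category plus the
    totals, as produced by :func:`liqbio.enumeration.rates_table`). One test
    is run per category and total; results are ordered by ascending p-value,
    ties broken by category name.
    """
    if len(utuc) == 0 or len(nd) == 0:
        raise ValueError("both cohorts must be nonempty")
    if categories is None:
        skip = {"sample_id", "cohort", "volume_ml"}
        categories = [c for c in utuc.columns if c not in skip]
    rows = []
    for cat in categories:
        res = rank_sum_test(utuc[cat].to_numpy(), nd[cat].to_numpy())
        rows.append({
            "category": cat, "u": res.u, "z": res.z, "p": res.p,
            "method": res.method, "significant": res.significant,
            "utuc_median": float(np.median(utuc[cat])),
            "nd_median": float(np.median(nd[cat])),
        })
    out = pd.DataFrame(rows)
    if bh_correction:
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= ALPHA
    return out.sort_values(["p", "category"], kind="mergesort").reset_index(drop=True)


def correlate_clinical(analytes: pd.DataFrame, clinical: pd.DataFrame,
                       variable_types: dict[str, str],
                       min_group: int = 4,
                       bh_correction: bool = False) -> pd.DataFrame:
    """Clinical-variable vs analyte association with type dispatch.

    Continuous and ordinal variables are tested with Spearman's rank
    correlation; binary/categorical variables with the rank-sum test between
    the two groups. Binary results where either group has fewer than
    ``min_group`` patients are computed but flagged ``suppressed`` (the
    reporting rule); multi-level nominal variables are expanded one-vs-rest.
    Both tables must carry ``sample_id`` keys.
    """
    merged = clinical.merge(analytes, on="sample_id", suffixes=("", "_rate"))
    skip = {"sample_id", "cohort", "volume_ml"}
    analyte_cols = [c for c in analytes.columns if c not in skip]
    rows = []
    for var, vtype in variable_types.items():
        if var not in merged.columns:
            continue
        if vtype in ("continuous", "ordinal"):
            x = encode_ordinal(merged[var], var) if vtype == "ordinal" \
                else pd.to_numeric(merged[var])
            for a in analyte_cols:
                res = spearman_rho(x.to_numpy(), merged[a].to_numpy())
                if res is None:
                    continue
                rows.append({
                    "variable": var, "analyte": a, "method": "spearman",
                    "statistic": res.rho, "p": res.p,
                    "significant": res.significant, "suppressed": False,
                })
        elif vtype in ("binary", "nominal"):
            levels = sorted(merged[var].dropna().unique(), key=str)
            pairs = [(levels[1], None)] if (vtype == "binary" and len(levels) == 2) \
                else [(lv, None) for lv in levels]
            for lv, _ in pairs:
                in_grp = merged[var] == lv
                g1, g0 = merged[in_grp], merged[~in_grp]
                if len(g1) == 0 or len(g0) == 0:
                    continue
                suppressed = min(len(g1), len(g0)) < min_group
                for a in analyte_cols:
                    if np.ptp(merged[a].to_numpy()) == 0:
                        continue
                    res = rank_sum_test(g1[a].to_numpy(), g0[a].to_numpy())
                    label = var if vtype == "binary" else f"{var}={lv}"
                    rows.append({
                        "variable": label, "analyte": a, "method": "rank_sum",
                        "statistic": res.z, "p": res.p,
                        "significant": res.significant, "suppressed": suppressed,
                    })
        else:
            raise ValueError(f"unknown variable type {vtype!r} for {var!r}")
    out = pd.DataFrame(
        rows, columns=["variable", "analyte", "method", "statistic", "p",
                       "significant", "suppressed"])
    if bh_correction and len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= ALPHA
    return out.sort_values(["p", "variable", "analyte"],
                           kind="mergesort").reset_index(drop=True)
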