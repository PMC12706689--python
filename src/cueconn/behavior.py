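"""Nonparametric behavioral battery, implemented from the defining formulas.

Covers the statistics applied to the odor-naming trial tables: Pearson
chi-square test of independence (no continuity correction), Mann-Whitney U
(midranks, tie-corrected variance, continuity correction, exact enumeration
for small samples), Kruskal-Wallis H with tie correction, Dunn's post hoc
test with Bonferroni adjustment, and Spearman / Kendall tau-b rank
correlations with tie-corrected inference.  Conventions are fixed and
tested so results are reproducible to the digit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult", "chi_square_independence", "mann_whitney_u",
    "kruskal_wallis", "dunn_posthoc", "rank_correlations", "run_battery",
]


@dataclass
class TestResult:
    """One statistical test outcome."""

    name: str
    statistic: float
    pvalue: float
    df: float | None = None
    n: int | None = None
    direction: float | None = None   # signed effect where defined
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError("p-value outside [0, 1]")

    def as_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.pvalue,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``stat = sum (O - E)^2 / E`` with ``E = row_total * col_total / N``,
    df = (r-1)(c-1), upper-tail chi-square p-value.  No continuity
    correction.  Zero row or column totals are an error; expected counts
    below 5 warn.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rtot = obs.sum(axis=1)
    ctot = obs.sum(axis=0)
    if np.any(rtot == 0) or np.any(ctot == 0):
        raise ValueError("zero row or column total: test undefined")
    N = obs.sum()
    expected = np.outer(rtot, ctot) / N
    if np.any(expected < 5):
        import warnings

        warnings.warn("expected cell count below 5; chi-square approximation "
                      "may be poor", stacklevel=2)
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return TestResult("chi_square_independence", stat, p, df=df, n=int(N))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample from midrank sums."""
    n1 = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    Ties receive midranks.  When ``n1 + n2 <= exact_max_n`` the two-sided
    p-value is computed by exact enumeration of all label assignments
    (``P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|)``); otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if N <= exact_max_n:
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        dev_obs = abs(u - mu)
        count = 0
        total = 0
        idx = range(N)
        for subset in itertools.combinations(idx, n1):
            r1 = ranks[list(subset)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu - np.sign(u - mu) * 0.5) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult("mann_whitney_u", u, min(p, 1.0), n=N,
                      direction=float(np.sign(u - mu)),
                      extra={"n1": n1, "n2": n2})


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def _kw_parts(groups: list[np.ndarray]):
    sizes = [g.size for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    allv = np.concatenate(groups)
    N = allv.size
    ranks = stats.rankdata(allv)
    rank_groups = []
    pos = 0
    for s in sizes:
        rank_groups.append(ranks[pos: pos + s])
        pos += s
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum())
    return rank_groups, sizes, N, tie_term


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    ``H = (12 / (N (N+1))) sum R_j^2 / n_j - 3 (N+1)``, divided by
    ``1 - sum(t^3 - t) / (N^3 - N)``.  All-identical data returns H = 0
    (degenerate tie correction, by convention).  p is upper-tail
    chi-square with k-1 df.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rank_groups, sizes, N, tie_term = _kw_parts(groups)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    h = 12.0 / (N * (N + 1)) * sum(
        rg.sum() ** 2 / s for rg, s in zip(rank_groups, sizes)
    ) - 3.0 * (N + 1)
    correction = 1.0 - tie_term / (N ** 3 - N)
    if correction <= 0:
        h = 0.0   # all observations identical
    else:
        h = h / correction
    h = max(h, 0.0)
    df = len(groups) - 1
    return TestResult("kruskal_wallis", float(h),
                      float(stats.chi2.sf(h, df)), df=df, n=N)


def dunn_posthoc(groups, adjust: str = "bonferroni",
                 labels: list[str] | None = None) -> list[TestResult]:
    """Dunn's pairwise post hoc z tests after Kruskal-Wallis.

    ``z = (mean rank_i - mean rank_j) / SE`` with the pooled tie-corrected
    variance ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)``.
    Two-sided p-values are multiplied by the number of comparisons
    (Bonferroni), capped at 1.
    """
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is provided")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError(
            "Dunn's test needs >= 3 groups; for two groups use mann_whitney_u"
        )
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    rank_groups, sizes, N, tie_term = _kw_parts(groups)
    mean_ranks = [rg.mean() for rg in rank_groups]
    pooled = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    m = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(pooled * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        out.append(TestResult(
            f"dunn[{labels[i]} vs {labels[j]}]", float(z), float(p),
            n=sizes[i] + sizes[j], direction=float(np.sign(z)),
            extra={"comparisons": m},
        ))
    return out


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------

def rank_correlations(a, b) -> tuple[TestResult, TestResult]:
    """Spearman rho and Kendall tau-b between two equal-length sequences.

    rho is the Pearson correlation of midranks with a two-tailed t
    approximation; tau-b counts concordant/discordant pairs with the
    standard tie terms and uses the tie-corrected normal approximation.
    Constant inputs are an error (correlation undefined).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: rank correlation undefined")

    ra, rb = stats.rankdata(a), stats.rankdata(b)
    ra_c, rb_c = ra - ra.mean(), rb - rb.mean()
    rho = float((ra_c @ rb_c) / np.sqrt((ra_c @ ra_c) * (rb_c @ rb_c)))
    if abs(rho) >= 1.0:
        p_rho = 0.0
    else:
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p_rho = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    spearman = TestResult("spearman_rho", rho, p_rho, df=n - 2, n=n,
                          direction=float(np.sign(rho)))

    # tau-b: vectorized pairwise concordance counts
    sa = np.sign(a[:, None] - a[None, :]).astype(np.int8)
    sb = np.sign(b[:, None] - b[None, :]).astype(np.int8)
    prod = sa.astype(np.int32) * sb
    iu = np.triu_indices(n, k=1)
    s = float(prod[iu].sum())               # concordant - discordant
    n0 = n * (n - 1) / 2.0
    _, ta = np.unique(a, return_counts=True)
    _, tb = np.unique(b, return_counts=True)
    n1 = float((ta * (ta - 1) / 2.0).sum())
    n2 = float((tb * (tb - 1) / 2.0).sum())
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom
    # tie-corrected variance of S (Kendall 1970)
    vt = float((ta * (ta - 1) * (2 * ta + 5)).sum())
    vu = float((tb * (tb - 1) * (2 * tb + 5)).sum())
    v0 = n * (n - 1) * (2 * n + 5)
    v1 = float((ta * (ta - 1)).sum()) * float((tb * (tb - 1)).sum()) / (
        2.0 * n * (n - 1)
    )
    v2 = (
        float((ta * (ta - 1) * (ta - 2)).sum())
        * float((tb * (tb - 1) * (tb - 2)).sum())
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        p_tau = 1.0
    else:
        z = s / np.sqrt(var_s)
        p_tau = float(2.0 * stats.norm.sf(abs(z)))
    kendall = TestResult("kendall_tau_b", float(tau), p_tau, n=n,
                         direction=float(np.sign(tau)))
    return spearman, kendall


# ---------------------------------------------------------------------------
# full battery over a trial table
# ---------------------------------------------------------------------------

def run_battery(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the behavioral battery on a trial table.

    Sequence: chi-square (cue x response category), Mann-Whitney on RT by
    cue, Kruskal-Wallis (+ Dunn-Bonferroni) of familiarity / liking / TON
    across response categories, and Spearman / tau-b correlations of
    familiarity and liking with RT and of TON with response category.
    Mixed-model estimates (participant and odor random effects) are out of
    scope for this battery and would slot in after the chi-square stage.

    Returns a tidy results table (test, statistic, df, p, n).
    """
    results: list[TestResult] = []

    table = pd.crosstab(trials["cue_type"], trials["response_category"])
    results.append(chi_square_independence(table.to_numpy()))

    rt_cue = {c: g["rt"].dropna().to_numpy()
              for c, g in trials.groupby("cue_type")}
    if len(rt_cue) == 2:
        keys = sorted(rt_cue)
        r = mann_whitney_u(rt_cue[keys[0]], rt_cue[keys[1]])
        r.name = f"mann_whitney_rt[{keys[0]} vs {keys[1]}]"
        results.append(r)

    cats = sorted(trials["response_category"].unique())
    for rating in ("familiarity", "liking", "ton"):
        groups = [trials.loc[trials["response_category"] == c, rating].to_numpy()
                  for c in cats]
        if len(groups) >= 2 and all(g.size for g in groups):
            r = kruskal_wallis(groups)
            r.name = f"kruskal_wallis_{rating}_by_category"
            results.append(r)
            if len(groups) >= 3:
                results.extend(dunn_posthoc(
                    groups, labels=[f"cat{c}" for c in cats]))

    answered = trials.dropna(subset=["rt"])
    for rating in ("familiarity", "liking"):
        try:
            sp, kd = rank_correlations(answered[rating], answered["rt"])
            sp.name = f"spearman_{rating}_rt"
            kd.name = f"kendall_{rating}_rt"
            results.extend([sp, kd])
        except ValueError:
            pass
    try:
        sp, kd = rank_correlations(trials["ton"], trials["response_category"])
        sp.name = "spearman_ton_accuracy"
        kd.name = "kendall_ton_accuracy"
        results.extend([sp, kd])
    except ValueError:
        pass

    df = pd.DataFrame([r.as_row() for r in results])
    df["significant"] = df["p"] < alpha
    return df
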