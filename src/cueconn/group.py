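"""Group-level connectivity: robust aggregation, consistency, FDR, differences.

Subject-level F matrices are built by winsorizing epoch-level F values
within each subject-condition pool (IQR rule, capped not removed) and
averaging; epoch p-values combine by Fisher's method.  At the group level
the consistency of each directed connection is the fraction of subjects
for whom it is significant (p < alpha, optionally after Benjamini-Hochberg
FDR across that subject's pairs); connections significant in strictly more
than 95% of subjects are deemed robust.  Condition differences are
reported as color-minus-lexical mean-F maps with markers for
condition-specific robust connections and for pairs whose per-subject
paired comparison survives FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .granger import GcMatrix
from .montage import Montage

__all__ = [
    "winsorize_iqr", "bh_fdr", "subject_summary", "group_aggregate",
    "extract_network", "region_aggregate", "difference_matrix",
    "GroupSummary", "DifferenceMatrix", "GroupConnectivity", "GroupResults",
]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def winsorize_iqr(values, k: float = 1.5) -> np.ndarray:
    """Cap values outside [Q1 - k*IQR, Q3 + k*IQR] at those bounds.

    Quantiles use linear interpolation of order statistics.  NaNs are
    passed through untouched and ignored when computing the bounds.
    Requires at least 4 finite values for meaningful quartiles.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        raise ValueError(
            f"winsorize_iqr needs >= 4 finite values, got {int(finite.sum())}"
        )
    q1, q3 = np.percentile(arr[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = arr.copy()
    out[finite] = np.clip(arr[finite], lo, hi)
    return out


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject mask, adjusted p-values); adjusted p-values are
    monotone non-decreasing in the rank of the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # step-up: largest i with p_(i) <= i*alpha/m; reject 1..i
    thresh = alpha * np.arange(1, m + 1) / m
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

def subject_summary(
    epoch_matrices: list[GcMatrix],
    combine: str = "fisher",
    winsor_k: float = 1.5,
    alpha: float = 0.05,
) -> GcMatrix:
    """Combine epoch-level GC matrices into one subject-level matrix.

    F values from all epochs and all defined pairs form one
    subject-condition pool that is winsorized (IQR rule) before the
    per-pair average.  The subject p-value per pair is Fisher's
    combination ``-2 sum(ln p) ~ chi2(2k)`` (``combine="fisher"``), or the
    subject is deemed significant when more than half of the epochs have
    p < alpha (``combine="proportion"``; the decision is stored in
    ``sig_mask`` and the Fisher p is still reported).

    With a single (e.g. pooled-mode) matrix the combination is the
    identity apart from winsorizing.
    """
    if not epoch_matrices:
        raise ValueError("need at least one epoch matrix")
    labs = epoch_matrices[0].channel_labels
    for m in epoch_matrices:
        if m.channel_labels != labs:
            raise ValueError("mismatched channel sets across epoch matrices")
    if combine not in ("fisher", "proportion"):
        raise ValueError("combine must be 'fisher' or 'proportion'")
    C = len(labs)
    stack_F = np.stack([m.F for m in epoch_matrices])        # epochs x C x C
    stack_P = np.stack([m.pvalue for m in epoch_matrices])
    n_ep = stack_F.shape[0]
    defined = ~np.eye(C, dtype=bool)

    # winsorize over the full subject-condition pool of defined entries
    pool = stack_F[:, defined]
    if pool.size >= 4:
        capped = winsorize_iqr(pool.ravel(), k=winsor_k).reshape(pool.shape)
        stack_F = stack_F.copy()
        stack_F[:, defined] = capped
    F_subj = stack_F.mean(axis=0)
    F_subj[~defined] = np.nan

    with np.errstate(divide="ignore"):
        logs = np.log(np.clip(stack_P, 1e-300, 1.0))
    fisher_stat = -2.0 * logs.sum(axis=0)
    p_subj = stats.chi2.sf(fisher_stat, 2 * n_ep)
    p_subj = np.where(defined, p_subj, np.nan)

    sig_mask = None
    if combine == "proportion":
        frac = (stack_P < alpha).mean(axis=0)
        sig_mask = np.where(defined, frac > 0.5, False)

    first = epoch_matrices[0]
    return GcMatrix(
        F=F_subj, pvalue=p_subj, df_num=first.df_num, df_den=first.df_den,
        level="subject", condition=first.condition, channel_labels=list(labs),
        subject_id=first.subject_id, sig_mask=sig_mask,
    )


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Group-level connectivity summary for one condition."""

    condition: str
    channel_labels: list[str]
    mean_F: np.ndarray
    sd_F: np.ndarray
    consistency: np.ndarray
    robust_mask: np.ndarray
    fdr_rejected: np.ndarray
    zscore_F: np.ndarray
    subject_F: np.ndarray           # subjects x C x C (winsorized subject F)
    subject_sig: np.ndarray         # subjects x C x C boolean
    alpha: float = 0.05
    robust_cut: float = 0.95

    @property
    def n_subjects(self) -> int:
        return self.subject_F.shape[0]

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.eye(len(self.channel_labels), dtype=bool)

    @property
    def viz_threshold(self) -> float:
        """Mean + 1 SD of the group-mean F over defined pairs (recomputed)."""
        vals = self.mean_F[self.defined_mask]
        return float(np.mean(vals) + np.std(vals, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        labs = self.channel_labels
        rows = []
        C = len(labs)
        for t in range(C):
            for s in range(C):
                if s == t:
                    continue
                rows.append((
                    labs[s], labs[t], self.mean_F[t, s], self.sd_F[t, s],
                    self.consistency[t, s], bool(self.robust_mask[t, s]),
                    bool(self.fdr_rejected[t, s]), self.zscore_F[t, s],
                ))
        return pd.DataFrame(rows, columns=[
            "source", "target", "mean_F", "sd_F", "consistency", "robust",
            "fdr_rejected", "zscore_F",
        ])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def group_aggregate(
    subject_matrices: list[GcMatrix],
    alpha: float = 0.05,
    robust_cut: float = 0.95,
    fdr_scope: str = "subject",
) -> GroupSummary:
    """Aggregate subject-level GC matrices into a GroupSummary.

    Per pair: mean and SD of subject F; consistency = fraction of subjects
    significant (each subject's significance from its ``sig_mask`` when
    present, otherwise from p < alpha after BH-FDR across that subject's
    defined pairs when ``fdr_scope="subject"``, or from raw p < alpha when
    ``fdr_scope="none"``).  ``robust_mask`` requires consistency strictly
    greater than ``robust_cut`` (so 38/40 subjects at cut 0.95 is not
    robust, 39/40 is).  ``fdr_rejected`` applies BH across pairs to
    group-level Fisher-combined subject p-values.
    """
    if len(subject_matrices) < 2:
        raise ValueError("group aggregation needs >= 2 subjects")
    if fdr_scope not in ("subject", "none"):
        raise ValueError("fdr_scope must be 'subject' or 'none'")
    labs = subject_matrices[0].channel_labels
    for m in subject_matrices:
        if m.channel_labels != labs:
            raise ValueError("mismatched channel sets across subjects")
    C = len(labs)
    defined = ~np.eye(C, dtype=bool)
    stack_F = np.stack([m.F for m in subject_matrices])
    stack_P = np.stack([m.pvalue for m in subject_matrices])
    n_subj = stack_F.shape[0]

    sig = np.zeros((n_subj, C, C), dtype=bool)
    for i, m in enumerate(subject_matrices):
        if m.sig_mask is not None:
            sig[i] = m.sig_mask
        elif fdr_scope == "subject":
            rej, _ = bh_fdr(m.pvalue[defined], alpha=alpha)
            full = np.zeros((C, C), dtype=bool)
            full[defined] = rej
            sig[i] = full
        else:
            sig[i] = (m.pvalue < alpha) & defined

    mean_F = stack_F.mean(axis=0)
    sd_F = stack_F.std(axis=0, ddof=1)
    consistency = sig.mean(axis=0).astype(float)
    consistency[~defined] = np.nan
    robust = np.where(defined, consistency > robust_cut, False)

    # group-level FDR across pairs on Fisher-combined subject p-values
    with np.errstate(divide="ignore"):
        logs = np.log(np.clip(stack_P, 1e-300, 1.0))
    group_p = stats.chi2.sf(-2.0 * logs.sum(axis=0), 2 * n_subj)
    rej, _ = bh_fdr(group_p[defined], alpha=alpha)
    fdr_rejected = np.zeros((C, C), dtype=bool)
    fdr_rejected[defined] = rej

    vals = mean_F[defined]
    mu, sdev = float(np.mean(vals)), float(np.std(vals, ddof=1))
    zscore = np.where(defined, (mean_F - mu) / (sdev if sdev > 0 else np.inf),
                      np.nan)

    return GroupSummary(
        condition=subject_matrices[0].condition,
        channel_labels=list(labs),
        mean_F=np.where(defined, mean_F, np.nan),
        sd_F=np.where(defined, sd_F, np.nan),
        consistency=consistency,
        robust_mask=robust,
        fdr_rejected=fdr_rejected,
        zscore_F=zscore,
        subject_F=stack_F,
        subject_sig=sig,
        alpha=alpha,
        robust_cut=robust_cut,
    )


def extract_network(
    summary: GroupSummary,
    threshold: float | str = "mean_plus_sd",
) -> pd.DataFrame:
    """Edges with group-mean F strictly above threshold, sorted descending.

    ``"mean_plus_sd"`` recomputes mean + 1 SD of the group-mean F over
    defined pairs (the visualization threshold).
    """
    thr = summary.viz_threshold if threshold == "mean_plus_sd" else float(threshold)
    labs = summary.channel_labels
    C = len(labs)
    rows = []
    for t in range(C):
        for s in range(C):
            if s == t:
                continue
            f = summary.mean_F[t, s]
            if f > thr:
                rows.append((labs[s], labs[t], f))
    df = pd.DataFrame(rows, columns=["source", "target", "F"])
    return df.sort_values("F", ascending=False).reset_index(drop=True)


def region_aggregate(
    summary: GroupSummary,
    montage: Montage,
    reducer: str = "count",
    threshold: float | str = "mean_plus_sd",
) -> pd.DataFrame:
    """Aggregate supra-threshold edges to an ordered region x region table.

    Cells hold the count, sum, or mean of edge F values whose source /
    target channels fall in the (row, column) region pair; within-region
    (diagonal) cells are included.  Empty cells are 0.
    """
    if reducer not in ("mean", "sum", "count"):
        raise ValueError("reducer must be 'mean', 'sum' or 'count'")
    montage.validate(summary.channel_labels)
    edges = extract_network(summary, threshold)
    regions = montage.region_names
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for _, e in edges.iterrows():
        i = idx[montage.region_of(e.source)]
        j = idx[montage.region_of(e.target)]
        total[i, j] += e.F
        count[i, j] += 1
    if reducer == "count":
        out = count
    elif reducer == "sum":
        out = total
    else:
        with np.errstate(invalid="ignore"):
            out = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return pd.DataFrame(out, index=regions, columns=regions)


# ---------------------------------------------------------------------------
# condition differences
# ---------------------------------------------------------------------------

@dataclass
class DifferenceMatrix:
    """Color-minus-lexical mean-F difference map with robustness markers.

    ``marker`` holds "C" where a connection is robust only under the color
    cue, "L" where robust only under the lexical cue, "" otherwise.
    ``star`` flags pairs whose paired per-subject F comparison (Wilcoxon
    signed-rank) survives BH-FDR across pairs.
    """

    channel_labels: list[str]
    diff_F: np.ndarray
    marker: np.ndarray          # object array of "", "C", "L"
    star: np.ndarray            # boolean
    paired_p: np.ndarray

    def markers_combined(self) -> np.ndarray:
        out = np.empty(self.diff_F.shape, dtype=object)
        for t in range(out.shape[0]):
            for s in range(out.shape[1]):
                tag = ("*" if self.star[t, s] else "") + str(self.marker[t, s])
                out[t, s] = tag
        return out

    def to_frame(self) -> pd.DataFrame:
        labs = self.channel_labels
        C = len(labs)
        rows = []
        for t in range(C):
            for s in range(C):
                if s == t:
                    continue
                rows.append((labs[s], labs[t], self.diff_F[t, s],
                             str(self.marker[t, s]), bool(self.star[t, s]),
                             self.paired_p[t, s]))
        return pd.DataFrame(rows, columns=[
            "source", "target", "diff_F", "marker", "star", "paired_p",
        ])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for paired subject F values."""
    d = a - b
    d = d[np.isfinite(d)]
    if d.size < 5 or np.allclose(d, 0.0):
        return 1.0
    try:
        return float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
    except ValueError:
        return 1.0


def difference_matrix(
    color: GroupSummary,
    lexical: GroupSummary,
    alpha: float = 0.05,
) -> DifferenceMatrix:
    """Condition-difference map: color mean_F minus lexical mean_F.

    The sign convention is fixed (color - lexical: positive entries are
    color-dominant).  "C"/"L" markers flag connections robust in exactly
    one condition; the "*" flag marks pairs whose paired per-subject
    comparison is significant after BH-FDR across all defined pairs
    (requires the same subjects in both conditions, the within-subject
    design).
    """
    if color.channel_labels != lexical.channel_labels:
        raise ValueError("channel sets differ between conditions")
    C = len(color.channel_labels)
    defined = ~np.eye(C, dtype=bool)
    diff = color.mean_F - lexical.mean_F

    marker = np.full((C, C), "", dtype=object)
    only_c = color.robust_mask & ~lexical.robust_mask
    only_l = lexical.robust_mask & ~color.robust_mask
    marker[only_c] = "C"
    marker[only_l] = "L"

    star = np.zeros((C, C), dtype=bool)
    paired_p = np.full((C, C), np.nan)
    if color.subject_F.shape == lexical.subject_F.shape:
        pv = np.ones((C, C))
        for t in range(C):
            for s in range(C):
                if s == t:
                    continue
                pv[t, s] = _paired_p(color.subject_F[:, t, s],
                                     lexical.subject_F[:, t, s])
        rej, adj = bh_fdr(pv[defined], alpha=alpha)
        star[defined] = rej
        paired_p[defined] = pv[defined]

    return DifferenceMatrix(
        channel_labels=list(color.channel_labels),
        diff_F=np.where(defined, diff, np.nan),
        marker=marker,
        star=star,
        paired_p=paired_p,
    )


# ---------------------------------------------------------------------------
# model front-end
# ---------------------------------------------------------------------------

class GroupConnectivity:
    """Group-level model over per-subject GC matrices for one condition."""

    def __init__(
        self,
        subject_matrices: list[GcMatrix],
        alpha: float = 0.05,
        robust_cut: float = 0.95,
        fdr_scope: str = "subject",
    ):
        self.subject_matrices = subject_matrices
        self.alpha = alpha
        self.robust_cut = robust_cut
        self.fdr_scope = fdr_scope

    def fit(self) -> "GroupResults":
        summary = group_aggregate(
            self.subject_matrices, alpha=self.alpha,
            robust_cut=self.robust_cut, fdr_scope=self.fdr_scope,
        )
        return GroupResults(self, summary)


class GroupResults:
    """Fitted group summary with convenience accessors."""

    def __init__(self, model: GroupConnectivity, summary: GroupSummary):
        self.model = model
        self.group_summary = summary

    @property
    def robust_edges(self) -> list[tuple[str, str]]:
        labs = self.group_summary.channel_labels
        t_idx, s_idx = np.nonzero(self.group_summary.robust_mask)
        return [(labs[s], labs[t]) for t, s in zip(t_idx, s_idx)]

    def extract_network(self, threshold="mean_plus_sd") -> pd.DataFrame:
        return extract_network(self.group_summary, threshold)

    def region_table(self, montage: Montage, reducer: str = "count",
                     threshold="mean_plus_sd") -> pd.DataFrame:
        return region_aggregate(self.group_summary, montage, reducer, threshold)

    def difference(self, other: "GroupResults", alpha: float | None = None) -> DifferenceMatrix:
        """self as the color condition, other as the lexical condition."""
        return difference_matrix(self.group_summary, other.group_summary,
                                 alpha=alpha if alpha is not None else self.model.alpha)

    def summary(self) -> str:
        gs = self.group_summary
        vals = gs.mean_F[gs.defined_mask]
        n_robust = int(gs.robust_mask.sum())
        lines = [
            "Group connectivity summary",
            "=" * 60,
            f"condition {gs.condition}: {gs.n_subjects} subjects, "
            f"{gs.defined_mask.sum()} directed connections",
            f"mean F {np.mean(vals):.2f} (SD {np.std(vals, ddof=1):.2f}), "
            f"visualization threshold {gs.viz_threshold:.2f}",
            f"robust connections (> {gs.robust_cut:.0%} of subjects): "
            f"{n_robust} ({n_robust / gs.defined_mask.sum():.1%})",
            f"FDR-rejected pairs at alpha={gs.alpha}: "
            f"{int(gs.fdr_rejected.sum())}",
        ]
        return "\n".join(lines)
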