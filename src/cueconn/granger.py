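"""Conditional Granger causality over all ordered channel pairs.

A source channel Granger-causes a target if its past improves prediction
of the target beyond the target's own past and - in the conditional
variant used by default - beyond the past of every other recorded channel.
The statistic is the nested-regression F test

    F = [(RSS_reduced - RSS_full) / p] / [RSS_full / (T_eff - k_full)]

where the full model regresses the target on ``p`` lags of all channels
("full" conditioning) or of the source-target pair ("bivariate"), and the
reduced model omits all lags of the source.  p-values come from the upper
tail of F(p, T_eff - k_full).

The model front-end (:class:`GrangerModel` / :class:`GrangerResults`)
handles order selection and the epoch-wise estimation mode, in which each
epoch is treated as an independent realization and fitted separately; the
subject-level combination rule lives in :mod:`cueconn.group`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochSet
from .var import build_lagged_design, history_window_ms, select_order

__all__ = ["GcMatrix", "gc_pair", "gc_all_pairs", "GrangerModel",
           "GrangerResults"]


@dataclass
class GcMatrix:
    """Directed-connectivity F statistics over all ordered channel pairs.

    ``F[t, s]`` is undefined (NaN) on the diagonal and holds the statistic
    for source ``s`` -> target ``t`` elsewhere.  ``sig_mask`` is an
    optional precomputed per-pair significance decision (used by the
    proportion-based subject combination rule); when absent, downstream
    stages derive significance from ``pvalue``.
    """

    F: np.ndarray
    pvalue: np.ndarray
    df_num: int
    df_den: float
    level: str = "epoch"           # "epoch" | "subject" | "group"
    condition: str = ""
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    sig_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.pvalue = np.asarray(self.pvalue, dtype=float)
        c = self.F.shape[0]
        if self.F.shape != (c, c) or self.pvalue.shape != (c, c):
            raise ValueError("F and pvalue must be square and congruent")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(c)]

    @property
    def n_channels(self) -> int:
        return self.F.shape[0]

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.eye(self.n_channels, dtype=bool)

    @property
    def n_defined(self) -> int:
        c = self.n_channels
        return c * (c - 1)

    def pair(self, source: str, target: str) -> tuple[float, float]:
        """(F, p) for a named source -> target connection."""
        s = self.channel_labels.index(source)
        t = self.channel_labels.index(target)
        if s == t:
            raise ValueError("source and target must differ")
        return float(self.F[t, s]), float(self.pvalue[t, s])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labs = self.channel_labels
        for t in range(self.n_channels):
            for s in range(self.n_channels):
                if s == t:
                    continue
                rows.append((labs[s], labs[t], self.F[t, s],
                             self.pvalue[t, s], self.df_num, self.df_den))
        return pd.DataFrame(
            rows, columns=["source", "target", "F", "p", "df_num", "df_den"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# core computation
# ---------------------------------------------------------------------------

def _rss_multi(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _lag_columns(n_channels: int, order: int, channels, include_intercept=True):
    """Design-column indices for the given channels' lags (+ intercept)."""
    off = 1 if include_intercept else 0
    cols = list(range(off)) if include_intercept else []
    for l in range(order):
        base = off + l * n_channels
        cols.extend(base + c for c in channels)
    return cols


def gc_all_pairs(
    epochs: EpochSet,
    order: int,
    conditioning: str = "full",
    condition: str | None = None,
    level: str = "epoch",
) -> GcMatrix:
    """Conditional (or bivariate) GC F tests for every ordered pair.

    Epochs in ``epochs`` are pooled as independent realizations into one
    stacked regression.  With C channels exactly C*(C-1) entries are
    defined.  The full-model fit is shared across targets: one full
    regression per target and one reduced regression per source.
    """
    if conditioning not in ("full", "bivariate"):
        raise ValueError("conditioning must be 'full' or 'bivariate'")
    C = epochs.n_channels
    if C < 2:
        raise ValueError("need at least 2 channels")
    p = order
    X, Y = build_lagged_design(epochs.data, p, include_intercept=True)
    T_eff = X.shape[0]
    F = np.full((C, C), np.nan)
    P = np.full((C, C), np.nan)

    if conditioning == "full":
        k_full = X.shape[1]
        df_den = T_eff - k_full
        if df_den <= 0:
            raise ValueError(
                f"non-positive denominator df: T_eff={T_eff}, k_full={k_full}"
            )
        rss_full = _rss_multi(X, Y)
        for s in range(C):
            keep = [c for c in range(C) if c != s]
            cols = _lag_columns(C, p, keep)
            rss_red = _rss_multi(X[:, cols], Y)
            for t in range(C):
                if t == s:
                    continue
                F[t, s] = ((rss_red[t] - rss_full[t]) / p) / (
                    rss_full[t] / df_den
                )
        F = np.where(np.eye(C, dtype=bool), np.nan, np.maximum(F, 0.0))
        P = stats.f.sf(F, p, df_den)
        P[np.eye(C, dtype=bool)] = np.nan
    else:
        k_full = 2 * p + 1
        df_den = T_eff - k_full
        if df_den <= 0:
            raise ValueError(
                f"non-positive denominator df: T_eff={T_eff}, k_full={k_full}"
            )
        for s in range(C):
            for t in range(C):
                if t == s:
                    continue
                cols_full = _lag_columns(C, p, sorted({s, t}))
                cols_red = _lag_columns(C, p, [t])
                rss_full = _rss_multi(X[:, cols_full], Y[:, [t]])[0]
                rss_red = _rss_multi(X[:, cols_red], Y[:, [t]])[0]
                F[t, s] = max(((rss_red - rss_full) / p) / (rss_full / df_den), 0.0)
                P[t, s] = stats.f.sf(F[t, s], p, df_den)

    return GcMatrix(
        F=F, pvalue=P, df_num=p, df_den=float(df_den), level=level,
        condition=condition if condition is not None else epochs.condition,
        channel_labels=list(epochs.channel_labels),
        subject_id=epochs.subject_id,
    )


def gc_pair(
    epochs: EpochSet,
    source: str,
    target: str,
    order: int,
    conditioning: str = "full",
) -> tuple[float, float, int, float]:
    """GC F test for one directed connection; returns (F, p, df_num, df_den)."""
    if source == target:
        raise ValueError("source and target must differ")
    s = epochs.channel_index(source)
    t = epochs.channel_index(target)
    C = epochs.n_channels
    p = order
    X, Y = build_lagged_design(epochs.data, p, include_intercept=True)
    if conditioning == "full":
        cols_full = _lag_columns(C, p, range(C))
        cols_red = _lag_columns(C, p, [c for c in range(C) if c != s])
    elif conditioning == "bivariate":
        cols_full = _lag_columns(C, p, sorted({s, t}))
        cols_red = _lag_columns(C, p, [t])
    else:
        raise ValueError("conditioning must be 'full' or 'bivariate'")
    k_full = len(cols_full)
    df_den = X.shape[0] - k_full
    if df_den <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    rss_full = _rss_multi(X[:, cols_full], Y[:, [t]])[0]
    rss_red = _rss_multi(X[:, cols_red], Y[:, [t]])[0]
    F = max(((rss_red - rss_full) / p) / (rss_full / df_den), 0.0)
    return F, float(stats.f.sf(F, p, df_den)), p, float(df_den)


# ---------------------------------------------------------------------------
# model front-end
# ---------------------------------------------------------------------------

class GrangerModel:
    """Directed-connectivity model for one subject-condition EpochSet.

    Parameters
    ----------
    epochs : EpochSet
        Stationarity-enforced epochs.
    order : int or None
        VAR lag order; None triggers selection by ``criterion`` up to
        ``max_order``.
    criterion : "fixed" | "BIC" | "AIC" | "HQC"
        With "fixed" (default) the order is ``order`` (or ``max_order``
        when order is None), reproducing an a-priori maxlag-10 analysis.
    conditioning : "full" | "bivariate"
    mode : "per_epoch" | "pooled"
        Per-epoch fits each epoch separately (each an independent
        realization); pooled stacks all epochs into one regression.
    """

    def __init__(
        self,
        epochs: EpochSet,
        order: int | None = 10,
        criterion: str = "fixed",
        max_order: int = 10,
        conditioning: str = "full",
        mode: str = "per_epoch",
    ):
        if mode not in ("per_epoch", "pooled"):
            raise ValueError("mode must be 'per_epoch' or 'pooled'")
        self.epochs = epochs
        self.criterion = criterion
        self.max_order = max_order
        self.conditioning = conditioning
        self.mode = mode
        if criterion.lower() == "fixed":
            self.order = order if order is not None else max_order
        else:
            self.order = select_order(epochs, max_order=max_order,
                                      criterion=criterion)

    def fit(self) -> "GrangerResults":
        if self.mode == "pooled":
            mats = [gc_all_pairs(self.epochs, self.order, self.conditioning,
                                 level="subject")]
        else:
            mats = []
            for e in range(self.epochs.n_epochs):
                sub = self.epochs.copy_with(data=self.epochs.data[e:e + 1])
                mats.append(gc_all_pairs(sub, self.order, self.conditioning,
                                         level="epoch"))
        return GrangerResults(self, mats)


class GrangerResults:
    """Per-epoch (or pooled) GC matrices for one subject-condition."""

    def __init__(self, model: GrangerModel, matrices: list[GcMatrix]):
        self.model = model
        self.matrices = matrices

    @property
    def order(self) -> int:
        return self.model.order

    @property
    def history_ms(self) -> float:
        return history_window_ms(self.order, self.model.epochs.srate)

    def subject_summary(self, combine: str = "fisher", winsor_k: float = 1.5,
                        alpha: float = 0.05) -> GcMatrix:
        """Combine epoch-level matrices into one subject-level matrix."""
        from .group import subject_summary

        return subject_summary(self.matrices, combine=combine,
                               winsor_k=winsor_k, alpha=alpha)

    def summary(self, top: int = 10) -> str:
        m = self.subject_summary() if len(self.matrices) > 1 else self.matrices[0]
        df = m.to_frame().sort_values("F", ascending=False).head(top)
        lines = [
            "Granger causality summary",
            "=" * 60,
            f"subject {m.subject_id}  condition {m.condition}",
            f"order {self.order} ({self.history_ms:.0f} ms history at "
            f"{self.model.epochs.srate:g} Hz), "
            f"conditioning {self.model.conditioning}, mode {self.model.mode}",
            f"{m.n_defined} directed connections over {m.n_channels} channels",
            "-" * 60,
            f"{'source':>8} {'target':>8} {'F':>10} {'p':>12}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r.source:>8} {r.target:>8} {r.F:>10.3f} {r.p:>12.4g}"
            )
        return "\n".join(lines)
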