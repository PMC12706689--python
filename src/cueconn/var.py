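"""VAR estimation by ordinary least squares and information-criterion order selection.

Epochs are treated as independent realizations of one process: lagged
design rows are stacked across epochs without cross-epoch lag contamination
(the first ``p`` samples of each epoch serve only as regressors).  Model
order is selected over 1..max_order by AIC, BIC or HQC computed from the
log-determinant of the innovation covariance; a maximum lag of 10 at
500 Hz corresponds to a 20 ms history window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet

__all__ = ["VarFit", "fit_var", "select_order", "history_window_ms",
           "build_lagged_design"]


def history_window_ms(order: int, srate: float) -> float:
    """Temporal span of ``order`` lags at sampling rate ``srate`` (ms)."""
    return 1000.0 * order / srate


def build_lagged_design(
    data: np.ndarray,
    order: int,
    include_intercept: bool = True,
    presample: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged regressor rows across epochs.

    Parameters
    ----------
    data : (n_epochs, n_channels, n_samples)
    order : p
    presample : int
        Number of leading samples of each epoch reserved as regressors
        (defaults to ``order``; a larger value keeps the estimation sample
        fixed while comparing different orders).

    Returns
    -------
    X : (T_eff, [1 +] n_channels * order)
        Columns ordered intercept first, then lag 1 of every channel, lag 2
        of every channel, ...
    Y : (T_eff, n_channels)
    """
    n_ep, n_ch, n_samp = data.shape
    p = order
    pre = order if presample is None else presample
    if pre < p:
        raise ValueError("presample must be >= order")
    rows = n_samp - pre
    if rows < 1:
        raise ValueError(f"epochs of {n_samp} samples too short for presample {pre}")
    T_eff = rows * n_ep
    k_lag = n_ch * p
    X = np.empty((T_eff, (1 if include_intercept else 0) + k_lag))
    Y = np.empty((T_eff, n_ch))
    col0 = 0
    if include_intercept:
        X[:, 0] = 1.0
        col0 = 1
    for e in range(n_ep):
        sl = slice(e * rows, (e + 1) * rows)
        Y[sl] = data[e, :, pre:].T
        for l in range(1, p + 1):
            X[sl, col0 + (l - 1) * n_ch: col0 + l * n_ch] = (
                data[e, :, pre - l: n_samp - l].T
            )
    return X, Y


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS for all equations at once; returns (beta, rss per equation, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return beta, rss, int(rank)


@dataclass
class VarFit:
    """A fitted VAR(p): per-equation OLS estimates and fit criteria."""

    order: int
    coefs: np.ndarray          # n_channels x k (intercept first)
    rss: np.ndarray            # residual sum of squares per equation
    t_eff: int
    resid_cov: np.ndarray
    criteria: dict = field(default_factory=dict)  # aic / bic / hqc
    channel_labels: list[str] = field(default_factory=list)
    include_intercept: bool = True

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[0]

    def lag_matrix(self, lag: int) -> np.ndarray:
        """Estimated coefficient matrix at ``lag`` (entry [j, k]: k -> j)."""
        if not 1 <= lag <= self.order:
            raise ValueError("lag out of range")
        c = self.n_channels
        off = 1 if self.include_intercept else 0
        return self.coefs[:, off + (lag - 1) * c: off + lag * c]


def _criteria(rss_cov: np.ndarray, t_eff: int, n_params: int) -> dict:
    sign, logdet = np.linalg.slogdet(rss_cov)
    if sign <= 0:
        logdet = -np.inf
    return {
        "aic": logdet + 2.0 * n_params / t_eff,
        "bic": logdet + np.log(t_eff) * n_params / t_eff,
        "hqc": logdet + 2.0 * np.log(np.log(t_eff)) * n_params / t_eff,
    }


def fit_var(
    epochs: EpochSet,
    order: int,
    include_intercept: bool = True,
    presample: int | None = None,
) -> VarFit:
    """Estimate a VAR(p) by equation-wise OLS over stacked epochs.

    Raises on a rank-deficient design (e.g. exactly duplicated channels).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n_ch = epochs.n_channels
    X, Y = build_lagged_design(epochs.data, order, include_intercept, presample)
    k = X.shape[1]
    if X.shape[0] - k <= 0:
        raise ValueError(
            f"insufficient samples: T_eff={X.shape[0]} <= {k} parameters"
        )
    beta, rss, rank = _ols_multi(X, Y)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"rank-deficient lagged design (rank {rank} < {k}) for equation "
            f"{epochs.channel_labels[0]!r} (and all others); check for "
            "duplicated or collinear channels"
        )
    t_eff = X.shape[0]
    resid = Y - X @ beta
    resid_cov = resid.T @ resid / t_eff
    n_params = n_ch * k
    return VarFit(
        order=order,
        coefs=beta.T,
        rss=rss,
        t_eff=t_eff,
        resid_cov=resid_cov,
        criteria=_criteria(resid_cov, t_eff, n_params),
        channel_labels=list(epochs.channel_labels),
        include_intercept=include_intercept,
    )


def select_order(
    epochs: EpochSet,
    max_order: int = 10,
    criterion: str = "BIC",
) -> int:
    """Select the VAR order over 1..max_order by an information criterion.

    ``criterion="fixed"`` imposes ``max_order`` without any search (the
    default pipeline configuration, reproducing an a-priori order of 10).
    All candidate orders are scored on the common estimation sample
    obtained by reserving ``max_order`` presample points per epoch.
    """
    crit = criterion.lower()
    if crit == "fixed":
        return max_order
    if crit not in ("aic", "bic", "hqc"):
        raise ValueError("criterion must be 'AIC', 'BIC', 'HQC' or 'fixed'")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n_ch = epochs.n_channels
    t_eff = (epochs.n_samples - max_order) * epochs.n_epochs
    if t_eff <= n_ch * max_order + 1:
        raise ValueError(
            f"insufficient samples for max_order={max_order}: "
            f"T_eff={t_eff} <= {n_ch * max_order + 1}"
        )
    scores = {}
    for p in range(1, max_order + 1):
        fit = fit_var(epochs, p, presample=max_order)
        scores[p] = fit.criteria[crit]
    return min(scores, key=scores.get)
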