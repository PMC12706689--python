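"""Per-channel, per-epoch stationarity assessment and bounded differencing.

Valid Granger-causality inference requires (covariance-) stationary inputs.
Each channel of each epoch is tested with the (augmented) Dickey-Fuller
unit-root test; channels failing to reject the unit root at ``alpha`` are
differenced, re-tested, and differenced at most a second time.  The policy
is bounded at two differences to preserve interpretability of the signal;
channels still non-stationary after two differences are flagged in the
report but retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .epochs import EpochSet

__all__ = ["adf_test", "enforce_stationarity", "StationarityReport"]

_REGRESSION = {"constant": "c", "none": "n", "trend": "ct"}


def adf_test(
    series,
    regression: str = "constant",
    lag_policy: str | int = "aic",
) -> tuple[float, float]:
    """(Augmented) Dickey-Fuller unit-root test.

    Parameters
    ----------
    series : 1-D real sequence
    regression : "constant" | "none" | "trend"
        Deterministic term in the ADF regression.
    lag_policy : "aic" or a fixed lag count
        ``"aic"`` selects the augmentation lag automatically by AIC up to
        the Schwert bound ``floor(12 * (T/100)**0.25)``; an integer fixes
        the lag (0 gives the plain Dickey-Fuller regression).

    Returns
    -------
    (statistic, pvalue)
        The t-ratio on the lagged level and its unit-root p-value from the
        standard Dickey-Fuller response surfaces.  The null hypothesis is
        a unit root; small p-values indicate stationarity.
    """
    y = np.asarray(series, dtype=float).ravel()
    if regression not in _REGRESSION:
        raise ValueError(f"regression must be one of {sorted(_REGRESSION)}")
    if np.ptp(y) == 0.0:
        raise ValueError("zero-variance input: constant series has no unit-root test")
    T = y.size
    if isinstance(lag_policy, str):
        if lag_policy != "aic":
            raise ValueError("lag_policy must be 'aic' or an integer lag count")
        maxlag = int(np.floor(12.0 * (T / 100.0) ** 0.25))
        autolag = "AIC"
    else:
        maxlag = int(lag_policy)
        autolag = None
    if T <= 3 * (maxlag + 2):
        raise ValueError(
            f"series too short (T={T}) for max lag {maxlag}"
        )
    stat, pvalue, *_ = adfuller(
        y, maxlag=maxlag, regression=_REGRESSION[regression], autolag=autolag
    )
    return float(stat), float(pvalue)


@dataclass
class StationarityReport:
    """Per-(epoch, channel) differencing decisions."""

    table: pd.DataFrame  # epoch, channel, statistic, pvalue, diff_order, stationary_after

    @property
    def diff_orders(self) -> np.ndarray:
        """epoch x channel matrix of applied differencing orders."""
        return (
            self.table.pivot(index="epoch", columns="channel", values="diff_order")
            .to_numpy()
        )

    @property
    def n_flagged(self) -> int:
        return int((~self.table["stationary_after"]).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def enforce_stationarity(
    epochs: EpochSet,
    alpha: float = 0.05,
    max_diff: int = 2,
    regression: str = "constant",
    lag_policy: str | int = "aic",
) -> tuple[EpochSet, StationarityReport]:
    """Difference each channel the minimal number of times (0..max_diff).

    Each channel in each epoch is ADF-tested; on failure to reject the unit
    root at ``alpha`` it is first-differenced and re-tested, up to
    ``max_diff`` times.  Channels still non-stationary after exhausting the
    policy are flagged (``stationary_after = False``) but kept.

    After the per-channel decisions, all channels are truncated from the
    front to a common length ``n_samples - max(applied order)`` so the
    channel set stays aligned for the VAR stage; already-stationary
    channels are truncated, not re-differenced, preserving their dynamics.

    Returns the aligned EpochSet and a report of every decision.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_ep, n_ch, n_samp = epochs.data.shape
    rows = []
    series_out = [[None] * n_ch for _ in range(n_ep)]
    orders = np.zeros((n_ep, n_ch), dtype=int)
    for e in range(n_ep):
        for c in range(n_ch):
            y = epochs.data[e, c]
            d = 0
            try:
                stat, p = adf_test(y, regression=regression, lag_policy=lag_policy)
                while p >= alpha and d < max_diff:
                    y = np.diff(y)
                    d += 1
                    stat, p = adf_test(y, regression=regression,
                                       lag_policy=lag_policy)
            except ValueError as err:
                raise ValueError(
                    f"epoch {e}, channel {epochs.channel_labels[c]!r}: {err}"
                ) from err
            rows.append(
                (e, epochs.channel_labels[c], stat, p, d, bool(p < alpha))
            )
            series_out[e][c] = y
            orders[e, c] = d
    max_order = int(orders.max(initial=0))
    out_len = n_samp - max_order
    data = np.empty((n_ep, n_ch, out_len))
    for e in range(n_ep):
        for c in range(n_ch):
            y = series_out[e][c]
            data[e, c] = y[y.size - out_len:]
    report = StationarityReport(
        pd.DataFrame(
            rows,
            columns=["epoch", "channel", "statistic", "pvalue", "diff_order",
                     "stationary_after"],
        )
    )
    return epochs.copy_with(data=data), report
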