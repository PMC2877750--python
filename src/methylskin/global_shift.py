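"""RS-curve construction and the Gaussian-null global shift test.

The RS ("ratio over sum") plot is a cumulative variant of the MA-plot:
probes are sorted by absolute delta-beta in decreasing order and the N-th
point is the cumulative delta-beta of the top N probes divided by their
cumulative beta sum, against N/M on the x axis. A genome-wide methylation
shift makes the curve leave zero at the left edge and decay toward the
global shift ratio at the right.

The cumulative ratio-over-sum form is a documented reconstruction: it is
consistent with the plot's name, the prescribed sorting rule and the
MA-plot analogy, and it is isolated in :func:`rs_curve` so an alternative
formula can be swapped without touching callers.

The shift test asks whether the delta-beta distribution of the
significant, low-variance markers differs from chance: a Welch two-sample
t-test of the filtered delta-beta values against draws from a Gaussian
null with mean 0.0 and sd 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, PreconditionError

__all__ = ["rs_curve", "shift_test", "plot_rs_curves", "ShiftTestResult"]

NULL_MEAN = 0.0
NULL_SD = 0.1
SD_THRESHOLD = 0.1


def rs_curve(delta: pd.Series, sums: pd.Series) -> pd.DataFrame:
    """RS curve points over probes sorted by |delta-beta| descending.

    ``sums`` holds the per-probe total of the two group means
    (beta_A + beta_B). Ties in |delta| break lexicographically by probe id.
    Returns columns rank, x (= rank/M), y (cumulative ratio), probe_id and
    delta_beta.
    """
    if len(delta) == 0:
        raise InputError("empty input")
    delta, sums = delta.align(sums, join="inner")
    if len(delta) == 0:
        raise InputError("delta and sums share no probes")
    order_frame = pd.DataFrame({
        "abs_delta": delta.abs().to_numpy(),
        "pid": delta.index.to_numpy(),
    })
    positions = order_frame.sort_values(
        ["abs_delta", "pid"], ascending=[False, True], kind="stable"
    ).index.to_numpy()
    order = delta.index.to_numpy()[positions]
    d = delta.to_numpy(dtype=float)[positions]
    s = sums.to_numpy(dtype=float)[positions]
    cum_d = np.cumsum(d)
    cum_s = np.cumsum(s)
    if np.any(cum_s == 0):
        warnings.warn("zero cumulative beta sum: undefined RS points (NaN)",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(cum_s != 0, cum_d / np.where(cum_s != 0, cum_s, 1.0),
                     np.nan)
    m = d.size
    return pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "x": np.arange(1, m + 1) / m,
            "y": y,
            "probe_id": order,
            "delta_beta": d,
        }
    )


@dataclass
class ShiftTestResult:
    n_markers: int
    mean_delta: float
    sd_delta: float
    t_statistic: float
    p_value: float
    null_mean: float
    null_sd: float
    n_null: int
    p_threshold: float | None
    sd_threshold: float | None

    def summary(self) -> dict:
        return {
            "n_markers": self.n_markers,
            "mean_delta": self.mean_delta,
            "sd_delta": self.sd_delta,
            "t": self.t_statistic,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_null": self.n_null,
        }


def shift_test(
    delta: pd.Series | np.ndarray,
    p_values: pd.Series | np.ndarray | None = None,
    sd: pd.Series | np.ndarray | None = None,
    p_threshold: float | None = 0.01,
    sd_threshold: float | None = SD_THRESHOLD,
    null_mean: float = NULL_MEAN,
    null_sd: float = NULL_SD,
    n_null: int = 10_000,
    seed: int = 0,
    one_sample: bool = False,
) -> ShiftTestResult:
    """Test the filtered delta-beta distribution against a Gaussian null.

    Markers first pass ``p_values < p_threshold`` and ``sd < sd_threshold``
    (either filter is skipped when its argument is None). The surviving
    delta-beta values are compared with ``n_null`` seeded draws from
    Normal(null_mean, null_sd) by a Welch two-sample t-test; with
    ``one_sample=True`` a one-sample t-test against ``null_mean`` is used
    instead.
    """
    delta = pd.Series(np.asarray(delta, dtype=float)) \
        if not isinstance(delta, pd.Series) else delta.astype(float)
    mask = ~delta.isna()
    if p_threshold is not None:
        if p_values is None:
            raise InputError("p_threshold set but no P-values supplied")
        p_values = pd.Series(np.asarray(p_values, dtype=float),
                             index=delta.index) \
            if not isinstance(p_values, pd.Series) else p_values
        mask &= p_values.reindex(delta.index) < p_threshold
        if mask.sum() < 3:
            raise PreconditionError(
                f"fewer than 3 markers survive the P < {p_threshold} filter"
            )
    if sd_threshold is not None and sd is not None:
        sd = pd.Series(np.asarray(sd, dtype=float), index=delta.index) \
            if not isinstance(sd, pd.Series) else sd
        mask &= sd.reindex(delta.index) < sd_threshold
        if mask.sum() < 3:
            raise PreconditionError(
                f"fewer than 3 markers survive the sd < {sd_threshold} filter"
            )
    values = delta[mask].to_numpy()
    if values.size < 3:
        raise PreconditionError("fewer than 3 markers available for the test")
    if one_sample:
        res = sps.ttest_1samp(values, popmean=null_mean)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5817]))
        null_draws = rng.normal(null_mean, null_sd, size=n_null)
        res = sps.ttest_ind(values, null_draws, equal_var=False)
    return ShiftTestResult(
        n_markers=int(values.size),
        mean_delta=float(values.mean()),
        sd_delta=float(values.std(ddof=1)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        null_mean=null_mean,
        null_sd=null_sd,
        n_null=0 if one_sample else n_null,
        p_threshold=p_threshold,
        sd_threshold=sd_threshold,
    )


def plot_rs_curves(curves: dict[str, pd.DataFrame], path=None, ax=None):
    """Plot one or more RS curves (cumulative shift vs. marker fraction)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(curve["x"], curve["y"], label=label, lw=1.5)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("fraction of markers (sorted by |Δβ|)")
    ax.set_ylabel("cumulative Δβ / Σβ ratio")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
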