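"""Bead-level intensities to a detection-filtered beta matrix.

Pipeline order: per-channel quantile normalization across samples, bead
aggregation to per-(probe, sample, channel) summaries, negative-bead
detection P-values (one-sided Mann-Whitney per channel, Benjamini-Hochberg
adjusted across probes within each channel before taking the per-probe
minimum), beta computation ``M / (M + U + offset)``, and removal of probes
whose detection P exceeds the threshold in any sample.

The beta offset defaults to 100, the platform convention for this array
generation; the normalization scope defaults to all samples in the manifest
jointly. The detection alternative is one-sided (probe beads exceed the
negative beads): signal detection is inherently directional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, PreconditionError
from .stats import bh_adjust, mannwhitney_p

__all__ = [
    "quantile_normalize",
    "quantile_normalize_channel",
    "normalize_bead_channels",
    "aggregate_beads",
    "detection_pvalue",
    "detection_pvalue_matrix",
    "compute_beta",
    "build_beta_matrix",
    "filter_detected",
    "group_stats",
    "preprocess_beads",
    "BetaMatrix",
]

NEGATIVE_ID = "NEGATIVE"
CHANNELS = ("green", "red")
DEFAULT_OFFSET = 100.0
DEFAULT_DETECTION_THRESHOLD = 0.05


def _assign_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``values`` onto ``reference`` (sorted) by rank, averaging over ties."""
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    # segment boundaries of tied runs in the sorted input
    starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    seg_sums = np.add.reduceat(reference, starts)
    seg_lens = np.diff(np.r_[starts, sorted_vals.size])
    seg_means = seg_sums / seg_lens
    out_sorted = np.repeat(seg_means, seg_lens)
    out = np.empty_like(values, dtype=float)
    out[order] = out_sorted
    return out


def quantile_normalize(samples: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Quantile-normalize one channel's values across samples.

    After normalization every sample's sorted vector equals the rank-wise
    mean of the sorted inputs; within-sample rank order is preserved and
    ties receive the mean of the reference values they span. Samples of
    unequal length are handled by linear interpolation of the mean quantile
    function.
    """
    keys = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in keys]
    if len(arrays) == 0:
        raise InputError("no samples to normalize")
    if len(arrays) == 1:
        warnings.warn("single sample: quantile normalization is the identity",
                      stacklevel=2)
        return {keys[0]: arrays[0].copy()}
    lengths = {a.size for a in arrays}
    if 0 in lengths:
        raise InputError("cannot normalize an empty sample")
    if len(lengths) == 1:
        reference = np.mean([np.sort(a) for a in arrays], axis=0)
        return {
            k: _assign_reference(a, reference) for k, a in zip(keys, arrays)
        }
    # unequal counts: average the per-sample quantile functions on the grid
    # of the largest sample, then read each sample off that curve
    n_max = max(lengths)
    grid = (np.arange(n_max) + 0.5) / n_max
    reference = np.mean(
        [np.quantile(a, grid, method="linear") for a in arrays], axis=0
    )
    out = {}
    for k, a in zip(keys, arrays):
        positions = (np.arange(a.size) + 0.5) / a.size
        ref_for_sample = np.interp(positions, grid, reference)
        out[k] = _assign_reference(a, ref_for_sample)
    return out


def quantile_normalize_channel(matrix: np.ndarray) -> np.ndarray:
    """Matrix convenience wrapper: rows are samples, columns are values."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise InputError("expected a samples x values matrix")
    normalized = quantile_normalize({i: row for i, row in enumerate(matrix)})
    return np.vstack([normalized[i] for i in range(matrix.shape[0])])


def normalize_bead_channels(beads: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize bead intensities per channel across samples.

    All beads of a sample-channel (probe and negative-control alike) form
    one vector; the two channels are normalized independently because their
    raw intensity distributions differ in shape.
    """
    beads = beads.copy()
    intensity = beads["intensity"].to_numpy(dtype=float).copy()
    groups = beads.groupby(["channel", "sample_id"], observed=True).indices
    for channel in CHANNELS:
        channel_groups = {
            sample: idx for (ch, sample), idx in groups.items() if ch == channel
        }
        if not channel_groups:
            continue
        vectors = {s: intensity[idx] for s, idx in channel_groups.items()}
        if len(vectors) == 1:
            continue  # nothing to normalize against
        normalized = quantile_normalize(vectors)
        for s, idx in channel_groups.items():
            intensity[idx] = normalized[s]
    beads["intensity"] = intensity
    return beads


def aggregate_beads(beads: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample sd (ddof=1, 0 for a single bead) and count per
    (probe, sample, channel, allele); negative-control beads are excluded."""
    probe_beads = beads[beads["probe_id"] != NEGATIVE_ID]
    if probe_beads.empty:
        raise InputError("no probe beads to aggregate")
    grouped = probe_beads.groupby(
        ["probe_id", "sample_id", "channel", "allele"], observed=True
    )["intensity"]
    summary = grouped.agg(mean="mean", sd="std", n_beads="size").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    for col in ("probe_id", "sample_id", "channel", "allele"):
        summary[col] = summary[col].astype(str)
    return summary


def detection_pvalue(
    probe_beads: Mapping[str, np.ndarray],
    negative_beads: Mapping[str, np.ndarray],
) -> float:
    """Detection P for a single probe: minimum over channels of the
    one-sided Mann-Whitney P of probe beads against the channel's
    negative-control beads.

    For a single probe the Benjamini-Hochberg adjustment is the identity;
    across a full array use :func:`detection_pvalue_matrix`, which adjusts
    within each channel before taking the minimum.
    """
    p_channels = []
    for channel, x in probe_beads.items():
        x = np.asarray(x, dtype=float)
        neg = np.asarray(negative_beads[channel], dtype=float)
        if neg.size == 0:
            raise InputError(f"empty negative-bead pool for channel {channel}")
        if x.size < 3 or neg.size < 10:
            raise InputError(
                "need >= 3 probe beads and >= 10 negative beads per channel"
            )
        p_channels.append(mannwhitney_p(x, neg, alternative="greater"))
    return float(min(p_channels))


def _channel_raw_pvalues(
    bead_matrix: np.ndarray, negatives: np.ndarray
) -> np.ndarray:
    """Vectorized one-sided Mann-Whitney P of each row against ``negatives``."""
    res = sps.mannwhitneyu(
        bead_matrix,
        np.broadcast_to(negatives, (bead_matrix.shape[0], negatives.size)),
        alternative="greater",
        method="asymptotic",
        axis=-1,
    )
    return np.asarray(res.pvalue, dtype=float)


def detection_pvalue_matrix(beads: pd.DataFrame) -> pd.DataFrame:
    """Per-(probe, sample) detection P-values for a whole bead table.

    Within each sample and channel the probe-vs-negative P-values are BH
    adjusted across all probes, then the per-probe minimum over the two
    channels is taken.
    """
    negatives = beads[beads["probe_id"] == NEGATIVE_ID]
    probe_beads = beads[beads["probe_id"] != NEGATIVE_ID]
    if negatives.empty:
        raise InputError("bead table contains no negative-control beads")
    neg_groups = negatives.groupby(["sample_id", "channel"], observed=True)[
        "intensity"
    ]
    neg_pools = {key: grp.to_numpy(dtype=float) for key, grp in neg_groups}
    per_channel: dict[str, pd.DataFrame] = {}
    for channel in CHANNELS:
        chan = probe_beads[probe_beads["channel"] == channel]
        cols = {}
        for sample_id, sample_chan in chan.groupby("sample_id", observed=True):
            neg = neg_pools.get((sample_id, channel))
            if neg is None or neg.size < 10:
                raise InputError(
                    f"sample {sample_id} channel {channel}: insufficient "
                    "negative beads"
                )
            counts = sample_chan.groupby("probe_id", observed=True).size()
            if counts.nunique() == 1:
                ordered = sample_chan.sort_values("probe_id", kind="stable")
                probes = counts.sort_index().index.to_numpy()
                matrix = ordered["intensity"].to_numpy(dtype=float).reshape(
                    probes.size, counts.iloc[0]
                )
                raw = _channel_raw_pvalues(matrix, neg)
            else:  # ragged bead counts: per-probe scalar path
                probes = counts.index.to_numpy()
                raw = np.array([
                    mannwhitney_p(grp.to_numpy(dtype=float), neg,
                                  alternative="greater", method="asymptotic")
                    for _, grp in sample_chan.groupby(
                        "probe_id", observed=True)["intensity"]
                ])
            cols[sample_id] = pd.Series(bh_adjust(raw), index=probes)
        per_channel[channel] = pd.DataFrame(cols)
    aligned = [per_channel[ch] for ch in CHANNELS if ch in per_channel]
    detection = aligned[0]
    for other in aligned[1:]:
        detection = np.minimum(detection, other)
    detection.index.name = "probe_id"
    return detection.sort_index()


def compute_beta(m_intensity, u_intensity, offset: float = DEFAULT_OFFSET):
    """Beta value ``M / (M + U + offset)`` with negatives floored to zero.

    Returns 0 where the denominator is zero (fully degenerate signal).
    """
    if offset < 0:
        raise InputError("offset must be non-negative")
    m = np.maximum(np.asarray(m_intensity, dtype=float), 0.0)
    u = np.maximum(np.asarray(u_intensity, dtype=float), 0.0)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    if beta.ndim == 0:
        return float(beta)
    return beta


def build_beta_matrix(
    summaries: pd.DataFrame, offset: float = DEFAULT_OFFSET
) -> pd.DataFrame:
    """Probes x samples beta matrix from aggregated bead summaries.

    The methylated signal is the green-channel methylated-allele mean, the
    unmethylated signal the red-channel unmethylated-allele mean. Missing
    (probe, sample) combinations become NaN.
    """
    m = summaries[
        (summaries["channel"] == "green")
        & (summaries["allele"] == "methylated")
    ].pivot(index="probe_id", columns="sample_id", values="mean")
    u = summaries[
        (summaries["channel"] == "red")
        & (summaries["allele"] == "unmethylated")
    ].pivot(index="probe_id", columns="sample_id", values="mean")
    m, u = m.align(u)
    beta = pd.DataFrame(
        compute_beta(m.to_numpy(), u.to_numpy(), offset),
        index=m.index, columns=m.columns,
    )
    beta[m.isna() | u.isna()] = np.nan
    beta.columns.name = None
    return beta.sort_index()


def filter_detected(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop probes whose detection P exceeds ``threshold`` in any sample.

    Returns the filtered matrix and an exclusion report (probe, worst P,
    number of failing samples). Raises if nothing survives.
    """
    if not 0 < threshold < 1:
        raise InputError("detection threshold must lie in (0, 1)")
    detection_p = detection_p.reindex(index=beta.index, columns=beta.columns)
    failing = detection_p.gt(threshold)
    excluded_mask = failing.any(axis=1)
    report = pd.DataFrame(
        {
            "max_detection_p": detection_p.max(axis=1)[excluded_mask],
            "n_samples_failing": failing.sum(axis=1)[excluded_mask],
        }
    )
    report.index.name = "probe_id"
    filtered = beta.loc[~excluded_mask]
    if filtered.empty:
        raise PreconditionError(
            "all probes excluded by the detection filter"
        )
    return filtered, report.reset_index()


def group_stats(beta: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Per-probe mean and sd of beta over a sample group (NaN-aware)."""
    missing = [s for s in samples if s not in beta.columns]
    if missing:
        raise InputError(f"samples absent from beta matrix: {missing}")
    sub = beta[list(samples)]
    return pd.DataFrame(
        {"mean": sub.mean(axis=1), "sd": sub.std(axis=1, ddof=1).fillna(0.0)}
    )


@dataclass
class BetaMatrix:
    """Detection-filtered beta values with their provenance."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    excluded: pd.DataFrame
    offset: float = DEFAULT_OFFSET
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD

    @property
    def excluded_fraction(self) -> float:
        n_total = len(self.beta) + len(self.excluded)
        return len(self.excluded) / n_total if n_total else 0.0


def preprocess_beads(
    beads: pd.DataFrame,
    offset: float = DEFAULT_OFFSET,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    normalize: bool = True,
) -> BetaMatrix:
    """Run the full preprocessing chain on a bead table."""
    if beads.empty:
        raise InputError("no beads")
    if normalize:
        beads = normalize_bead_channels(beads)
    summaries = aggregate_beads(beads)
    detection = detection_pvalue_matrix(beads)
    beta = build_beta_matrix(summaries, offset=offset)
    filtered, report = filter_detected(beta, detection, detection_threshold)
    return BetaMatrix(
        beta=filtered,
        detection_p=detection.loc[filtered.index],
        excluded=report,
        offset=offset,
        detection_threshold=detection_threshold,
    )
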