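"""Differential methylation calling between sample groups.

The effect size is the difference of group-mean beta values (delta-beta);
significance comes from a two-sided two-sample Wilcoxon rank-sum test per
probe (exact for the small group sizes of this study design), with
Benjamini-Hochberg adjustment across all retained probes of one comparison.
A marker is called hypermethylated at delta-beta >= 0.2 and hypomethylated
at <= -0.2; optionally the adjusted P < 0.01 requirement is added
("substantial" calls). Counts can then be stratified by CpG-island status
or localized to the X chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "delta_beta",
    "wilcoxon_per_probe",
    "bh_adjust",
    "classify_markers",
    "stratify_by_island",
    "overlap_markers",
    "profile_correlation",
    "x_localization",
    "differential_analysis",
    "DifferentialResult",
]

DELTA_THRESHOLD = 0.2
P_BH_THRESHOLD = 0.01


def _check_groups(beta: pd.DataFrame, group_a, group_b) -> tuple[list, list]:
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise InputError(f"groups overlap: {sorted(overlap)}")
    missing = [s for s in group_a + group_b if s not in beta.columns]
    if missing:
        raise InputError(f"samples absent from beta matrix: {missing}")
    return group_a, group_b


def delta_beta(beta: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Per-probe difference of group means: mean_A(beta) - mean_B(beta).

    Missing values are excluded from the means.
    """
    group_a, group_b = _check_groups(beta, group_a, group_b)
    delta = beta[group_a].mean(axis=1) - beta[group_b].mean(axis=1)
    delta.name = "delta_beta"
    return delta


def wilcoxon_per_probe(beta: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Two-sided Wilcoxon rank-sum P per probe.

    Exact permutation null for group sizes up to 10 per side; probes with
    fewer than two non-missing values in either group return NaN.
    """
    group_a, group_b = _check_groups(beta, group_a, group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("need at least 2 samples per group")
    a = beta[group_a].to_numpy(dtype=float)
    b = beta[group_b].to_numpy(dtype=float)
    p = np.full(len(beta), np.nan)
    complete = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)
    if complete.any():
        p[complete] = wilcoxon_rank_sum(a[complete], b[complete])
    for i in np.flatnonzero(~complete):
        ai = a[i][~np.isnan(a[i])]
        bi = b[i][~np.isnan(b[i])]
        if ai.size >= 2 and bi.size >= 2:
            p[i] = wilcoxon_rank_sum(ai[None, :], bi[None, :])[0]
    return pd.Series(p, index=beta.index, name="p_raw")


def classify_markers(
    delta: pd.Series,
    p_bh: pd.Series | None = None,
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float = P_BH_THRESHOLD,
    require_p: bool = False,
) -> tuple[pd.Series, dict]:
    """Call each probe hyper/hypo/unchanged.

    With ``require_p=False`` the call uses the delta-beta cutoff alone (the
    convention behind marker counts such as "104 of 27,578"); with
    ``require_p=True`` the BH-adjusted P must also fall below
    ``p_threshold`` ("substantially" changed markers).
    """
    if not 0 < delta_threshold <= 1:
        raise InputError("delta_threshold must lie in (0, 1]")
    if require_p and p_bh is None:
        raise InputError("require_p=True needs BH-adjusted P-values")
    hyper = delta >= delta_threshold
    hypo = delta <= -delta_threshold
    if require_p:
        significant = p_bh.reindex(delta.index) < p_threshold
        hyper &= significant
        hypo &= significant
    call = pd.Series("unchanged", index=delta.index, name="call")
    call[hyper] = "hyper"
    call[hypo] = "hypo"
    n = len(call)
    counts = {
        "n_probes": n,
        "n_hyper": int(hyper.sum()),
        "n_hypo": int(hypo.sum()),
        "n_unchanged": int(n - hyper.sum() - hypo.sum()),
        "frac_hyper": float(hyper.sum() / n) if n else 0.0,
        "frac_hypo": float(hypo.sum() / n) if n else 0.0,
    }
    return call, counts


def stratify_by_island(
    results: pd.DataFrame, call: str = "hyper"
) -> tuple[int, int]:
    """(island count, total count) of markers with the given call."""
    called = results[results["call"] == call]
    return int(called["cpg_island"].sum()), len(called)


def overlap_markers(set_a, set_b) -> tuple[set, int, int, int]:
    """Exact intersection of two marker sets with sizes (|A|, |B|, |A&B|)."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return inter, len(a), len(b), len(inter)


def profile_correlation(beta_sample_1, beta_sample_2) -> float:
    """Squared Pearson correlation between two methylation profiles.

    Pairs with a missing value in either profile are dropped; zero variance
    makes the coefficient undefined (NaN, with a warning).
    """
    x = np.asarray(beta_sample_1, dtype=float)
    y = np.asarray(beta_sample_2, dtype=float)
    if x.shape != y.shape:
        raise InputError("profiles must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InputError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def x_localization(
    variable_markers, annotation: pd.DataFrame
) -> tuple[int, int]:
    """(count on chromosome X, total count) for a set of marker ids."""
    markers = list(variable_markers)
    if not markers:
        return 0, 0
    chrom = annotation.set_index("probe_id")["chromosome"] \
        if annotation.index.name != "probe_id" else annotation["chromosome"]
    chrom = chrom.reindex(markers)
    if chrom.isna().any():
        raise InputError("markers missing from annotation")
    return int((chrom == "X").sum()), len(markers)


@dataclass
class DifferentialResult:
    """Full per-probe differential table for one comparison."""

    table: pd.DataFrame
    counts: dict
    counts_with_p: dict
    group_a: list[str]
    group_b: list[str]

    def markers(self, call: str = "hyper", require_p: bool = False) -> set:
        col = "call_p" if require_p else "call"
        return set(self.table.index[self.table[col] == call])


def differential_analysis(
    beta: pd.DataFrame,
    group_a,
    group_b,
    annotation: pd.DataFrame | None = None,
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float = P_BH_THRESHOLD,
) -> DifferentialResult:
    """Delta-beta, Wilcoxon, BH and classification in one pass.

    The returned table carries both the delta-only call (``call``) and the
    call additionally requiring P(BH) < ``p_threshold`` (``call_p``).
    Probes with an undefined test (too few complete values) are dropped
    with a warning.
    """
    delta = delta_beta(beta, group_a, group_b)
    p_raw = wilcoxon_per_probe(beta, group_a, group_b)
    usable = ~p_raw.isna() & ~delta.isna()
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} probes dropped (insufficient complete "
            "values for the rank test)",
            stacklevel=2,
        )
    delta, p_raw = delta[usable], p_raw[usable]
    p_bh = pd.Series(bh_adjust(p_raw.to_numpy()), index=p_raw.index,
                     name="p_bh")
    call, counts = classify_markers(
        delta, p_bh, delta_threshold, p_threshold, require_p=False
    )
    call_p, counts_p = classify_markers(
        delta, p_bh, delta_threshold, p_threshold, require_p=True
    )
    table = pd.DataFrame(
        {"delta_beta": delta, "p_raw": p_raw, "p_bh": p_bh,
         "call": call, "call_p": call_p}
    )
    if annotation is not None:
        ann = annotation.set_index("probe_id") \
            if annotation.index.name != "probe_id" else annotation
        table["cpg_island"] = ann["cpg_island"].reindex(table.index)
        table["chromosome"] = ann["chromosome"].reindex(table.index)
    return DifferentialResult(
        table=table, counts=counts, counts_with_p=counts_p,
        group_a=list(group_a), group_b=list(group_b),
    )
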