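#!/usr/bin/env python
"""Global methylation shift: RS curves and Gaussian-null tests.

For the age and sun contrasts, builds the RS (ratio-over-sum) curve over
probes sorted by |delta-beta| and tests the filtered delta-beta
distribution against a Normal(0, 0.1) null. The marker filter uses the
raw rank-test P < 0.01 (see docs/methods.md for why genome-wide BH at
0.01 cannot bind with five samples per group) plus the sd < 0.1 rule.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

from methylskin import differential_analysis, rs_curve, shift_test
from methylskin import io as mio
from methylskin.global_shift import plot_rs_curves
from methylskin.pipeline import DEFAULT_COMPARISONS, _pooled_sd, select_samples
from methylskin.preprocess import group_stats

SEED = 20100527


def main() -> None:
    if not (SCRATCH / "beta.tsv").exists():
        sys.exit("run analysis/01_simulate_and_preprocess.py first")
    beta = mio.read_beta_matrix(SCRATCH / "beta.tsv")
    design = mio.read_manifest(SCRATCH / "manifest.tsv")

    curves = {}
    tests = {}
    for comp in DEFAULT_COMPARISONS:
        if comp.group_by not in ("age_group", "sun"):
            continue
        group_a = select_samples(design, comp.subset, comp.group_by, comp.a)
        group_b = select_samples(design, comp.subset, comp.group_by, comp.b)
        result = differential_analysis(beta, group_a, group_b)
        stats_a = group_stats(beta, group_a).loc[result.table.index]
        stats_b = group_stats(beta, group_b).loc[result.table.index]
        curve = rs_curve(result.table["delta_beta"],
                         stats_a["mean"] + stats_b["mean"])
        curves[comp.name] = curve
        sd = _pooled_sd(stats_a, stats_b, len(group_a), len(group_b))
        res = shift_test(result.table["delta_beta"],
                         p_values=result.table["p_raw"], sd=sd,
                         p_threshold=0.01, sd_threshold=0.1, seed=SEED)
        tests[comp.name] = res.summary()
        direction = "hyper" if res.mean_delta > 0 else "hypo"
        print(f"{comp.name}: {res.n_markers} markers enter; mean delta "
              f"{res.mean_delta:+.3f} ({direction}methylation), "
              f"t = {res.t_statistic:.1f}, P = {res.p_value:.2e}")
        mio.write_tsv(curve, SCRATCH / f"rs_{comp.name}.tsv")

    plot_rs_curves(curves, ROOT / "scratch" / "rs_curves.png")
    (RESULTS / "shift_tests.json").write_text(
        json.dumps(tests, indent=2) + "\n")
    print(f"wrote {RESULTS / 'shift_tests.json'} and scratch/rs_curves.png")


if __name__ == "__main__":
    main()
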