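#!/usr/bin/env python
"""Call differential methylation for every study contrast.

Reads the preprocessed beta matrix from scratch/study/ (run
01_simulate_and_preprocess.py first) and calls markers for the age, sun,
tissue and sex contrasts at the delta-beta >= 0.2 convention. Writes the
called-marker tables (small) and a counts summary to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

from methylskin import differential_analysis, overlap_markers, x_localization
from methylskin import io as mio
from methylskin.pipeline import DEFAULT_COMPARISONS, select_samples


def main() -> None:
    if not (SCRATCH / "beta.tsv").exists():
        sys.exit("run analysis/01_simulate_and_preprocess.py first")
    beta = mio.read_beta_matrix(SCRATCH / "beta.tsv")
    design = mio.read_manifest(SCRATCH / "manifest.tsv")
    annotation = mio.read_annotation(SCRATCH / "annotation.tsv")
    truth = mio.read_tsv(SCRATCH / "truth_labels.tsv")
    planted_age = set(truth.loc[truth.effect == "age_hyper", "probe_id"])

    counts = {}
    hyper_sets = {}
    for comp in DEFAULT_COMPARISONS:
        group_a = select_samples(design, comp.subset, comp.group_by, comp.a)
        group_b = select_samples(design, comp.subset, comp.group_by, comp.b)
        result = differential_analysis(beta, group_a, group_b,
                                       annotation=annotation)
        counts[comp.name] = result.counts
        hyper_sets[comp.name] = result.markers("hyper")
        called = result.table[result.table["call"] != "unchanged"]
        mio.write_tsv(called.reset_index(), SCRATCH / f"markers_{comp.name}.tsv")
        print(f"{comp.name}: {result.counts['n_hyper']} hyper, "
              f"{result.counts['n_hypo']} hypo "
              f"(of {result.counts['n_probes']})")
        if comp.group_by == "sex":
            variable = result.table.index[
                result.table["delta_beta"].abs() >= 0.2]
            n_x, n_var = x_localization(variable, annotation)
            counts[comp.name]["variable_on_x"] = n_x
            counts[comp.name]["variable_markers"] = n_var
            print(f"  sex-variable markers on X: {n_x}/{n_var}")

    _, n_a, n_b, n_common = overlap_markers(
        hyper_sets["age_blister_epidermis"],
        hyper_sets["age_punch_epidermis"])
    print(f"age-hyper overlap between independent sample sets: "
          f"{n_common} of {n_a} (blister) / {n_b} (punch)")

    recovered = len(hyper_sets["age_blister_epidermis"] & planted_age)
    print(f"planted age-effect recovery: {recovered}/{len(planted_age)}")

    counts["age_overlap_blister_punch"] = n_common
    counts["planted_age_recovered"] = recovered
    (RESULTS / "marker_counts.json").write_text(
        json.dumps(counts, indent=2) + "\n")
    print(f"wrote {RESULTS / 'marker_counts.json'}")


if __name__ == "__main__":
    main()
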