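"""End-to-end orchestration: simulate -> normalize -> detect -> beta ->
differential -> global shift, with all outputs written as commented TSV/JSON.

The default comparisons mirror the study design: age within the blister
and punch-biopsy epidermis sets, sun exposure within the punch biopsies,
epidermis vs dermis, and female vs male epidermis (the X-chromosome
check).

Note on the shift-test filter: the marker filter feeding the Gaussian-null
shift test uses the raw rank-test P < 0.01 rather than the BH-adjusted P.
With five samples per group the exact two-sided Wilcoxon P can never fall
below 2/252 ~ 0.0079, so a genome-wide BH-adjusted threshold of 0.01 is
unattainable at this group size; the raw-P filter is the same selection
rule at the granularity the design supports (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputError, PreconditionError
from . import io as mio
from .differential import (
    differential_analysis,
    profile_correlation,
    stratify_by_island,
    x_localization,
)
from .global_shift import rs_curve, shift_test
from .preprocess import group_stats, preprocess_beads
from .synthetic import (
    EffectSpec,
    default_design,
    make_annotation,
    make_true_betas,
    simulate_beads,
)

__all__ = ["Comparison", "RunConfig", "run_pipeline", "select_samples"]


@dataclass(frozen=True)
class Comparison:
    """One two-group contrast: subset the manifest, then split by a column."""

    name: str
    group_by: str
    a: str
    b: str
    subset: dict = field(default_factory=dict)


DEFAULT_COMPARISONS = [
    Comparison("age_blister_epidermis", "age_group", "old", "young",
               {"sampling": "suction_blister"}),
    Comparison("age_punch_epidermis", "age_group", "old", "young",
               {"sampling": "punch_biopsy", "tissue": "epidermis",
                "sun": "protected"}),
    Comparison("sun_epidermis", "sun", "exposed", "protected",
               {"sampling": "punch_biopsy", "tissue": "epidermis"}),
    Comparison("tissue_epidermis_vs_dermis", "tissue", "epidermis", "dermis",
               {"sampling": "punch_biopsy"}),
    Comparison("sex_young_epidermis", "sex", "female", "male",
               {"tissue": "epidermis", "age_group": "young",
                "sun": "protected"}),
]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-study run."""

    n_probes: int = 27578
    seed: int = 0
    island_fraction: float = 0.73
    x_fraction: float = 0.04
    effects: EffectSpec = field(default_factory=EffectSpec)
    total_intensity_mean: float = 2000.0
    bead_count: int = 15
    noise_cv: float = 0.1
    negative_scale: float = 0.02
    n_negative: int = 150
    beta_offset: float = 100.0
    detection_threshold: float = 0.05
    delta_threshold: float = 0.2
    p_bh_threshold: float = 0.01
    shift_p_raw_threshold: float = 0.01
    shift_sd_threshold: float = 0.1
    null_sd: float = 0.1
    n_null: int = 10_000
    comparisons: list[Comparison] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS)
    )

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("detection_threshold", 0.0, 1.0),
            ("delta_threshold", 0.0, 1.0),
            ("p_bh_threshold", 0.0, 1.0),
            ("shift_p_raw_threshold", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not lo < value < hi:
                raise InputError(f"{name} must lie in ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "effects" in raw:
            raw["effects"] = EffectSpec(**raw["effects"])
        if "comparisons" in raw:
            raw["comparisons"] = [Comparison(**c) for c in raw["comparisons"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [asdict(c) for c in self.comparisons]
        return d


def select_samples(design: pd.DataFrame, subset: dict,
                   column: str, level: str) -> list[str]:
    if column not in design.columns:
        raise InputError(f"manifest has no column {column!r}")
    mask = pd.Series(True, index=design.index)
    for col, value in subset.items():
        if col not in design.columns:
            raise InputError(f"manifest has no column {col!r}")
        mask &= design[col] == value
    mask &= design[column] == level
    samples = design.loc[mask, "sample_id"].to_list()
    if not samples:
        raise InputError(
            f"no samples match subset={subset}, {column}={level!r}"
        )
    return samples


def _pooled_sd(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
               n_a: int, n_b: int) -> pd.Series:
    var = (
        (n_a - 1) * stats_a["sd"] ** 2 + (n_b - 1) * stats_b["sd"] ** 2
    ) / (n_a + n_b - 2)
    return np.sqrt(var)


def run_pipeline(config: RunConfig, out_dir=None,
                 design: pd.DataFrame | None = None,
                 keep_tables: bool = False) -> dict:
    """Run the full analysis on a synthetic study; returns the summary dict.

    When ``out_dir`` is given, every stage's table and a ``summary.json``
    are written there with the config hash in their headers. With
    ``keep_tables`` the summary additionally carries the in-memory
    per-comparison results, truth labels, annotation and beta matrix under
    the ``_objects`` key (never serialized).
    """
    meta = {"config": mio.config_hash(config.to_dict()),
            "version": __version__}
    design = default_design() if design is None else design
    annotation = make_annotation(
        config.n_probes, config.island_fraction, config.x_fraction,
        seed=config.seed,
    )
    true_betas, truth = make_true_betas(
        annotation, design, config.effects, seed=config.seed
    )
    beads = simulate_beads(
        true_betas, design,
        total_intensity_mean=config.total_intensity_mean,
        bead_count=config.bead_count,
        noise_cv=config.noise_cv,
        negative_scale=config.negative_scale,
        n_negative=config.n_negative,
        seed=config.seed,
    )
    matrix = preprocess_beads(
        beads, offset=config.beta_offset,
        detection_threshold=config.detection_threshold,
    )
    beta = matrix.beta

    objects: dict = {
        "annotation": annotation, "truth": truth, "matrix": matrix,
        "design": design, "results": {},
    }
    summary: dict = {
        "seed": config.seed,
        "n_probes": config.n_probes,
        "n_samples": len(design),
        "detection_excluded_fraction": matrix.excluded_fraction,
        "comparisons": {},
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        mio.write_tsv(design, out / "manifest.tsv", meta=meta)
        mio.write_tsv(annotation, out / "annotation.tsv", meta=meta)
        mio.write_tsv(truth.frame().reset_index(), out / "truth_labels.tsv",
                      meta=meta)
        mio.write_beta_matrix(beta, out / "beta.tsv", meta=meta)
        mio.write_beta_matrix(matrix.detection_p, out / "detection_p.tsv",
                              meta=meta)
        mio.write_tsv(matrix.excluded, out / "excluded_probes.tsv", meta=meta)

    for comparison in config.comparisons:
        group_a = select_samples(design, comparison.subset,
                                 comparison.group_by, comparison.a)
        group_b = select_samples(design, comparison.subset,
                                 comparison.group_by, comparison.b)
        result = differential_analysis(
            beta, group_a, group_b, annotation=annotation,
            delta_threshold=config.delta_threshold,
            p_threshold=config.p_bh_threshold,
        )
        table = result.table
        stats_a = group_stats(beta, group_a).loc[table.index]
        stats_b = group_stats(beta, group_b).loc[table.index]
        curve = rs_curve(table["delta_beta"],
                         stats_a["mean"] + stats_b["mean"])
        sd = _pooled_sd(stats_a, stats_b, len(group_a), len(group_b))
        try:
            shift = shift_test(
                table["delta_beta"], p_values=table["p_raw"], sd=sd,
                p_threshold=config.shift_p_raw_threshold,
                sd_threshold=config.shift_sd_threshold,
                null_sd=config.null_sd, n_null=config.n_null,
                seed=config.seed,
            ).summary()
        except PreconditionError as exc:
            shift = {"error": str(exc)}
        n_island_hyper, n_hyper = stratify_by_island(table, "hyper")
        comp_summary = {
            "group_a": group_a,
            "group_b": group_b,
            "counts_delta_only": result.counts,
            "counts_with_p": result.counts_with_p,
            "hyper_island": n_island_hyper,
            "hyper_total": n_hyper,
            "rs_final_ratio": float(curve["y"].iloc[-1]),
            "shift_test": shift,
        }
        if comparison.group_by == "sex":
            variable = set(
                table.index[table["delta_beta"].abs()
                            >= config.delta_threshold]
            )
            n_x, n_var = x_localization(variable, annotation)
            comp_summary["variable_markers"] = n_var
            comp_summary["variable_on_x"] = n_x
        summary["comparisons"][comparison.name] = comp_summary
        objects["results"][comparison.name] = result
        if out is not None:
            mio.write_tsv(table.reset_index(), out / f"diff_{comparison.name}.tsv",
                          meta=meta)
            mio.write_tsv(curve, out / f"rs_{comparison.name}.tsv", meta=meta)

    # interindividual similarity within the young blister replicate group
    replicate_group = design.loc[
        (design["age_group"] == "young") & (design["sex"] == "male"),
        "sample_id",
    ].to_list()
    if len(replicate_group) >= 2:
        pairs = [
            profile_correlation(beta[a], beta[b])
            for i, a in enumerate(replicate_group)
            for b in replicate_group[i + 1:]
        ]
        summary["replicate_r2_min"] = float(min(pairs))
        summary["replicate_r2_max"] = float(max(pairs))

    if out is not None:
        mio.write_json(summary, out / "summary.json", meta=meta)
    if keep_tables:
        summary["_objects"] = objects
    return summary
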