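"""Synthetic bead-level array data and bisulfite reads.

Emulates a two-channel 27,578-probe methylation BeadChip study of human
skin: a bimodal beta-value architecture (CpG-island probes mostly
unmethylated, non-island probes much more often methylated), planted
age-related hypermethylation at a small fraction of markers, sun-exposure
hypomethylation at an even smaller fraction, tissue-differential markers
between epidermis and dermis, and X-chromosome hypermethylation in female
samples. Bead intensities get multiplicative lognormal noise;
negative-control beads are drawn from a low-intensity distribution.

Ground-truth effect subsets are sampled disjointly and only from probes
whose baseline leaves room for the full shift (baseline <= 1-delta for
hypermethylation, >= delta for hypomethylation), so the planted effect size
is exact rather than censored by the [0, 1] clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import find_cpg_sites
from .errors import InputError

__all__ = [
    "CHROMOSOMES",
    "EffectSpec",
    "TruthLabels",
    "make_annotation",
    "make_design",
    "default_design",
    "make_true_betas",
    "simulate_beads",
    "simulate_bisulfite_reads",
]

AUTOSOMES = [str(i) for i in range(1, 23)]
CHROMOSOMES = AUTOSOMES + ["X", "Y"]

TISSUES = ("epidermis", "dermis")
AGE_GROUPS = ("young", "old")
SUN = ("exposed", "protected")
SEXES = ("male", "female")
SAMPLING = ("suction_blister", "punch_biopsy")

#: probe universe of the array generation being emulated
N_PROBES_DEFAULT = 27578


@dataclass(frozen=True)
class EffectSpec:
    """Planted-effect magnitudes and baseline beta architecture.

    Defaults encode the study conditions: ~0.4% of markers age-hypermethylated
    (110 of 27,578) with most of them CpG-island associated, ~0.05%
    sun-hypomethylated (14 of 27,578), ~6.4% tissue-differential (1,776 of
    27,578, of which 742 are epidermis-hyper), all at a delta-beta of 0.3,
    and a +0.3 shift of X-chromosome probes in females. Baseline fractions:
    86% of island probes unmethylated, 5% methylated; 29% of non-island
    probes methylated.
    """

    frac_age_hyper: float = 110 / N_PROBES_DEFAULT
    age_delta: float = 0.3
    frac_sun_hypo: float = 14 / N_PROBES_DEFAULT
    sun_delta: float = 0.3
    frac_tissue_diff: float = (742 + 1034) / N_PROBES_DEFAULT
    tissue_delta: float = 0.3
    x_female_beta_shift: float = 0.3
    island_unmeth_frac: float = 0.86
    island_meth_frac: float = 0.05
    non_island_meth_frac: float = 0.29
    #: fraction of age-effect probes drawn from CpG-island probes (90/104)
    age_island_frac: float = 90 / 104
    #: epidermis-hyper share of the tissue-differential set (742/1776)
    tissue_epi_frac: float = 742 / (742 + 1034)
    #: mid-methylation (uniform) component weight for non-island probes
    non_island_mid_frac: float = 0.20

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not 0.0 <= value <= 1.0:
                raise InputError(f"EffectSpec.{f.name} must lie in [0, 1]")
        if self.island_unmeth_frac + self.island_meth_frac > 1.0:
            raise InputError("island component weights exceed 1")
        if self.non_island_meth_frac + self.non_island_mid_frac > 1.0:
            raise InputError("non-island component weights exceed 1")


@dataclass
class TruthLabels:
    """Ground-truth effect membership; the subsets are disjoint."""

    age_hyper: list[str]
    sun_hypo: list[str]
    tissue_epidermis_hyper: list[str]
    tissue_dermis_hyper: list[str]
    baseline: pd.Series

    def frame(self) -> pd.DataFrame:
        effect = pd.Series("none", index=self.baseline.index, name="effect")
        effect[self.age_hyper] = "age_hyper"
        effect[self.sun_hypo] = "sun_hypo"
        effect[self.tissue_epidermis_hyper] = "tissue_epidermis_hyper"
        effect[self.tissue_dermis_hyper] = "tissue_dermis_hyper"
        return pd.DataFrame({"effect": effect, "baseline_beta": self.baseline})


def make_annotation(
    n_probes: int = N_PROBES_DEFAULT,
    island_fraction: float = 0.73,
    x_fraction: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe annotation: unique ids, chromosome, CpG-island flag.

    Exactly ``round(n_probes * island_fraction)`` probes are island-associated
    and ``round(n_probes * x_fraction)`` sit on chromosome X; the rest are
    spread uniformly over the autosomes.
    """
    if n_probes <= 0:
        raise InputError("n_probes must be positive")
    if not (0 <= island_fraction <= 1 and 0 <= x_fraction <= 1):
        raise InputError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x414E]))
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    chromosome = rng.choice(AUTOSOMES, size=n_probes)
    n_x = round(n_probes * x_fraction)
    x_idx = rng.choice(n_probes, size=n_x, replace=False)
    chromosome[x_idx] = "X"
    island = np.zeros(n_probes, dtype=bool)
    n_island = round(n_probes * island_fraction)
    island[rng.choice(n_probes, size=n_island, replace=False)] = True
    gene = [f"GENE{i // 2:05d}" for i in range(n_probes)]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chromosome,
            "cpg_island": island,
            "gene_symbol": gene,
        }
    ).set_index("probe_id", drop=False)


def make_design(groups: Sequence[dict], n_per_group: int = 5) -> pd.DataFrame:
    """Build a sample manifest from group descriptors.

    Each descriptor needs ``tissue``, ``age_group``, ``sun``, ``sex``,
    ``sampling`` and a ``label`` used to derive sample ids.
    """
    rows = []
    for grp in groups:
        for i in range(1, n_per_group + 1):
            row = {k: grp[k] for k in
                   ("tissue", "age_group", "sun", "sex", "sampling")}
            row["sample_id"] = f"{grp['label']}_{i}"
            rows.append(row)
    design = pd.DataFrame(rows)[
        ["sample_id", "tissue", "age_group", "sun", "sex", "sampling"]
    ]
    validate_design(design)
    return design.set_index("sample_id", drop=False)


def validate_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        raise InputError("sample_id values must be unique")
    allowed = {
        "tissue": TISSUES, "age_group": AGE_GROUPS, "sun": SUN,
        "sex": SEXES, "sampling": SAMPLING,
    }
    for col, values in allowed.items():
        bad = set(design[col]) - set(values)
        if bad:
            raise InputError(f"invalid {col} value(s): {sorted(bad)}")


def default_design() -> pd.DataFrame:
    """The 50-sample study layout.

    Ten suction-blister epidermis samples from male donors (5 young, 5 old,
    sun-protected volar forearm) and forty punch-biopsy samples from ten
    female donors (5 young, 5 old), each contributing epidermis and dermis
    from a sun-exposed (outer forearm) and a sun-protected (inner arm) site.
    """
    groups = [
        dict(label="SB_YM", tissue="epidermis", age_group="young",
             sun="protected", sex="male", sampling="suction_blister"),
        dict(label="SB_OM", tissue="epidermis", age_group="old",
             sun="protected", sex="male", sampling="suction_blister"),
    ]
    for tissue in TISSUES:
        for sun in SUN:
            for age in AGE_GROUPS:
                groups.append(
                    dict(
                        label=f"PB_{age[0].upper()}F_{tissue[:3]}_{sun[:4]}",
                        tissue=tissue, age_group=age, sun=sun, sex="female",
                        sampling="punch_biopsy",
                    )
                )
    return make_design(groups, n_per_group=5)


def _draw_baseline(
    rng: np.random.Generator, island: np.ndarray, spec: EffectSpec
) -> np.ndarray:
    """Three-component baseline mixture.

    Unmethylated probes ~ Beta(1, 20), methylated ~ Beta(20, 1),
    intermediate ~ Uniform(0.2, 0.8); component weights differ by island
    status (islands mostly unmethylated).
    """
    n = island.size
    island_mid = 1.0 - spec.island_unmeth_frac - spec.island_meth_frac
    weights = np.where(
        island[:, None],
        np.array([[spec.island_unmeth_frac, spec.island_meth_frac, island_mid]]),
        np.array([[1.0 - spec.non_island_meth_frac - spec.non_island_mid_frac,
                   spec.non_island_meth_frac, spec.non_island_mid_frac]]),
    )
    u = rng.random(n)
    component = (u[:, None] >= np.cumsum(weights, axis=1)).sum(axis=1)
    low = rng.beta(1.0, 20.0, size=n)
    high = rng.beta(20.0, 1.0, size=n)
    mid = rng.uniform(0.2, 0.8, size=n)
    return np.select([component == 0, component == 1], [low, high], default=mid)


def _sample_subset(
    rng: np.random.Generator, pool: np.ndarray, size: int, what: str
) -> np.ndarray:
    if size > pool.size:
        raise InputError(
            f"cannot plant {size} {what} probes: only {pool.size} eligible "
            "probes remain (effect fractions overlap beyond the probe count)"
        )
    return rng.choice(pool, size=size, replace=False)


def make_true_betas(
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    spec: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Ground-truth beta per (probe, sample) plus effect membership.

    The baseline draw is shared by all samples of a probe; group effects are
    added per sample (age hypermethylation for old donors, sun
    hypomethylation at exposed sites, tissue shifts for dermis relative to
    the epidermis baseline, X hypermethylation in females) and the result is
    clamped to [0, 1].
    """
    spec = spec or EffectSpec()
    ss = np.random.SeedSequence([seed, 0xBE7A])
    rng_base, rng_subset = [np.random.default_rng(s) for s in ss.spawn(2)]
    probes = annotation["probe_id"].to_numpy()
    island = annotation["cpg_island"].to_numpy()
    n = probes.size
    baseline = _draw_baseline(rng_base, island, spec)

    # floor with a tolerance so fractions defined as k/n plant exactly k
    def _count(frac: float) -> int:
        return int(np.floor(n * frac + 1e-9))

    n_age = _count(spec.frac_age_hyper)
    n_sun = _count(spec.frac_sun_hypo)
    n_tissue = _count(spec.frac_tissue_diff)
    n_tissue_epi = int(round(n_tissue * spec.tissue_epi_frac))

    taken = np.zeros(n, dtype=bool)

    def pool(mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(mask & ~taken)

    hyper_ok = baseline <= 1.0 - spec.age_delta
    n_age_island = int(round(n_age * spec.age_island_frac))
    age_idx = np.concatenate([
        _sample_subset(rng_subset, pool(hyper_ok & island), n_age_island,
                       "age-hyper island"),
        _sample_subset(rng_subset, pool(hyper_ok & ~island),
                       n_age - n_age_island, "age-hyper non-island"),
    ]).astype(np.intp)
    taken[age_idx] = True

    sun_idx = _sample_subset(
        rng_subset, pool(baseline >= spec.sun_delta), n_sun, "sun-hypo"
    )
    taken[sun_idx] = True

    tissue_epi_idx = _sample_subset(
        rng_subset, pool(baseline >= spec.tissue_delta), n_tissue_epi,
        "epidermis-hyper",
    )
    taken[tissue_epi_idx] = True
    tissue_derm_idx = _sample_subset(
        rng_subset, pool(baseline <= 1.0 - spec.tissue_delta),
        n_tissue - n_tissue_epi, "dermis-hyper",
    )
    taken[tissue_derm_idx] = True

    on_x = (annotation["chromosome"] == "X").to_numpy()

    betas = np.tile(baseline[:, None], (1, len(design)))
    for j, (_, sample) in enumerate(design.iterrows()):
        if sample["age_group"] == "old":
            betas[age_idx, j] += spec.age_delta
        if sample["sun"] == "exposed":
            betas[sun_idx, j] -= spec.sun_delta
        if sample["tissue"] == "dermis":
            betas[tissue_derm_idx, j] += spec.tissue_delta
            betas[tissue_epi_idx, j] -= spec.tissue_delta
        if sample["sex"] == "female":
            betas[on_x, j] += spec.x_female_beta_shift
    np.clip(betas, 0.0, 1.0, out=betas)

    beta_df = pd.DataFrame(
        betas, index=pd.Index(probes, name="probe_id"),
        columns=design["sample_id"].to_list(),
    )
    truth = TruthLabels(
        age_hyper=sorted(probes[age_idx]),
        sun_hypo=sorted(probes[sun_idx]),
        tissue_epidermis_hyper=sorted(probes[tissue_epi_idx]),
        tissue_dermis_hyper=sorted(probes[tissue_derm_idx]),
        baseline=pd.Series(baseline, index=beta_df.index, name="baseline_beta"),
    )
    return beta_df, truth


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_beads(
    true_betas: pd.DataFrame,
    design: pd.DataFrame,
    total_intensity_mean: float = 2000.0,
    bead_count: int = 15,
    noise_cv: float = 0.1,
    negative_scale: float = 0.02,
    n_negative: int = 150,
    negative_cv: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Bead-level two-channel intensities for every sample.

    Per probe and sample, the methylated-allele beads (green channel) have
    mean ``total * beta`` and the unmethylated-allele beads (red channel)
    mean ``total * (1 - beta)``, with multiplicative lognormal noise at the
    given coefficient of variation. Negative-control beads (probe_id
    ``NEGATIVE``) are drawn per channel from a low-intensity lognormal with
    mean ``total * negative_scale``.
    """
    if total_intensity_mean <= 0:
        raise InputError("total_intensity_mean must be positive")
    if bead_count < 3:
        raise InputError("bead_count must be at least 3")
    if not 0 <= noise_cv < 1:
        raise InputError("noise_cv must lie in [0, 1)")
    if n_negative < 100:
        raise InputError("need at least 100 negative-control beads per channel")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEAD]))
    probes = true_betas.index.to_numpy()
    n_probes = probes.size
    sample_frames = []
    probe_col = np.repeat(probes, bead_count)
    neg_mean = total_intensity_mean * negative_scale
    for sample_id in design["sample_id"]:
        beta = true_betas[sample_id].to_numpy()
        frames = {}
        for channel, allele, level in (
            ("green", "methylated", beta),
            ("red", "unmethylated", 1.0 - beta),
        ):
            means = np.repeat(total_intensity_mean * level, bead_count)
            intensities = means * _lognormal_factors(
                rng, noise_cv, n_probes * bead_count
            )
            frames[(channel, allele)] = intensities
        neg = {
            channel: neg_mean * _lognormal_factors(rng, negative_cv, n_negative)
            for channel in ("green", "red")
        }
        for (channel, allele), intensities in frames.items():
            sample_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "probe_id": probe_col,
                        "channel": channel,
                        "allele": allele,
                        "intensity": intensities,
                    }
                )
            )
        for channel in ("green", "red"):
            sample_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "probe_id": "NEGATIVE",
                        "channel": channel,
                        "allele": "-",
                        "intensity": neg[channel],
                    }
                )
            )
    beads = pd.concat(sample_frames, ignore_index=True)
    for col in ("sample_id", "probe_id", "channel", "allele"):
        beads[col] = beads[col].astype("category")
    beads["intensity"] = beads["intensity"].clip(lower=0.0)
    return beads


def simulate_bisulfite_reads(
    amplicon_sequence: str,
    cpg_meth_probs: Sequence[float],
    n_reads: int,
    conversion_rate: float = 0.995,
    seed: int = 0,
) -> list[SeqRecord]:
    """Full-length bisulfite reads from an amplicon.

    Each CpG cytosine stays C (methylated) with its site probability and is
    converted to T otherwise; every non-CpG cytosine converts to T with
    probability ``conversion_rate`` (deamination efficiency). Reads are
    error-free apart from conversion.
    """
    seq = amplicon_sequence.upper()
    cpg_positions = find_cpg_sites(seq)
    if not cpg_positions:
        raise InputError("amplicon contains no CpG dinucleotide")
    probs = np.asarray(cpg_meth_probs, dtype=float)
    if probs.size != len(cpg_positions):
        raise InputError(
            f"got {probs.size} methylation probabilities for "
            f"{len(cpg_positions)} CpG sites"
        )
    if np.any((probs < 0) | (probs > 1)):
        raise InputError("methylation probabilities must lie in [0, 1]")
    if not 0 < conversion_rate <= 1:
        raise InputError("conversion_rate must lie in (0, 1]")
    if n_reads <= 0:
        raise InputError("n_reads must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB15F]))
    base = np.frombuffer(seq.encode(), dtype="S1")
    cpg_set = set(cpg_positions)
    other_c = np.array(
        [i for i, b in enumerate(seq) if b == "C" and i not in cpg_set],
        dtype=np.intp,
    )
    cpg_arr = np.asarray(cpg_positions, dtype=np.intp)
    reads = []
    for i in range(n_reads):
        out = base.copy()
        meth = rng.random(cpg_arr.size) < probs
        out[cpg_arr[~meth]] = b"T"
        if other_c.size:
            converted = rng.random(other_c.size) < conversion_rate
            out[other_c[converted]] = b"T"
        reads.append(
            SeqRecord(Seq(out.tobytes().decode()), id=f"read_{i:05d}",
                      description="")
        )
    return reads
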