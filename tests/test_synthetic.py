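"""Generator behaviour: counts, determinism, distributions, effect planting."""

import numpy as np
import pandas as pd
import pytest

from methylskin import (
    EffectSpec,
    default_design,
    make_annotation,
    make_design,
    make_true_betas,
    simulate_beads,
    simulate_bisulfite_reads,
)
from methylskin.errors import InputError
from methylskin.synthetic import CHROMOSOMES


class TestAnnotation:
    def test_counts_forced_by_rounding(self):
        ann = make_annotation(1000, island_fraction=0.7, x_fraction=0.04,
                              seed=1)
        assert ann["cpg_island"].sum() == 700
        assert (ann["chromosome"] == "X").sum() == 40

    def test_unique_ids_and_allowed_chromosomes(self):
        ann = make_annotation(27578, island_fraction=0.73, x_fraction=0.04,
                              seed=7)
        assert ann["probe_id"].is_unique
        assert len(ann) == 27578
        assert set(ann["chromosome"]) <= set(CHROMOSOMES)

    def test_deterministic_given_seed(self):
        a = make_annotation(500, seed=42)
        b = make_annotation(500, seed=42)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(make_annotation(500, seed=43))

    def test_rejects_nonpositive_n(self):
        with pytest.raises(InputError):
            make_annotation(0)


class TestTrueBetas:
    def test_planted_counts_match_fractions(self):
        ann = make_annotation(27578, seed=2)
        design = default_design()
        spec = EffectSpec(frac_age_hyper=0.004)
        _, truth = make_true_betas(ann, design, spec, seed=2)
        assert len(truth.age_hyper) == int(27578 * 0.004)  # floor -> 110
        assert len(truth.sun_hypo) == 14

    def test_effect_subsets_disjoint(self, small_annotation, small_design):
        spec = EffectSpec(frac_age_hyper=0.1, frac_sun_hypo=0.1,
                          frac_tissue_diff=0.2)
        _, truth = make_true_betas(small_annotation, small_design, spec,
                                   seed=5)
        sets = [set(truth.age_hyper), set(truth.sun_hypo),
                set(truth.tissue_epidermis_hyper),
                set(truth.tissue_dermis_hyper)]
        assert sum(len(s) for s in sets) == len(set().union(*sets))

    def test_no_effect_case_columns_identical(self, small_annotation):
        design = default_design()
        spec = EffectSpec(frac_age_hyper=0, frac_sun_hypo=0,
                          frac_tissue_diff=0, x_female_beta_shift=0)
        betas, _ = make_true_betas(small_annotation, design, spec, seed=9)
        # same baseline draw everywhere: every column equals the first
        assert np.allclose(betas.to_numpy(),
                           betas.iloc[:, [0]].to_numpy())

    def test_island_unmethylated_fraction(self):
        """Island probes with beta < 0.2 sit near the 86% architecture."""
        ann = make_annotation(20000, seed=4)
        design = default_design()
        spec = EffectSpec(frac_age_hyper=0, frac_sun_hypo=0,
                          frac_tissue_diff=0, x_female_beta_shift=0)
        betas, _ = make_true_betas(ann, design, spec, seed=4)
        island = ann["cpg_island"].to_numpy()
        frac = (betas.iloc[:, 0].to_numpy()[island] < 0.2).mean()
        assert frac == pytest.approx(0.86, abs=0.02)

    def test_betas_bounded_and_deterministic(self, small_annotation,
                                             small_design):
        b1, t1 = make_true_betas(small_annotation, small_design, seed=8)
        b2, _ = make_true_betas(small_annotation, small_design, seed=8)
        pd.testing.assert_frame_equal(b1, b2)
        assert float(b1.min().min()) >= 0.0
        assert float(b1.max().max()) <= 1.0

    def test_overflowing_effect_request_rejected(self, small_annotation,
                                                 small_design):
        with pytest.raises(InputError, match="eligible"):
            make_true_betas(small_annotation, small_design,
                            EffectSpec(frac_age_hyper=0.99,
                                       frac_tissue_diff=0.5), seed=1)

    def test_planted_age_delta_is_exact(self, small_annotation):
        """The +0.3 label is the realized shift, never clamp-censored."""
        design = default_design()
        spec = EffectSpec(frac_age_hyper=0.1)
        betas, truth = make_true_betas(small_annotation, design, spec, seed=6)
        males = design[design["sex"] == "male"]
        old = males[males["age_group"] == "old"]["sample_id"].iloc[0]
        young = males[males["age_group"] == "young"]["sample_id"].iloc[0]
        diff = betas.loc[truth.age_hyper, old] - betas.loc[truth.age_hyper,
                                                           young]
        assert np.allclose(diff, spec.age_delta)


class TestSimulateBeads:
    def test_symmetric_beta_means_equal_without_noise(self, small_design):
        betas = pd.DataFrame(
            0.5, index=pd.Index(["p1"], name="probe_id"),
            columns=small_design["sample_id"],
        )
        beads = simulate_beads(betas, small_design, noise_cv=0.0, seed=1)
        probe = beads[beads["probe_id"] == "p1"]
        meth = probe[probe["allele"] == "methylated"]["intensity"]
        unmeth = probe[probe["allele"] == "unmethylated"]["intensity"]
        assert np.allclose(meth.to_numpy(), unmeth.to_numpy())

    def test_fully_methylated_floors_unmethylated_at_zero(self, small_design):
        betas = pd.DataFrame(
            1.0, index=pd.Index(["p1"], name="probe_id"),
            columns=small_design["sample_id"],
        )
        beads = simulate_beads(betas, small_design, noise_cv=0.0, seed=1)
        unmeth = beads[(beads["probe_id"] == "p1")
                       & (beads["allele"] == "unmethylated")]["intensity"]
        assert (unmeth == 0).all()

    def test_bead_mean_within_clt_bound(self, small_design):
        """beta=0.6, total=2000, cv=0.1, 15 beads: mean within 3 se of 1200."""
        one_sample = small_design.iloc[:1]
        betas = pd.DataFrame(
            0.6, index=pd.Index(["p1"], name="probe_id"),
            columns=one_sample["sample_id"],
        )
        beads = simulate_beads(betas, one_sample, total_intensity_mean=2000,
                               bead_count=15, noise_cv=0.1, seed=3)
        meth = beads[(beads["probe_id"] == "p1")
                     & (beads["allele"] == "methylated")]["intensity"]
        assert len(meth) == 15
        assert abs(meth.mean() - 1200) < 3 * (0.1 * 1200) / np.sqrt(15)

    def test_negative_bead_pool_present(self, small_design):
        betas = pd.DataFrame(
            0.5, index=pd.Index(["p1", "p2"], name="probe_id"),
            columns=small_design["sample_id"],
        )
        beads = simulate_beads(betas, small_design, seed=2)
        negs = beads[beads["probe_id"] == "NEGATIVE"]
        counts = negs.groupby(["sample_id", "channel"], observed=True).size()
        assert (counts >= 100).all()
        assert (beads["intensity"] >= 0).all()

    def test_determinism_and_bead_count_floor(self, small_design):
        betas = pd.DataFrame(
            0.3, index=pd.Index(["p1"], name="probe_id"),
            columns=small_design["sample_id"],
        )
        b1 = simulate_beads(betas, small_design, seed=5)
        b2 = simulate_beads(betas, small_design, seed=5)
        pd.testing.assert_frame_equal(b1, b2)
        with pytest.raises(InputError):
            simulate_beads(betas, small_design, bead_count=2)


class TestBisulfiteReads:
    AMPLICON = "TTACGTTCGATCCATTACCGTT"  # CpGs at 3, 7, 18; non-CpG Cs at 12, 16

    def test_full_conversion_no_cytosines_left(self):
        reads = simulate_bisulfite_reads(self.AMPLICON, [0, 0, 0], 20,
                                         conversion_rate=1.0, seed=1)
        assert all("C" not in str(r.seq) for r in reads)

    def test_full_methylation_retains_cpg_c_only(self):
        reads = simulate_bisulfite_reads(self.AMPLICON, [1, 1, 1], 20,
                                         conversion_rate=1.0, seed=1)
        for r in reads:
            seq = str(r.seq)
            assert [i for i, b in enumerate(seq) if b == "C"] == [3, 7, 18]
            assert len(seq) == len(self.AMPLICON)

    def test_site_fraction_within_binomial_bound(self):
        """prob 0.61 at 500 reads: within 3*sqrt(p(1-p)/n) of 0.61."""
        reads = simulate_bisulfite_reads("AACGAA", [0.61], 500, seed=2)
        frac = np.mean([str(r.seq)[2] == "C" for r in reads])
        assert abs(frac - 0.61) < 3 * np.sqrt(0.61 * 0.39 / 500)

    def test_rejects_mismatched_probability_list(self):
        with pytest.raises(InputError, match="CpG sites"):
            simulate_bisulfite_reads(self.AMPLICON, [0.5], 10)

    def test_rejects_amplicon_without_cpg(self):
        with pytest.raises(InputError, match="no CpG"):
            simulate_bisulfite_reads("ATTATTA", [], 10)


def test_make_design_rejects_bad_levels():
    with pytest.raises(InputError, match="tissue"):
        make_design([dict(label="G", tissue="muscle", age_group="young",
                          sun="exposed", sex="male",
                          sampling="punch_biopsy")])
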