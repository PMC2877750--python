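"""Preprocessing: quantile normalization, aggregation, detection, beta."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from methylskin import (
    aggregate_beads,
    compute_beta,
    detection_pvalue,
    detection_pvalue_matrix,
    filter_detected,
    preprocess_beads,
    quantile_normalize,
    quantile_normalize_channel,
    simulate_beads,
)
from methylskin.errors import InputError, PreconditionError
from methylskin.preprocess import normalize_bead_channels
from .test_stats import oracle_onesided_greater_p


class TestQuantileNormalize:
    def test_two_sample_worked_example(self):
        out = quantile_normalize({"s1": [1, 2, 3], "s2": [2, 4, 6]})
        assert np.allclose(out["s1"], [1.5, 3.0, 4.5])
        assert np.allclose(out["s2"], [1.5, 3.0, 4.5])

    def test_identical_distributions_unchanged(self):
        x = np.array([5.0, 1.0, 3.0])
        out = quantile_normalize({"a": x, "b": x[::-1]})
        assert np.allclose(out["a"], x)
        assert np.allclose(out["b"], x[::-1])

    @given(hnp.arrays(np.float64, (4, 30),
                      elements=st.floats(0, 1e5, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_column_distributions_exactly_equal(self, matrix):
        # tie-free within each sample (ties legitimately split the
        # reference values they span)
        jitter = np.linspace(0, 1e-6, matrix.shape[1])
        matrix = matrix + jitter[None, :]
        out = quantile_normalize_channel(matrix)
        sorted_rows = np.sort(out, axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0], atol=1e-9)
        # within-sample rank order preserved
        for raw, norm in zip(matrix, out):
            assert np.all(np.diff(norm[np.argsort(raw, kind="stable")])
                          >= -1e-12)

    def test_tie_handling_averages_reference(self):
        out = quantile_normalize({"a": [1.0, 1.0, 5.0], "b": [1.0, 3.0, 9.0]})
        # sample a's tied pair shares the mean of the two lowest refs
        assert out["a"][0] == out["a"][1]
        assert np.allclose(np.sort(out["b"]), np.sort([1.0, 2.0, 7.0]))

    def test_unequal_lengths_interpolated(self):
        out = quantile_normalize({"a": np.arange(10.0),
                                  "b": np.arange(0.0, 20, 4)})
        assert out["a"].size == 10 and out["b"].size == 5
        assert np.all(np.diff(out["b"]) > 0)

    def test_single_sample_identity_with_warning(self):
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize({"only": [3.0, 1.0]})
        assert np.allclose(out["only"], [3.0, 1.0])

    def test_matches_limma_normalize_quantiles(self, rng):
        """Independent oracle: limma::normalizeQuantiles on a tie-free matrix."""
        matrix = rng.random((6, 4))  # values x samples for limma
        values = ",".join(repr(float(v)) for v in matrix.ravel(order="F"))
        script = (
            "suppressMessages(library(limma));"
            f"m <- matrix(c({values}), ncol=4);"
            "cat(sprintf('%.12f', normalizeQuantiles(m)), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        expected = np.fromstring(out.stdout, sep="\n").reshape((6, 4),
                                                               order="F")
        ours = quantile_normalize_channel(matrix.T).T
        assert np.allclose(ours, expected, atol=1e-9)


class TestAggregateBeads:
    @staticmethod
    def bead_frame(intensities, probe="p1", sample="s1"):
        return pd.DataFrame({
            "sample_id": sample, "probe_id": probe, "channel": "green",
            "allele": "methylated", "intensity": intensities,
        })

    def test_hand_mean_and_sd(self):
        out = aggregate_beads(self.bead_frame([100.0, 200.0, 300.0]))
        assert out["mean"].iloc[0] == 200.0
        assert out["sd"].iloc[0] == 100.0  # sample sd, n-1
        assert out["n_beads"].iloc[0] == 3

    def test_single_bead_sd_zero(self):
        out = aggregate_beads(self.bead_frame([150.0]))
        assert out["mean"].iloc[0] == 150.0
        assert out["sd"].iloc[0] == 0.0

    def test_permutation_invariance(self, rng):
        values = rng.random(20) * 1000
        a = aggregate_beads(self.bead_frame(values))
        b = aggregate_beads(self.bead_frame(rng.permutation(values)))
        pd.testing.assert_frame_equal(a, b)

    def test_negative_controls_excluded(self):
        beads = pd.concat([
            self.bead_frame([1.0, 2.0]),
            self.bead_frame([5.0], probe="NEGATIVE"),
        ])
        out = aggregate_beads(beads)
        assert set(out["probe_id"]) == {"p1"}


class TestDetection:
    def test_separated_probe_exact_p(self):
        p = detection_pvalue(
            {"green": np.arange(100, 105), "red": np.arange(200, 205)},
            {"green": np.arange(5, 25), "red": np.arange(5, 25)},
        )
        assert p == pytest.approx(1 / 53130, rel=1e-12)

    def test_all_tied_midrank_half(self):
        p = detection_pvalue(
            {"green": [5.0] * 5, "red": [5.0] * 5},
            {"green": [5.0] * 20, "red": [5.0] * 20},
        )
        assert p == pytest.approx(0.5)

    def test_small_input_matches_enumeration_oracle(self, rng):
        """Exact branch agrees with brute-force U enumeration (<=8 beads)."""
        for _ in range(30):
            x = rng.random(int(rng.integers(3, 9)))
            neg = rng.random(12)
            p = detection_pvalue({"green": x, "red": x + 5},
                                 {"green": neg, "red": neg})
            expected = min(oracle_onesided_greater_p(x, neg),
                           oracle_onesided_greater_p(x + 5, neg))
            assert p == pytest.approx(expected, rel=1e-10)

    def test_requires_negative_pool(self):
        with pytest.raises(InputError):
            detection_pvalue({"green": [1.0, 2.0, 3.0]}, {"green": []})

    def test_matrix_null_uniformity(self, rng):
        """Probe beads drawn from the negative distribution give ~uniform
        detection P over replicates (fresh negative pool per replicate;
        a shared pool correlates the P-values)."""
        from scipy import stats as sps

        probes = rng.lognormal(3.0, 0.5, size=(5000, 15))
        negatives = rng.lognormal(3.0, 0.5, size=(5000, 150))
        p = sps.mannwhitneyu(probes, negatives, alternative="greater",
                             method="asymptotic", axis=-1).pvalue
        assert sps.kstest(p, "uniform").statistic < 0.05


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,offset,expected",
        [(1000, 1000, 0, 0.5), (0, 2000, 100, 0.0), (300, 100, 100, 0.6),
         (0, 0, 0, 0.0), (-50, 100, 0, 0.0)],
    )
    def test_examples(self, m, u, offset, expected):
        assert compute_beta(m, u, offset) == pytest.approx(expected)

    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0.1, 1e4),
           st.floats(0.1, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_m_and_u(self, m, u, dm, offset):
        base = compute_beta(m, u, offset)
        assert compute_beta(m + dm, u, offset) >= base
        assert compute_beta(m, u + dm, offset) <= base
        assert 0.0 <= base <= 1.0

    def test_negative_offset_rejected(self):
        with pytest.raises(InputError):
            compute_beta(1, 1, -1)


class TestFilterDetected:
    @staticmethod
    def matrices(p_values):
        idx = pd.Index([f"p{i}" for i in range(len(p_values))],
                       name="probe_id")
        beta = pd.DataFrame({"s1": 0.5}, index=idx)
        detection = pd.DataFrame({"s1": p_values}, index=idx)
        return beta, detection

    def test_no_exclusions_when_all_detected(self):
        beta, det = self.matrices([0.001] * 10)
        filtered, report = filter_detected(beta, det)
        assert len(filtered) == 10 and report.empty

    def test_single_failing_probe_excluded(self):
        beta, det = self.matrices([0.001] * 999 + [0.2])
        filtered, report = filter_detected(beta, det)
        assert len(filtered) == 999
        assert report["probe_id"].tolist() == ["p999"]

    def test_all_excluded_is_hard_error(self):
        beta, det = self.matrices([0.9, 0.8])
        with pytest.raises(PreconditionError):
            filter_detected(beta, det)


class TestEndToEnd:
    def test_synthetic_defaults_exclude_under_point1_percent(
            self, full_study):
        assert full_study["matrix"].excluded_fraction < 0.001

    def test_normalization_preserves_detection_ranks(self, small_design):
        """Detection P depends only on within-sample ranks, which quantile
        normalization preserves."""
        betas = pd.DataFrame(
            np.full((50, len(small_design)), 0.4),
            index=pd.Index([f"p{i}" for i in range(50)], name="probe_id"),
            columns=small_design["sample_id"],
        )
        beads = simulate_beads(betas, small_design, seed=7)
        raw = detection_pvalue_matrix(beads)
        normed = detection_pvalue_matrix(normalize_bead_channels(beads))
        pd.testing.assert_frame_equal(raw, normed)

    def test_empty_bead_table_rejected(self):
        with pytest.raises(InputError, match="no beads"):
            preprocess_beads(pd.DataFrame(columns=["sample_id", "probe_id",
                                                   "channel", "allele",
                                                   "intensity"]))
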