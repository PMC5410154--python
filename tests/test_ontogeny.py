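"""clr mechanics, the empirical-null outlier test, and consensus calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomont import load_fixture
from venomont.datatypes import (
    ExpressionMatrix,
    OutlierFlagMatrix,
    SampleMeta,
    TranscriptCatalog,
    ValidationError,
)
from venomont.ontogeny import (
    ClrMatrix,
    clr_transform,
    consensus_call,
    empirical_percentile,
    flags_from_pairs,
    intersect_detections,
    pair_outliers,
    replace_zeros,
    replicate_concordance,
    tpm_from_counts,
)
from venomont.synthetic import ExpressionSimSpec, default_pairs, gen_expression_dataset


def _matrix(values, labels=("ANF-A", "ANF-J")):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"t{i}" for i in range(values.shape[0])],
        [SampleMeta.from_label(lab) for lab in labels],
        values,
    )


class TestReplaceZeros:
    def test_only_exact_zeros_floored(self):
        m = _matrix([[0.0, 0.3], [2.0, 0.0]])
        out = replace_zeros(m)
        np.testing.assert_array_equal(out.values, [[1.0, 0.3], [2.0, 1.0]])

    def test_positive_matrix_unchanged(self):
        m = _matrix([[0.5, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(replace_zeros(m).values, m.values)


class TestClr:
    def test_identical_column_maps_to_zero(self):
        m = _matrix([[7.0], [7.0], [7.0]], labels=("ANF-A",))
        np.testing.assert_allclose(clr_transform(m).values, 0.0)

    def test_closed_form_powers_of_e(self):
        m = _matrix([[1.0], [np.e**2], [np.e**4]], labels=("ANF-A",))
        np.testing.assert_allclose(clr_transform(m).values[:, 0], [-2.0, 0.0, 2.0], atol=1e-12)

    def test_zero_value_directs_to_replace_zeros(self):
        with pytest.raises(ValidationError, match="replace_zeros"):
            clr_transform(_matrix([[0.0], [1.0]], labels=("ANF-A",)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-3, 1e6), min_size=2, max_size=50))
    def test_columns_sum_to_zero(self, column):
        m = _matrix(np.array(column)[:, None], labels=("ANF-A",))
        assert abs(clr_transform(m).values.sum()) < 1e-8 * len(column)


class TestPercentile:
    def test_sort_based_oracle(self, rng):
        """Linear interpolation between order statistics, against index arithmetic."""
        for _ in range(1000):
            n = rng.integers(2, 200)
            v = rng.normal(size=n)
            q = float(rng.uniform(0, 100))
            s = np.sort(v)
            h = (n - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            expected = s[lo] + (h - lo) * (s[hi] - s[lo])
            assert empirical_percentile(v, q) == pytest.approx(expected, abs=1e-12)


def _sim_clr(seed=0, planted=None, **kw):
    spec = ExpressionSimSpec(
        n_nontoxins=kw.pop("n_nontoxins", 500),
        n_toxins=kw.pop("n_toxins", 10),
        planted_effects=planted or {},
        seed=seed,
        **kw,
    )
    matrix, catalog, _ = gen_expression_dataset(spec)
    clr = clr_transform(replace_zeros(matrix))
    return clr, catalog, default_pairs(matrix)


class TestPairOutliers:
    def test_boundary_equal_to_threshold_is_not_outlier(self):
        # nontoxins with |delta| up to 1; toxin delta exactly at the 99th pct
        ids = [f"nt{i}" for i in range(101)] + ["tox"]
        deltas = np.concatenate([np.linspace(-1, 1, 101), [0]])
        clr_a = deltas.copy()
        threshold = empirical_percentile(np.abs(deltas[:101]), 99)
        clr_a[-1] = threshold  # exactly at threshold
        clr = ClrMatrix(
            ids,
            [SampleMeta.from_label("ANF-A"), SampleMeta.from_label("ANF-J")],
            np.column_stack([clr_a, np.zeros(102)]),
        )
        catalog = TranscriptCatalog.build(ids, [False] * 101 + [True], [100] * 102)
        comps = pair_outliers(clr, catalog, [("ANF-A", "ANF-J", "ANF")])
        assert comps[0].toxin_flags["tox"] == "none"
        # strictly above flips to an outlier
        clr.values[-1, 0] = threshold * 1.0001
        comps = pair_outliers(clr, catalog, [("ANF-A", "ANF-J", "ANF")])
        assert comps[0].toxin_flags["tox"] == "up"

    def test_degenerate_zero_threshold_errors(self):
        ids = [f"nt{i}" for i in range(120)] + ["tox"]
        vals = np.zeros((121, 2))
        vals[-1, 0] = 1.0
        clr = ClrMatrix(
            ids,
            [SampleMeta.from_label("ANF-A"), SampleMeta.from_label("ANF-J")],
            vals,
        )
        catalog = TranscriptCatalog.build(ids, [False] * 120 + [True], [100] * 121)
        with pytest.raises(ValidationError, match="degenerate"):
            pair_outliers(clr, catalog, [("ANF-A", "ANF-J", "ANF")])

    def test_too_few_nontoxins_errors(self):
        clr, catalog, pairs = _sim_clr(n_nontoxins=50)
        with pytest.raises(ValidationError, match="nontoxin"):
            pair_outliers(clr, catalog, pairs)

    def test_planted_strong_effect_flagged_in_every_population(self):
        for seed in range(20):
            clr, catalog, pairs = _sim_clr(
                seed=seed, planted={"TOX-1": 3.0}, n_nontoxins=2000, log_noise_sd=0.4
            )
            comps = pair_outliers(clr, catalog, pairs)
            assert all(c.toxin_flags["TOX-1"] == "up" for c in comps)

    def test_log_base_invariance(self):
        """Flags are identical when clr values are rescaled by 1/ln(10)."""
        clr, catalog, pairs = _sim_clr(seed=4, planted={"TOX-2": -2.5}, n_nontoxins=800)
        base = pair_outliers(clr, catalog, pairs)
        scaled = ClrMatrix(clr.transcript_ids, clr.samples, clr.values / np.log(10))
        rescaled = pair_outliers(scaled, catalog, pairs)
        for a, b in zip(base, rescaled):
            assert a.toxin_flags == b.toxin_flags
            assert b.null_threshold == pytest.approx(a.null_threshold / np.log(10))


class TestConsensusCall:
    def _flags(self, rows):
        return OutlierFlagMatrix(
            [f"t{i}" for i in range(len(rows))],
            ["ANF", "BR", "CAL", "ENP", "LSG"],
            np.array(rows, dtype=object),
        )

    def test_four_up_called_up(self):
        calls = consensus_call(self._flags([["up", "up", "up", "none", "up"]]))
        assert calls[0].call == "up" and calls[0].n_outlier == 4

    def test_split_directions_not_called(self):
        calls = consensus_call(self._flags([["up", "up", "down", "down", "none"]]))
        assert calls[0].call == "none" and calls[0].n_outlier == 4

    def test_direction_counts_partition_outliers(self):
        calls = consensus_call(self._flags([["up", "down", "up", "none", "up"]]))
        c = calls[0]
        assert (c.n_up, c.n_down, c.n_outlier) == (3, 1, 4)
        assert c.call == "up"

    def test_monotonicity_adding_agreeing_flag_never_uncalls(self):
        rows = [["up", "up", "up", "none", "none"]]
        before = consensus_call(self._flags(rows))[0].call
        rows_more = [["up", "up", "up", "up", "none"]]
        after = consensus_call(self._flags(rows_more))[0].call
        assert before == "up" and after == "up"

    def test_fixture_reproduces_13_up_4_down(self):
        calls = consensus_call(load_fixture("table5_outliers"))
        assert sum(c.call == "up" for c in calls) == 13
        assert sum(c.call == "down" for c in calls) == 4


class TestIntersectDetections:
    def test_fixture_confirmations(self):
        calls = consensus_call(load_fixture("table5_outliers"))
        deseq = load_fixture("table5_deseq")
        deseq2 = load_fixture("table5_deseq2")
        assert len(deseq.detected_ids) == 11
        assert len(deseq2.detected_ids) == 16
        merged = intersect_detections(calls, [deseq, deseq2])
        assert sum(c.confirmed for c in merged) == 12

    def test_empty_detections_confirm_nothing(self):
        calls = consensus_call(load_fixture("table5_outliers"))
        assert sum(c.confirmed for c in intersect_detections(calls, [])) == 0

    def test_all_detected_confirms_exactly_called_set(self):
        calls = consensus_call(load_fixture("table5_outliers"))
        import pandas as pd

        from venomont.datatypes import DetectionFlags

        allhit = DetectionFlags(
            "everything",
            pd.DataFrame(
                {
                    "transcript_id": [c.transcript_id for c in calls],
                    "adjusted_p": [1e-6] * len(calls),
                }
            ),
        )
        merged = intersect_detections(calls, [allhit])
        assert {c.transcript_id for c in merged if c.confirmed} == {
            c.transcript_id for c in merged if c.call != "none"
        }


class TestReplicateConcordance:
    def test_identical_columns_perfect(self):
        v = np.arange(59, dtype=float)
        rho, r = replicate_concordance(v, v)
        assert rho == pytest.approx(1.0) and r == pytest.approx(1.0)

    def test_reversed_ranks(self):
        v = np.arange(59, dtype=float)
        rho, _ = replicate_concordance(v, v[::-1].copy())
        assert rho == pytest.approx(-1.0)

    def test_constant_column_reports_nan(self):
        rho, r = replicate_concordance(np.zeros(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(r)

    def test_simulated_gland_replicates_highly_concordant(self, rng):
        """Left/right glands share true expression; sd-0.1 log noise keeps rho >= 0.97."""
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            true_log = rng.normal(5, 2, size=59)
            left = true_log + rng.normal(0, 0.1, size=59)
            right = true_log + rng.normal(0, 0.1, size=59)
            rho, _ = replicate_concordance(left, right)
            hits += rho >= 0.97
        assert hits / n_trials >= 0.95


class TestTpmFromCounts:
    def test_equal_everything(self):
        np.testing.assert_allclose(
            tpm_from_counts([10, 10, 10, 10], [100] * 4), [250_000.0] * 4
        )

    def test_length_normalization(self):
        np.testing.assert_allclose(
            tpm_from_counts([10, 10], [100, 200]),
            [666_666.6667, 333_333.3333],
            rtol=1e-6,
        )

    def test_sums_to_one_million(self, rng):
        counts = rng.integers(0, 1000, size=30)
        counts[0] = 5  # ensure nonzero
        lengths = rng.integers(200, 3000, size=30)
        assert tpm_from_counts(counts, lengths).sum() == pytest.approx(1e6, rel=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            tpm_from_counts([0, 0], [100, 100])


class TestParameterRecoveryUnit:
    def test_single_seed_full_recovery(self):
        planted = {f"TOX-{i + 1}": lfc for i, lfc in enumerate(
            [2.0, -2.0, 2.5, -2.5, 3.0, -3.0, 2.0, 2.2, -2.2, 2.8, -2.8, 2.1]
        )}
        spec = ExpressionSimSpec(
            n_nontoxins=2000, n_toxins=59, planted_effects=planted, log_noise_sd=0.4, seed=123
        )
        matrix, catalog, truth = gen_expression_dataset(spec)
        clr = clr_transform(replace_zeros(matrix))
        comps = pair_outliers(clr, catalog, default_pairs(matrix))
        calls = consensus_call(flags_from_pairs(comps))
        called = {c.transcript_id for c in calls if c.call != "none"}
        assert called == set(planted)
        # directions agree with the planted sign
        by_id = {c.transcript_id: c.call for c in calls}
        for t, lfc in planted.items():
            assert by_id[t] == ("up" if lfc > 0 else "down")
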