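"""Read mapping, the coverage-based absence rule, subsampling, summaries."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from venomont import load_fixture
from venomont.assembler import Read, revcomp
from venomont.consensus import DepthProfile
from venomont.datatypes import PresenceAbsenceMatrix, SampleMeta, ValidationError
from venomont.presence_absence import (
    AlignmentPolicy,
    call_absent,
    map_reads,
    presence_matrix_from_profiles,
    subsample_reads,
    summarize_absence,
)
from venomont.synthetic import ReadSimSpec, gen_paralog_family, gen_reads


def _read(rid, seq):
    return Read(rid, seq, [40] * len(seq))


class TestMapReads:
    def test_exact_reads_give_expected_depth(self, paralog_pair, transcript_reads):
        tid, seq = paralog_pair[0]
        res = map_reads(transcript_reads, [paralog_pair[0]])
        assert res.n_discarded == 0
        # every read aligns end-to-end, so total depth = reads x read length
        assert res.profiles[tid].depth.sum() == pytest.approx(len(transcript_reads) * 150)
        assert res.profiles[tid].depth.mean() == pytest.approx(40, rel=0.25)

    def test_three_mismatches_discarded(self, paralog_pair):
        tid, seq = paralog_pair[0]
        frag = list(seq[100:250])
        for p in (10, 50, 90):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        res = map_reads([_read("r", "".join(frag))], [paralog_pair[0]])
        assert res.n_discarded == 1 and res.n_mapped == 0

    def test_two_mismatches_kept(self, paralog_pair):
        tid, seq = paralog_pair[0]
        frag = list(seq[100:250])
        for p in (10, 50):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        res = map_reads([_read("r", "".join(frag))], [paralog_pair[0]])
        assert res.n_mapped == 1

    def test_reverse_strand_counted_once(self, paralog_pair):
        tid, seq = paralog_pair[0]
        res = map_reads([_read("r", revcomp(seq[200:350]))], [paralog_pair[0]])
        assert res.n_mapped == 1
        assert res.profiles[tid].depth.sum() == pytest.approx(150)

    def test_paralog_read_discarded_at_5pct_divergence(self):
        """A 150-nt read from a 5%-diverged paralog carries >2 expected mismatches.

        Verified against a brute-force sliding Hamming alignment.
        """
        fam = gen_paralog_family(600, 2, 0.025, seed=31)  # ~5% pairwise
        (t1, s1), (t2, s2) = fam
        read_seq = s2[200:350]
        # brute-force: best end-to-end Hamming distance of the read along s1
        best = min(
            sum(a != b for a, b in zip(read_seq, s1[p : p + 150]))
            for p in range(len(s1) - 149)
        )
        assert best > 2  # oracle: no placement within the mismatch budget
        res = map_reads([_read("r", read_seq)], [(t1, s1)])
        assert res.n_discarded == 1

    def test_multimap_fractional_split(self):
        s = gen_paralog_family(300, 1, 0.0, seed=32)[0][1]
        res = map_reads([_read("r", s[50:200])], [("a", s), ("b", s)])
        assert res.profiles["a"].depth.max() == pytest.approx(0.5)
        assert res.profiles["b"].depth.max() == pytest.approx(0.5)

    def test_reference_shorter_than_read_skipped(self):
        res = map_reads([_read("r", "ACGT" * 50)], [("short", "ACGT" * 10)])
        assert res.n_skipped_short == 1

    def test_empty_references_error(self):
        with pytest.raises(ValidationError):
            map_reads([], [])


class TestCallAbsent:
    def _profile(self, depths):
        return DepthProfile("t", np.array(depths, dtype=float))

    def test_uniform_exactly_at_min_depth_is_present(self):
        assert not call_absent(self._profile([5] * 100))

    def test_eleven_percent_low_is_absent(self):
        assert call_absent(self._profile([0] * 11 + [100] * 89))

    def test_exactly_ten_percent_low_is_present(self):
        assert not call_absent(self._profile([4] * 10 + [100] * 90))

    def test_lowering_min_depth_never_adds_absences(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            depths = rng.poisson(6, size=200)
            strict = call_absent(self._profile(depths), AlignmentPolicy(min_depth=5))
            lax = call_absent(self._profile(depths), AlignmentPolicy(min_depth=4))
            assert not (lax and not strict)


class TestSubsample:
    def test_full_sample_is_identity_in_canonical_order(self, transcript_reads):
        out = subsample_reads(transcript_reads, len(transcript_reads), seed=1)
        assert out == sorted(transcript_reads, key=lambda r: r.id)

    def test_zero_sample_empty(self, transcript_reads):
        assert subsample_reads(transcript_reads, 0, seed=1) == []

    def test_oversample_errors(self, transcript_reads):
        with pytest.raises(ValidationError):
            subsample_reads(transcript_reads, len(transcript_reads) + 1, seed=1)

    def test_determinism(self, transcript_reads):
        a = subsample_reads(transcript_reads, 50, seed=9)
        b = subsample_reads(transcript_reads, 50, seed=9)
        assert a == b

    def test_two_seed_overlap_matches_hypergeometric(self):
        n, k = 10_000, 5_000
        reads = [_read(f"r{i:05d}", "ACGT" * 40) for i in range(n)]
        a = {r.id for r in subsample_reads(reads, k, seed=1)}
        b = {r.id for r in subsample_reads(reads, k, seed=2)}
        overlap = len(a & b)
        mean = hypergeom.mean(n, k, k)
        sd = hypergeom.std(n, k, k)
        assert abs(overlap - mean) <= 3 * sd


class TestSummarize:
    def _meta(self, matrix):
        return [SampleMeta.from_label(c) for c in matrix.transcriptome_ids]

    def test_full_fixture_statistics(self):
        m = load_fixture("table4_full")
        s = summarize_absence(m, self._meta(m))
        assert s.per_transcriptome_missing == dict(
            zip(m.transcriptome_ids, [3, 4, 1, 8, 5, 4, 3, 13, 4, 0])
        )
        assert s.n_variable_transcripts == 17
        assert s.overall_mean_missing == pytest.approx(4.5)
        assert s.adult_mean == pytest.approx(3.2)
        assert s.juvenile_mean == pytest.approx(5.8)
        assert s.max_missing == 13
        assert s.welch_p == pytest.approx(0.31, abs=0.01)

    def test_subsampled_fixture_statistics(self):
        m = load_fixture("table4_sub")
        s = summarize_absence(m, self._meta(m))
        assert s.n_variable_transcripts == 20
        assert s.overall_mean_missing == pytest.approx(5.4)
        assert s.adult_mean == pytest.approx(3.4)
        assert s.juvenile_mean == pytest.approx(7.4)

    def test_all_present_matrix(self):
        ids = ["t1", "t2"]
        cols = ["ANF-A", "ANF-J", "BR-A", "BR-J"]
        m = PresenceAbsenceMatrix(ids, cols, np.ones((2, 4), dtype=bool))
        s = summarize_absence(m, [SampleMeta.from_label(c) for c in cols])
        assert s.overall_mean_missing == 0 and s.n_variable_transcripts == 0

    def test_too_few_samples_gives_nan_p(self):
        m = PresenceAbsenceMatrix(["t1"], ["ANF-A", "ANF-J"], np.ones((1, 2), dtype=bool))
        s = summarize_absence(m, [SampleMeta.from_label(c) for c in m.transcriptome_ids])
        assert np.isnan(s.welch_p)


class TestEndToEndRecovery:
    def test_dropouts_and_only_dropouts_called_absent(self):
        """map_reads -> call_absent marks exactly the dropout transcripts."""
        transcripts = []
        for k in range(20):
            fam = gen_paralog_family(500, 1, 0.0, seed=100 + k)
            transcripts.append((f"t{k:02d}", fam[0][1]))
        dropouts = ["t03", "t11", "t17"]
        for seed in range(10):
            reads = gen_reads(
                ReadSimSpec(
                    transcripts=transcripts,
                    mean_depth=30,
                    read_length=150,
                    dropout_ids=dropouts,
                    seed=seed,
                )
            )
            res = map_reads(reads, transcripts)
            absent = {tid for tid, _ in transcripts if call_absent(res.profiles[tid])}
            assert absent == set(dropouts)

    def test_presence_matrix_builder(self):
        profiles = {
            "ANF-A": {"t1": DepthProfile("t1", np.full(100, 30.0)),
                      "t2": DepthProfile("t2", np.zeros(100))},
        }
        m = presence_matrix_from_profiles(profiles, ["t1", "t2"])
        assert m.present[0, 0] and not m.present[1, 0]
        assert list(m.absent_counts) == [1]
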