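"""Alignment engine: DP correctness against brute force, PID, significance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfxsurvey.align import (LocalAlignment, corrected_pid, default_scheme,
                             empirical_significance, global_align, local_align,
                             local_score, SubstitutionScheme)
from rfxsurvey.exceptions import InputError, ParameterError

from oracle import brute_force_global_score, brute_force_local_score

SHORT = st.text(alphabet="ACDE", min_size=1, max_size=8)


class TestLocalAlign:
    def test_identity_alignment(self, scheme):
        aln = local_align("MKV", "MKV", scheme)
        assert aln.identities == 3
        assert aln.query_interval == (0, 3)
        assert aln.target_interval == (0, 3)
        assert aln.aligned_query == "MKV"

    def test_no_positive_scoring_cell_gives_empty_alignment(self, scheme):
        aln = local_align("AAAA", "WWWW", scheme)  # A/W scores -3
        assert aln.score == 0
        assert aln.query_interval == (0, 0) and aln.target_interval == (0, 0)
        assert aln.aligned_query == ""

    def test_unknown_residue_rejected(self, scheme):
        with pytest.raises(InputError):
            local_align("MKB", "MKV", scheme)

    def test_x_scores_zero_and_never_identical(self, scheme):
        aln = local_align("MKXV", "MKXV", scheme)
        assert aln.identities == 3  # X-X column aligned but not identical

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(q=SHORT, t=SHORT)
    def test_score_matches_brute_force(self, q, t, scheme, gappy_scheme):
        for sch in (scheme, gappy_scheme):
            assert local_align(q, t, sch).score == brute_force_local_score(q, t, sch)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(q=SHORT, t=SHORT)
    def test_score_only_kernel_agrees_with_traceback_path(self, q, t, gappy_scheme):
        assert local_score(q, t, gappy_scheme) == local_align(q, t, gappy_scheme).score

    def test_alignment_strings_consistent_with_intervals_and_score(self, gappy_scheme):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            q = "".join(rng.choice(list(aas), size=rng.integers(10, 40)))
            t = "".join(rng.choice(list(aas), size=rng.integers(10, 40)))
            aln = local_align(q, t, gappy_scheme)
            qs, qe = aln.query_interval
            ts, te = aln.target_interval
            assert aln.aligned_query.replace("-", "") == q[qs:qe]
            assert aln.aligned_target.replace("-", "") == t[ts:te]
            assert aln.identities <= min(qe - qs, te - ts)

    def test_cross_check_against_biopython_scores(self, scheme):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        aligner.mode = "local"
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            q = "".join(rng.choice(list(aas), size=rng.integers(20, 60)))
            t = "".join(rng.choice(list(aas), size=rng.integers(20, 60)))
            assert local_align(q, t, scheme).score == int(aligner.score(q, t))


class TestGlobalAlign:
    def test_identical_sequences_gapless(self, scheme):
        aln = global_align("MKVLAGHW", "MKVLAGHW", scheme)
        assert "-" not in aln.aligned_query + aln.aligned_target
        assert aln.identities == 8

    def test_classic_pair_matches_brute_force(self, scheme, gappy_scheme):
        q, t = "HEAGAWGH", "PAWHEAE"  # classic textbook pair, truncated to 8
        for sch in (scheme, gappy_scheme):
            assert global_align(q, t, sch).score == brute_force_global_score(q, t, sch)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(q=SHORT, t=SHORT)
    def test_score_matches_brute_force(self, q, t, gappy_scheme):
        assert global_align(q, t, gappy_scheme).score == \
            brute_force_global_score(q, t, gappy_scheme)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(q=SHORT, t=SHORT)
    def test_score_symmetric_in_arguments(self, q, t, gappy_scheme):
        assert global_align(q, t, gappy_scheme).score == \
            global_align(t, q, gappy_scheme).score

    def test_spans_both_sequences_entirely(self, scheme):
        aln = global_align("MKVLA", "MKA", scheme)
        assert aln.query_interval == (0, 5)
        assert aln.target_interval == (0, 3)
        assert aln.aligned_query.replace("-", "") == "MKVLA"
        assert aln.aligned_target.replace("-", "") == "MKA"


class TestSubstitutionScheme:
    def test_rejects_asymmetric_matrix(self, scheme):
        m = scheme.matrix.copy()
        m[0, 1] += 1
        with pytest.raises(ParameterError):
            SubstitutionScheme(matrix=m, gap_open=11, gap_extend=1)

    def test_rejects_bad_gap_order(self, scheme):
        with pytest.raises(ParameterError):
            SubstitutionScheme(matrix=scheme.matrix, gap_open=1, gap_extend=2)


class TestCorrectedPid:
    def test_full_identity_is_100(self, scheme):
        aln = local_align("MKVLAG", "MKVLAG", scheme)
        assert corrected_pid(aln, 6) == 100.0

    def test_divides_by_full_query_length(self):
        aln = LocalAlignment((0, 30), (0, 30), "A" * 30, "A" * 30, 60, 30)
        assert corrected_pid(aln, 76) == pytest.approx(100 * 30 / 76)
        assert corrected_pid(aln, 76) < 40  # below the acceptance threshold

    def test_zero_query_length_rejected(self, scheme):
        aln = local_align("MKV", "MKV", scheme)
        with pytest.raises(ParameterError):
            corrected_pid(aln, 0)

    def test_never_exceeds_ungapped_upper_bound(self, gappy_scheme):
        rng = np.random.default_rng(2)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            q = "".join(rng.choice(list(aas), size=rng.integers(5, 30)))
            t = "".join(rng.choice(list(aas), size=rng.integers(5, 30)))
            pid = corrected_pid(local_align(q, t, gappy_scheme), len(q))
            assert pid <= 100.0 * min(len(q), len(t)) / len(q) + 1e-12


class TestEmpiricalSignificance:
    def test_unbeatable_score_gives_plus_one_floor(self, scheme):
        sig = empirical_significance(10**6, "MKVLAG", "MKVLAGWH", scheme,
                                     n_shuffles=199, rng_seed=0)
        assert sig.p_value == pytest.approx(1 / 200)

    def test_score_zero_gives_p_one(self, scheme):
        sig = empirical_significance(0, "MKVLAG", "MKVLAGWH", scheme,
                                     n_shuffles=99, rng_seed=0)
        assert sig.p_value == 1.0

    def test_p_value_non_increasing_in_score(self, scheme):
        q = "MKVLAGHWMKVLAGHW"
        t = "WHGALVKMWHGALVKMPQRS"
        ps = [empirical_significance(s, q, t, scheme, n_shuffles=99,
                                     rng_seed=3).p_value
              for s in (0, 5, 10, 20, 40, 80)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_reproducible_from_seed(self, scheme):
        args = (25, "MKVLAGHW", "WHGALVKMQR", scheme)
        a = empirical_significance(*args, n_shuffles=99, rng_seed=11)
        b = empirical_significance(*args, n_shuffles=99, rng_seed=11)
        assert a == b

    def test_too_few_shuffles_rejected(self, scheme):
        with pytest.raises(ParameterError):
            empirical_significance(5, "MKV", "MKV", scheme, n_shuffles=50, rng_seed=0)


def test_default_scheme_is_blosum62_with_zero_scoring_x():
    sch = default_scheme()
    assert sch.matrix[0, 0] == 4  # A-A under BLOSUM62
    assert (sch.matrix[20, :] == 0).all() and (sch.matrix[:, 20] == 0).all()
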