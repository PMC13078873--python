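"""Flank extraction and probability-logo binomial statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from redoxome.errors import ConsistencyError, EmptyResultError
from redoxome.io import ProteinDb
from redoxome.motif import (
    FlankSet,
    binomial_logodds,
    build_motif_result,
    extract_flanks,
    significance_threshold,
)


class TestExtractFlanks:
    db = ProteinDb(
        {
            # Cys at positions 2, 10 and 30 (the final residue)
            "Q1": "ACDEFGHIKCLMNPQRSTVWYADEFGHIKC",
        }
    )

    def test_interior_site_has_full_window(self):
        fs = extract_flanks(["Q1:10"], self.db, w=6)
        assert fs.sequences == ["EFGHIKCLMNPQR"]

    def test_near_n_terminus_left_padded_with_x(self):
        fs = extract_flanks(["Q1:2"], self.db, w=6)
        # 1-based position 2: only one upstream residue exists
        assert fs.sequences == ["XXXXX" + "ACDEFGHI"]
        assert fs.sequences[0][6] == "C"

    def test_final_residue_right_half_all_x(self):
        fs = extract_flanks(["Q1:30"], self.db, w=6)
        assert fs.sequences[0].endswith("XXXXXX")
        assert fs.sequences[0][6] == "C"

    def test_non_cysteine_site_rejected(self):
        with pytest.raises(ConsistencyError):
            extract_flanks(["Q1:3"], self.db, w=6)

    def test_off_center_window_rejected_by_flankset(self):
        with pytest.raises(ConsistencyError):
            FlankSet(w=2, sequences=["AAAAA"])


class TestBinomialLogOdds:
    def test_certain_event_scores_zero(self):
        assert binomial_logodds(10, 10, 1.0) == 0.0

    def test_underrepresentation_closed_form(self):
        # P[X ≤ 0] = 0.95^10 = 0.598737…; signed negative
        score = binomial_logodds(0, 10, 0.05)
        assert score == pytest.approx(math.log10(0.95**10), abs=1e-12)
        assert score == pytest.approx(-0.2227639, abs=1e-6)

    def test_tie_counts_as_overrepresentation(self):
        # k/n = p0 = 0.5 → over; oracle: brute-force pmf sum of terms 5..10
        brute = sum(
            math.comb(10, i) * 0.5**i * 0.5 ** (10 - i) for i in range(5, 11)
        )
        assert binomial_logodds(5, 10, 0.5) == pytest.approx(
            -math.log10(brute), abs=1e-12
        )

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_logodds(11, 10, 0.5)

    @given(
        n=st.integers(1, 120),
        k_frac=st.floats(0, 1),
        p0=st.sampled_from([0.01, 0.05, 0.3, 0.5, 0.9]),
    )
    @settings(max_examples=150, deadline=None)
    def test_tails_match_scipy_binomial(self, n, k_frac, p0):
        k = min(n, int(round(k_frac * n)))
        score = binomial_logodds(k, n, p0)
        if k / n >= p0:
            ref = stats.binom.sf(k - 1, n, p0)
            assert score == pytest.approx(-math.log10(ref), rel=1e-9, abs=1e-9)
        else:
            ref = stats.binom.cdf(k, n, p0)
            assert score == pytest.approx(math.log10(ref), rel=1e-9, abs=1e-9)

    def test_score_monotone_in_k_for_fixed_n_and_p0(self):
        scores = [binomial_logodds(k, 50, 0.2) for k in range(10, 51)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestThreshold:
    def test_standard_window_reproduces_published_cutoff(self):
        assert round(significance_threshold(0.05, 20, 12), 2) == 3.68
        assert significance_threshold(0.05, 20, 12) == pytest.approx(
            -math.log10(0.05 / 240), abs=1e-12
        )

    def test_threshold_vanishes_as_corrected_alpha_approaches_one(self):
        # alpha/(R·W) → 1 drives the cutoff to 0 from above
        assert significance_threshold(1 - 1e-12, 1, 1) == pytest.approx(0.0, abs=1e-9)
        assert significance_threshold(0.5, 1, 1) > 0.0

    def test_ten_position_window(self):
        assert significance_threshold(0.05, 20, 10) == pytest.approx(
            3.6020599913, abs=1e-9
        )

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_alpha_outside_unit_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            significance_threshold(alpha, 20, 12)


class TestBuildMotifResult:
    def _uniform_flanks(self, n, seed=0):
        import numpy as np

        rng = np.random.default_rng(seed)
        letters = "ADEFGHIKLMNPQRSTVWY"
        seqs = [
            "".join(rng.choice(list(letters), size=13)) for _ in range(n)
        ]
        return FlankSet(w=6, sequences=[s[:6] + "C" + s[7:] for s in seqs])

    def test_self_comparison_finds_nothing(self):
        fs = self._uniform_flanks(80)
        res = build_motif_result(fs, fs)
        assert not res.cells["significant"].any()

    def test_single_sequence_foreground_cannot_reach_threshold(self):
        fg = FlankSet(w=6, sequences=["AAAAAA" + "C" + "AAAAAA"])
        bg = self._uniform_flanks(500, seed=1)
        res = build_motif_result(fg, bg)
        # max possible |score| at n_p = 1 is −log10(min p0) << 3.68 for
        # backgrounds without vanishing frequencies
        finite = res.cells.loc[res.cells.p0 > 0, "score"]
        assert (finite.abs() < res.threshold).all()

    def test_planted_enrichment_is_detected(self):
        bg = self._uniform_flanks(400, seed=2)
        fg_seqs = [s[:1] + "K" + s[2:] for s in self._uniform_flanks(60, seed=3).sequences]
        fg = FlankSet(w=6, sequences=fg_seqs)  # K forced at position −5
        res = build_motif_result(fg, bg)
        cell = res.cells[(res.cells.position == -5) & (res.cells.residue == "K")]
        assert bool(cell.significant.iloc[0])
        assert cell.score.iloc[0] > res.threshold

    def test_pwm_columns_sum_to_one(self):
        res = build_motif_result(
            self._uniform_flanks(30), self._uniform_flanks(100, seed=4)
        )
        sums = res.pwm.sum(axis=0)
        assert all(abs(s - 1.0) < 1e-9 for s in sums)

    def test_x_padding_excluded_from_denominators(self):
        fg = FlankSet(w=6, sequences=["XXXXXX" + "C" + "KKKKKK", "XXXXXX" + "C" + "KKKKKK"])
        bg = self._uniform_flanks(100, seed=5)
        res = build_motif_result(fg, bg)
        left = res.cells[res.cells.position == -1]
        assert (left.n_p == 0).all()
        right = res.cells[(res.cells.position == 1) & (res.cells.residue == "K")]
        assert right.n_p.iloc[0] == 2 and right.k.iloc[0] == 2

    def test_empty_foreground_rejected(self):
        with pytest.raises(EmptyResultError):
            build_motif_result(FlankSet(w=6, sequences=[]), self._uniform_flanks(10))
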