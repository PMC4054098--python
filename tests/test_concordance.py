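"""Interval overlap, confusion counts, binomial CIs and beta-by-state summaries."""

import numpy as np
import pandas as pd
import math

import pytest
from scipy import stats

from methcna.concordance import (
    associate_beta_with_state,
    binom_tp,
    make_bins,
    overlap_segments,
    profile_correlation,
    sensitivity_specificity,
)
from methcna.io import CNAState, DataError, Segment, SegmentSet
from methcna.preprocess import BetaMatrix
from conftest import make_manifest, make_profile


def truth_set() -> SegmentSet:
    return SegmentSet(
        "T",
        [
            Segment("1", 1, 1000, 5, -0.4, CNAState.LOSS),
            Segment("1", 1001, 3000, 10, 0.0, CNAState.NEUTRAL),
            Segment("1", 3001, 4000, 4, 0.4, CNAState.GAIN),
            Segment("2", 1, 500, 6, -2.5, CNAState.DELETION),
            Segment("2", 2001, 2500, 2, -0.4, CNAState.LOSS),
            Segment("2", 2501, 5000, 8, 0.0, CNAState.NEUTRAL),
        ],
    )


def called_set() -> SegmentSet:
    return SegmentSet(
        "S",
        [
            Segment("1", 500, 1200, 4, -0.35, CNAState.LOSS),
            Segment("1", 3500, 4800, 3, 0.45, CNAState.GAIN),
            Segment("2", 601, 900, 4, -2.0, CNAState.DELETION),
            Segment("2", 2100, 2300, 5, -0.5, CNAState.LOSS),
        ],
    )


def fixed_bins():
    return [("1", 1 + 500 * i, 500 * (i + 1)) for i in range(10)] + [
        ("2", 1 + 500 * i, 500 * (i + 1)) for i in range(10)
    ]


class TestOverlapSegments:
    def test_one_bp_overlap_matches(self):
        a = SegmentSet("a", [Segment("9", 1000, 2000, 4, -2.5, CNAState.DELETION)])
        b = SegmentSet("b", [Segment("9", 2000, 3000, 5, -2.2, CNAState.DELETION)])
        part = overlap_segments(a, b, CNAState.DELETION, min_markers=3)
        assert len(part.matched_a) == 1 and not part.unmatched_a

    def test_low_marker_counterpart_is_excluded_not_matched(self):
        a = SegmentSet("a", [Segment("9", 1000, 2000, 4, -2.5, CNAState.DELETION)])
        b = SegmentSet("b", [Segment("9", 1500, 3000, 2, -2.2, CNAState.DELETION)])
        part = overlap_segments(a, b, CNAState.DELETION, min_markers=3)
        assert not part.matched_a and len(part.unmatched_a) == 1
        assert len(part.excluded_b) == 1 and not part.unmatched_b

    def test_states_are_stratified(self):
        a = SegmentSet("a", [Segment("9", 1000, 2000, 4, -2.5, CNAState.DELETION)])
        b = SegmentSet("b", [Segment("9", 1000, 2000, 4, -0.4, CNAState.LOSS)])
        part = overlap_segments(a, b, CNAState.DELETION, min_markers=3)
        assert not part.matched_a and len(part.unmatched_a) == 1

    def test_counting_conservation(self):
        a, b = truth_set(), called_set()
        for state in (CNAState.DELETION, CNAState.LOSS, CNAState.GAIN):
            part = overlap_segments(a, b, state, min_markers=3)
            eligible_a = [s for s in a if s.state == state and s.n_probes >= 3]
            assert len(part.matched_a) + len(part.unmatched_a) == len(eligible_a)
            eligible_b = [s for s in b if s.state == state and s.n_probes >= 3]
            assert len(part.matched_b) + len(part.unmatched_b) == len(eligible_b)

    def test_uncalled_segments_are_rejected(self):
        a = SegmentSet("a", [Segment("9", 1, 10, 4, 0.0, None)])
        with pytest.raises(DataError, match="state-called"):
            overlap_segments(a, a, CNAState.LOSS)


class TestSensitivitySpecificity:
    def test_identity_comparison_is_perfect(self):
        t = truth_set()
        for state in (CNAState.DELETION, CNAState.LOSS, CNAState.GAIN):
            r = sensitivity_specificity(t, t, state, min_markers=3, bins=fixed_bins())
            assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_seven_of_ten_matched_gives_point_seven(self):
        truth = SegmentSet(
            "t",
            [Segment("1", 1 + i * 1000, 500 + i * 1000, 5, -0.4, CNAState.LOSS) for i in range(10)],
        )
        # tests overlap the first seven truth segments only
        test = SegmentSet(
            "s",
            [Segment("1", 100 + i * 1000, 400 + i * 1000, 4, -0.4, CNAState.LOSS) for i in range(7)],
        )
        r = sensitivity_specificity(truth, test, CNAState.LOSS, bins=[])
        assert r.sensitivity == pytest.approx(0.7)
        assert (r.tp, r.fn, r.fp) == (7, 3, 0)

    def test_hand_counted_confusion_table(self):
        t, s, bins = truth_set(), called_set(), fixed_bins()
        loss = sensitivity_specificity(t, s, CNAState.LOSS, min_markers=3, bins=bins)
        assert (loss.tp, loss.fn, loss.fp, loss.tn) == (1, 0, 1, 16)
        assert loss.sensitivity == 1.0
        assert loss.specificity == pytest.approx(16 / 17)

        gain = sensitivity_specificity(t, s, CNAState.GAIN, min_markers=3, bins=bins)
        assert (gain.tp, gain.fn, gain.fp, gain.tn) == (1, 0, 0, 16)

        dele = sensitivity_specificity(t, s, CNAState.DELETION, min_markers=3, bins=bins)
        assert (dele.tp, dele.fn, dele.fp, dele.tn) == (0, 1, 1, 18)
        assert dele.sensitivity == 0.0
        assert dele.specificity == pytest.approx(18 / 19)

    def test_empty_truth_state_reports_na_not_zero(self):
        t = truth_set()
        r = sensitivity_specificity(t, t, CNAState.AMPLIFICATION, bins=fixed_bins())
        assert r.sensitivity is None and r.binom_p is None


class TestBinomTp:
    def test_boundaries(self):
        p0, (lo0, _) = binom_tp(0, 10)
        assert p0 == 0.0 and lo0 == 0.0
        p1, (_, hi1) = binom_tp(10, 10)
        assert p1 == 1.0 and hi1 == 1.0

    def test_zero_n_is_error(self):
        with pytest.raises(DataError):
            binom_tp(0, 0)

    @pytest.mark.parametrize("tp,n", [(5, 10), (1, 20), (19, 20), (7, 13)])
    def test_clopper_pearson_matches_binomial_tail_oracle(self, tp, n):
        # oracle: invert the exact binomial tail by bisection, no beta functions
        def binom_cdf(k, n, p):
            return sum(
                math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1)
            )

        def bisect(f, lo, hi, tol=1e-12):
            for _ in range(200):
                mid = (lo + hi) / 2
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        _, (lo, hi) = binom_tp(tp, n)
        # lower bound: P(X >= tp | p) = 0.025 ; upper: P(X <= tp | p) = 0.025
        lo_oracle = bisect(lambda p: 0.025 - (1 - binom_cdf(tp - 1, n, p)), 0, 1)
        hi_oracle = bisect(lambda p: binom_cdf(tp, n, p) - 0.025, 0, 1)
        assert lo == pytest.approx(lo_oracle, abs=1e-9)
        assert hi == pytest.approx(hi_oracle, abs=1e-9)

    def test_interval_coverage_near_nominal(self):
        # 2000 seeded replicates at n=20: nominal 95% CI covers true p >= 93%
        rng = np.random.default_rng(0)
        p_true, n = 0.3, 20
        draws = rng.binomial(n, p_true, size=2000)
        covered = 0
        cis = {k: binom_tp(k, n)[1] for k in range(n + 1)}
        for k in draws:
            lo, hi = cis[k]
            covered += lo <= p_true <= hi
        assert covered / 2000 >= 0.93


class TestProfileCorrelation:
    def _binned_profiles(self, seed=0, noise=0.1):
        rng = np.random.default_rng(seed)
        truth = np.repeat(rng.normal(0, 0.5, 40), 25)  # 40 segments x 25 probes
        a = make_profile(truth + rng.normal(0, noise, truth.size), sample_id="a")
        b = make_profile(truth + rng.normal(0, noise, truth.size), sample_id="b")
        bins = [("1", 1 + i * 25_000, (i + 1) * 25_000) for i in range(40)]
        return a, b, bins

    def test_self_correlation_is_one(self):
        a, _, bins = self._binned_profiles()
        r, r2 = profile_correlation(a, a, bins)
        assert r == pytest.approx(1.0)

    def test_negated_profile_gives_minus_one(self):
        a, _, bins = self._binned_profiles()
        neg = make_profile(-a.log2r, sample_id="neg")
        r, _ = profile_correlation(a, neg, bins)
        assert r == pytest.approx(-1.0)

    def test_two_platform_renderings_highly_correlated(self):
        a, b, bins = self._binned_profiles(seed=3)
        r, r2 = profile_correlation(a, b, bins)
        assert r2 > 0.9

    def test_zero_variance_side_warns_and_returns_nan(self):
        a, _, bins = self._binned_profiles()
        flat = make_profile(np.zeros(a.log2r.size), sample_id="flat")
        with pytest.warns(UserWarning, match="variance"):
            r, r2 = profile_correlation(a, flat, bins)
        assert np.isnan(r)


class TestAssociateBetaWithState:
    def _beta(self, values, manifest):
        return BetaMatrix(
            probes=manifest.probe_ids, samples=["s1"],
            beta=np.asarray(values, dtype=float)[:, None],
        )

    def test_all_neutral_yields_single_row(self):
        man = make_manifest(chroms=["1"] * 5, positions=[10, 20, 30, 40, 50])
        segs = SegmentSet("s", [Segment("1", 1, 100, 5, 0.0, CNAState.NEUTRAL)])
        summary, _ = associate_beta_with_state(self._beta([0.1] * 5, man), segs, man)
        assert len(summary) == 1 and summary.loc[0, "state"] == "NEUTRAL"

    def test_matches_hand_grouping_on_small_fixture(self):
        n = 20
        man = make_manifest(chroms=["1"] * n, positions=np.arange(1, n + 1) * 10)
        values = np.linspace(0.05, 0.95, n)
        segs = SegmentSet(
            "s",
            [
                Segment("1", 1, 100, 10, -0.4, CNAState.LOSS),     # probes 0..9
                Segment("1", 101, 200, 10, 0.0, CNAState.NEUTRAL),  # probes 10..19
            ],
        )
        summary, (rho, pval) = associate_beta_with_state(self._beta(values, man), segs, man)
        by_state = summary.set_index("state")
        assert by_state.loc["LOSS", "n"] == 10
        assert by_state.loc["LOSS", "mean"] == pytest.approx(values[:10].mean())
        assert by_state.loc["NEUTRAL", "median"] == pytest.approx(np.median(values[10:]))
        # beta increases with state order here, so the trend is positive
        assert rho > 0 and pval < 0.01

    def test_island_probes_less_methylated_within_amplification(self):
        rng = np.random.default_rng(0)
        n = 400
        island = rng.random(n) < 0.5
        man = make_manifest(
            chroms=["1"] * n, positions=np.arange(1, n + 1) * 10, island=island.tolist()
        )
        beta = np.where(island, rng.beta(2, 10, n), rng.beta(10, 2.5, n))
        segs = SegmentSet("s", [Segment("1", 1, n * 10 + 1, n, 0.8, CNAState.AMPLIFICATION)])
        summary, _ = associate_beta_with_state(
            self._beta(beta, man), segs, man, by_island=True
        )
        amp = summary[summary["state"] == "AMPLIFICATION"].set_index("cpg_island")
        assert amp.loc[True, "mean"] < amp.loc[False, "mean"]

    def test_make_bins_tiles_shared_coverage(self):
        t = truth_set()
        bins = make_bins([t, t], bin_size=1000)
        chr1 = [b for b in bins if b[0] == "1"]
        assert chr1[0] == ("1", 1, 1000) and chr1[-1][2] == 4000
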