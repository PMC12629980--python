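import math

import numpy as np
import pytest

from dendrodate import (
    MatchPolicy,
    RingSeries,
    SyntheticScenario,
    assess_same_tree,
    generate_boards,
    generate_master,
    scan_offsets,
)
from dendrodate.crossdating import (
    T_CAP,
    UndefinedStatisticError,
    classify_match,
    glk_statistic,
    tbp_statistic,
)
from dendrodate import BoardSpec
from dendrodate.ring_signal import bp_transform, sign_series


def _series(widths, last_year=1600, sid="S"):
    return RingSeries(sid, np.asarray(widths, dtype=float), last_year)


def _rand_series(rng, n, last_year=1600, sid="R"):
    return _series(np.exp(0.25 * rng.standard_normal(n)), last_year, sid)


def _phi(z):
    """Standard normal CDF via erfc — independent of scipy."""
    return 0.5 * math.erfc(-z / math.sqrt(2))


class TestTbp:
    def test_self_match_reports_cap(self):
        rng = np.random.default_rng(0)
        s = _rand_series(rng, 50)
        t = bp_transform(s)
        r, tval, n = tbp_statistic(t, t, s.last_ring_year)
        assert r == pytest.approx(1.0)
        assert tval == T_CAP
        assert n == s.n - 4

    def test_matches_brute_force_pearson(self):
        """t equals r*sqrt(n-2)/sqrt(1-r^2) with r from explicit sums, on a
        pair whose transformed overlap has 10 values."""
        rng = np.random.default_rng(1)
        a, b = _rand_series(rng, 14, sid="A"), _rand_series(rng, 14, sid="B")
        at, bt = bp_transform(a), bp_transform(b)
        r, tval, n = tbp_statistic(at, bt, 1600)
        assert n == 10
        x, y = at.values, bt.values
        mx, my = sum(x) / len(x), sum(y) / len(y)
        sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        sxx = sum((xi - mx) ** 2 for xi in x)
        syy = sum((yi - my) ** 2 for yi in y)
        r_bf = sxy / math.sqrt(sxx * syy)
        assert r == pytest.approx(r_bf, abs=1e-12)
        assert tval == pytest.approx(r_bf * math.sqrt(8) / math.sqrt(1 - r_bf**2), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _rand_series(rng, 40, 1600, "A")
        b = _rand_series(rng, 55, 1610, "B")
        at, bt = bp_transform(a), bp_transform(b)
        r1, t1, n1 = tbp_statistic(at, bt, 1600)
        # same physical alignment expressed from b's side
        r2, t2, n2 = tbp_statistic(bt, at, 1610)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert t1 == pytest.approx(t2, abs=1e-9)
        assert n1 == n2

    def test_short_overlap_and_zero_variance(self):
        rng = np.random.default_rng(2)
        a = _rand_series(rng, 20)
        const = _series([1.0] * 20)
        with pytest.raises(UndefinedStatisticError):
            tbp_statistic(bp_transform(a), bp_transform(const), 1600)
        b = _rand_series(rng, 20, last_year=1700)
        with pytest.raises(UndefinedStatisticError):
            tbp_statistic(bp_transform(a), bp_transform(b), 1625)  # no overlap


class TestGlk:
    def test_self_is_100(self):
        rng = np.random.default_rng(3)
        s = _rand_series(rng, 60)
        sg = sign_series(s)
        glk, p, cls = glk_statistic(sg, sg, s.last_ring_year)
        assert glk == 100.0
        assert cls == "p001"

    def test_negation_is_0(self):
        w = np.array([1, 2, 1.5, 2.5, 2, 3, 2.2, 3.1])
        up = _series(w)
        down = _series(w.max() + w.min() - w)  # reflected: all moves reversed
        glk, p, _ = glk_statistic(sign_series(up), sign_series(down), 1600)
        assert glk == 0.0
        assert p > 0.99

    def test_63_percent_normal_approximation(self):
        """63 agreements in 100 tie-free intervals: %PV = 63 and the one-sided
        p equals 1 - Phi(2 * 0.13 * sqrt(100)), evaluated independently."""
        a = np.zeros(101)
        b = np.zeros(101)
        a[0] = b[0] = 1.0
        step = np.tile([0.1, -0.1], 51)
        for i in range(1, 101):
            a[i] = a[i - 1] + step[i]
            b[i] = b[i - 1] + (step[i] if i <= 63 else -step[i])
        glk, p, cls = glk_statistic(
            sign_series(_series(a, 1700)), sign_series(_series(b, 1700)), 1700
        )
        assert glk == pytest.approx(63.0)
        assert p == pytest.approx(1 - _phi(2 * 0.13 * 10), rel=1e-9)
        assert cls == "p01"

    def test_half_credit_for_single_tie(self):
        a = _series([1, 2, 3])    # +1 +1
        b = _series([1, 2, 2])    # +1  0
        glk, _, _ = glk_statistic(sign_series(a), sign_series(b), 1600)
        assert glk == pytest.approx(75.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _rand_series(rng, 30, sid="A"), _rand_series(rng, 30, sid="B")
        glk, p, _ = glk_statistic(sign_series(a), sign_series(b), 1600)
        assert 0.0 <= glk <= 100.0
        assert 0.0 < p <= 1.0


class TestClassification:
    POLICY = MatchPolicy()

    @pytest.mark.parametrize(
        "t,ol,glk,p,expected",
        [
            (4.49, 206, 60.0, 0.2, "potential"),   # over 3.5 at Ol >= 100, below 5
            (3.4, 206, 60.0, 0.2, "no_match"),
            (4.49, 80, 60.0, 0.2, "no_match"),     # overlap too short for potential
            (5.6, 206, 68.0, 0.001, "accepted"),
            (5.6, 206, 58.0, 0.001, "potential"),  # %PV below 63 blocks acceptance
        ],
    )
    def test_thresholds(self, t, ol, glk, p, expected):
        assert classify_match(t, ol, glk, p, self.POLICY) == expected


class TestScanOffsets:
    def test_verbatim_window_ranks_true_year_first(self):
        sc = SyntheticScenario(seed=4)
        master = generate_master(sc)
        cut = RingSeries("CUT", master.widths[100:220], master.first_ring_year + 219)
        res = scan_offsets(cut, master)
        assert res[0].proposed_end_year == cut.last_ring_year
        assert res[0].r == pytest.approx(1.0)
        assert res[0].t_bp == T_CAP

    @pytest.mark.parametrize("seed", range(5))
    def test_synthetic_board_recovers_true_end_year(self, seed):
        sc = SyntheticScenario(seed=seed, n_trees=1)
        master = generate_master(sc)
        (board,), truth = generate_boards(sc)
        res = scan_offsets(board, master)
        assert res[0].proposed_end_year == truth["boards"][0]["true_end_year"]
        assert res[0].t_bp > 5

    def test_overlap_bookkeeping(self):
        sc = SyntheticScenario(seed=4, n_trees=1)
        master = generate_master(sc)
        (board,), truth = generate_boards(sc)
        res = scan_offsets(board, master)
        top = res[0]
        assert top.overlap == board.n  # fully nested in the master span
        assert top.overlap_t == board.n - 4
        assert min(r.overlap for r in res) >= MatchPolicy().min_overlap_scan

    def test_ranking_deterministic(self):
        sc = SyntheticScenario(seed=9, n_trees=1)
        master = generate_master(sc)
        (board,), _ = generate_boards(sc)
        r1 = scan_offsets(board, master)
        r2 = scan_offsets(board, master)
        assert [c.proposed_end_year for c in r1] == [c.proposed_end_year for c in r2]
        ts = [c.t_bp for c in r1]
        assert ts == sorted(ts, reverse=True)

    def test_short_reference_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            scan_offsets(_rand_series(rng, 60), _rand_series(rng, 30))


class TestSameTree:
    def test_self_is_positive(self):
        rng = np.random.default_rng(5)
        s = _rand_series(rng, 120)
        res = assess_same_tree(s, s, s.last_ring_year)
        assert res.match_class == "same_tree_candidate"
        assert res.r == pytest.approx(1.0)

    def test_boards_of_one_tree_are_flagged(self, study_boards):
        boards, truth = study_boards
        res = assess_same_tree(boards["GNM"], boards["RM"], 1606)
        assert res.match_class == "same_tree_candidate"
        assert res.t_bp > 10
        assert res.significance_class == "p001"

    def test_boards_of_different_trees_are_not(self):
        negatives = 0
        trials = 30
        for seed in range(trials):
            sc = SyntheticScenario(
                seed=seed,
                board_specs=(
                    BoardSpec(tree=0, n_rings=210, end_year=1600, board_id="A"),
                    BoardSpec(tree=1, n_rings=210, end_year=1600, board_id="B"),
                ),
            )
            boards, truth = generate_boards(sc)
            a, b = boards
            res = assess_same_tree(a, b, 1600)
            if res.match_class != "same_tree_candidate":
                negatives += 1
        assert negatives >= trials - 3

    def test_disregard_window_excludes_corrupt_span(self, study_boards):
        """Excluding an early span known to be corrupted raises the statistic,
        mirroring the practice of disregarding a faulty series start."""
        boards, _ = study_boards
        gnm, rm = boards["GNM"], boards["RM"]
        rng = np.random.default_rng(11)
        w = gnm.widths.copy()
        w[:31] = np.exp(0.25 * rng.standard_normal(31))  # corrupt 1397-1427
        corrupt = RingSeries("GNM2", w, gnm.last_ring_year)
        plain = assess_same_tree(corrupt, rm, 1606)
        masked = assess_same_tree(corrupt, rm, 1606, disregard=(1397, 1427))
        assert masked.t_bp > plain.t_bp
        assert masked.match_class == "same_tree_candidate"
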