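import numpy as np
import pytest

from dendrodate import (
    BoardSpec,
    SyntheticScenario,
    generate_boards,
    generate_master,
    inject_errors,
    study_scenario,
)
from dendrodate.crossdating import _pearson
from dendrodate.ring_signal import bp_transform
from dendrodate.synthetic_data import scenario_from_dict


def _acf1(x):
    x = x - x.mean()
    return float((x[:-1] @ x[1:]) / (x @ x))


class TestMaster:
    def test_deterministic_under_seed(self):
        a = generate_master(SyntheticScenario(seed=3))
        b = generate_master(SyntheticScenario(seed=3))
        np.testing.assert_array_equal(a.widths, b.widths)
        c = generate_master(SyntheticScenario(seed=4))
        assert not np.array_equal(a.widths, c.widths)

    def test_white_noise_has_no_persistence(self):
        sc = SyntheticScenario(seed=0, ar1_phi=0.0, master_span=(1100, 1599))
        m = generate_master(sc)
        assert abs(_acf1(np.log(m.widths))) < 0.1

    def test_phi_recovered_from_long_path(self):
        sc = SyntheticScenario(seed=1, ar1_phi=0.5, master_span=(0, 4999))
        m = generate_master(sc)
        assert _acf1(np.log(m.widths)) == pytest.approx(0.5, abs=0.05)

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            SyntheticScenario(ar1_phi=1.0)
        with pytest.raises(ValueError):
            SyntheticScenario(ar1_phi=-0.2)

    def test_span_and_positivity(self):
        m = generate_master(SyntheticScenario(seed=2))
        assert (m.first_ring_year, m.last_ring_year) == (1100, 1650)
        assert (m.widths > 0).all()


class TestBoards:
    def test_zero_measurement_noise_gives_identical_boards(self):
        sc = SyntheticScenario(seed=5, n_trees=1, boards_per_tree=2, measurement_sd=0.0)
        (a, b), _ = generate_boards(sc)
        np.testing.assert_array_equal(a.widths, b.widths)

    def test_study_scenario_reproduces_panel_structure(self):
        boards, truth = generate_boards(study_scenario(seed=7))
        by_id = {b.series_id: b for b in boards}
        gnm, rm, mh = by_id["GNM"], by_id["RM"], by_id["MH"]
        assert (gnm.n, gnm.first_ring_year, gnm.last_ring_year) == (210, 1397, 1606)
        assert gnm.hw_sw_border_is_last_ring and gnm.n_sapwood == 0
        assert (rm.n, rm.last_ring_year, rm.n_sapwood) == (231, 1614, 8)
        assert (mh.n, mh.first_ring_year, mh.last_ring_year) == (99, 1503, 1601)
        t = {b["board_id"]: b for b in truth["boards"]}
        assert t["GNM"]["tree"] == t["RM"]["tree"] != t["MH"]["tree"]
        assert t["GNM"]["hw_sw_border_year"] == t["RM"]["hw_sw_border_year"] == 1606

    def test_same_tree_boards_correlate_more_than_cross_tree(self):
        same, cross = [], []
        for seed in range(30):
            sc = SyntheticScenario(
                seed=seed,
                board_specs=(
                    BoardSpec(0, 210, 1600, "A0"),
                    BoardSpec(0, 210, 1600, "A1"),
                    BoardSpec(1, 210, 1600, "B0"),
                ),
            )
            (a0, a1, b0), _ = generate_boards(sc)
            ta0, ta1, tb0 = (bp_transform(s).values for s in (a0, a1, b0))
            same.append(_pearson(ta0, ta1))
            cross.append(_pearson(ta0, tb0))
        assert np.mean(same) > np.mean(cross) + 0.2

    def test_inter_board_correlation_monotone_in_signal_share(self):
        means = []
        for share in (0.2, 0.45, 0.7):
            rs = []
            for seed in range(30):
                sc = SyntheticScenario(
                    seed=seed,
                    tree_signal_share=share,
                    board_specs=(
                        BoardSpec(0, 210, 1600, "A"),
                        BoardSpec(1, 210, 1600, "B"),
                    ),
                )
                (a, b), _ = generate_boards(sc)
                rs.append(_pearson(bp_transform(a).values, bp_transform(b).values))
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_all_widths_positive(self):
        for seed in range(10):
            boards, _ = generate_boards(SyntheticScenario(seed=seed, n_trees=2, boards_per_tree=2))
            assert all((b.widths > 0).all() for b in boards)

    def test_board_outside_master_span_rejected(self):
        sc = SyntheticScenario(board_specs=(BoardSpec(0, 210, 1120, "X"),))
        with pytest.raises(ValueError, match="outside the master span"):
            generate_boards(sc)

    def test_determinism(self):
        a, ta = generate_boards(study_scenario(seed=3))
        b, tb = generate_boards(study_scenario(seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.widths, y.widths)
        assert ta == tb


class TestInjectErrors:
    def test_no_events_is_identity(self):
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        out = inject_errors(b, [])
        np.testing.assert_array_equal(out.widths, b.widths)
        assert out.last_ring_year == b.last_ring_year

    def test_doubled_conserves_total_width(self):
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        y = b.first_ring_year + 50
        out = inject_errors(b, [("doubled", y)])
        assert out.n == b.n + 1
        assert out.last_ring_year == b.last_ring_year + 1
        assert out.widths.sum() == pytest.approx(b.widths.sum())
        pos = y - b.first_ring_year
        assert out.widths[pos] == out.widths[pos + 1] == pytest.approx(b.widths[pos] / 2)

    def test_missing_drops_one_ring(self):
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        y = b.first_ring_year + 50
        out = inject_errors(b, [("missing", y)])
        assert out.n == b.n - 1
        assert out.last_ring_year == b.last_ring_year - 1
        np.testing.assert_array_equal(out.widths[:50], b.widths[:50])
        np.testing.assert_array_equal(out.widths[50:], b.widths[51:])

    def test_compensating_pair_preserves_length(self):
        """One ring too many and one too few: the series length and end year
        are unchanged, the classic hidden-error configuration."""
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        out = inject_errors(
            b, [("missing", b.first_ring_year + 8), ("doubled", b.first_ring_year + 30)]
        )
        assert out.n == b.n
        assert out.last_ring_year == b.last_ring_year

    def test_overlapping_events_rejected(self):
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        y = b.first_ring_year + 10
        with pytest.raises(ValueError, match="overlapping"):
            inject_errors(b, [("missing", y), ("doubled", y)])

    def test_event_outside_span_rejected(self):
        (b,), _ = generate_boards(SyntheticScenario(seed=0, n_trees=1))
        with pytest.raises(ValueError, match="outside"):
            inject_errors(b, [("missing", b.last_ring_year + 5)])


def test_scenario_from_dict_round_trip():
    cfg = {
        "seed": 9,
        "master_span": [1100, 1650],
        "sapwood_stats": {"region": "Poland (Wazny)", "sw_min": 9, "sw_median": 15,
                          "sw_max": 24, "confidence": 0.9},
        "board_specs": [
            {"tree": 0, "n_rings": 210, "end_year": 1606, "board_id": "GNM",
             "hw_sw_border_is_last_ring": True},
        ],
    }
    sc = scenario_from_dict(cfg)
    boards, truth = generate_boards(sc)
    assert boards[0].series_id == "GNM"
    assert boards[0].n == 210
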