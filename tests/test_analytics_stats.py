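"""Bout/transition analytics and statistics vs independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sstats

import swdsleep as sw
from swdsleep.types import ValidationError

W, N, R = sw.WAKE, sw.NREM, sw.REM


def rle_oracle(labels):
    out = []
    pos = 0
    for val, grp in itertools.groupby(labels):
        n = len(list(grp))
        out.append((val, pos, pos + n))
        pos += n
    return out


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestBouts:
    def test_constant_hypnogram_single_bout(self):
        bouts = sw.segment_bouts(sw.Hypnogram(np.array([W] * 8)))
        assert len(bouts) == 1
        assert bouts.loc[0, "duration_s"] == 40.0

    def test_alternating_labels(self):
        bouts = sw.segment_bouts(sw.Hypnogram(np.array([W, N, W, N])))
        assert len(bouts) == 4
        assert (bouts["end_epoch"] - bouts["start_epoch"] == 1).all()

    def test_matches_rle_oracle_on_random_hypnograms(self, rng):
        for _ in range(300):
            labels = rng.choice([W, N, R], size=rng.integers(1, 60))
            bouts = sw.segment_bouts(sw.Hypnogram(labels))
            want = rle_oracle(labels.tolist())
            assert len(bouts) == len(want)
            for (state, s, e), (_, row) in zip(want, bouts.iterrows()):
                assert (row["state"], row["start_epoch"], row["end_epoch"]) == (state, s, e)

    def test_bouts_tile_the_hypnogram(self, rng):
        labels = rng.choice([W, N, R], size=500)
        bouts = sw.segment_bouts(sw.Hypnogram(labels))
        assert bouts.loc[0, "start_epoch"] == 0
        assert bouts["end_epoch"].iloc[-1] == 500
        assert np.array_equal(
            bouts["start_epoch"].to_numpy()[1:], bouts["end_epoch"].to_numpy()[:-1]
        )


class TestStateTotals:
    def test_all_wake_24h(self):
        hyp = sw.Hypnogram(np.array([W] * (24 * 720)))
        s = sw.state_totals(hyp, sw.empty_events())
        assert s.states_24h[W]["total_min"] == 1440.0
        assert s.states_24h[W]["n_bouts"] == 1

    def test_swd_masking_reduces_wake_minutes(self):
        hyp = sw.Hypnogram(np.array([W] * 720))  # 1 h of wake
        ev = sw.events_frame([100.0], [160.0])  # 60-s event
        s = sw.state_totals(hyp, ev)
        masked_epochs = math.ceil(160 / 5) - math.floor(100 / 5)
        assert s.states_24h[W]["total_min"] == pytest.approx(60.0 - masked_epochs * 5 / 60)
        assert s.swd_masked_min == pytest.approx(masked_epochs * 5 / 60)

    def test_time_conservation_with_random_events(self, rng):
        labels = rng.choice([W, N, R], size=720)
        hyp = sw.Hypnogram(labels)
        starts = np.sort(rng.uniform(0, 3500, size=8))
        starts = starts[np.diff(np.concatenate([starts, [1e9]])) > 30]
        ev = sw.events_frame(starts, starts + 5.0)
        s = sw.state_totals(hyp, ev)
        state_min = sum(s.states_24h[x]["total_min"] for x in sw.STATES)
        total = state_min + s.swd_masked_min + s.unscored_min
        assert total == pytest.approx(s.duration_min, abs=hyp.epoch_len_s / 60)

    def test_hourly_state_minutes_sum_to_totals(self, rng):
        labels = rng.choice([W, N, R], size=720 * 3)
        hyp = sw.Hypnogram(labels)
        s = sw.state_totals(hyp, sw.empty_events())
        for x in sw.STATES:
            assert sum(s.hourly_state_min[x]) == pytest.approx(
                s.states_24h[x]["total_min"], abs=hyp.epoch_len_s / 60
            )


class TestEventStates:
    def test_transition_swd_flagged(self):
        labels = np.array([W] * 6 + [N] * 12)
        hyp = sw.Hypnogram(labels)
        ev = sw.events_frame([32.0], [36.0])  # 2 s into the NREM bout
        out = sw.assign_event_states(ev, hyp)
        assert out.loc[0, "onset_state"] == N
        assert bool(out.loc[0, "transition_flag"])

    def test_mid_wake_swd_not_flagged(self):
        hyp = sw.Hypnogram(np.array([W] * 120))
        out = sw.assign_event_states(sw.events_frame([300.0], [304.0]), hyp)
        assert out.loc[0, "onset_state"] == W
        assert not out.loc[0, "transition_flag"]

    def test_late_nrem_swd_not_flagged(self):
        labels = np.array([W] * 6 + [N] * 60)
        hyp = sw.Hypnogram(labels)
        ev = sw.events_frame([200.0], [204.0])  # far beyond the 30-s window
        out = sw.assign_event_states(ev, hyp)
        assert out.loc[0, "onset_state"] == N
        assert not out.loc[0, "transition_flag"]

    def test_batch_equals_per_event_assignment(self, rng):
        labels = rng.choice([W, N, R], size=240)
        hyp = sw.Hypnogram(labels)
        starts = np.sort(rng.uniform(0, 1150, size=12))
        starts = starts[np.diff(np.concatenate([starts, [1e9]])) > 10]
        ev = sw.events_frame(starts, starts + 3.0)
        whole = sw.assign_event_states(ev, hyp)
        for i in range(len(ev)):
            single = sw.assign_event_states(ev.iloc[[i]], hyp)
            assert single.loc[0, "onset_state"] == whole.loc[i, "onset_state"]
            assert single.loc[0, "transition_flag"] == whole.loc[i, "transition_flag"]

    def test_event_beyond_hypnogram_rejected(self):
        hyp = sw.Hypnogram(np.array([W] * 10))
        with pytest.raises(ValidationError):
            sw.assign_event_states(sw.events_frame([100.0], [104.0]), hyp)

    def test_proportions_arithmetic(self):
        ev = sw.events_frame(
            np.arange(20) * 10.0, np.arange(20) * 10.0 + 2,
            onset_state=[W] * 19 + [N],
        )
        pct = sw.state_event_proportions(ev)
        assert pct == {W: 95.0, N: 5.0, R: 0.0}

    def test_all_rem_onsets(self):
        ev = sw.events_frame([0.0], [1.0], onset_state=[R])
        assert sw.state_event_proportions(ev) == {W: 0.0, N: 0.0, R: 100.0}

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            sw.state_event_proportions(sw.empty_events())


class TestHourlyAndPhase:
    def test_hour_boundary_goes_to_later_bin(self):
        ev = sw.events_frame([3600.0], [3604.0])
        counts = sw.hourly_counts(ev, start_clock="00:00")
        assert counts[1] == 1 and counts.sum() == 1

    def test_empty_table_all_zero(self):
        assert sw.hourly_counts(sw.empty_events()).sum() == 0

    def test_bin_sums_conserve_total(self, rng):
        starts = np.sort(rng.uniform(0, 86000, size=40))
        starts = starts[np.diff(np.concatenate([starts, [1e9]])) > 10]
        ev = sw.events_frame(starts, starts + 2.0)
        assert sw.hourly_counts(ev).sum() == len(ev)

    def test_phase_split_partition(self, rng):
        hourly = rng.integers(0, 10, size=24)
        light, dark = sw.phase_split(hourly, lights_off_clock="19:00")
        assert light + dark == hourly.sum()
        # 19:00-06:59 are the dark hours
        assert dark == hourly[19:].sum() + hourly[:7].sum()

    def test_percent_of_baseline(self):
        assert sw.percent_of_baseline(20.0, 20.0) == 100.0
        assert sw.percent_of_baseline(5.0, 20.0) == 25.0
        with pytest.raises(ValidationError):
            sw.percent_of_baseline(5.0, 0.0)


class TestFisher:
    def test_reproduces_transition_contingency_p(self):
        # 15/15 animals with transition-initiated events vs 3/9
        p = sw.fisher_exact_2x2([[15, 0], [3, 6]])
        assert f"{p:.2g}" == "0.00062"

    def test_balanced_table_p_one(self):
        assert sw.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_symmetric_under_row_and_column_swap(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            p1 = sw.fisher_exact_2x2([[a, b], [c, d]])
            p2 = sw.fisher_exact_2x2([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            sw.fisher_exact_2x2([[0, 0], [0, 0]])


class TestKappa:
    def test_perfect_agreement(self):
        assert sw.cohens_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)

    def test_independent_margins_give_zero(self):
        # every cell equals row x col / total exactly
        mat = np.outer([10, 30], [20, 20]) / 40
        assert sw.cohens_kappa(mat) == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle_random(self, rng):
        for _ in range(100):
            mat = rng.integers(0, 40, size=(3, 3)).astype(float)
            if mat.sum() == 0:
                continue
            total = mat.sum()
            p_o = np.trace(mat) / total
            p_e = sum(mat[i].sum() * mat[:, i].sum() for i in range(3)) / total**2
            if np.isclose(p_e, 1):
                continue
            assert sw.cohens_kappa(mat) == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_matches_sklearn_on_label_vectors(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.choice([0, 1, 2], size=300)
        b = np.where(rng.random(300) < 0.7, a, rng.choice([0, 1, 2], size=300))
        mat = np.zeros((3, 3))
        for x, y in zip(a, b):
            mat[x, y] += 1
        assert sw.cohens_kappa(mat) == pytest.approx(cohen_kappa_score(a, b))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, t, df, p = sw.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reported_t_for_constructed_r(self):
        # n = 15, r = -0.514 -> t = -2.16, df = 13
        rng = np.random.default_rng(0)
        x = rng.standard_normal(15)
        e = rng.standard_normal(15)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # orthogonalize
        target = -0.514
        y = target * (x - x.mean()) / x.std() + np.sqrt(1 - target**2) * e / e.std()
        r, t, df, p = sw.pearson_r(x, y)
        assert r == pytest.approx(target, abs=1e-9)
        assert df == 13
        assert t == pytest.approx(-2.16, abs=0.01)

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            r, t, df, p = sw.pearson_r(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            r_direct = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
            assert r == pytest.approx(r_direct)
            assert t == pytest.approx(r_direct * np.sqrt(10) / np.sqrt(1 - r_direct**2))
            assert p == pytest.approx(2 * sstats.t.sf(abs(t), 10))

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            sw.pearson_r(np.ones(5), np.arange(5.0))


class TestTwoSample:
    def test_identical_groups_rank_sum_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = sw.two_sample_test(a, a + 0.0001 * np.array([1, -1, 1, -1]),
                                  method="rank_sum")
        assert p > 0.8

    def test_exact_rank_sum_matches_permutation_oracle(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(6) + 0.8
        w_obs, p = sw.two_sample_test(a, b, method="rank_sum")
        combined = np.concatenate([a, b])
        ranks = sstats.rankdata(combined)
        n = len(a)
        w_all = np.array([
            sum(ranks[list(idx)]) for idx in itertools.combinations(range(11), n)
        ])
        mu = w_all.mean()
        p_oracle = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
        assert w_obs == pytest.approx(sum(ranks[:n]))
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_welch_t_matches_scipy(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(15) + 1.0
        stat, p = sw.two_sample_test(a, b, method="welch_t")
        ref = sstats.ttest_ind(a, b, equal_var=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_power_at_large_standardized_difference(self, rng):
        hits = 0
        for _ in range(60):
            a = rng.standard_normal(9)
            b = rng.standard_normal(15) + 1.5
            _, p = sw.two_sample_test(a, b)
            hits += p < 0.05
        assert hits >= 0.8 * 60

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            sw.two_sample_test([1.0], [2.0, 3.0])
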