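"""Shift classification, round aggregation, clade stratification, sweep."""

import random

import numpy as np
import pytest

from ghostshift import (
    GhostShiftError,
    GhostTransfer,
    classify_pair,
    ghost_fraction_sweep,
    make_fixture_space,
    pair_matrix,
    round_rng,
    run_experiment,
    run_round,
    shift_probability_oracle,
)

FECA, LECA = 2.42, 1.89


def _gt(g, tau, label="S", bid="b0"):
    return GhostTransfer(bid, label, g, tau, observed_age=g)


class TestClassifyPair:
    def test_consistent_ordering_is_no_shift(self, window):
        c = classify_pair((_gt(2.3, 2.1), _gt(2.0, 1.95)), window)
        assert (c.true_early, c.observed_early, c.is_shift) == (1, 1, False)

    def test_constructed_reversal_inside_window(self, window):
        c = classify_pair((_gt(2.4, 1.90), _gt(2.0, 1.99)), window)
        assert (c.true_early, c.observed_early) == (2, 1)
        assert c.is_shift and not c.outside_window

    def test_shift_with_observed_age_older_than_window(self, window):
        c = classify_pair((_gt(2.50, 1.90), _gt(2.0, 1.99)), window)
        assert c.is_shift and c.outside_window

    def test_ties_classify_as_no_shift(self, window):
        assert not classify_pair((_gt(2.0, 2.0), _gt(2.0, 1.95)), window).is_shift
        assert not classify_pair((_gt(2.1, 1.95), _gt(2.3, 1.95)), window).is_shift

    def test_member_swap_symmetry(self, window):
        rng = random.Random(0)
        for _ in range(300):
            a = _gt(rng.uniform(LECA, 3.0), rng.uniform(LECA, FECA))
            b = _gt(rng.uniform(LECA, 3.0), rng.uniform(LECA, FECA))
            fwd = classify_pair((a, b), window)
            rev = classify_pair((b, a), window)
            assert fwd.is_shift == rev.is_shift
            assert fwd.outside_window == rev.outside_window


class TestRunRound:
    def test_single_pair_proportion_is_binary(self, symmetric_space):
        space, window = symmetric_space
        s = run_round(space, window, 1, round_rng(1, 0))
        assert s.shift_proportion in (0.0, 1.0)

    def test_symmetric_fixture_quarter(self, symmetric_space):
        space, window = symmetric_space
        s = run_round(space, window, 100_000, round_rng(2, 0))
        se = np.sqrt(0.25 * 0.75 / 100_000)
        assert abs(s.shift_proportion - 0.25) < 3 * se

    def test_symmetric_fixture_never_outside_window(self, symmetric_space):
        # sister born exactly at the older bound: ghost births can't exceed it
        space, window = symmetric_space
        s = run_round(space, window, 50_000, round_rng(3, 0))
        assert s.outside_given_shift == 0.0
        assert s.confounding_proportion == s.shift_proportion

    def test_invalid_arguments(self, symmetric_space):
        space, window = symmetric_space
        with pytest.raises(GhostShiftError):
            run_round(space, window, 0, round_rng(0, 0))
        with pytest.raises(GhostShiftError):
            run_round(space, window, 10, round_rng(0, 0), p_ghost=1.5)


class TestRunExperiment:
    def test_deterministic_given_seed(self, symmetric_space):
        space, window = symmetric_space
        a = run_experiment(space, window, n_rounds=3, n_pairs=50, seed=7)
        b = run_experiment(space, window, n_rounds=3, n_pairs=50, seed=7)
        assert a.rounds.equals(b.rounds)
        assert a.pairs.equals(b.pairs)

    def test_pooled_mean_near_quarter(self, symmetric_space):
        space, window = symmetric_space
        e = run_experiment(space, window, n_rounds=100, n_pairs=1000, seed=11)
        se = np.sqrt(0.25 * 0.75 / e.n_pairs_total)
        assert abs(e.shift_proportion - 0.25) < 3 * se
        q = e.pooled.loc["shift_prop"]
        assert q["q2.5"] <= q["q50"] <= q["q97.5"]

    def test_confounding_identity_per_round(self, two_clade_fixture):
        space, window = make_fixture_space(two_clade_fixture)
        e = run_experiment(space, window, n_rounds=20, n_pairs=500, seed=13)
        r = e.rounds.dropna()
        np.testing.assert_allclose(
            r["confounding_prop"], r["shift_prop"] * (1 - r["outside_prop"])
        )
        assert (e.rounds["confounding_prop"] <= e.rounds["shift_prop"] + 1e-12).all()

    def test_shift_proportion_bounded_by_coin_flip(self, two_clade_fixture):
        space, window = make_fixture_space(two_clade_fixture)
        e = run_experiment(space, window, n_rounds=10, n_pairs=10_000, seed=17)
        se = np.sqrt(0.25 / e.n_pairs_total)
        assert e.shift_proportion <= 0.5 + 3 * se

    def test_audit_log_schema(self, symmetric_space):
        space, window = symmetric_space
        e = run_experiment(space, window, n_rounds=2, n_pairs=5, seed=1, audit=True)
        assert list(e.audit.columns) == [
            "round", "pair_index", "member", "branch_id",
            "clade_label", "ghost_birth", "transfer_age", "observed_age",
        ]
        assert len(e.audit) == 2 * 2 * 5
        assert (e.audit["observed_age"] == e.audit["ghost_birth"]).all()


class TestPairMatrix:
    def test_single_clade_collapses_to_overall_proportion(self, symmetric_space):
        space, window = symmetric_space
        e = run_experiment(space, window, n_rounds=5, n_pairs=400, seed=3)
        mat = pair_matrix(e.pairs)
        assert mat.labels == ["S"]
        prop, n = mat.cell("S", "S")
        assert n == 2000
        assert prop == pytest.approx(e.shift_proportion)

    def test_two_clade_cells_match_conditional_oracle(self, two_clade_fixture):
        space, window = make_fixture_space(two_clade_fixture)
        e = run_experiment(space, window, n_rounds=10, n_pairs=10_000, seed=23)
        mat = pair_matrix(e.pairs)
        for pair_idx, cell in (((0, 0), ("P", "P")), ((0, 1), ("P", "Q")), ((1, 1), ("Q", "Q"))):
            p_hat, n = mat.cell(*cell)
            p_oracle, se_o = shift_probability_oracle(
                two_clade_fixture, pair_idx, p_ghost=1.0, n_draws=60_000, seed=101
            )
            se = np.sqrt(se_o**2 + p_hat * (1 - p_hat) / n)
            assert abs(p_hat - p_oracle) < 3 * se, cell

    def test_matrix_is_symmetric_with_nan_for_empty(self, two_clade_fixture):
        space, window = make_fixture_space(two_clade_fixture)
        e = run_experiment(space, window, n_rounds=2, n_pairs=200, seed=5)
        m = pair_matrix(e.pairs).to_matrix()
        assert m.equals(m.T)
        assert not m.isna().any().any()  # all three cells sampled here


class TestGhostFractionSweep:
    def test_p_zero_yields_exactly_no_shifts(self, symmetric_space):
        space, window = symmetric_space
        df = ghost_fraction_sweep(space, window, [0.0], 5000, seed=1)
        assert df["shift_prop"].iloc[0] == 0.0

    def test_p_one_matches_base_simulation(self, symmetric_space):
        space, window = symmetric_space
        df = ghost_fraction_sweep(space, window, [1.0], 100_000, seed=2)
        se = np.sqrt(0.25 * 0.75 / 100_000)
        assert abs(df["shift_prop"].iloc[0] - 0.25) < 3 * se

    def test_half_ghosts_match_mixture_decomposition_oracle(self, symmetric_space):
        """p=0.5 decomposes over the four ghost/sampled member combinations.

        Weights {p^2, p(1-p), (1-p)p, (1-p)^2}; both-sampled contributes 0,
        the two single-ghost terms are equal by symmetry. Conditional shift
        probabilities are Monte-Carlo-integrated with straight-line draws.
        """
        space, window = symmetric_space
        p = 0.5
        rng = random.Random(99)
        n = 60_000
        shifts_gg = shifts_ge = 0
        for _ in range(n):
            g1, g2 = (rng.uniform(LECA, FECA) for _ in range(2))
            t1, t2 = rng.uniform(LECA, g1), rng.uniform(LECA, g2)
            if (t1 - t2) * (g1 - g2) < 0:
                shifts_gg += 1
            if (t1 - t2) * (g1 - t2) < 0:
                shifts_ge += 1
        expected = p * p * shifts_gg / n + 2 * p * (1 - p) * shifts_ge / n
        df = ghost_fraction_sweep(space, window, [p], 100_000, seed=3)
        observed = df["shift_prop"].iloc[0]
        se = np.sqrt(expected * (1 - expected) * (1 / n + 1 / 100_000))
        assert abs(observed - expected) < 3 * se

    def test_grid_validation(self, symmetric_space):
        space, window = symmetric_space
        with pytest.raises(GhostShiftError, match="outside"):
            ghost_fraction_sweep(space, window, [0.0, 1.5], 100, seed=1)

    def test_sweep_curve_rises_from_zero_toward_plateau(self, symmetric_space):
        space, window = symmetric_space
        df = ghost_fraction_sweep(space, window, [0.0, 0.25, 0.5, 0.75, 1.0], 20_000, seed=4)
        vals = df["shift_prop"].to_numpy()
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) > -0.01)  # rising, up to Monte Carlo wiggle
        assert vals[-1] > 0.2
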