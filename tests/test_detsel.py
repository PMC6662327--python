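"""Deterministic one-locus selection, frequency dependence, mutation balance, sex ratio."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popgenlab import (
    AllOneSexError,
    DomainError,
    FitnessScheme,
    SexRatioModel,
    delta_p,
    equilibria,
    freqdep_step,
    freqdep_trajectory,
    mean_fitness,
    mutation_selection_equilibrium,
    mutation_selection_step,
    selection_step,
    selection_trajectory,
    sexratio_step,
    sexratio_trajectory,
)


def bisect_delta_p(w, lo=1e-9, hi=1 - 1e-9, tol=1e-12):
    """Independent bisection oracle for the interior root of delta-p."""
    flo = delta_p(lo, w)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = delta_p(mid, w)
        if hi - lo < tol:
            return mid
        if (flo < 0) == (fmid < 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestFitnessScheme:
    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, math.nan, 1), (1, math.inf, 1), (0, 0, 0)])
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(DomainError):
            FitnessScheme(*bad)

    def test_dominance_predicates(self):
        assert FitnessScheme(1, 2, 1).is_overdominant
        assert FitnessScheme(1, 0.5, 1).is_underdominant
        assert FitnessScheme(1, 1, 1).is_neutral


class TestMeanFitness:
    @pytest.mark.parametrize("p, w, expected", [
        (0.5, (1, 1, 1), 1.0),
        (0.5, (1, 2, 1), 1.5),       # 0.25*1 + 0.5*2 + 0.25*1
        (0.0, (1.3, 0.7, 0.4), 0.4),  # monomorphic aa
        (1.0, (1.3, 0.7, 0.4), 1.3),  # monomorphic AA
    ])
    def test_known_values(self, p, w, expected):
        assert mean_fitness(p, FitnessScheme(*w)) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_frequency(self):
        with pytest.raises(DomainError):
            mean_fitness(1.5, FitnessScheme(1, 1, 1))


class TestSelectionStep:
    def test_neutrality_is_identity(self):
        assert selection_step(0.5, FitnessScheme(1, 1, 1)) == 0.5
        assert selection_step(0.123, FitnessScheme(2, 2, 2)) == 0.123

    def test_boundaries_are_fixed_points(self):
        w = FitnessScheme(1.4, 0.9, 0.2)
        assert selection_step(0.0, w) == 0.0
        assert selection_step(1.0, w) == 1.0
        assert delta_p(0.0, w) == 0.0
        assert delta_p(1.0, w) == 0.0

    def test_overdominant_interior_equilibrium_matches_bisection(self):
        w = FitnessScheme(0.8, 1, 0.9)
        root = bisect_delta_p(w)
        assert root == pytest.approx(1 / 3, abs=1e-9)
        assert selection_step(root, w) == pytest.approx(root, abs=1e-12)

    def test_directional_advantage_increases_p(self):
        assert selection_step(0.1, FitnessScheme(1.2, 1.1, 1.0)) > 0.1

    def test_degenerate_mean_fitness_raises(self):
        from popgenlab import DegenerateModelError
        with pytest.raises(DegenerateModelError):
            # the only surviving genotype is vanishingly rare: wbar underflows to 0
            selection_step(0.999, FitnessScheme(0, 0, 5e-324))


class TestDeltaP:
    def test_symmetric_overdominance_equilibrium(self):
        assert delta_p(0.5, FitnessScheme(1, 2, 1)) == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_underdominance_unstable(self):
        w = FitnessScheme(1, 0.8, 1)
        assert delta_p(0.5, w) == pytest.approx(0.0, abs=1e-15)
        eps = 1e-3
        assert abs(selection_step(0.5 + eps, w) - 0.5) > eps
        assert abs(selection_step(0.5 - eps, w) - 0.5) > eps


class TestSelectionTrajectory:
    def test_record_shape_and_initial_value(self):
        traj = selection_trajectory(0.3, FitnessScheme(1, 0.9, 0.8), 50)
        assert traj.p.size == 51
        assert traj.p[0] == 0.3
        assert np.all((traj.p >= 0) & (traj.p <= 1))

    def test_starts_at_equilibrium_stays_there(self):
        traj = selection_trajectory(0.5, FitnessScheme(1, 2, 1), 100)
        assert np.all(traj.p == 0.5)

    def test_dominant_advantage_fast_start_slow_finish(self):
        # dominant advantageous allele: rapid early gain, decelerating approach to 1
        traj = selection_trajectory(0.01, FitnessScheme(1, 1, 0.8), 2000)
        dp = np.diff(traj.p)
        assert traj.p[-1] > 0.99
        assert np.argmax(dp) < 100            # early surge
        assert np.all(np.diff(dp[-200:]) <= 1e-15)  # late deceleration

    def test_recessive_advantage_starts_slower_than_dominant(self):
        dom = selection_trajectory(0.01, FitnessScheme(1, 1, 0.8), 50)
        rec = selection_trajectory(0.01, FitnessScheme(1, 0.8, 0.8), 50)
        assert rec.p[-1] < dom.p[-1]

    def test_mean_fitness_never_decreases(self):
        for w in [(1, 0.9, 0.8), (0.8, 1, 0.9), (1, 0.8, 0.9), (1.5, 1.2, 1.0)]:
            traj = selection_trajectory(0.2, FitnessScheme(*w), 300)
            assert np.all(np.diff(traj.wbar) >= -1e-12)

    @given(
        p0=st.floats(0.01, 0.99),
        c=st.floats(0.1, 10.0),
        w=st.tuples(st.floats(0.1, 2.0), st.floats(0.1, 2.0), st.floats(0.1, 2.0)),
    )
    def test_fitness_scale_invariance(self, p0, c, w):
        base = selection_trajectory(p0, FitnessScheme(*w), 50)
        scaled = selection_trajectory(p0, FitnessScheme(*w).scaled(c), 50)
        assert np.allclose(base.p, scaled.p, atol=1e-12)

    @given(p0=st.floats(0.0, 1.0),
           w=st.tuples(st.floats(0.05, 3.0), st.floats(0.05, 3.0), st.floats(0.05, 3.0)))
    def test_frequencies_stay_in_unit_interval(self, p0, w):
        traj = selection_trajectory(p0, FitnessScheme(*w), 30)
        assert np.all((traj.p >= 0.0) & (traj.p <= 1.0))

    def test_csv_export_row_count(self, tmp_path):
        traj = selection_trajectory(0.3, FitnessScheme(1, 0.9, 0.8), 10)
        f = tmp_path / "traj.csv"
        traj.to_csv(f)
        lines = f.read_text().strip().splitlines()
        assert lines[0] == "generation,p,q,wbar"
        assert len(lines) == 12


class TestEquilibria:
    def test_symmetric_overdominance(self):
        report = equilibria(FitnessScheme(1, 2, 1))
        interior = report.interior
        assert interior.p_hat == pytest.approx(0.5, abs=1e-12)
        assert interior.stability == "stable"

    def test_interior_matches_bisection_oracle(self):
        w = FitnessScheme(0.8, 1, 0.9)
        report = equilibria(w)
        assert report.interior.p_hat == pytest.approx(bisect_delta_p(w), abs=1e-9)
        assert report.interior.stability == "stable"

    def test_underdominance_interior_unstable(self):
        report = equilibria(FitnessScheme(1, 0.8, 0.9))
        assert report.interior.p_hat == pytest.approx(1 / 3, abs=1e-12)
        assert report.interior.stability == "unstable"

    def test_directional_scheme_has_boundaries_only(self):
        # codominant directional advantage: delta-p > 0 throughout (0, 1)
        report = equilibria(FitnessScheme(1.2, 1.1, 1.0))
        assert report.interior is None
        stabilities = {eq.p_hat: eq.stability for eq in report}
        assert stabilities[0.0] == "unstable"
        assert stabilities[1.0] == "stable"

    def test_boundaries_always_reported(self):
        for w in [(1, 1, 1), (1, 2, 1), (1.2, 1.1, 1)]:
            p_hats = [eq.p_hat for eq in equilibria(FitnessScheme(*w))]
            assert 0.0 in p_hats and 1.0 in p_hats


class TestFreqDep:
    def test_zero_coefficient_is_neutral(self):
        for p in (0.1, 0.5, 0.9):
            assert freqdep_step(p, 0.0) == p

    def test_positive_s_half_is_unstable(self):
        assert freqdep_step(0.5, 0.5) == pytest.approx(0.5, abs=1e-15)
        eps = 1e-3
        traj_up = freqdep_trajectory(0.5 + eps, 0.5, 200)
        traj_dn = freqdep_trajectory(0.5 - eps, 0.5, 200)
        assert traj_up.p[-1] > 0.5 + eps
        assert traj_dn.p[-1] < 0.5 - eps

    def test_negative_s_stable_polymorphism_at_half(self):
        for p0 in (0.2, 0.8):
            traj = freqdep_trajectory(p0, -0.5, 2000)
            assert traj.p[-1] == pytest.approx(0.5, abs=1e-9)

    def test_invalid_coefficient(self):
        with pytest.raises(DomainError):
            freqdep_step(0.5, 1.5)


class TestMutationSelection:
    def test_zero_mutation_reduces_to_selection(self):
        w = FitnessScheme(1, 0.9, 0.8)
        assert mutation_selection_step(0.4, w, 0.0) == selection_step(0.4, w)

    def test_pure_mutation_decay(self):
        assert mutation_selection_step(0.5, FitnessScheme(1, 1, 1), 0.01) == \
            pytest.approx(0.495, abs=1e-15)

    def test_recessive_lethal_balance_near_sqrt_mu(self):
        # classic q_hat ~ sqrt(mu/s); s=1 here, and the recursion's exact
        # fixed point is q = sqrt(mu)
        p_hat = mutation_selection_equilibrium(FitnessScheme(1, 1, 0), 1e-4)
        q_hat = 1 - p_hat
        assert q_hat == pytest.approx(0.01, rel=0.05)

    def test_balance_agrees_with_independent_fixed_point_iteration(self):
        w, mu = FitnessScheme(1, 1, 0.5), 1e-3
        p = 0.999
        for _ in range(200000):  # plain-loop oracle
            p_next = selection_step(p, w) * (1 - mu)
            if abs(p_next - p) < 1e-13:
                break
            p = p_next
        assert mutation_selection_equilibrium(w, mu) == pytest.approx(p, abs=1e-10)

    def test_invalid_mu(self):
        with pytest.raises(DomainError):
            mutation_selection_step(0.5, FitnessScheme(1, 1, 1), 1.0)


class TestSexRatio:
    def test_fisherian_optimum_is_fixed_point(self):
        m = SexRatioModel(ratios=(0.5,), freqs=(1.0,))
        out = sexratio_step(m)
        assert out.freqs == (1.0,)
        assert out.mean_ratio == 0.5

    def test_balanced_mixture_unchanged(self):
        m = SexRatioModel(ratios=(0.3, 0.7), freqs=(0.5, 0.5))
        out = sexratio_step(m)
        assert out.freqs[0] == pytest.approx(0.5, abs=1e-15)
        assert out.freqs[1] == pytest.approx(0.5, abs=1e-15)

    def test_scarcer_sex_strategy_wins(self):
        # both strategies overproduce daughters; the one nearer 1/2 fixes
        m = SexRatioModel(ratios=(0.2, 0.5), freqs=(0.5, 0.5))
        traj = sexratio_trajectory(m, 2000)
        # convergence is algebraic once R nears 1/2, so check monotone approach
        assert np.all(np.diff(traj.freqs[:, 1]) > 0)
        assert traj.freqs[-1, 1] == pytest.approx(1.0, abs=2e-3)

    def test_mean_fitness_is_exactly_two(self):
        m = SexRatioModel(ratios=(0.2, 0.6, 0.9), freqs=(0.3, 0.5, 0.2))
        R = m.mean_ratio
        w = [r / R + (1 - r) / (1 - R) for r in m.ratios]
        assert sum(f * wi for f, wi in zip(m.freqs, w)) == pytest.approx(2.0, abs=1e-12)

    def test_frequencies_stay_normalised(self):
        m = SexRatioModel(ratios=(0.1, 0.4, 0.8), freqs=(0.6, 0.3, 0.1))
        traj = sexratio_trajectory(m, 500)
        assert np.allclose(traj.freqs.sum(axis=1), 1.0, atol=1e-12)

    def test_all_one_sex_raises(self):
        with pytest.raises(AllOneSexError):
            sexratio_step(SexRatioModel(ratios=(0.0,), freqs=(1.0,)))

    def test_invalid_frequencies(self):
        with pytest.raises(DomainError):
            SexRatioModel(ratios=(0.5, 0.5), freqs=(0.7, 0.7))
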