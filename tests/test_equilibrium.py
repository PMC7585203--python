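"""Competitive-equilibrium solver: oracles, invariants, partition prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylbind.equilibrium import (
    BindingSystem,
    DomainError,
    StoichiometryScenario,
    excess_limit_ratio,
    predict_partition,
    solve_competitive,
    solve_single_site,
    sweep_scenarios,
)


def bisection_receptor_free(r_total, ligand_totals, kds, tol=1e-14, max_iter=500):
    """Independent oracle: plain bisection on the scalar mass-balance residual."""
    ligand_totals = list(ligand_totals)
    kds = list(kds)

    def f(r):
        return r * (1.0 + sum(l / (k + r) for l, k in zip(ligand_totals, kds))) - r_total

    lo, hi = 0.0, r_total
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(1.0, r_total):
            break
    return 0.5 * (lo + hi)


def fixed_point_state(r_total, ligand_totals, kds, damping=0.5, tol=1e-12, max_iter=100_000):
    """Independent oracle: damped fixed-point iteration on free concentrations."""
    lf = np.asarray(ligand_totals, dtype=float).copy()
    kds = np.asarray(kds, dtype=float)
    lt = np.asarray(ligand_totals, dtype=float)
    r = r_total
    for _ in range(max_iter):
        r_new = r_total / (1.0 + np.sum(lf / kds))
        lf_new = lt / (1.0 + r_new / kds)
        r_next = damping * r_new + (1 - damping) * r
        lf_next = damping * lf_new + (1 - damping) * lf
        if abs(r_next - r) < tol and np.all(np.abs(lf_next - lf) < tol):
            r, lf = r_next, lf_next
            break
        r, lf = r_next, lf_next
    complexes = r * lf / kds
    return r, lf, complexes


def assert_mass_conserved(state, rtol=1e-9):
    total = state.receptor_free + sum(state.complexes)
    assert total == pytest.approx(state.receptor_total, rel=rtol, abs=1e-15)
    for lt, lf, c in zip(state.ligand_totals, state.ligand_free, state.complexes):
        assert lf + c == pytest.approx(lt, rel=rtol, abs=1e-15)
    assert state.free_fraction + sum(state.occupancy_fractions) == pytest.approx(1.0, abs=1e-9)
    assert state.receptor_free >= 0
    assert all(v >= 0 for v in state.ligand_free + state.complexes)


class TestSingleSite:
    def test_no_ligand_leaves_receptor_free(self):
        st_ = solve_single_site(1.0, 0.0, 0.041)
        assert st_.complexes[0] == 0.0
        assert st_.receptor_free == 1.0

    def test_saturating_ligand_drives_full_occupancy(self):
        st_ = solve_single_site(1.0, 1e6, 0.041)
        assert st_.occupancy_fractions[0] == pytest.approx(1.0, abs=1e-4)

    def test_matches_bisection_on_comparable_totals(self):
        r = bisection_receptor_free(0.5, [0.5], [0.19])
        expected_complex = 0.5 - r
        st_ = solve_single_site(0.5, 0.5, 0.19)
        assert st_.complexes[0] == pytest.approx(expected_complex, abs=1e-10)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, -1, 1), (1, 1, 0), (1, 1, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            solve_single_site(*bad)


class TestCompetitiveSolver:
    def test_degenerate_second_ligand_reduces_to_single_site(self):
        sys2 = BindingSystem(1.0, (0.7, 0.0), (0.19, 0.041))
        st2 = solve_competitive(sys2)
        st1 = solve_single_site(1.0, 0.7, 0.19)
        assert st2.complexes[0] == pytest.approx(st1.complexes[0], rel=1e-9)
        assert st2.complexes[1] == 0.0

    def test_single_ligand_matches_closed_form_quadratic(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            r_t, l_t = rng.uniform(0, 100, 2)
            kd = 10 ** rng.uniform(-3, 3)
            st_c = solve_competitive(BindingSystem(r_t, (l_t,), (kd,)))
            st_q = solve_single_site(r_t, l_t, kd)
            assert st_c.complexes[0] == pytest.approx(st_q.complexes[0], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("n_ligands", [1, 2, 3, 4])
    def test_matches_bisection_oracle_random_systems(self, n_ligands):
        rng = np.random.default_rng(123 + n_ligands)
        for _ in range(50):
            r_t = rng.uniform(0, 100)
            lig = rng.uniform(0, 100, n_ligands)
            kds = 10 ** rng.uniform(-3, 3, n_ligands)
            state = solve_competitive(BindingSystem(r_t, tuple(lig), tuple(kds)))
            r_oracle = bisection_receptor_free(r_t, lig, kds)
            assert state.receptor_free == pytest.approx(r_oracle, rel=1e-9, abs=1e-9)
            assert_mass_conserved(state)

    def test_matches_damped_fixed_point_oracle_small_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            r_t = rng.uniform(0, 10)
            lig = rng.uniform(0, 10, 3)
            kds = 10 ** rng.uniform(-2, 2, 3)
            state = solve_competitive(BindingSystem(r_t, tuple(lig), tuple(kds)))
            r_fp, lf_fp, c_fp = fixed_point_state(r_t, lig, kds)
            assert state.receptor_free == pytest.approx(r_fp, rel=1e-8, abs=1e-10)
            np.testing.assert_allclose(state.complexes, c_fp, rtol=1e-8, atol=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        r_t=st.floats(0.0, 100.0),
        lig=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=4),
        log_kds=st.lists(st.floats(-3, 3), min_size=4, max_size=4),
    )
    def test_mass_conservation_property(self, r_t, lig, log_kds):
        kds = tuple(10.0 ** k for k in log_kds[: len(lig)])
        state = solve_competitive(BindingSystem(r_t, tuple(lig), kds))
        assert_mass_conserved(state)

    def test_occupancy_monotone_in_own_total_and_kd_and_competitor(self):
        base = dict(r_t=1.0, l1=5.0, l2=5.0, kd1=0.5, kd2=0.5)

        def occ0(l1, l2, kd1, kd2):
            s = solve_competitive(BindingSystem(base["r_t"], (l1, l2), (kd1, kd2)))
            return s.occupancy_fractions[0]

        grid = np.linspace(0.1, 50, 12)
        occ_own = [occ0(l1, 5.0, 0.5, 0.5) for l1 in grid]
        assert np.all(np.diff(occ_own) >= -1e-12)
        occ_kd = [occ0(5.0, 5.0, kd, 0.5) for kd in grid]
        assert np.all(np.diff(occ_kd) <= 1e-12)
        occ_comp = [occ0(5.0, l2, 0.5, 0.5) for l2 in grid]
        assert np.all(np.diff(occ_comp) <= 1e-12)


class TestPartitionPrediction:
    def test_default_scenario_gives_99_percent_on_histone(self):
        state = predict_partition()
        h3 = state.occupancy("H3K9me2")
        lig1 = state.occupancy("LIG1K126me2")
        assert round(h3 * 100) == 99
        assert lig1 * 100 < 1.0

    def test_no_histone_methylation_hands_receptor_to_lig1(self):
        scen = StoichiometryScenario(h3_me2_fraction=0.0, absolute_scale=100.0)
        state = predict_partition(scen)
        assert state.occupancy("H3K9me2") == 0.0
        # LIG1 total is half the receptor total, so all bound receptor is
        # LIG1-bound and the ligand itself is nearly exhausted
        bound = sum(state.complexes)
        assert state.complexes[1] == pytest.approx(bound, rel=1e-12)
        assert state.ligand_free[1] / state.ligand_totals[1] < 0.05

    def test_scale_robustness_of_headline_fraction(self):
        for scale in [0.1, 1.0, 10.0, 100.0, 1000.0]:
            state = predict_partition(StoichiometryScenario(absolute_scale=scale))
            assert state.occupancy("H3K9me2") >= 0.985

    def test_partition_approaches_excess_limit_at_large_scale(self):
        shares = excess_limit_ratio([350.0, 0.5], [0.19, 0.041])
        for scale in [10.0, 100.0]:
            state = predict_partition(StoichiometryScenario(absolute_scale=scale))
            occ = np.array(state.occupancy_fractions)
            ratio_model = occ[0] / occ[1]
            ratio_limit = shares[0] / shares[1]
            assert ratio_model == pytest.approx(ratio_limit, rel=0.05)


class TestExcessLimit:
    def test_published_abundances_put_under_one_percent_on_lig1(self):
        shares = excess_limit_ratio([350.0, 0.5], [0.19, 0.041])
        w = np.array([350.0 / 0.19, 0.5 / 0.041])
        np.testing.assert_allclose(shares, w / w.sum())
        assert shares[1] < 0.01

    def test_symmetric_ligands_split_evenly(self):
        np.testing.assert_allclose(excess_limit_ratio([3, 3], [0.2, 0.2]), [0.5, 0.5])

    def test_weak_binder_share_vanishes(self):
        shares = excess_limit_ratio([1.0, 1.0], [0.1, 1e12])
        assert shares[1] == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_totals_rejected(self):
        with pytest.raises(DomainError):
            excess_limit_ratio([0.0, 0.0], [0.1, 0.1])


class TestSweep:
    def test_methyl_fraction_sweep_spans_printed_abundance_band(self):
        base = StoichiometryScenario()
        res = sweep_scenarios(base, {"h3_me2_fraction": (0.35, 1.0)}, grid_size=14)
        ratios = res.table["methyl_abundance_ratio"]
        assert ratios.min() == pytest.approx(700.0)
        assert ratios.max() == pytest.approx(2000.0)
        # discussion band: vary LIG1 me2 fraction instead
        res2 = sweep_scenarios(base, {"lig1_me2_fraction": (0.35, 1.0)}, grid_size=14)
        r2 = res2.table["methyl_abundance_ratio"]
        assert r2.min() == pytest.approx(350.0)
        assert r2.max() == pytest.approx(1000.0)

    def test_degenerate_interval_is_point_prediction(self):
        base = StoichiometryScenario()
        res = sweep_scenarios(base, {"kd_lig1": (0.041, 0.041)}, grid_size=9)
        assert len(res.table) == 1
        state = predict_partition(base)
        assert res.table["H3K9me2_occupancy"].iloc[0] == pytest.approx(
            state.occupancy("H3K9me2"), rel=1e-12
        )

    def test_weakening_lig1_kd_monotonically_lowers_its_occupancy(self):
        base = StoichiometryScenario()
        res = sweep_scenarios(base, {"kd_lig1": (0.01, 10.0)}, grid_size=15)
        occ = res.table.sort_values("kd_lig1")["LIG1K126me2_occupancy"].to_numpy()
        assert np.all(np.diff(occ) <= 1e-12)

    def test_envelope_brackets_all_rows(self):
        base = StoichiometryScenario()
        res = sweep_scenarios(
            base,
            {"h3_me2_fraction": (0.2, 0.5), "absolute_scale": (0.1, 100.0)},
            grid_size=5,
        )
        assert len(res.table) == 25
        env = res.envelope
        col = "H3K9me2_occupancy"
        assert env.loc["min", col] <= res.table[col].min() + 1e-15
        assert env.loc["max", col] >= res.table[col].max() - 1e-15

    def test_empty_ranges_rejected(self):
        with pytest.raises(DomainError):
            sweep_scenarios(StoichiometryScenario(), {})
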