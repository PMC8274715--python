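"""CoC curves and gamma-shape fitting, checked against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from meioco import (coc_curve, coc_pairs, default_interval_count, fit_gamma,
                    fit_gamma_cohort, inter_focus_gaps, interference_report,
                    preset_params, simulate_cohort)
from meioco.errors import ConfigurationError, FitError, ValidationError

from conftest import make_cohort, make_sc


# ---------------------------------------------------------------------------
# independent naive CoC counter (loops and sets only — no linear algebra)

def naive_coc_records(scs, n_intervals):
    """Exhaustive per-pair counting, the hand-enumeration way."""
    n = len(scs)
    occupied = []
    for sc in scs:
        intervals = set()
        for p in sc.focus_positions_um:
            k = int(p / sc.sc_length_um * n_intervals)
            intervals.add(min(k, n_intervals - 1))
        occupied.append(intervals)
    out = {}
    for i in range(n_intervals):
        for j in range(i + 1, n_intervals):
            fi = sum(1 for occ in occupied if i in occ) / n
            fj = sum(1 for occ in occupied if j in occ) / n
            both = sum(1 for occ in occupied if i in occ and j in occ) / n
            out[(i, j)] = (both, fi * fj)
    return out


def random_micro_cohort(rng):
    n_scs = rng.integers(1, 11)
    specs = []
    for s in range(n_scs):
        length = float(rng.uniform(2.0, 12.0))
        k = int(rng.poisson(2.0))
        pos = np.sort(rng.uniform(0, length, size=k))
        specs.append((f"n{s}", int(rng.integers(1, 8)), length, pos.tolist()))
    # one SC per nucleus so duplicate chromosome ids cannot collide
    return make_cohort("g", [(f"n{i}", c, L, p) for i, (_, c, L, p) in enumerate(specs)])


class TestInterFocusGaps:
    def test_micrometer_gaps(self):
        sc = make_sc(length=8.0, positions=(1.5, 4.0, 6.2))
        np.testing.assert_allclose(inter_focus_gaps(sc), [2.5, 2.2])

    def test_percent_gaps(self):
        sc = make_sc(length=10.0, positions=(1.5, 4.0, 6.2))
        np.testing.assert_allclose(inter_focus_gaps(sc, "percent"), [25.0, 22.0])

    def test_orientation_invariance(self):
        sc = make_sc(length=8.0, positions=(1.5, 4.0, 6.2))
        np.testing.assert_allclose(sorted(inter_focus_gaps(sc.reversed())),
                                   sorted(inter_focus_gaps(sc)))

    @pytest.mark.parametrize("positions", [(), (3.0,)])
    def test_fewer_than_two_foci_no_gaps(self, positions):
        assert inter_focus_gaps(make_sc(positions=positions)).size == 0


class TestDefaultIntervalCount:
    def test_quarter_rule_strict(self):
        # mean length 12, mean gap 4 -> smallest n with 12/n < 1 is 13
        cohort = make_cohort("g", [("n1", 1, 12.0, (2.0, 6.0, 10.0))])
        assert default_interval_count(cohort) == 13

    def test_quarter_rule_non_integer(self):
        # mean length 8, mean gap 3.2 -> floor(10) + 1 = 11
        cohort = make_cohort("g", [("n1", 1, 8.0, (0.8, 4.0, 7.2))])
        assert default_interval_count(cohort) == 11

    def test_minimum_two_intervals(self):
        # one long SC carries a huge gap while focus-free short SCs drag the
        # class mean length down: the rule would give < 2, the floor holds
        cohort = make_cohort("g", [("n1", 1, 10.0, (0.5, 9.5))] +
                             [(f"n{i}", 1, 1.0, ()) for i in range(2, 5)])
        assert default_interval_count(cohort) == 2

    def test_no_gaps_raises_configuration_error(self):
        cohort = make_cohort("g", [("n1", 1, 10.0, (5.0,))])
        with pytest.raises(ConfigurationError):
            default_interval_count(cohort)


class TestCoCPairs:
    def test_independent_occupancies_give_unit_coc(self):
        # occupancies {11, 10, 01, 00}: f1 = f2 = 1/2, doubles = 1/4 -> CoC 1
        cohort = make_cohort("g", [
            ("n1", 1, 10.0, (2.0, 8.0)), ("n2", 1, 10.0, (2.0,)),
            ("n3", 1, 10.0, (8.0,)), ("n4", 1, 10.0, ()),
        ])
        curve = coc_pairs(cohort, "all", 2)
        assert len(curve.pair_records) == 1
        assert curve.pair_records["coc"].iloc[0] == pytest.approx(1.0)

    def test_perfect_interference_gives_zero_coc(self):
        # occupancies {10, 10, 01, 01}: no doubles -> CoC 0
        cohort = make_cohort("g", [
            ("n1", 1, 10.0, (2.0,)), ("n2", 1, 10.0, (2.0,)),
            ("n3", 1, 10.0, (8.0,)), ("n4", 1, 10.0, (8.0,)),
        ])
        rec = coc_pairs(cohort, "all", 2).pair_records
        assert rec["coc"].iloc[0] == pytest.approx(0.0)

    def test_zero_expected_pairs_withheld(self):
        cohort = make_cohort("g", [("n1", 1, 10.0, (1.0,)), ("n2", 1, 10.0, (6.0,))])
        curve = coc_pairs(cohort, "all", 4)  # only intervals 0 and 2 ever occupied
        assert curve.n_withheld_pairs == 5   # every pair touching an empty interval
        assert len(curve.pair_records) + curve.n_withheld_pairs == 6

    def test_matches_naive_enumeration_on_random_micro_cohorts(self):
        rng = np.random.default_rng(101)
        for _ in range(100):
            cohort = random_micro_cohort(rng)
            n_intervals = int(rng.integers(2, 5))
            curve = coc_pairs(cohort, "all", n_intervals)
            oracle = naive_coc_records(cohort.scs(), n_intervals)
            kept = {(int(r.interval_i), int(r.interval_j)): (r.observed, r.expected)
                    for r in curve.pair_records.itertuples()}
            n_withheld = 0
            for pair, (obs, exp) in oracle.items():
                if exp == 0:
                    n_withheld += 1
                    assert pair not in kept
                else:
                    assert kept[pair][0] == pytest.approx(obs)
                    assert kept[pair][1] == pytest.approx(exp)
            assert n_withheld == curve.n_withheld_pairs

    def test_orientation_invariance(self, wt_cohort):
        fwd = coc_pairs(wt_cohort, "all", 20).pair_records
        rev = coc_pairs(wt_cohort.reversed(), "all", 20).pair_records
        # reversing flips interval labels but the multiset of (distance, coc)
        # pairs — and hence the curve — is unchanged
        np.testing.assert_allclose(
            np.sort(fwd[["distance_um", "coc"]].to_numpy(), axis=0),
            np.sort(rev[["distance_um", "coc"]].to_numpy(), axis=0), rtol=1e-12)


class TestCoCCurve:
    def test_single_pair_single_bin(self):
        cohort = make_cohort("g", [
            ("n1", 1, 10.0, (2.0, 8.0)), ("n2", 1, 10.0, ()),
        ])
        curve = coc_curve(coc_pairs(cohort, "all", 2))
        assert len(curve.binned) == 1
        assert curve.binned["n_pairs"].iloc[0] == 1

    def test_huge_bin_collapses_to_global_mean(self, wt_cohort):
        base = coc_pairs(wt_cohort, "all", 15)
        curve = coc_curve(base, bin_width_um=1e6)
        assert len(curve.binned) == 1
        assert curve.binned["mean_coc"].iloc[0] == pytest.approx(
            base.pair_records["coc"].mean())

    def test_interference_shape_from_simulation(self):
        """ν = 5 cohort: strong CoC suppression at short distances, ≈1 far out."""
        params = preset_params("wt", seed=23, n_nuclei=286, fixed_lengths=True)
        cohort = simulate_cohort(params.with_(nu=5.0), "s")
        curve = coc_curve(coc_pairs(cohort, "all"))
        binned = curve.binned
        assert binned["mean_coc"].iloc[0] < 0.5
        far = binned[binned["bin_center_um"] > 2.5 * params.mean_gap_um]
        assert abs(far["mean_coc"].mean() - 1.0) < 0.25


class TestFitGamma:
    def test_exponential_recovers_shape_one(self, rng):
        gaps = rng.exponential(2.0, size=10_000)
        fit = fit_gamma(gaps, n_bootstrap=0)
        assert fit.shape_nu == pytest.approx(1.0, abs=0.05)

    def test_gamma_shape_five_recovered(self, rng):
        gaps = rng.gamma(5.0, 1.0, size=10_000)
        fit = fit_gamma(gaps, n_bootstrap=0)
        assert fit.shape_nu == pytest.approx(5.0, abs=0.15)

    def test_scale_equivariance_of_shape(self, rng):
        gaps = rng.gamma(3.0, 2.0, size=500)
        s1 = fit_gamma(gaps, n_bootstrap=0).shape_nu
        s2 = fit_gamma(gaps * 137.0, n_bootstrap=0).shape_nu
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_too_few_gaps_raises(self):
        with pytest.raises(FitError):
            fit_gamma(np.ones(9) + np.arange(9) * 0.1, n_bootstrap=0)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValidationError):
            fit_gamma(np.array([1.0, 0.0] + [1.0] * 10), n_bootstrap=0)

    def test_bootstrap_se_positive_and_reasonable(self, wt_cohort):
        fit = fit_gamma_cohort(wt_cohort, normalization="um", n_bootstrap=200, seed=0)
        assert fit.n_bootstrap == 200
        assert 0 < fit.se_nu < fit.shape_nu  # SE far smaller than the estimate


@pytest.fixture(scope="module")
def two_cohorts():
    base = preset_params("wt", seed=31, n_nuclei=150, fixed_lengths=True)
    return {nu: simulate_cohort(base.with_(nu=float(nu)), f"nu{nu}")
            for nu in (2, 5)}


class TestMonotoneInterferenceOrdering:

    def test_fitted_shape_orders_with_generating_shape(self, two_cohorts):
        fits = {nu: fit_gamma_cohort(c, normalization="um", n_bootstrap=0).shape_nu
                for nu, c in two_cohorts.items()}
        assert fits[2] < fits[5]

    def test_short_distance_coc_orders_inversely(self, two_cohorts):
        first_bin = {}
        for nu, cohort in two_cohorts.items():
            binned = coc_curve(coc_pairs(cohort, "all")).binned
            first_bin[nu] = binned["mean_coc"].iloc[0]
        assert first_bin[5] < first_bin[2]


class TestInterferenceReport:
    def test_full_cohort_has_all_three_curves_and_fit(self, wt_cohort):
        report = interference_report(wt_cohort, n_bootstrap=0)
        assert set(report.curves) == {"long", "short", "all"}
        assert report.gamma is not None
        assert report.gamma.shape_nu > 1

    def test_sparse_cohort_degrades_gracefully(self):
        cohort = make_cohort("g", [(f"n{i}", 1, 10.0, (5.0,)) for i in range(6)])
        report = interference_report(cohort, n_bootstrap=0)
        assert report.gamma is None
        assert "gamma_unavailable" in report.diagnostics

    def test_orientation_invariance_of_gamma_fit(self, wt_cohort):
        f1 = fit_gamma_cohort(wt_cohort, normalization="um", n_bootstrap=0)
        f2 = fit_gamma_cohort(wt_cohort.reversed(), normalization="um", n_bootstrap=0)
        assert f1.shape_nu == pytest.approx(f2.shape_nu, rel=1e-9)
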