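"""Isotopologue fractions, the TCA labeling simulator, and set enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mmaomics.tracing import (
    IsotopologueVector,
    TracingParams,
    citrate_ratio,
    fit_reductive_fraction,
    isotopologue_fractions,
    metabolite_set_enrichment,
    pool_size_compare,
    simulate_labeling,
)


def _peak_table(areas_by_met, sample="s1", polarity="neg", is_area=10.0):
    rows = [
        {"sample": sample, "metabolite": met, "isotopologue": i, "area": a,
         "polarity": polarity}
        for met, areas in areas_by_met.items()
        for i, a in enumerate(areas)
    ]
    standards = pd.DataFrame(
        [{"sample": sample, "polarity": polarity, "area": is_area}]
    )
    return pd.DataFrame(rows), standards


class TestIsotopologueFractions:
    def test_simple_fractions(self):
        peaks, standards = _peak_table({"succinate": [1.0, 1.0, 2.0]})
        (v,) = isotopologue_fractions(peaks, standards)
        np.testing.assert_allclose(v.fractions[:3], [0.25, 0.25, 0.5])

    def test_all_zero_metabolite_is_an_error(self):
        peaks, standards = _peak_table({"succinate": [0.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero areas"):
            isotopologue_fractions(peaks, standards)

    def test_scale_invariance(self):
        peaks1, std1 = _peak_table({"malate": [2.0, 4.0, 6.0]}, is_area=10.0)
        peaks2, std2 = _peak_table({"malate": [4.0, 8.0, 12.0]}, is_area=20.0)
        (v1,) = isotopologue_fractions(peaks1, std1)
        (v2,) = isotopologue_fractions(peaks2, std2)
        np.testing.assert_allclose(v1.fractions, v2.fractions, atol=1e-12)

    def test_missing_internal_standard_is_an_error(self):
        peaks, standards = _peak_table({"citrate": [1.0, 1.0]})
        standards["polarity"] = "pos"  # mismatch with the peaks' negative mode
        with pytest.raises(ValueError, match="internal standard"):
            isotopologue_fractions(peaks, standards)

    def test_missing_isotopologues_imputed_as_zero(self):
        peaks, standards = _peak_table({"succinate": [3.0]})
        (v,) = isotopologue_fractions(peaks, standards)
        assert v.fractions.size == 5  # 4 carbons -> M+0..M+4
        np.testing.assert_allclose(v.fractions, [1.0, 0, 0, 0, 0])


class TestCitrateRatio:
    def test_direct_ratio(self):
        v = IsotopologueVector("s", "citrate", [0.3, 0.2, 0.1, 0.1, 0.2, 0.1, 0.0])
        assert citrate_ratio(v) == pytest.approx(0.5)

    def test_zero_m4_is_an_error(self):
        v = IsotopologueVector("s", "citrate", [0.5, 0.2, 0.1, 0.1, 0.0, 0.1, 0.0])
        with pytest.raises(ZeroDivisionError):
            citrate_ratio(v)

    def test_no_reductive_route_no_m5(self):
        sim = simulate_labeling(TracingParams(r=0.0, a=0.0, e=1.0, turns=1))
        assert citrate_ratio(sim["citrate"]) == 0.0


class TestSimulateLabeling:
    def test_single_turn_oxidative_identity(self):
        """Pure oxidative turning of fully labeled glutamine: M+4 everywhere
        downstream of the decarboxylation."""
        sim = simulate_labeling(TracingParams(r=0.0, a=0.0, e=1.0, turns=1))
        np.testing.assert_allclose(sim["citrate"].fractions, [0, 0, 0, 0, 1, 0, 0])
        np.testing.assert_allclose(sim["succinate"].fractions, [0, 0, 0, 0, 1])
        np.testing.assert_allclose(sim["malate"].fractions, [0, 0, 0, 0, 1])

    def test_single_turn_reductive_identity(self):
        sim = simulate_labeling(TracingParams(r=1.0, a=0.0, e=1.0, turns=1))
        np.testing.assert_allclose(sim["citrate"].fractions, [0, 0, 0, 0, 0, 1, 0])

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.integers(1, 5)
    )
    def test_outputs_live_on_the_simplex(self, r, a, e, turns):
        sim = simulate_labeling(TracingParams(r=r, a=a, e=e, turns=turns))
        for v in sim.values():
            assert np.all(v.fractions >= -1e-12)
            assert v.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ratio_strictly_increasing_in_r(self):
        ratios = [
            citrate_ratio(
                simulate_labeling(TracingParams(r=float(r), a=0.2, e=0.95, turns=3))["citrate"]
            )
            for r in np.linspace(0, 1, 21)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_anaplerotic_dilution_raises_m0_monotonically(self):
        """More unlabeled anaplerotic inflow means more M+0 in the 4-carbon
        pool metabolites."""
        for met in ("succinate", "fumarate", "malate"):
            m0 = [
                simulate_labeling(TracingParams(r=0.1, a=float(a), e=0.95, turns=3))[met].fractions[0]
                for a in np.linspace(0, 1, 11)
            ]
            assert all(b >= a for a, b in zip(m0, m0[1:]))
            assert m0[-1] > m0[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TracingParams(r=1.5)
        with pytest.raises(ValueError):
            TracingParams(turns=0)


class TestFitReductiveFraction:
    def test_noiseless_recovery_across_grid(self):
        for r_true in np.linspace(0, 1, 11):
            obs = simulate_labeling(TracingParams(r=float(r_true), a=0.2, e=0.95, turns=3))
            fit = fit_reductive_fraction(obs["citrate"], a=0.2, e=0.95, turns=3)
            assert abs(fit.r_hat - r_true) < 1e-3

    def test_boundary_recovery(self):
        obs = simulate_labeling(TracingParams(r=0.0, a=0.3, e=0.9, turns=2))
        fit = fit_reductive_fraction(obs["citrate"], a=0.3, e=0.9, turns=2)
        assert fit.r_hat <= 0.01

    def test_noisy_recovery_within_tolerance(self):
        gen = np.random.default_rng(17)
        r_true = 0.35
        clean = simulate_labeling(TracingParams(r=r_true, a=0.2, e=0.95, turns=3))["citrate"]
        estimates = []
        for _ in range(50):
            f = np.clip(clean.fractions + 0.02 * gen.standard_normal(7), 0, None)
            noisy = IsotopologueVector("s", "citrate", f / f.sum())
            fit = fit_reductive_fraction(noisy, a=0.2, e=0.95, turns=3)
            estimates.append(fit.r_hat)
        assert abs(np.mean(estimates) - r_true) < 0.05

    def test_flat_objective_flagged_non_identifiable(self):
        """With zero enrichment the citrate pattern is independent of r."""
        obs = simulate_labeling(TracingParams(r=0.4, a=0.2, e=0.0, turns=2))
        fit = fit_reductive_fraction(obs["citrate"], a=0.2, e=0.0, turns=2)
        assert not fit.identifiable


class TestPoolSizeCompare:
    @staticmethod
    def _frame(g1, g2):
        rows = [
            {"metabolite": "citrate", "condition": "A", "total": v} for v in g1
        ] + [{"metabolite": "citrate", "condition": "B", "total": v} for v in g2]
        return pd.DataFrame(rows)

    def test_extreme_separation_matches_enumeration_oracle(self):
        """{1,2,3} vs {10,11,12}: the rank-sum is the most extreme of the
        C(6,3)=20 equally likely splits -> two-sided p = 2/20 = 0.1."""
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        obs_u = 0.0  # no crossing pairs
        count = 0
        for combo in combinations(range(6), 3):
            g1 = [values[i] for i in combo]
            g2 = [values[i] for i in range(6) if i not in combo]
            u = sum(a > b for a in g1 for b in g2)
            count += min(u, 9 - u) <= min(obs_u, 9 - obs_u)
        expected = count / comb(6, 3)
        out = pool_size_compare(self._frame([1.0, 2.0, 3.0], [10.0, 11.0, 12.0]))
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        out = pool_size_compare(self._frame([5.0, 6.0, 7.0], [5.5, 6.5, 7.5]))
        assert out["p"].iloc[0] > 0.6

    def test_label_permutation_invariance(self):
        a, b = [1.0, 5.0, 3.0, 8.0], [2.0, 9.0, 4.0, 7.0]
        p1 = pool_size_compare(self._frame(a, b))["p"].iloc[0]
        p2 = pool_size_compare(self._frame(b, a))["p"].iloc[0]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            pool_size_compare(self._frame([1.0, 2.0], [3.0, 4.0, 5.0]))


class TestMetaboliteSetEnrichment:
    def test_disjoint_pathway_gives_p_one(self):
        out = metabolite_set_enrichment(
            {"a", "b"}, {"a", "b", "c", "d"}, {"path": {"c", "d"}}
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_complete_overlap_closed_form(self):
        """Universe 20, pathway 5, significant 5, overlap 5:
        p = 1 / C(20,5)."""
        universe = {f"m{i}" for i in range(20)}
        pathway = {f"m{i}" for i in range(5)}
        out = metabolite_set_enrichment(pathway, universe, {"path": pathway})
        assert out["p"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_matches_brute_force_enumeration_small_universe(self):
        """Exhaustive draw enumeration on a 12-metabolite universe."""
        universe = [f"m{i}" for i in range(12)]
        pathway = set(universe[:5])
        significant = set(universe[2:6])  # overlap 3
        k_obs = len(pathway & significant)
        count = 0
        total = 0
        for draw in combinations(universe, len(significant)):
            total += 1
            count += len(set(draw) & pathway) >= k_obs
        out = metabolite_set_enrichment(significant, set(universe), {"path": pathway})
        assert out["p"].iloc[0] == pytest.approx(count / total, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            metabolite_set_enrichment(set(), set(), {})

    def test_bh_adjustment_across_pathways(self):
        universe = {f"m{i}" for i in range(30)}
        sig = {f"m{i}" for i in range(6)}
        pathways = {"hit": set(list(sig)), "null": {f"m{i}" for i in range(20, 28)}}
        out = metabolite_set_enrichment(sig, universe, pathways)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestSyntheticTracingLayer:
    def test_deficient_condition_raises_citrate_ratio(self, small_bundle):
        """The synthetic MMUT-deficient condition (higher reductive fraction,
        less unlabeled inflow) must show the higher M+5/M+4 citrate ratio."""
        vectors = isotopologue_fractions(
            small_bundle.tracing_peaks, small_bundle.tracing_standards
        )
        ratios = {}
        for v in vectors:
            if v.metabolite == "citrate":
                cond = v.sample.rsplit("_", 1)[0]
                ratios.setdefault(cond, []).append(citrate_ratio(v))
        assert np.mean(ratios["MMUT-deficient"]) > 2 * np.mean(ratios["control"])

    def test_pool_comparison_detects_reduced_tca_pools(self, small_bundle):
        pools = (
            small_bundle.tracing_peaks.groupby(["sample", "metabolite"])["area"]
            .sum()
            .reset_index()
            .rename(columns={"area": "total"})
        )
        pools["condition"] = pools["sample"].str.rsplit("_", n=1).str[0]
        out = pool_size_compare(pools)
        assert set(out["metabolite"]) == {
            "glutamate", "oxoglutarate", "succinate", "fumarate", "malate", "citrate"
        }
        assert (out["p"] <= 1.0).all() and (out["p"] >= 0.0).all()
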