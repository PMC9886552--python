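"""Identification thresholds, bait-prey set logic, ANOVA enrichment, network."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmaomics.ipms import (
    PresenceMatrix,
    anova_enrichment,
    apply_id_thresholds,
    build_network,
    specific_prey,
    venn_partition,
)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["protein", "bait", "replicate", "protein_probability",
                 "peptide_probabilities"],
    )


class TestApplyIdThresholds:
    def test_passing_record_present(self):
        pm = apply_id_thresholds(
            _records([("P1", "MMUT", 1, 0.995, "0.96;0.97")])
        )
        assert pm.detected.loc["P1", ("MMUT", 1)]

    def test_low_protein_probability_absent(self):
        pm = apply_id_thresholds(
            _records([("P1", "MMUT", 1, 0.98, "0.99;0.99;0.99")])
        )
        assert not pm.detected.loc["P1", ("MMUT", 1)]

    def test_single_passing_peptide_absent(self):
        pm = apply_id_thresholds(
            _records([("P1", "MMUT", 1, 0.999, "0.96;0.90")])
        )
        assert not pm.detected.loc["P1", ("MMUT", 1)]

    def test_thresholds_are_strict_inequalities(self):
        pm = apply_id_thresholds(
            _records([("P1", "MMUT", 1, 0.99, "0.95;0.95")])
        )
        assert not pm.detected.loc["P1", ("MMUT", 1)]


def _random_presence(gen, n_proteins=8, n_baits=6, n_reps=3):
    baits = [f"B{i}" for i in range(n_baits)]
    proteins = [f"P{i}" for i in range(n_proteins)]
    cols = pd.MultiIndex.from_tuples(
        [(b, r) for b in baits for r in range(1, n_reps + 1)], names=["bait", "replicate"]
    )
    detected = pd.DataFrame(
        gen.random((n_proteins, n_baits * n_reps)) < 0.4, index=proteins, columns=cols
    )
    roles = {b: ("negative_control" if i >= 4 else "experimental") for i, b in enumerate(baits)}
    return PresenceMatrix(detected=detected, bait_roles=roles)


class TestSpecificPrey:
    def test_single_control_replicate_excludes(self):
        cols = pd.MultiIndex.from_tuples(
            [("MMUT", 1), ("MMUT", 2), ("EV", 1), ("EV", 2)], names=["bait", "replicate"]
        )
        detected = pd.DataFrame(
            [[True, True, True, False]], index=["P1"], columns=cols
        )
        pm = PresenceMatrix(detected, {"MMUT": "experimental", "EV": "negative_control"})
        assert specific_prey(pm, {"MMUT"}, 1, {"EV"}) == set()

    def test_clean_prey_included(self):
        cols = pd.MultiIndex.from_tuples(
            [("MMUT", 1), ("MMUT", 2), ("EV", 1)], names=["bait", "replicate"]
        )
        detected = pd.DataFrame([[True, True, False]], index=["P1"], columns=cols)
        pm = PresenceMatrix(detected, {"MMUT": "experimental", "EV": "negative_control"})
        assert specific_prey(pm, {"MMUT"}, 1, {"EV"}) == {"P1"}

    def test_matches_brute_force_enumeration_on_random_tensors(self):
        """Random 8 proteins x 6 baits x 3 replicates tensors against an
        exhaustive set-logic oracle."""
        gen = np.random.default_rng(99)
        for _ in range(20):
            pm = _random_presence(gen)
            required = {"B0", "B1", "B2", "B3"}
            forbidden = {"B4", "B5"}
            for min_required in (1, 2, 3, 4):
                expected = set()
                for protein in pm.detected.index:
                    row = pm.detected.loc[protein]
                    n_req = sum(row[b].any() for b in required)
                    in_forb = any(row[b].any() for b in forbidden)
                    if n_req >= min_required and not in_forb:
                        expected.add(protein)
                got = specific_prey(pm, required, min_required, forbidden)
                assert got == expected

    def test_monotone_in_forbidden_set_and_min_required(self):
        gen = np.random.default_rng(5)
        pm = _random_presence(gen)
        base = specific_prey(pm, {"B0", "B1", "B2"}, 1, {"B4"})
        assert specific_prey(pm, {"B0", "B1", "B2"}, 1, {"B4", "B5"}) <= base
        assert specific_prey(pm, {"B0", "B1", "B2"}, 2, {"B4"}) <= base

    def test_overlapping_bait_sets_rejected(self):
        gen = np.random.default_rng(5)
        pm = _random_presence(gen)
        with pytest.raises(ValueError, match="overlap"):
            specific_prey(pm, {"B0"}, 1, {"B0"})

    def test_unknown_bait_rejected(self):
        gen = np.random.default_rng(5)
        pm = _random_presence(gen)
        with pytest.raises(ValueError, match="unknown bait"):
            specific_prey(pm, {"NOPE"}, 1, {"B4"})


class TestVennPartition:
    def test_singleton_region(self):
        cols = pd.MultiIndex.from_tuples(
            [("A", 1), ("B", 1)], names=["bait", "replicate"]
        )
        detected = pd.DataFrame([[True, False]], index=["P1"], columns=cols)
        pm = PresenceMatrix(detected, {"A": "experimental", "B": "experimental"})
        regions = venn_partition(pm)
        assert regions[frozenset({"A"})] == {"P1"}
        assert regions[frozenset({"A", "B"})] == set()

    def test_regions_partition_detected_proteins(self):
        gen = np.random.default_rng(7)
        pm = _random_presence(gen, n_proteins=30)
        regions = venn_partition(pm)
        detected = {
            p for p in pm.detected.index if pm.detected.loc[p].any()
        }
        assert sum(len(v) for v in regions.values()) == len(detected)
        union = set()
        for v in regions.values():
            assert not union & v  # disjoint
            union |= v
        assert union == detected

    def test_region_counts_match_enumeration_oracle(self):
        gen = np.random.default_rng(13)
        pm = _random_presence(gen, n_proteins=12, n_baits=4)
        baits = pm.baits
        regions = venn_partition(pm, baits)
        for k in range(1, 5):
            for combo in combinations(baits, k):
                expected = set()
                for p in pm.detected.index:
                    members = {b for b in baits if pm.detected.loc[p, b].any()}
                    if members == set(combo):
                        expected.add(p)
                assert regions[frozenset(combo)] == expected


class TestAnovaEnrichment:
    GROUPS = {"MMUT": ["m1", "m2", "m3"], "EV": ["e1", "e2", "e3"],
              "VLCAD": ["v1", "v2", "v3"]}
    COLS = ["m1", "m2", "m3", "e1", "e2", "e3", "v1", "v2", "v3"]

    def test_identical_groups_give_null_result(self, rng):
        base = rng.standard_normal(3)
        row = np.concatenate([base, base, base])
        quant = pd.DataFrame([row], index=["P1"], columns=self.COLS)
        out = anova_enrichment(quant, self.GROUPS)
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_anova"].iloc[0] == pytest.approx(1.0)

    def test_strong_separation_significant(self, rng):
        row = np.concatenate(
            [10 + 0.1 * rng.standard_normal(3), 0.1 * rng.standard_normal(3),
             0.1 * rng.standard_normal(3)]
        )
        quant = pd.DataFrame([row], index=["P1"], columns=self.COLS)
        out = anova_enrichment(quant, self.GROUPS)
        assert out["p_anova"].iloc[0] < 0.001

    def test_matches_sum_of_squares_oracle(self):
        """F and p against a direct between/within sum-of-squares computation
        on 50 random instances."""
        gen = np.random.default_rng(31)
        for _ in range(50):
            data = gen.standard_normal(9) + np.repeat(gen.standard_normal(3), 3)
            quant = pd.DataFrame([data], index=["P"], columns=self.COLS)
            out = anova_enrichment(quant, self.GROUPS)
            groups = [data[:3], data[3:6], data[6:]]
            grand = data.mean()
            ss_between = sum(3 * (g.mean() - grand) ** 2 for g in groups)
            ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
            F = (ss_between / 2) / (ss_within / 6)
            p = stats.f.sf(F, 2, 6)
            assert out["F"].iloc[0] == pytest.approx(F, abs=1e-8)
            assert out["p_anova"].iloc[0] == pytest.approx(p, abs=1e-8)

    def test_null_pvalues_are_uniform(self):
        """1,000 null proteins, 3 equal-mean groups: the p-value ECDF must
        track the uniform (KS < 0.05)."""
        gen = np.random.default_rng(8)
        quant = pd.DataFrame(
            gen.standard_normal((1000, 9)),
            index=[f"P{i}" for i in range(1000)],
            columns=self.COLS,
        )
        out = anova_enrichment(quant, self.GROUPS)
        ks = stats.kstest(out["p_anova"], "uniform").statistic
        assert ks < 0.05

    def test_too_few_replicates_rejected(self, rng):
        quant = pd.DataFrame([rng.standard_normal(9)], index=["P"], columns=self.COLS)
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_enrichment(quant, {"MMUT": ["m1"], "EV": ["e1", "e2"]})


class TestBuildNetwork:
    def _presence(self):
        cols = pd.MultiIndex.from_tuples(
            [("MMUT", 1), ("MMAA", 1), ("EV", 1)], names=["bait", "replicate"]
        )
        detected = pd.DataFrame(
            [[True, True, False], [True, False, False], [False, True, False]],
            index=["P1", "P2", "P3"],
            columns=cols,
        )
        return PresenceMatrix(
            detected,
            {"MMUT": "experimental", "MMAA": "experimental", "EV": "negative_control"},
        )

    def test_empty_prey_set_and_no_significant(self):
        enr = pd.DataFrame({"protein": ["P1"], "F": [0.1], "p_anova": [0.9]})
        G = build_network(set(), enr, self._presence())
        assert G.number_of_edges() == 0

    def test_edge_weights_monotone_in_significance(self):
        enr = pd.DataFrame(
            {"protein": ["P1", "P2"], "F": [9.0, 5.0], "p_anova": [0.01, 0.04]}
        )
        G = build_network({"P1", "P2"}, enr, self._presence())
        assert G["MMUT"]["P1"]["weight"] > G["MMUT"]["P2"]["weight"]

    def test_edge_count_sums_over_baits(self):
        enr = pd.DataFrame(
            {"protein": ["P1", "P2", "P3"], "F": [9.0, 5.0, 7.0],
             "p_anova": [0.01, 0.04, 0.02]}
        )
        G = build_network({"P1"}, enr, self._presence())
        # P1 in MMUT+MMAA (2 edges), P2 in MMUT (1), P3 in MMAA (1)
        assert G.number_of_edges() == 4
        assert G.nodes["P1"]["kind"] == "exclusive_prey"
        assert G.nodes["P2"]["kind"] == "shared_prey"


class TestSyntheticIpmsLayer:
    def test_core_preys_recovered_specifically(self, small_bundle):
        """The planted control-free prey set must be recovered exactly by the
        four-bait specificity rule."""
        from mmaomics.cohort import BAIT_ROLES

        pm = apply_id_thresholds(small_bundle.ipms_ids, bait_roles=BAIT_ROLES)
        preys = specific_prey(
            pm, {"MMUT", "MMAA", "MMAB", "MCEE"}, 4, {"EV", "VLCAD"}
        )
        core = set(small_bundle.truth["ipms"]["core_prey"])
        # nearly every planted core prey survives per-replicate detection noise
        assert len(preys & core) >= 0.9 * len(core)
        # any extra prey is a background protein that happened to satisfy the
        # rule: detected in every required bait, never in a control replicate
        for extra in preys - core:
            assert extra.startswith("BG")
            for control in ("EV", "VLCAD"):
                assert extra not in pm.detected_in_bait(control)

    def test_enrichment_separates_true_preys(self, small_bundle):
        quant = np.log2(small_bundle.ipms_quant)
        groups = {
            "MMUT": [f"MMUT_r{r}" for r in (1, 2, 3)],
            "EV": [f"EV_r{r}" for r in (1, 2, 3)],
            "VLCAD": [f"VLCAD_r{r}" for r in (1, 2, 3)],
        }
        out = anova_enrichment(quant, groups).set_index("protein")
        core = small_bundle.truth["ipms"]["core_prey"]
        sig_core = (out.loc[core, "p_anova"] < 0.05).mean()
        assert sig_core > 0.9
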