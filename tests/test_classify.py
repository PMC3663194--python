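"""Susceptibility tiering, specific-species detection, subset selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cq_table, make_pair_sheet
from hemomir.classify import (
    TIER_ELEVATED_ALL,
    TIER_ELEVATED_ONE,
    TIER_ELEVATED_TWO,
    TIER_INDETERMINATE,
    TIER_SPECIFIC,
    TIER_STABLE,
    TIERS,
    identify_specific,
    select_subsets,
    tier_mirnas,
)
from hemomir.errors import ConfigurationError
from hemomir.relquant import FoldChange, fold_change_matrix
from hemomir.synth import generate_paired_study


def fc(mir, pair, value=None, status="ok"):
    if value is None:
        return FoldChange(mir, pair, status=status)
    return FoldChange(mir, pair, (value,), value, 0.0, "ok")


def build(fcs_by_mir: dict[str, list]) -> list:
    """{mir: [fc_P1, fc_P2, fc_P3]} with None = one-sided/undetected."""
    out = []
    for mir, values in fcs_by_mir.items():
        for i, v in enumerate(values, start=1):
            if v is None:
                out.append(fc(mir, f"P{i}", status="both_undetected"))
            else:
                out.append(fc(mir, f"P{i}", v))
    return out


class TestTierMirnas:
    def test_examples(self):
        report = tier_mirnas(
            build(
                {
                    "miR-16": [3.55, 10.18, 2.5],  # >=2-fold everywhere
                    "flat": [1.0, 1.0, 1.0],
                    "two": [2.5, 2.1, 1.2],
                    "one": [2.5, 1.2, 1.0],
                    "down": [0.3, 0.4, 0.5],  # decreased species are indeterminate
                    "edge": [1.6, 1.0, 1.0],  # outside band, below threshold
                }
            )
        )
        t = report.frame["tier"]
        assert t["miR-16"] == TIER_ELEVATED_ALL
        assert t["flat"] == TIER_STABLE
        assert t["two"] == TIER_ELEVATED_TWO
        assert t["one"] == TIER_ELEVATED_ONE
        assert t["down"] == TIER_INDETERMINATE
        assert t["edge"] == TIER_INDETERMINATE

    def test_threshold_is_inclusive(self):
        report = tier_mirnas(build({"m": [2.0, 2.0, 2.0]}))
        assert report.frame.loc["m", "tier"] == TIER_ELEVATED_ALL

    def test_stability_band_is_multiplicative(self):
        report = tier_mirnas(build({"lo": [2 / 3, 1.0, 1.0], "outside": [0.6, 1.0, 1.0]}))
        assert report.frame.loc["lo", "tier"] == TIER_STABLE
        assert report.frame.loc["outside", "tier"] == TIER_INDETERMINATE

    def test_single_pair_design_uses_one_pair_tier(self):
        report = tier_mirnas([fc("m", "P1", 3.0)])
        assert report.frame.loc["m", "tier"] == TIER_ELEVATED_ONE

    def test_specific_ids_preempt(self):
        report = tier_mirnas(
            build({"m": [None, None, None]}), specific_ids=["m"]
        )
        assert report.frame.loc["m", "tier"] == TIER_SPECIFIC

    def test_zero_evaluable_without_specific_is_indeterminate(self):
        report = tier_mirnas(build({"m": [None, None, None]}))
        assert report.frame.loc["m", "tier"] == TIER_INDETERMINATE

    def test_random_cohort_matches_bruteforce_oracle(self):
        """Tier counts on random 50-miR cohorts equal an independent
        re-classification loop."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            values = {
                f"m{i}": list(np.exp(rng.normal(0.3, 0.8, size=3)))
                for i in range(50)
            }
            report = tier_mirnas(build(values))
            for mir, fcs in values.items():
                n_elev = sum(v >= 2.0 for v in fcs)
                if n_elev == 3:
                    expected = TIER_ELEVATED_ALL
                elif n_elev == 2:
                    expected = TIER_ELEVATED_TWO
                elif n_elev == 1:
                    expected = TIER_ELEVATED_ONE
                elif all(2 / 3 <= v <= 1.5 for v in fcs):
                    expected = TIER_STABLE
                else:
                    expected = TIER_INDETERMINATE
                assert report.frame.loc[mir, "tier"] == expected

    def test_nesting_and_partition(self):
        rng = np.random.default_rng(3)
        values = {f"m{i}": list(np.exp(rng.normal(0, 1, size=3))) for i in range(200)}
        report = tier_mirnas(build(values))
        cum = report.elevated_cumulative()
        assert cum["all_pairs"] <= cum["at_least_two"] <= cum["at_least_one"]
        counts = report.tier_counts()
        assert sum(counts.values()) == 200
        assert set(report.frame["tier"]) <= set(TIERS)


class TestIdentifySpecific:
    def make_study(self):
        # m_spec: RBC + one hemolyzed only; m_leaky: also in a non-hemolyzed
        # sample; m_dim: RBC + hemolyzed but never below Cq 35.
        t = make_cq_table(
            {
                ("P1_NH", "1"): [None, 30.0, None, 25.0],
                ("P1_H", "1"): [32.0, 31.0, 36.0, 24.0],
                ("P2_NH", "1"): [None, None, None, 25.0],
                ("P2_H", "1"): [33.0, 30.0, 37.0, 24.5],
                ("RBC", "1"): [22.0, 21.0, 36.5, 18.0],
            },
            ["m_spec", "m_leaky", "m_dim", "m_common"],
        )
        sheet = make_pair_sheet({"P1": (0.14, 0.41), "P2": (0.15, 0.40)})
        return t, sheet

    def test_pattern_recovery(self):
        t, sheet = self.make_study()
        assert identify_specific(t, sheet) == ["m_spec"]

    def test_requires_rbc_sample(self):
        t, _ = self.make_study()
        sheet = make_pair_sheet({"P1": (0.14, 0.41), "P2": (0.15, 0.40)}, rbc=False)
        with pytest.raises(ConfigurationError):
            identify_specific(t, sheet)

    def test_planted_specific_recovered_noise_free(self):
        study = generate_paired_study(seed=5, n_mirs=80, noise_sd=0.0)
        planted = set(study.truth.index[study.truth["truth_label"] == "specific"])
        found = set(identify_specific(study.cq_table, study.sample_sheet))
        assert found == planted


class TestSelectSubsets:
    def sheet(self):
        # N1-like and MPM1-like extensively hemolyzed pairs plus a mild one
        return make_pair_sheet(
            {"Pmild": (0.184, 0.250), "Pmid": (0.174, 0.411), "Phigh": (0.124, 0.562)},
            rbc=False,
        )

    def entries(self, fc_mid, fc_high, mir="m"):
        return [fc(mir, "Pmild", 1.0), fc(mir, "Pmid", fc_mid), fc(mir, "Phigh", fc_high)]

    def test_changing_follows_degree(self):
        subsets = select_subsets(self.entries(2.50, 26.93), self.sheet())
        assert subsets["changing"] == ["m"]
        assert subsets["unaffected"] == []

    def test_unaffected_band(self):
        subsets = select_subsets(self.entries(1.14, 1.20), self.sheet())
        assert subsets == {"changing": [], "unaffected": ["m"]}

    def test_order_violation_excluded(self):
        subsets = select_subsets(self.entries(26.9, 2.5), self.sheet())
        assert subsets == {"changing": [], "unaffected": []}

    def test_subsets_disjoint_on_random_input(self):
        rng = np.random.default_rng(8)
        entries = []
        for i in range(100):
            entries += self.entries(
                float(np.exp(rng.normal(0.5, 1))), float(np.exp(rng.normal(0.5, 1))),
                mir=f"m{i}",
            )
        subsets = select_subsets(entries, self.sheet())
        assert not set(subsets["changing"]) & set(subsets["unaffected"])

    def test_too_few_extensive_pairs(self):
        sheet = make_pair_sheet({"P1": (0.184, 0.250), "P2": (0.2, 0.3)}, rbc=False)
        with pytest.raises(ConfigurationError, match="degree_cutoff"):
            select_subsets([fc("m", "P1", 2.0), fc("m", "P2", 2.0)], sheet)


def test_end_to_end_noise_free_recovery(noise_free_study):
    """Noise-free synthetic study: every planted label is recovered."""
    study = noise_free_study
    specific = identify_specific(study.cq_table, study.sample_sheet)
    fcs = fold_change_matrix(study.cq_table, study.sample_sheet)
    report = tier_mirnas(fcs, specific_ids=specific)
    truth = study.truth["truth_label"]
    elevated = {TIER_ELEVATED_ALL, TIER_ELEVATED_TWO, TIER_ELEVATED_ONE}
    for mir, label in truth.items():
        tier = report.frame.loc[mir, "tier"]
        if label == "susceptible":
            assert tier in elevated
        elif label == "stable":
            assert tier == TIER_STABLE
        else:
            assert tier == TIER_SPECIFIC
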