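"""Exactness and invariances of the two-component prevalence decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prevdecomp.core import GroupSummary
from prevdecomp.datasets import group_summaries_from_margins
from prevdecomp.decomposition import (
    advanced_decomposition,
    basic_decomposition,
    decompose_summaries,
    summarize_groups,
)


def summaries(shares, prevs, labels=None):
    labels = labels or [f"g{i}" for i in range(len(shares))]
    return [
        GroupSummary(group=l, share=s, prevalence=p, n_effective=100.0)
        for l, s, p in zip(labels, shares, prevs)
    ]


@st.composite
def wave_pairs(draw, k_max=6):
    k = draw(st.integers(2, k_max))
    def shares():
        raw = draw(st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k))
        total = sum(raw)
        return [r / total for r in raw]
    def prevs():
        return draw(st.lists(st.floats(0.0, 1.0), min_size=k, max_size=k))
    return summaries(shares(), prevs()), summaries(shares(), prevs())


class TestBasicDecomposition:
    def test_published_education_split(self):
        """The printed education shares and prevalences of the first and
        last waves reproduce the published 17.5% / 82.5% split."""
        st_ = group_summaries_from_margins("education", "2006")
        st1 = group_summaries_from_margins("education", "2016-17")
        r = decompose_summaries(st_, st1)
        assert r.compositional_share == pytest.approx(17.5, abs=0.2)
        assert r.behavioral_share == pytest.approx(82.5, abs=0.2)
        assert r.delta_Y == pytest.approx(0.125, abs=0.001)

    def test_age_compositional_component_near_zero(self):
        """Age-group shares barely move between the first and last wave, so
        the compositional part is a small fraction of a percentage point;
        it equals the direct arithmetic sum(d_share * mid_prev)."""
        sa = group_summaries_from_margins("age_group", "2006")
        sa1 = group_summaries_from_margins("age_group", "2016-17")
        r = decompose_summaries(sa, sa1)
        oracle = sum(
            (b.share - a.share) * 0.5 * (a.prevalence + b.prevalence)
            for a, b in zip(sa, sa1)
        )
        assert r.compositional == pytest.approx(oracle, abs=1e-15)
        assert abs(100 * r.compositional) < 0.1  # fraction of a pp

    def test_identical_waves_give_zero(self):
        s = summaries([0.5, 0.5], [0.2, 0.4])
        r = decompose_summaries(s, s)
        assert r.delta_Y == r.compositional == r.behavioral == 0

    def test_single_group(self):
        a = summaries([1.0], [0.2], ["all"])
        b = summaries([1.0], [0.5], ["all"])
        r = decompose_summaries(a, b)
        assert r.behavioral == pytest.approx(0.3)
        assert r.compositional == 0

    def test_mismatched_group_sets_error(self):
        a = summaries([0.5, 0.5], [0.1, 0.2], ["x", "y"])
        b = summaries([0.5, 0.5], [0.1, 0.2], ["x", "z"])
        with pytest.raises(ValueError, match="group sets differ"):
            decompose_summaries(a, b)

    def test_shares_sum_to_100(self):
        a = summaries([0.3, 0.7], [0.1, 0.6])
        b = summaries([0.6, 0.4], [0.3, 0.2])
        r = decompose_summaries(a, b)
        assert r.compositional_share + r.behavioral_share == 100.0

    @given(wave_pairs())
    @settings(max_examples=200, deadline=None)
    def test_exact_additivity(self, pair):
        a, b = pair
        r = decompose_summaries(a, b)
        y0 = sum(s.share * s.prevalence for s in a)
        y1 = sum(s.share * s.prevalence for s in b)
        assert r.compositional + r.behavioral == pytest.approx(r.delta_Y, abs=1e-10)
        assert r.delta_Y == pytest.approx(y1 - y0, abs=1e-10)

    @given(wave_pairs())
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, pair):
        a, b = pair
        r, rr = decompose_summaries(a, b), decompose_summaries(b, a)
        assert rr.delta_Y == pytest.approx(-r.delta_Y, abs=1e-12)
        assert rr.compositional == pytest.approx(-r.compositional, abs=1e-12)
        assert rr.behavioral == pytest.approx(-r.behavioral, abs=1e-12)

    @given(wave_pairs())
    @settings(max_examples=50, deadline=None)
    def test_null_group_invariance(self, pair):
        a, b = pair
        r = decompose_summaries(a, b)
        a2 = a + summaries([0.0], [0.0], ["ghost"])
        b2 = b + summaries([0.0], [0.0], ["ghost"])
        r2 = decompose_summaries(a2, b2)
        assert r2.compositional == pytest.approx(r.compositional, abs=1e-12)
        assert r2.behavioral == pytest.approx(r.behavioral, abs=1e-12)

    def test_scale_invariance_percent_vs_proportion(self):
        a = summaries([0.3, 0.7], [0.11, 0.61])
        b = summaries([0.6, 0.4], [0.33, 0.22])
        ap = summaries([0.3, 0.7], [11.0 / 100, 61.0 / 100])
        r = decompose_summaries(a, b)
        rp = decompose_summaries(ap, b)
        assert r.compositional == pytest.approx(rp.compositional, abs=1e-15)


class TestSummarizeGroups:
    def test_matches_brute_force_oracle(self, two_wave_frame):
        got = summarize_groups(two_wave_frame, "w1", "education")
        sub = two_wave_frame[two_wave_frame["wave"] == "w1"]
        for g in got:
            d = sub[sub["education"] == g.group]
            assert g.share == pytest.approx(d["weight"].sum() / sub["weight"].sum(), abs=1e-12)
            assert g.prevalence == pytest.approx(
                (d["weight"] * d["outcome"]).sum() / d["weight"].sum(), abs=1e-12
            )

    def test_shares_sum_to_one(self, two_wave_frame):
        got = summarize_groups(two_wave_frame, "w2", "education")
        assert sum(g.share for g in got) == pytest.approx(1.0, abs=1e-9)

    def test_absent_group_filled_with_warning(self, two_wave_frame, caplog):
        with caplog.at_level("WARNING"):
            got = summarize_groups(
                two_wave_frame, "w1", "education", all_groups=["low", "mid", "high", "phd"]
            )
        assert got[-1].share == 0.0 and got[-1].prevalence == 0.0
        assert "phd" in caplog.text

    def test_missing_wave_raises(self, two_wave_frame):
        with pytest.raises(ValueError, match="no records"):
            summarize_groups(two_wave_frame, "w9", "education")

    def test_basic_decomposition_end_to_end(self, two_wave_frame):
        r = basic_decomposition(two_wave_frame, "w1", "w2", "education")
        assert r.compositional + r.behavioral == pytest.approx(r.delta_Y, abs=1e-12)
        assert r.delta_Y > 0  # the second wave was generated more prevalent


def two_wave_grouped_frame(y_by_cell, cell_n=None):
    """Tiny deterministic two-wave dataset; y_by_cell maps
    (wave, group, within_cat) -> prevalence, realized exactly with
    ``cell_n[(group, within_cat)]`` respondents per cell (default 100)."""
    rows = []
    for (wave, g, x), p in y_by_cell.items():
        n = (cell_n or {}).get((g, x), 100)
        n1 = int(round(n * p))
        for i in range(n):
            rows.append(
                {
                    "respondent_id": f"{wave}{g}{x}{i}",
                    "wave": wave,
                    "stratum_id": "s",
                    "cluster_id": f"{wave}{g}{x}",
                    "weight": 1.0,
                    "outcome": 1 if i < n1 else 0,
                    "grp": g,
                    "wcov": x,
                }
            )
    return pd.DataFrame(rows)


class TestAdvancedDecomposition:
    def test_refinement_sums_to_behavioral_terms(self, two_wave_frame):
        adv = advanced_decomposition(two_wave_frame, "w1", "w2", "residence", "education")
        for g, s in zip(adv.basic.per_group, adv.per_group_behavioral_split):
            total = s.intercept_term + s.covariate_term + s.slope_term + s.residual_term
            assert total == pytest.approx(g.behavioral, abs=1e-10)

    def test_constant_shift_is_pure_intercept_change(self):
        """If every subgroup prevalence moves by the same constant c the
        fit assigns the whole change to the intercept."""
        base = {("w1", g, x): p for g, x, p in [
            ("a", "u", 0.10), ("a", "v", 0.30), ("b", "u", 0.20), ("b", "v", 0.40),
        ]}
        shifted = {("w2", g, x): p + 0.25 for (_, g, x), p in base.items()}
        # groups need different within-covariate composition for the slope
        # to be identified in the across-group regression
        cell_n = {("a", "u"): 160, ("a", "v"): 40, ("b", "u"): 40, ("b", "v"): 160}
        frame = two_wave_grouped_frame({**base, **shifted}, cell_n)
        adv = advanced_decomposition(frame, "w1", "w2", "grp", "wcov")
        assert adv.beta_change == pytest.approx(0.0, abs=1e-10)
        assert adv.alpha_change == pytest.approx(0.25, abs=1e-10)
        for s in adv.per_group_behavioral_split:
            assert s.covariate_term == pytest.approx(0.0, abs=1e-10)
            assert s.slope_term == pytest.approx(0.0, abs=1e-10)
            assert s.residual_term == pytest.approx(0.0, abs=1e-10)

    def test_doubled_slope_carried_by_slope_term(self):
        """Prevalences exactly linear in the within-covariate score with
        the slope doubled in wave two: residual changes vanish and the
        slope term carries the behavioral change (composition held fixed)."""
        # groups differ in composition over x so X_j differs; y = a + b*xbar
        # exactly at the group level requires linearity in x per respondent
        cells = {}
        for wave, (a, b) in [("w1", (0.1, 0.2)), ("w2", (0.1, 0.4))]:
            for g in ("a", "b"):
                for xi, x in enumerate(("u", "v")):
                    cells[(wave, g, x)] = a + b * xi
        cell_n = {("a", "u"): 160, ("a", "v"): 40, ("b", "u"): 40, ("b", "v"): 160}
        frame = two_wave_grouped_frame(cells, cell_n)
        adv = advanced_decomposition(frame, "w1", "w2", "grp", "wcov")
        assert adv.beta_change == pytest.approx(0.2, abs=1e-10)
        for s in adv.per_group_behavioral_split:
            assert s.residual_term == pytest.approx(0.0, abs=1e-10)
            assert s.covariate_term == pytest.approx(0.0, abs=1e-10)

    def test_too_few_within_categories_rejected(self, two_wave_frame):
        frame = two_wave_frame.copy()
        frame["const"] = "only"
        with pytest.raises(ValueError, match=">=2"):
            advanced_decomposition(frame, "w1", "w2", "residence", "const")
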