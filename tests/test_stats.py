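"""Correlation, multiple-testing, effect-size and responder statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from reachkin.errors import (
    InvalidArgumentError,
    UndefinedBandError,
    UndefinedCorrelationError,
    UndefinedEffectSizeError,
)
from reachkin.published import (
    CONSISTENT_EFFECT_ROWS,
    GROUP_SUMMARIES,
    recompute_effect_magnitude,
)
from reachkin.stats import (
    bootstrap_paired_t,
    cohens_d,
    correlation_matrix,
    effect_size_label,
    hinkle_label,
    holm_adjust,
    mcid_flags,
    nonparetic_band,
    paired_tests_table,
    spearman,
    within_band,
)


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_worked_example(self):
        # 1 - 6 * sum(d^2) / (n (n^2 - 1)) with sum(d^2) = 2, n = 4
        r, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_antisymmetry(self):
        r1, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        r2, _ = spearman([1, 2, 3, 4], [4, 2, 3, 1])
        assert r2 == pytest.approx(-r1)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spearman([1, 2, 3], [1, 2, 3])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3)
        assert r2 == pytest.approx(r1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert holm_adjust([]).size == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_statsmodels_and_dominates_raw(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 25))
        ours = holm_adjust(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= p - 1e-15).all()
        bonferroni = np.minimum(p * p.size, 1.0)
        assert (bonferroni >= ours - 1e-15).all()


class TestHinkleLabel:
    @pytest.mark.parametrize(
        "r,label",
        [
            (-0.73, "high"), (0.0, "negligible"), (0.50, "moderate"),
            (0.30, "low"), (0.70, "high"), (0.49, "low"), (-1.0, "high"),
            (0.69, "moderate"), (0.29, "negligible"),
        ],
    )
    def test_boundaries_assigned_to_higher_class(self, r, label):
        assert hinkle_label(r) == label


class TestCohensD:
    @pytest.mark.parametrize("variable", CONSISTENT_EFFECT_ROWS)
    def test_printed_group_effect_sizes_recomputed(self, variable):
        """Baseline-SD d recomputed from printed pre/post summaries matches
        the tabulated magnitude to two decimals."""
        printed = {
            "FMA_UE": 0.76, "WMFT_Time": 0.35, "MAL_AOU": 1.12,
            "MAL_QOM": 1.31, "TpctVmax": 0.70, "CurvI": 0.30,
            "Vmax": 0.16, "TExc": 0.03,
        }
        assert round(recompute_effect_magnitude(variable), 2) == printed[variable]

    def test_fma_worked_example_signed(self):
        assert cohens_d(32.20, 9.60, 39.50, "increase") == pytest.approx(
            0.76, abs=0.005
        )

    def test_decrease_direction_flips_sign(self):
        assert cohens_d(10.0, 2.0, 8.0, "decrease") == pytest.approx(1.0)

    def test_no_change_is_zero(self):
        assert cohens_d(5.0, 1.0, 5.0) == 0.0

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(UndefinedEffectSizeError):
            cohens_d(5.0, 0.0, 6.0)

    @pytest.mark.parametrize(
        "d,label",
        [(0.1, "negligible"), (0.2, "small"), (0.5, "medium"),
         (0.8, "large"), (-0.9, "large")],
    )
    def test_effect_labels(self, d, label):
        assert effect_size_label(d) == label


class TestBootstrapPairedT:
    def test_identical_pre_post_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bootstrap_paired_t(x, x.copy(), B=200, seed=0)
        assert res.degenerate
        assert res.d == 0.0
        assert np.isnan(res.p_boot)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=12)
        post = pre + rng.normal(size=12)
        a = bootstrap_paired_t(pre, post, B=500, seed=17)
        b = bootstrap_paired_t(pre, post, B=500, seed=17)
        assert (a.p_boot, a.ci_low, a.ci_high) == (b.p_boot, b.ci_low, b.ci_high)

    def test_unit_shift_detected(self):
        """CI excludes 0 in >= 99% of 200 seeded runs with a true shift of
        one SD at n = 30."""
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            pre = rng.normal(size=30)
            post = pre + 1.0 + 0.3 * rng.normal(size=30)
            res = bootstrap_paired_t(pre, post, B=500, seed=rng)
            if res.ci_low > 0:
                hits += 1
        assert hits >= 198

    def test_family_table_applies_holm(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=10)
        data = {
            "a": (pre, pre + 3.0 + 0.2 * rng.normal(size=10)),
            "b": (pre, pre + rng.normal(scale=0.1, size=10)),
        }
        table = paired_tests_table(data, {"a": "increase", "b": "increase"},
                                   B=500, seed=0)
        assert (table["p_holm"] >= table["p_boot"] - 1e-12).all()
        assert set(table["variable"]) == {"a", "b"}


class TestCorrelationMatrix:
    def _tables(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(12):
            for session in ("pre", "post"):
                val = rng.normal() + (1.0 if session == "post" else 0.0)
                rows.append(
                    {
                        "subject_id": f"S{i:02d}", "session": session,
                        "arm": "paretic", "LDJ": val, "MT": rng.normal(),
                    }
                )
        kin = pd.DataFrame(rows)
        clin = kin[["subject_id", "session"]].copy()
        clin["FMA_UE"] = 30 + 2.0 * kin["LDJ"].to_numpy()  # exact monotone
        clin["FMA_UE_prox"] = 20 + 1.5 * kin["LDJ"].to_numpy()
        return kin, clin

    def test_perfect_monotone_link_gives_unit_correlation(self):
        kin, clin = self._tables()
        grid = correlation_matrix(
            kin, clin, "cross_sectional", ["LDJ"], measures=("FMA_UE",)
        )
        assert set(grid["variant"]) == {"total", "proximal"}
        assert (grid["r_s"] == pytest.approx(1.0)) if len(grid) == 1 else (
            grid["r_s"].to_numpy() == pytest.approx(np.ones(len(grid)))
        )
        assert (grid["label"] == "high").all()

    def test_longitudinal_uses_per_subject_deltas(self):
        kin, clin = self._tables()
        grid = correlation_matrix(
            kin, clin, "longitudinal", ["LDJ"], measures=("FMA_UE",)
        )
        total = grid[(grid["variant"] == "total")].iloc[0]
        assert total["r_s"] == pytest.approx(1.0)
        assert total["n"] == 12

    def test_subject_missing_a_session_dropped_from_longitudinal(self):
        kin, clin = self._tables()
        kin = kin[~((kin["subject_id"] == "S00") & (kin["session"] == "post"))]
        grid = correlation_matrix(
            kin, clin, "longitudinal", ["LDJ"], measures=("FMA_UE",)
        )
        assert grid.iloc[0]["n"] == 11

    def test_unknown_scope_rejected(self):
        kin, clin = self._tables()
        with pytest.raises(InvalidArgumentError):
            correlation_matrix(kin, clin, "diagonal", ["LDJ"])


class TestMcidAndBand:
    def _clinical(self):
        return pd.DataFrame(
            [
                # subject A: FMA gain exactly at MCID (flag, boundary incl.)
                {"subject_id": "A", "session": "pre", "FMA_UE": 30.0,
                 "WMFT_Time": 20.0},
                {"subject_id": "A", "session": "post", "FMA_UE": 35.25,
                 "WMFT_Time": 21.0},
                # subject B: deteriorates on both
                {"subject_id": "B", "session": "pre", "FMA_UE": 40.0,
                 "WMFT_Time": 15.0},
                {"subject_id": "B", "session": "post", "FMA_UE": 38.0,
                 "WMFT_Time": 18.0},
                # subject C: WMFT-Time improvement (decrease) beyond MCID
                {"subject_id": "C", "session": "pre", "FMA_UE": 25.0,
                 "WMFT_Time": 30.0},
                {"subject_id": "C", "session": "post", "FMA_UE": 26.0,
                 "WMFT_Time": 25.0},
            ]
        )

    def test_flags_and_responders_match_construction(self):
        flags, summary = mcid_flags(
            self._clinical(),
            {"FMA_UE": 5.25, "WMFT_Time": 1.5},
            {"FMA_UE": "increase", "WMFT_Time": "decrease"},
        )
        by = flags.set_index(["subject_id", "measure"])["meets_mcid"]
        assert bool(by[("A", "FMA_UE")]) is True  # boundary inclusive
        assert bool(by[("A", "WMFT_Time")]) is False  # worsened
        assert bool(by[("B", "FMA_UE")]) is False
        assert bool(by[("C", "WMFT_Time")]) is True
        responders = summary.set_index("subject_id")["responder"]
        assert bool(responders["A"]) and bool(responders["C"])
        assert not bool(responders["B"])
        assert int(summary["responder"].sum()) == 2

    def test_band_membership(self):
        vals = [10.0, 12.0, 14.0, 16.0, 18.0]
        band = nonparetic_band(vals)
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        assert band == (pytest.approx(mean - sd), pytest.approx(mean + sd))
        assert within_band(mean, band)
        assert not within_band(mean + 2 * sd, band)

    def test_band_needs_two_observations(self):
        with pytest.raises(UndefinedBandError):
            nonparetic_band([4.0])
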