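"""Agreement statistics: pairing, Bland–Altman, ICC, CV, t-test, verdicts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fetalvol import (
    PairedSeries,
    analyze_pairs,
    agreement_table,
    bland_altman,
    build_pairs,
    cv_estimate,
    equality_plot_data,
    icc_estimate,
    paired_t,
    percent_differences,
    verdict,
)
from fetalvol.errors import DegenerateDataError
from tests._reference import icc_two_way_oracle


def _pairs(a, b, design="inter"):
    a = np.asarray(a, dtype=float)
    return PairedSeries([str(i) for i in range(len(a))], a, np.asarray(b, float), design)


def _records(values):
    """values: {(subject, observer, repeat, organ): volume}"""
    rows = [
        {"subject_id": s, "observer_id": o, "repeat_index": r, "organ": g, "volume_mm3": v}
        for (s, o, r, g), v in values.items()
    ]
    return pd.DataFrame(rows)


class TestBuildPairs:
    def test_inter_averages_repeats_before_differencing(self):
        rec = _records(
            {
                ("S1", "o1", 1, "heart"): 100.0,
                ("S1", "o1", 2, "heart"): 110.0,
                ("S1", "o2", 1, "heart"): 80.0,
                ("S1", "o2", 2, "heart"): 90.0,
                ("S2", "o1", 1, "heart"): 200.0,
                ("S2", "o1", 2, "heart"): 210.0,
                ("S2", "o2", 1, "heart"): 190.0,
                ("S2", "o2", 2, "heart"): 200.0,
            }
        )
        pairs = build_pairs(rec, "inter", "heart", observers=("o1", "o2"))
        assert pairs.a[0] == 105.0 and pairs.b[0] == 85.0

    def test_missing_subjects_excluded_and_counted(self):
        values = {}
        for i in range(25):
            for o in ("o1", "o2"):
                for r in (1, 2):
                    v = float("nan") if (o == "o2" and i < 5) else 100.0 + i
                    values[(f"S{i:02d}", o, r, "kidney_left")] = v
        pairs = build_pairs(_records(values), "inter", "kidney_left", observers=("o1", "o2"))
        assert pairs.n == 20
        assert pairs.n_excluded == 5

    def test_intra_complete_data(self):
        values = {
            (f"S{i}", "o1", r, "heart"): 100.0 + i + r for i in range(6) for r in (1, 2)
        }
        pairs = build_pairs(_records(values), "intra", "heart", observer="o1")
        assert pairs.n == 6
        assert pairs.design == "intra:o1"

    def test_absent_organ_rejected(self):
        rec = _records({("S1", "o1", 1, "heart"): 100.0})
        with pytest.raises(ValueError):
            build_pairs(rec, "intra", "lung_left", observer="o1")


class TestPercentDifferences:
    def test_values(self):
        d = percent_differences(_pairs([100, 110, 100], [100, 90, 100]))
        np.testing.assert_allclose(d, [0.0, 20.0, 0.0])

    def test_zero_pair_mean_rejected(self):
        with pytest.raises(DegenerateDataError):
            percent_differences(_pairs([0.0, 1.0, 1.0], [0.0, 1.0, 1.0]))


class TestBlandAltman:
    def test_degenerate_zero_differences(self):
        ba = bland_altman(_pairs([100, 120, 140, 160], [100, 120, 140, 160]))
        assert ba.mean_diff_pct == 0.0
        assert ba.loa_lower_pct == ba.loa_upper_pct == 0.0

    def test_constant_differences_collapse_loa(self):
        a = np.array([105.0, 210.0, 315.0])
        b = a * 0.95 / 1.05  # constant 10% difference relative to the pair mean
        ba = bland_altman(_pairs(a, b))
        assert ba.mean_diff_pct == pytest.approx(10.0, abs=1e-9)
        assert ba.loa_lower_pct == pytest.approx(10.0, abs=1e-9)
        assert ba.loa_upper_pct == pytest.approx(10.0, abs=1e-9)

    def test_gaussian_coverage_at_large_n(self):
        """~95% of differences fall inside ±1.96·SD limits (n = 10,000)."""
        rng = np.random.default_rng(3)
        d = rng.normal(0, 10.0, size=10_000)
        a = 100.0 * (1 + d / 200.0)
        b = 100.0 * (1 - d / 200.0)
        ba = bland_altman(_pairs(a, b))
        inside = (ba.diffs_pct >= ba.loa_lower_pct) & (ba.diffs_pct <= ba.loa_upper_pct)
        assert 0.94 <= inside.mean() <= 0.96

    def test_small_n_rejected(self):
        with pytest.raises(DegenerateDataError):
            bland_altman(_pairs([1.0, 2.0], [1.0, 2.0]))


class TestICC:
    def test_perfect_agreement(self):
        icc, lo, hi = icc_estimate(_pairs([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]))
        assert icc == pytest.approx(1.0)
        assert lo <= icc <= hi

    def test_large_offset_small_spread_drives_icc_to_zero(self):
        a = np.array([100.0, 101.0, 102.0, 103.0, 104.0])
        icc, _, _ = icc_estimate(_pairs(a, a + 50.0))
        assert icc < 0.1

    def test_matches_sums_of_squares_oracle(self, rng):
        """ICC(A,1) equals the explicit ANOVA oracle to 1e-10 on 100 tables."""
        for _ in range(100):
            a = rng.normal(100, 30, 25)
            b = a * rng.uniform(0.7, 1.3) + rng.normal(0, 10, 25)
            icc, lo, hi = icc_estimate(_pairs(a, b))
            assert icc == pytest.approx(icc_two_way_oracle(a, b), abs=1e-10)
            assert lo <= icc <= hi

    def test_matches_pingouin_icc2(self, rng):
        """Estimate and CI agree with pingouin's ICC2 (independent oracle)."""
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            a = rng.normal(100, 30, 20)
            b = a + rng.normal(0, 12, 20)
            icc, lo, hi = icc_estimate(_pairs(a, b))
            long = pd.DataFrame(
                {
                    "subject": np.r_[np.arange(20), np.arange(20)],
                    "rater": ["r1"] * 20 + ["r2"] * 20,
                    "score": np.r_[a, b],
                }
            )
            ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
            row = ref[ref.Type.str.contains("A,1")].iloc[0]
            assert icc == pytest.approx(row.ICC, abs=1e-8)
            # pingouin rounds its CI to 2 decimals
            assert (lo, hi) == pytest.approx(tuple(row.CI95), abs=6e-3)

    def test_one_way_form_available(self, rng):
        a = rng.normal(100, 30, 15)
        b = a + rng.normal(0, 10, 15)
        icc2, _, _ = icc_estimate(_pairs(a, b), form="two_way")
        icc1, lo, hi = icc_estimate(_pairs(a, b), form="one_way")
        assert lo <= icc1 <= hi
        assert icc1 != icc2

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_estimate(_pairs([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]))

    def test_ci_coverage_under_two_way_model(self):
        """95% CI covers a true ICC of 0.8 in [92.5%, 97.5%] of replicates."""
        from fetalvol.simulate import icc_ci_coverage

        cov = icc_ci_coverage(true_icc=0.8, n_subjects=25, n_reps=400, seed=9)
        assert 0.925 <= cov <= 0.975


class TestCV:
    def test_identical_pairs_give_zero(self):
        assert cv_estimate(_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 0.0

    def test_rms_formula_on_20pct_difference(self):
        """Pairs (110, 90): d=20, m=100 → CV = 100·sqrt((400/2)/10000) = 14.142%."""
        pairs = _pairs([110.0] * 3, [90.0] * 3)
        assert cv_estimate(pairs) == pytest.approx(100.0 * math.sqrt(200.0 / 10000.0), abs=1e-3)

    def test_recovers_lognormal_within_subject_sigma(self, rng):
        """RMS CV ≈ 100·σ_w for lognormal within-subject error (MC oracle)."""
        sigma_w = 0.08
        n = 5000
        m = rng.lognormal(mean=4.5, sigma=0.4, size=n)
        a = m * np.exp(rng.normal(0, sigma_w, n) - sigma_w**2 / 2)
        b = m * np.exp(rng.normal(0, sigma_w, n) - sigma_w**2 / 2)
        cv = cv_estimate(_pairs(a, b))
        assert cv == pytest.approx(100.0 * sigma_w, rel=0.05)

    def test_sd_diff_variant(self):
        pairs = _pairs([110.0, 120.0, 100.0], [90.0, 100.0, 80.0])
        alt = cv_estimate(pairs, method="sd_diff")
        d = np.array([20.0, 20.0, 20.0])
        assert alt == pytest.approx(100.0 * d.std(ddof=1) / math.sqrt(2) / 100.0)


class TestPairedT:
    def test_symmetric_differences_give_t_zero(self):
        a = np.array([100.0, 100.0, 100.0, 100.0])
        d = np.array([-5.0, 5.0, -5.0, 5.0])
        b = a * (200.0 - d) / (200.0 + d)
        t, p = paired_t(_pairs(a, b))
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_t_and_p(self):
        """d=(1..5)%: t = 3/(1.5811/√5) = 4.2426; p from t(4)."""
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a = 100.0 * (200.0 + d) / 200.0
        b = a * (200.0 - d) / (200.0 + d)  # so 100·(a−b)/pair-mean == d
        t, p = paired_t(_pairs(a, b))
        assert t == pytest.approx(3.0 / (np.std(d, ddof=1) / math.sqrt(5)), abs=1e-6)
        assert t == pytest.approx(4.2426, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(4.242640687, 4), abs=1e-6)

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t(_pairs([110.0] * 4, [90.0] * 4))


class TestVerdict:
    def test_all_criteria_met(self):
        flags = verdict(icc=0.95, cv_pct=8.0, mean_diff_pct=2.0,
                        loa_lower_pct=-7.0, loa_upper_pct=11.0)
        assert flags == {"icc_ok": True, "cv_ok": True, "meandiff_ok": True, "loa_ok": True}

    def test_icc_below_090_fails(self):
        assert not verdict(0.86, 8.0, 2.0, -7.0, 11.0)["icc_ok"]

    def test_large_bias_fails_meandiff_and_loa(self):
        flags = verdict(icc=0.71, cv_pct=22.7, mean_diff_pct=30.3,
                        loa_lower_pct=-5.6, loa_upper_pct=66.2)
        assert not flags["meandiff_ok"]
        assert not flags["loa_ok"]
        assert not flags["cv_ok"]


class TestEqualityPlot:
    def test_identity_and_bias(self, tmp_path):
        a = np.array([1.0, 2.0, 3.0])
        tab = equality_plot_data(_pairs(a, a))
        assert (tab.a == tab.b).all()
        tab2 = equality_plot_data(_pairs(a, 0.75 * a))
        assert (tab2.b < tab2.a).all()
        path = tmp_path / "eq.csv"
        tab2.to_csv(path, index=False)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back[["a", "b"]].to_numpy(), tab2[["a", "b"]].to_numpy())


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        """% differences, CV, ICC, t and p are invariant under volume rescaling."""
        rng = np.random.default_rng(17)
        a = rng.normal(200, 50, 20).clip(10)
        b = (a * 0.9 + rng.normal(0, 10, 20)).clip(5)
        p1, p2 = _pairs(a, b), _pairs(scale * a, scale * b)
        np.testing.assert_allclose(percent_differences(p1), percent_differences(p2), rtol=1e-9)
        assert cv_estimate(p1) == pytest.approx(cv_estimate(p2), rel=1e-9)
        assert icc_estimate(p1)[0] == pytest.approx(icc_estimate(p2)[0], rel=1e-9)
        t1, pv1 = paired_t(p1)
        t2, pv2 = paired_t(p2)
        assert t1 == pytest.approx(t2, rel=1e-9)
        assert pv1 == pytest.approx(pv2, rel=1e-9)

    def test_analyze_pairs_report_consistency(self, rng):
        a = rng.normal(200, 50, 20).clip(10)
        b = a + rng.normal(0, 15, 20)
        rep = analyze_pairs(_pairs(a, b), organ="heart")
        assert rep.loa_lower_pct <= rep.mean_diff_pct <= rep.loa_upper_pct
        assert -1.0 <= rep.icc <= 1.0
        assert 0.0 < rep.p_value <= 1.0
        d = rep.to_dict()
        assert {"icc_ok", "cv_ok", "meandiff_ok", "loa_ok"} <= set(d)

    def test_agreement_table_has_15_rows_for_full_study(self, rng):
        values = {}
        for i in range(10):
            for o in ("o1", "o2"):
                for r in (1, 2):
                    for organ in ("heart", "lung_right", "lung_left",
                                  "kidney_right", "kidney_left"):
                        base = {"heart": 200, "lung_right": 370, "lung_left": 270,
                                "kidney_right": 100, "kidney_left": 90}[organ]
                        values[(f"S{i:02d}", o, r, organ)] = base * (1 + 0.1 * i) * (
                            1 + rng.normal(0, 0.05)
                        )
        table = agreement_table(_records(values), observers=("o1", "o2"))
        assert len(table) == 15
        assert set(table.design) == {"intra:o1", "intra:o2", "inter"}
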