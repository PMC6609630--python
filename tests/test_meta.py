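"""Meta-analysis engine: hand-arithmetic oracles, published-value checks,
independent-library cross-check and property tests."""

import json
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from dmetpk import (
    InsufficientDataError,
    StudyObservation,
    StudySet,
    cv_method_I,
    cv_method_II,
    cv_method_III,
    fixed_effect,
    forest_table,
    geometric_ci,
    heterogeneity_indices,
    random_effect,
    run_meta,
    weighted_mean,
)


def _study_set(means, sds, ns, protein="P"):
    return StudySet(protein=protein, tissue="liver", observations=[
        StudyObservation(label=f"S{i}", mean=m, sd=s, n=n, source=f"S{i}")
        for i, (m, s, n) in enumerate(zip(means, sds, ns))
    ])


# ---------------------------------------------------------------------------
# fixed / random effects
# ---------------------------------------------------------------------------

class TestFixedEffect:
    def test_hand_arithmetic(self, two_study_set):
        fe = fixed_effect(two_study_set)
        assert fe.weights == pytest.approx([1.0, 0.25])
        assert fe.mu_F == pytest.approx(12.0)
        assert fe.Q_F == pytest.approx(20.0)   # 1*(10-12)^2 + 0.25*(20-12)^2
        assert fe.df == 1

    def test_single_usable_study(self):
        ss = _study_set([10.0], [1.0], [5])
        fe = fixed_effect(ss)
        assert fe.mu_F == 10.0 and fe.Q_F == 0.0 and fe.df == 0

    def test_zero_sd_studies_excluded_and_counted(self):
        ss = _study_set([10, 20, 30], [1.0, 0.0, 2.0], [5, 5, 5])
        fe = fixed_effect(ss)
        assert fe.k_used == 2 and ss.k == 3

    def test_no_usable_study_raises(self, zero_sd_study_set):
        with pytest.raises(InsufficientDataError, match="TEST0"):
            fixed_effect(zero_sd_study_set)


class TestRandomEffect:
    def test_hand_arithmetic(self, two_study_set):
        fe = fixed_effect(two_study_set)
        re = random_effect(two_study_set, fe)
        assert re.tau2 == pytest.approx(47.5)   # (20-1)/(1.25-1.0625/1.25)
        assert re.weights_star == pytest.approx([1 / 48.5, 1 / 51.5])
        assert re.mu_R == pytest.approx(14.850, abs=5e-4)
        assert re.Q_R == pytest.approx(1.000, abs=5e-4)

    def test_collapse_onto_fixed_effect_when_q_below_df(self):
        # nearly identical means, large SDs -> Q_F < df
        ss = _study_set([10.0, 10.1, 9.9], [2.0, 2.0, 2.0], [5, 5, 5])
        fe = fixed_effect(ss)
        assert fe.Q_F <= fe.df
        re = random_effect(ss, fe)
        assert re.tau2 == 0.0
        assert re.mu_R == pytest.approx(fe.mu_F)
        assert re.Q_R == pytest.approx(fe.Q_F)

    def test_tie_q_equals_df_collapses(self):
        ss = _study_set([10.0, 12.0], [1.0, 1.0], [5, 5])
        fe = fixed_effect(ss)
        fe.Q_F = float(fe.df)  # force the tie
        re = random_effect(ss, fe)
        assert re.tau2 == 0.0

    def test_large_tau2_limit_is_unweighted_mean(self):
        # wildly separated means push tau2 so high that weights equalize
        means = [1.0, 100.0, 10000.0]
        ss = _study_set(means, [0.01, 0.01, 0.01], [5, 5, 5])
        fe = fixed_effect(ss)
        re = random_effect(ss, fe)
        assert re.mu_R == pytest.approx(np.mean(means), rel=1e-3)

    def test_metafor_cross_check(self, two_study_set, tmp_path):
        """Independent check of mu_F, tau2 (DerSimonian-Laird) and mu_R
        against R metafor with vi = SD_j^2."""
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(metafor));"
            "yi <- c(10, 20); vi <- c(1, 4);"
            "fe <- rma(yi=yi, vi=vi, method='FE');"
            "re <- rma(yi=yi, vi=vi, method='DL');"
            "cat(sprintf('{\"mu_F\": %.10f, \"tau2\": %.10f, \"mu_R\": %.10f}',"
            " as.numeric(fe$beta), re$tau2, as.numeric(re$beta)))\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout.strip())
        fe = fixed_effect(two_study_set)
        re = random_effect(two_study_set, fe)
        assert fe.mu_F == pytest.approx(ref["mu_F"], rel=1e-8)
        assert re.tau2 == pytest.approx(ref["tau2"], rel=1e-8)
        assert re.mu_R == pytest.approx(ref["mu_R"], rel=1e-8)


class TestHeterogeneityIndices:
    @pytest.mark.parametrize("Q,df,H2,I2,cls", [
        (31.24, 6, 5.21, 80.79, "high"),     # strongly heterogeneous
        (0.18, 1, 0.18, 0.00, "none"),       # negative I2 floored
        (3.89, 2, 1.95, 48.65, "medium"),
        (8.53, 6, 1.42, 29.67, "low"),
    ])
    def test_published_rows(self, Q, df, H2, I2, cls):
        het = heterogeneity_indices(Q, df)
        assert het.H2 == pytest.approx(H2, abs=0.01)
        assert het.I2_pct == pytest.approx(I2, abs=0.1)
        assert het.het_class == cls

    def test_q_equals_df_is_none(self):
        het = heterogeneity_indices(6.0, 6)
        assert het.H2 == 1.0 and het.I2_pct == 0.0
        assert het.het_class == "none"

    def test_df_zero_raises(self):
        with pytest.raises(InsufficientDataError, match="single study"):
            heterogeneity_indices(1.0, 0)

    def test_h2_concern_thresholds(self):
        assert heterogeneity_indices(16.0, 10).H2_concern == "considerable"
        assert heterogeneity_indices(13.0, 10).H2_concern == "intermediate"
        assert heterogeneity_indices(11.0, 10).H2_concern == "little"

    @pytest.mark.parametrize("Q,df", [(0.5, 1), (5.0, 3), (20.0, 7),
                                      (50.0, 10), (9.99, 10)])
    def test_p_value_against_numerical_integration(self, Q, df):
        """Upper-tail chi-square probability vs direct quadrature of the
        hand-written density."""
        def pdf(x):
            return (x ** (df / 2 - 1) * math.exp(-x / 2)
                    / (2 ** (df / 2) * math.gamma(df / 2)))
        expected, _ = integrate.quad(pdf, Q, np.inf, epsabs=1e-13,
                                     epsrel=1e-13)
        het = heterogeneity_indices(Q, df)
        assert het.P_value == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# pooling stage
# ---------------------------------------------------------------------------

class TestPooling:
    def test_weighted_mean_hand(self, two_study_set):
        assert weighted_mean(two_study_set) == pytest.approx(12.5)

    def test_weighted_mean_constant(self):
        ss = _study_set([7.0, 7.0, 7.0], [1, 1, 1], [3, 9, 2])
        assert weighted_mean(ss) == pytest.approx(7.0)

    def test_cv_method_I_hand(self, two_study_set):
        WM = weighted_mean(two_study_set)
        # nu = (3*6.25 + 56.25)/4 = 18.75
        assert cv_method_I(two_study_set, WM) == pytest.approx(
            100 * math.sqrt(18.75) / 12.5, rel=1e-12)
        assert cv_method_I(two_study_set, WM) == pytest.approx(34.64, abs=0.01)

    def test_cv_method_II_zero_sd_equals_method_I(self, zero_sd_study_set):
        WM = weighted_mean(zero_sd_study_set)
        assert cv_method_II(zero_sd_study_set, WM) == pytest.approx(
            cv_method_I(zero_sd_study_set, WM), rel=1e-12)
        # SS = 700 - 625 = 75 -> cv = 34.64
        assert cv_method_II(zero_sd_study_set, WM) == pytest.approx(
            34.64, abs=0.01)

    def test_cv_method_II_missing_sd_names_studies(self):
        ss = _study_set([10, 20], [1.0, None], [3, 3])
        with pytest.raises(InsufficientDataError, match="S1"):
            cv_method_II(ss, weighted_mean(ss))

    def test_cv_method_III_hand(self):
        ss = _study_set([10.0, 10.0], [1.0, 2.0], [3, 1])
        ss.observations[0].cv = 0.1
        ss.observations[1].cv = 0.2
        ss.observations[0].sd = 1.0
        ss.observations[1].sd = 2.0
        assert cv_method_III(ss) == pytest.approx(12.5)

    def test_cv_method_III_constant(self):
        ss = _study_set([10.0, 50.0], [2.0, 10.0], [4, 6])  # both CV=0.2
        assert cv_method_III(ss) == pytest.approx(20.0)

    def test_pseudo_individual_oracle_method_II(self):
        """Expanding each study into n_j exact pseudo-individuals, the plain
        pooled %CV of all individuals must equal method II, and method II
        must dominate method I (equality iff all SD=0)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = int(rng.integers(2, 7))
            means = rng.uniform(5, 200, k)
            sds = rng.uniform(0, 30, k)
            ns = rng.integers(2, 40, k)
            ss = _study_set(means.tolist(), sds.tolist(), ns.tolist())
            WM = weighted_mean(ss)
            individuals = []
            for m, s, n in zip(means, sds, ns):
                base = np.arange(n, dtype=float)
                z = (base - base.mean()) / (base.std() or 1.0)
                individuals.append(m + s * z)   # exact mean m, pop-SD s
            pooled = np.concatenate(individuals)
            oracle_cv = 100 * pooled.std() / pooled.mean()
            assert cv_method_II(ss, WM) == pytest.approx(oracle_cv, rel=1e-9)
            assert cv_method_II(ss, WM) >= cv_method_I(ss, WM) - 1e-12
            if np.any(sds > 0):
                assert cv_method_II(ss, WM) > cv_method_I(ss, WM)


class TestGeometricCI:
    @pytest.mark.parametrize("WM,cv,k,lo,hi", [
        (35.97, 102.97, 9, 20.64, 62.69),
        (24.63, 54.98, 2, 12.08, 50.21),
    ])
    def test_published_bounds(self, WM, cv, k, lo, hi):
        low, high = geometric_ci(WM, cv, k)
        assert low == pytest.approx(lo, abs=0.05)
        assert high == pytest.approx(hi, abs=0.05)

    def test_zero_cv_degenerates_to_point(self):
        assert geometric_ci(12.0, 0.0, 5) == (12.0, 12.0)

    def test_z_zero_is_point_and_widening_is_monotone(self):
        lo0, hi0 = geometric_ci(50.0, 40.0, 4, z=0.0)
        assert lo0 == hi0 == 50.0
        widths = []
        for z in (0.5, 1.0, 1.96, 4.26):
            lo, hi = geometric_ci(50.0, 40.0, 4, z=z)
            assert lo < 50.0 < hi
            widths.append(hi - lo)
        assert widths == sorted(widths)

    def test_log_symmetry(self):
        lo, hi = geometric_ci(50.0, 80.0, 3)
        assert math.log(50.0) - math.log(lo) == pytest.approx(
            math.log(hi) - math.log(50.0), rel=1e-12)

    def test_k_zero_raises(self):
        with pytest.raises(InsufficientDataError):
            geometric_ci(10.0, 20.0, 0)


# ---------------------------------------------------------------------------
# composite + properties
# ---------------------------------------------------------------------------

study_sets = st.integers(2, 8).flatmap(lambda k: st.tuples(
    st.lists(st.floats(0.5, 500.0), min_size=k, max_size=k),
    st.lists(st.floats(0.1, 50.0), min_size=k, max_size=k),
    st.lists(st.integers(2, 60), min_size=k, max_size=k),
))


class TestRunMeta:
    def test_report_is_complete(self, two_study_set):
        res = run_meta(two_study_set)
        assert res.fixed and res.random and res.het_fe and res.het_re
        assert set(res.pooled.cv_pct) == {"I", "II", "III"}
        d = res.to_dict()
        assert d["pooled"]["WM"] == pytest.approx(12.5)
        rows = forest_table(res)
        assert (rows.row_kind == "study").sum() == 2
        assert (rows.row_kind == "method_summary").sum() == 3

    def test_two_identical_studies_no_heterogeneity(self):
        ss = _study_set([30.0, 30.0], [3.0, 3.0], [10, 12])
        res = run_meta(ss)
        assert res.het_fe.I2_pct == 0.0
        assert res.het_fe.het_class == "none"

    def test_partial_report_without_sds(self):
        ss = _study_set([10.0, 20.0], [None, None], [3, 4])
        res = run_meta(ss)
        assert res.fixed is None and res.random is None
        assert res.pooled.WM == pytest.approx((30 + 80) / 7)
        assert "I" in res.pooled.cv_pct and "II" not in res.pooled.cv_pct
        assert res.notes

    def test_k1_rejected(self):
        ss = _study_set([10.0], [1.0], [3])
        with pytest.raises(InsufficientDataError, match="k >= 2"):
            run_meta(ss)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(study_sets)
    def test_invariants(self, data):
        means, sds, ns = data
        ss = _study_set(means, sds, ns)
        fe = fixed_effect(ss)
        re = random_effect(ss, fe)
        # RE weights never exceed FE weights, equality iff tau2 == 0
        for w, ws in zip(fe.weights, re.weights_star):
            assert ws <= w + 1e-12
            if re.tau2 > 0:
                assert ws < w
        # all summary estimates live inside the span of study means
        lo, hi = min(means) - 1e-9, max(means) + 1e-9
        WM = weighted_mean(ss)
        assert lo <= fe.mu_F <= hi
        assert lo <= re.mu_R <= hi
        assert lo <= WM <= hi
        # method II dominates method I
        assert cv_method_II(ss, WM) >= cv_method_I(ss, WM) - 1e-9
        # geometric CI brackets WM
        ci_lo, ci_hi = geometric_ci(WM, cv_method_II(ss, WM), ss.k)
        assert ci_lo <= WM <= ci_hi
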