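"""Integrated intensity, ARDI, ANOVA/Tukey, letters, dose response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hookquant import (
    DegenerateProfileError,
    IntensityProfile,
    MissingCellError,
    ValidationError,
    analytic_ardi,
    ardi,
    compact_letter_display,
    dose_response_slope,
    integrated_intensity,
    minimum_effective_concentration,
    one_way_anova_tukey,
    simulate_angle_table,
    two_way_anova_tukey,
)

from _oracles import (
    dense_profile_area_ardi,
    tukey_pvalues_from_scratch,
    two_way_ss_partition,
)


def _prof(values, n=None):
    v = np.asarray(values, float)
    return IntensityProfile(np.linspace(0, 1, v.size), v)


def _exp_prof(lam, n=101, B=0.0, S0=1.0):
    s = np.linspace(0, 1, n)
    return IntensityProfile(s, B + S0 * np.exp(-lam * s))


class TestIntegratedIntensity:
    def test_constant_profile(self):
        assert integrated_intensity(_prof(np.ones(11))) == pytest.approx(1.0)

    def test_linear_profile(self):
        assert integrated_intensity(_prof(np.linspace(0, 1, 11))) == pytest.approx(0.5)

    def test_exponential_against_closed_form(self):
        area = integrated_intensity(_exp_prof(2.0))
        assert area == pytest.approx((1 - np.exp(-2)) / 2, abs=5e-4)

    def test_linearity(self, rng):
        s = np.linspace(0, 1, 51)
        g, h = rng.uniform(0, 10, 51), rng.uniform(0, 10, 51)
        a, b = 2.5, 0.75
        lhs = integrated_intensity((s, a * g + b * h))
        rhs = a * integrated_intensity((s, g)) + b * integrated_intensity((s, h))
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestArdi:
    def test_uniform_profile_is_half(self):
        assert ardi(_prof(np.ones(101))) == pytest.approx(0.5, abs=1e-12)

    def test_mass_at_concave_edge(self):
        v = np.zeros(101)
        v[0] = 1.0
        assert ardi(_prof(v)) < 0.02

    def test_exponential_matches_analytic(self):
        assert ardi(_exp_prof(2.0)) == pytest.approx(
            analytic_ardi(2.0, 0.0, 1.0), abs=1e-3
        )
        assert ardi(_exp_prof(2.0)) == pytest.approx(0.2831, abs=1e-3)

    def test_zero_profile_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            ardi(_prof(np.zeros(11)))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.floats(1e-6, 1e6),
        lam=st.floats(0.0, 6.0),
    )
    def test_scale_invariance(self, c, lam):
        p = _exp_prof(lam)
        scaled = IntensityProfile(p.positions, c * p.values)
        assert ardi(scaled) == pytest.approx(ardi(p), abs=1e-12)

    def test_reflection_maps_to_complement(self, rng):
        for _ in range(20):
            v = rng.uniform(0.1, 10, 101)
            p = _prof(v)
            q = _prof(v[::-1].copy())
            assert ardi(q) == pytest.approx(1 - ardi(p), abs=1 / 100)

    def test_moving_mass_concaveward_never_increases_ardi(self, rng):
        for _ in range(100):
            v = rng.uniform(1.0, 10.0, 101)
            base = ardi(_prof(v))
            i = rng.integers(0, 50)  # concave half
            j = rng.integers(51, 101)  # convex half
            quantum = rng.uniform(0, v[j])
            v2 = v.copy()
            v2[j] -= quantum
            v2[i] += quantum
            assert ardi(_prof(v2)) <= base + 1e-12

    def test_agrees_with_fine_grid_oracle(self, rng):
        for _ in range(50):
            lam = rng.uniform(0, 5)
            B = rng.uniform(0, 200)
            S0 = rng.uniform(10, 200)
            area_o, ardi_o = dense_profile_area_ardi(lam, B, S0, n=100_001)
            p = _exp_prof(lam, B=B, S0=S0)
            assert integrated_intensity(p) == pytest.approx(area_o, abs=1e-3 * area_o)
            assert ardi(p) == pytest.approx(ardi_o, abs=1e-3)


class TestOneWayAnovaTukey:
    def test_overwhelming_separation_gets_distinct_letters(self):
        res = one_way_anova_tukey({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert set(res.letters["a"]) & set(res.letters["b"]) == set()

    def test_tukey_pvalues_match_from_scratch_studentized_range(self, rng):
        samples = [
            rng.normal(10, 2, 5),
            rng.normal(12, 2, 5),
            rng.normal(10.5, 2, 5),
        ]
        res = one_way_anova_tukey(dict(zip("abc", samples)))
        oracle = tukey_pvalues_from_scratch(samples)
        labels = ["a", "b", "c"]
        for (i, j), p_o in oracle.items():
            p_impl = res.pairwise_p[(labels[i], labels[j])]
            assert p_impl == pytest.approx(p_o, abs=1e-6)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(55)
        n_sim = 500
        rejects_f = 0
        rejects_letters = 0
        for _ in range(n_sim):
            groups = {g: rng.normal(100, 8, 15) for g in "abc"}
            res = one_way_anova_tukey(groups, alpha=0.05)
            if float(res.anova["p"].iloc[0]) < 0.05:
                rejects_f += 1
            if not all(
                set(res.letters[x]) & set(res.letters[y])
                for x, y in (("a", "b"), ("a", "c"), ("b", "c"))
            ):
                rejects_letters += 1
        assert 0.03 <= rejects_f / n_sim <= 0.07
        # Tukey familywise error is also controlled at alpha
        assert rejects_letters / n_sim <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_letters_consistent_with_pairwise_decisions(self, rng):
        for _ in range(20):
            k = rng.integers(3, 6)
            shift = rng.uniform(0, 6)
            groups = {
                f"g{i}": rng.normal(50 + shift * i, 4, 8) for i in range(k)
            }
            res = one_way_anova_tukey(groups, alpha=0.05)
            for a in res.groups:
                for b in res.groups:
                    if a >= b:
                        continue
                    share = bool(set(res.letters[a]) & set(res.letters[b]))
                    sig = res.pairwise_p[(a, b)] < res.alpha
                    assert share == (not sig)


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], [])
        assert set(letters.values()) == {"a"}

    def test_chain_structure(self):
        # a != c significant; a~b and b~c not: classic "ab / b / bc" pattern
        letters = compact_letter_display(["g1", "g2", "g3"], [("g1", "g3")])
        assert set(letters["g1"]) & set(letters["g3"]) == set()
        assert set(letters["g1"]) & set(letters["g2"])
        assert set(letters["g2"]) & set(letters["g3"])


class TestTwoWayAnovaTukey:
    def _balanced(self, rng, geno_effect=0.0, inter=0.0, n=4):
        rows = []
        for g in ("wt", "mut"):
            for t in ("mock", "npa"):
                mu = 100.0
                if g == "mut":
                    mu += geno_effect
                if g == "mut" and t == "npa":
                    mu += inter
                for _ in range(n):
                    rows.append(
                        {"genotype": g, "treatment": t,
                         "value": rng.normal(mu, 1.0)}
                    )
        return pd.DataFrame(rows)

    def test_identical_observations_nothing_significant(self):
        df = pd.DataFrame(
            [
                {"genotype": g, "treatment": t, "value": 42.0}
                for g in "ab"
                for t in "xy"
                for _ in range(3)
            ]
        )
        res = two_way_anova_tukey(df, "value", "genotype", "treatment")
        p = res.anova.set_index("source")["p"]
        assert not (p.iloc[:3] < 0.05).any()

    def test_extreme_genotype_effect_always_detected(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = self._balanced(rng, geno_effect=50.0, n=3)
            res = two_way_anova_tukey(df, "value", "genotype", "treatment")
            p_geno = float(res.anova.set_index("source").loc["genotype", "p"])
            assert p_geno < 0.05

    def test_sums_of_squares_match_naive_partition(self, rng):
        df = self._balanced(rng, geno_effect=5.0, inter=2.0, n=5)
        res = two_way_anova_tukey(df, "value", "genotype", "treatment")
        ss = res.anova.set_index("source")["sum_sq"]
        ss_a, ss_b, ss_ab, ss_e = two_way_ss_partition(
            df["value"], df["genotype"], df["treatment"]
        )
        assert ss["genotype"] == pytest.approx(ss_a, abs=1e-9)
        assert ss["treatment"] == pytest.approx(ss_b, abs=1e-9)
        assert ss["genotype:treatment"] == pytest.approx(ss_ab, abs=1e-9)
        assert ss["residual"] == pytest.approx(ss_e, abs=1e-9)

    def test_unbalanced_design_rejected_with_cell_named(self, rng):
        df = self._balanced(rng, n=3)
        df = df.drop(df.index[-1])
        with pytest.raises((ValidationError, MissingCellError), match="npa"):
            two_way_anova_tukey(df, "value", "genotype", "treatment")

    def test_empty_cell_rejected(self, rng):
        df = self._balanced(rng, n=3)
        df = df[~((df["genotype"] == "mut") & (df["treatment"] == "npa"))]
        with pytest.raises(MissingCellError, match="mut"):
            two_way_anova_tukey(df, "value", "genotype", "treatment")


class TestDoseResponse:
    def _table(self, slopes, noise_sd, n, seed=0, c=(0.005, 0.05)):
        means = {}
        for g, slope in slopes.items():
            means[(g, 2, c[0])] = 160.0
            means[(g, 2, c[1])] = 160.0 + slope * (np.log10(c[1]) - np.log10(c[0]))
        return simulate_angle_table(means, noise_sd=noise_sd, n_per_group=n,
                                    seed=seed)

    def test_equal_means_give_zero_slope(self):
        tab = simulate_angle_table(
            {("wt", 0.005): 120.0, ("wt", 0.05): 120.0}, noise_sd=0.0,
            n_per_group=3,
        )
        out = dose_response_slope(tab, 0.005, 0.05)
        assert out["slope_deg_per_decade"].iloc[0] == 0.0

    def test_one_decade_arithmetic(self):
        tab = simulate_angle_table(
            {("wt", 0.005): 160.0, ("wt", 0.05): 60.0}, noise_sd=0.0,
            n_per_group=3,
        )
        out = dose_response_slope(tab, 0.005, 0.05)
        assert out["slope_deg_per_decade"].iloc[0] == pytest.approx(-100.0)

    def test_injected_slopes_recovered_under_noise(self):
        truth = {"wt": -100.0, "hyl1": -60.0, "se": -140.0}
        tab = self._table(truth, noise_sd=5.0, n=30, seed=12)
        out = dose_response_slope(tab, 0.005, 0.05).set_index("genotype")
        for g, s in truth.items():
            assert out.loc[g, "slope_deg_per_decade"] == pytest.approx(s, abs=10.0)

    def test_mock_concentration_rejected_from_log_scale(self):
        tab = self._table({"wt": -100.0}, noise_sd=0.0, n=3)
        with pytest.raises(ValidationError):
            dose_response_slope(tab, 0.0, 0.05)

    def test_missing_concentration_cell_named(self):
        tab = self._table({"wt": -100.0}, noise_sd=0.0, n=3)
        with pytest.raises(MissingCellError, match="wt"):
            dose_response_slope(tab, 0.005, 0.5)


class TestMinimumEffectiveConcentration:
    def test_no_effect_returns_none(self):
        means = {("wt", 2, c): 150.0 for c in (0.0, 0.01, 0.1)}
        tab = simulate_angle_table(means, noise_sd=2.0, n_per_group=10, seed=4)
        out = minimum_effective_concentration(tab)
        assert np.isnan(out["mec_uM"].iloc[0])

    def test_overwhelming_single_shift_detected(self):
        means = {("wt", 2, 0.0): 150.0, ("wt", 2, 0.05): 70.0}
        tab = simulate_angle_table(means, noise_sd=2.0, n_per_group=20, seed=9)
        out = minimum_effective_concentration(tab)
        assert out["mec_uM"].iloc[0] == 0.05

    def test_threshold_between_levels_recovered(self):
        # effect kicks in at the 3rd tested level only
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            means = {
                ("wt", 2, 0.0): 160.0,
                ("wt", 2, 0.005): 160.0,
                ("wt", 2, 0.02): 160.0,
                ("wt", 2, 0.08): 120.0,
                ("wt", 2, 0.32): 80.0,
            }
            tab = simulate_angle_table(means, noise_sd=8.0, n_per_group=15,
                                       seed=seed)
            out = minimum_effective_concentration(tab)
            if out["mec_uM"].iloc[0] == 0.08:
                hits += 1
        assert hits >= 0.90 * n_rep

    def test_missing_mock_rejected(self):
        tab = simulate_angle_table(
            {("wt", 0.01): 150.0, ("wt", 0.1): 100.0}, noise_sd=1.0,
            n_per_group=5,
        )
        with pytest.raises(ValidationError, match="mock"):
            minimum_effective_concentration(tab)
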