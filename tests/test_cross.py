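"""Cross phenotyping: size correction, class assignment, ANOVA, LRTs, chi-square."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stickleqtl import cross, simulate
from stickleqtl.errors import DegenerateInputError


def _fish_frame(y, length=None, sex=None, family=None):
    n = len(y)
    return pd.DataFrame(
        {
            "fish_id": [f"f{i}" for i in range(n)],
            "family": family if family is not None else ["fam_0"] * n,
            "sex": sex if sex is not None else ["M"] * n,
            "std_length_mm": length if length is not None else np.full(n, 30.0),
            "tooth_total": y,
        }
    )


class TestSizeCorrect:
    def test_no_association_leaves_phenotype_unchanged(self, rng):
        y = rng.normal(50, 3, 40)
        length = rng.normal(30, 2, 40)
        fish = _fish_frame(y, length=length)
        cp = cross.size_correct(fish)
        assert cp.covariates_used == []
        np.testing.assert_allclose(cp.corrected.values, y)

    def test_four_fish_closed_form_residuals(self):
        # exact linear length effect: y = 2 * length + offset
        length = np.array([20.0, 22.0, 24.0, 26.0])
        offsets = np.array([1.0, -1.0, 2.0, -2.0])
        y = 2.0 * length + offsets
        fish = _fish_frame(y, length=length)
        cp = cross.size_correct(fish, alpha=0.5)
        # independent normal-equations oracle
        lx = length - length.mean()
        slope = (lx * (y - y.mean())).sum() / (lx * lx).sum()
        resid = y - (y.mean() + slope * lx)
        np.testing.assert_allclose(cp.corrected.values, resid + y.mean(), atol=1e-9)
        assert cp.covariates_used == ["length"]

    @given(
        st.lists(st.floats(min_value=10, max_value=100), min_size=6, max_size=25),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_mean_preserved_by_back_transformation(self, ys, seed):
        rng = np.random.default_rng(seed)
        y = np.asarray(ys)
        n = len(y)
        fish = _fish_frame(
            y,
            length=rng.normal(30, 3, n),
            sex=rng.choice(["M", "F"], n),
            family=rng.choice(["a", "b"], n),
        )
        cp = cross.size_correct(fish, alpha=0.5)
        assert math.isclose(cp.corrected.mean(), y.mean(), abs_tol=1e-9)

    def test_constant_response_warns_and_passes_through(self):
        fish = _fish_frame(np.full(10, 42.0), length=np.arange(10, 20.0))
        cp = cross.size_correct(fish)
        assert cp.warnings and np.allclose(cp.corrected, 42.0)

    def test_single_sex_skipped_not_fatal(self, rng):
        y = rng.normal(50, 2, 20)
        fish = _fish_frame(y, sex=["F"] * 20)
        cp = cross.size_correct(fish)
        assert "sex" not in cp.covariates_used


class TestAssignGenotypeClass:
    SPEC = cross.RecombinantSpec("Stn488", "Stn489", frozenset({("M", "B")}))

    def _fish(self, left, right):
        return pd.DataFrame(
            {"fish_id": ["f0"], "Stn488": [left], "Stn489": [right]}
        )

    def test_recombinant_haplotype_scored_r(self):
        classes, excluded = cross.assign_genotype_class(self._fish("M/M", "B/M"), self.SPEC)
        assert classes["f0"] == "RM" and excluded.empty

    def test_double_marine_scored_mm(self):
        classes, _ = cross.assign_genotype_class(self._fish("M/M", "M/M"), self.SPEC)
        assert classes["f0"] == "MM"

    def test_punnett_enumeration_matches_cross_design(self):
        # cross 1 design: R/M parent x M/B parent -> {RM, RB, MM, MB}
        expected = cross.punnett_classes(["R", "M"], ["M", "B"])
        assert expected == {"RM", "RB", "MM", "MB"}
        hap_alleles = {"R": ("M", "B"), "M": ("M", "M"), "B": ("B", "B")}
        got = set()
        for h1 in ("R", "M"):
            for h2 in ("M", "B"):
                l1, r1 = hap_alleles[h1]
                l2, r2 = hap_alleles[h2]
                fish = self._fish(f"{l1}/{l2}", f"{r1}/{r2}")
                classes, excluded = cross.assign_genotype_class(fish, self.SPEC)
                assert excluded.empty
                got.add(classes["f0"])
        assert got == expected

    def test_off_design_genotype_excluded_with_reason(self):
        classes, excluded = cross.assign_genotype_class(self._fish("B/M", "M/M"), self.SPEC)
        assert classes.empty
        assert len(excluded) == 1 and "outside cross design" in excluded.reason.iloc[0]


class TestGenotypeAnova:
    def test_textbook_two_class_anova(self):
        y = pd.Series([10.0, 12.0, 20.0, 22.0], index=list("abcd"))
        cls = pd.Series(["MM", "MM", "BB", "BB"], index=list("abcd"))
        res = cross.genotype_anova(y, cls)
        assert abs(res.F - 50.0) < 1e-9
        # closed form for F(1, 2): p = 1 - sqrt(F / (F + 2))
        assert abs(res.p_value - (1.0 - math.sqrt(50.0 / 52.0))) < 1e-9
        assert res.df_between == 1 and res.df_within == 2
        assert res.class_means == {"MM": 11.0, "BB": 21.0}

    def test_single_class_is_degenerate(self):
        y = pd.Series([1.0, 2.0, 3.0])
        cls = pd.Series(["MM", "MM", "MM"])
        with pytest.raises(DegenerateInputError):
            cross.genotype_anova(y, cls)

    def test_small_class_excluded(self):
        y = pd.Series(np.arange(7, dtype=float))
        cls = pd.Series(["MM", "MM", "MB", "MB", "BB", "MM", "MB"])
        res = cross.genotype_anova(y, cls.where(cls != "BB", "BB"))
        assert "BB" not in res.class_means  # 1 fish only


def _direction_cross(r_like, n=150, d=2.0, sd=1.0, seed=0):
    base = {"MM": 50.0, "MB": 50.0 + d}
    if r_like == "B":
        means = {**base, "RM": 50.0 + d, "RB": 50.0 + 2 * d}
    else:
        means = {**base, "RM": 50.0, "RB": 50.0 + d}
    p = simulate.CrossSimParams(
        n_offspring=n, class_means=means, residual_sd=sd,
        length_slope=0.0, length_sd=0.0, seed=seed,
    )
    fish = simulate.simulate_cross(p)
    y = pd.Series(fish.tooth_total.values, index=fish.fish_id)
    cls = pd.Series(fish.genotype_class.values, index=fish.fish_id)
    return y, cls


class TestRecombinantDirectionLrt:
    def test_benthic_behaving_recombinant_called_benthic_like(self):
        y, cls = _direction_cross("B", seed=21)
        res = cross.recombinant_direction_lrt(y, cls, alpha=0.01)
        assert res.supported_direction == cross.BENTHIC_LIKE
        assert res.p_value < 0.01
        assert res.statistic >= 0

    def test_marine_behaving_recombinant_called_marine_like(self):
        y, cls = _direction_cross("M", seed=22)
        res = cross.recombinant_direction_lrt(y, cls, alpha=0.01)
        assert res.supported_direction == cross.MARINE_LIKE
        assert res.p_value < 0.01

    def test_full_model_likelihood_dominates_merges(self):
        y, cls = _direction_cross("B", seed=23)
        res = cross.recombinant_direction_lrt(y, cls)
        assert res.full_loglik >= res.model_A_loglik >= res.model_B_loglik

    def test_intermediate_recombinant_is_indeterminate(self):
        means = {"MM": 50.0, "MB": 54.0, "RM": 52.0, "RB": 56.0}
        p = simulate.CrossSimParams(n_offspring=400, class_means=means,
                                    residual_sd=1.0, length_slope=0.0,
                                    length_sd=0.0, seed=24)
        fish = simulate.simulate_cross(p)
        res = cross.recombinant_direction_lrt(
            pd.Series(fish.tooth_total.values, index=fish.fish_id),
            pd.Series(fish.genotype_class.values, index=fish.fish_id),
        )
        assert res.supported_direction == cross.INDETERMINATE

    def test_no_recombinant_class_is_degenerate(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        cls = pd.Series(["MM", "MM", "BB", "BB"])
        with pytest.raises(DegenerateInputError):
            cross.recombinant_direction_lrt(y, cls)


class TestBenthicChromosomeLrt:
    def test_indistinguishable_chromosomes_reported_na(self, rng):
        hap = pd.DataFrame(
            {"fish_id": [f"f{i}" for i in range(20)],
             "hap1": rng.choice(["M", "B"], 20),
             "hap2": rng.choice(["M", "B"], 20)}
        )
        y = pd.Series(rng.normal(50, 2, 20), index=hap.fish_id)
        out = cross.benthic_chromosome_lrt(y, hap)
        (res,) = out.values()
        assert not res.applicable and "distinguished" in res.reason

    def test_both_effects_detected(self, rng):
        n = 200
        h1 = rng.choice(["M", "B1"], n)
        h2 = rng.choice(["M", "B2"], n)
        y = 50 + 2.0 * (h1 == "B1") + 2.0 * (h2 == "B2") + rng.normal(0, 1, n)
        hap = pd.DataFrame({"fish_id": [f"f{i}" for i in range(n)], "hap1": h1, "hap2": h2})
        out = cross.benthic_chromosome_lrt(pd.Series(y, index=hap.fish_id), hap)
        assert out["B1"].p_value < 0.05 and out["B2"].p_value < 0.05
        assert out["B1"].df == 1


class TestMendelianRatio:
    @pytest.mark.parametrize(
        "observed,ratio,stat,p",
        [
            ((25, 50, 25), (1, 2, 1), 0.0, 1.0),
            # hand oracle: expected (8, 16, 8) -> 0.5 + 1 + 4.5 = 6, p = exp(-3)
            ((10, 20, 2), (1, 2, 1), 6.0, math.exp(-3.0)),
            # expected (50, 50) -> 2 + 2 = 4
            ((60, 40), (1, 1), 4.0, 0.045500263896358),
        ],
    )
    def test_chi_square_matches_hand_oracle(self, observed, ratio, stat, p):
        res = cross.mendelian_ratio_test(observed, ratio)
        assert abs(res.statistic - stat) < 1e-9
        assert abs(res.p_value - p) < 1e-9
        assert res.df == len(observed) - 1

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateInputError):
            cross.mendelian_ratio_test((0, 0), (1, 1))

    def test_arity_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            cross.mendelian_ratio_test((1, 2, 3), (1, 1))


def test_size_correct_anova_invariant_to_length_shift(rng):
    p = simulate.CrossSimParams(n_offspring=80, length_slope=1.5, seed=17)
    fish = simulate.simulate_cross(p)
    cls = pd.Series(fish.genotype_class.values, index=fish.fish_id)

    def run(frame):
        cp = cross.size_correct(frame)
        return cross.genotype_anova(cp.corrected, cls)

    a = run(fish)
    shifted = fish.copy()
    shifted["std_length_mm"] = shifted["std_length_mm"] + 100.0
    b = run(shifted)
    assert abs(a.F - b.F) < 1e-8 and abs(a.p_value - b.p_value) < 1e-8
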