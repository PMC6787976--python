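import numpy as np
import pytest
from scipy import stats

from lobarflow import (
    ReferenceStats,
    RmsdForm,
    Sex,
    bonferroni,
    gap_index,
    ks_normality,
    leave_one_out_references,
    leave_one_out_rmsd,
    percent_difference,
    reference_stats,
    rmsd,
    welch_t_test,
)
from lobarflow.published import Q_MEAN


HEALTHY_Q = np.array([Q_MEAN["healthy"][n] for n in ("RU", "RL", "LL", "LU")])


class TestReferenceStats:
    def test_degenerate_lobe_sd_rejected(self):
        values = [[0.25, 0.25, 0.25, 0.25], [0.35, 0.15, 0.25, 0.25]]
        with pytest.raises(ValueError, match="zero variance"):
            reference_stats(values)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            reference_stats([[0.2, 0.3, 0.3, 0.2]])

    def test_mean_and_sample_sd(self, rng):
        values = rng.normal(HEALTHY_Q, 0.05, size=(6, 4))
        ref = reference_stats(values, "Q")
        assert ref.mean == pytest.approx(values.mean(axis=0))
        assert ref.sd == pytest.approx(values.std(axis=0, ddof=1))
        assert ref.n_reference == 6

    def test_simulated_cohort_recovery(self, rng):
        # 13 subjects around the healthy flow profile: means recovered
        # within 3 standard errors
        sd = 0.05
        values = rng.normal(HEALTHY_Q, sd, size=(13, 4))
        ref = reference_stats(values, "Q")
        assert np.all(np.abs(ref.mean - HEALTHY_Q) < 3 * sd / np.sqrt(13))


class TestRmsd:
    def _ref(self, mean, sd):
        return ReferenceStats("Q", np.asarray(mean, float), np.asarray(sd, float), 13)

    def test_identity_scores_zero(self):
        ref = self._ref([0.2, 0.3, 0.3, 0.2], [0.05] * 4)
        assert rmsd([0.2, 0.3, 0.3, 0.2], ref) == 0.0

    def test_one_sd_everywhere_scores_one(self):
        ref = self._ref([0.2, 0.3, 0.3, 0.2], [0.04, 0.05, 0.06, 0.07])
        x = ref.mean + ref.sd
        assert rmsd(x, ref) == pytest.approx(1.0)

    def test_worked_example(self):
        # z = (1, 2, 3, 2) → mean 2.0
        ref = self._ref([1, 2, 3, 4], [1, 1, 1, 2])
        assert rmsd([2, 4, 6, 8], ref) == pytest.approx(2.0)

    def test_lobe_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd([1, 2, 3], self._ref([1, 2, 3, 4], [1, 1, 1, 1]))

    def test_literal_never_exceeds_quadratic(self, rng):
        ref = self._ref(HEALTHY_Q, [0.03, 0.04, 0.05, 0.06])
        for _ in range(200):
            x = rng.normal(HEALTHY_Q, 0.1)
            assert rmsd(x, ref, RmsdForm.LITERAL) <= rmsd(x, ref, RmsdForm.QUADRATIC) + 1e-12

    def test_affine_invariance(self, rng):
        # mapping X, reference mean and SD through x -> a x + b leaves the
        # standardized score unchanged
        ref = self._ref(HEALTHY_Q, [0.03, 0.04, 0.05, 0.06])
        x = rng.normal(HEALTHY_Q, 0.1)
        for a, b in ((2.5, 1.0), (0.2, -7.0)):
            mapped = ReferenceStats("Q", a * ref.mean + b, a * ref.sd, 13)
            assert rmsd(a * x + b, mapped) == pytest.approx(rmsd(x, ref))

    def test_zero_iff_equal_to_reference(self, rng):
        ref = self._ref(HEALTHY_Q, [0.05] * 4)
        x = HEALTHY_Q.copy()
        x[2] += 1e-6
        assert rmsd(x, ref) > 0


class TestLeaveOneOut:
    def _cohort(self, n_healthy=13, n_ipf=9, healthy_sd=0.04, seed=0):
        rng = np.random.default_rng(seed)
        ipf_mean = np.array([Q_MEAN["ipf"][n] for n in ("RU", "RL", "LL", "LU")])
        values = np.vstack(
            [
                rng.normal(HEALTHY_Q, healthy_sd, size=(n_healthy, 4)),
                rng.normal(ipf_mean, 0.08, size=(n_ipf, 4)),
            ]
        )
        ids = [f"H{i+1}" for i in range(n_healthy)] + [f"D{i+1}" for i in range(n_ipf)]
        return values, ids, ids[:n_healthy]

    def test_thirteen_references_of_twelve(self):
        values, ids, healthy = self._cohort()
        refs = leave_one_out_references(values, ids, healthy)
        assert len(refs) == 13
        assert [left_out for left_out, _ in refs] == healthy
        assert all(ref.n_reference == 12 for _, ref in refs)

    def test_identical_healthy_subjects_are_degenerate(self):
        # literally identical healthy subjects leave the reference SD at
        # zero, which makes the standardization undefined — flagged as an
        # error rather than silently returning loo_sd = 0
        values = np.vstack([np.tile(HEALTHY_Q, (5, 1)), [[0.4, 0.2, 0.2, 0.2]]])
        ids = [f"S{i}" for i in range(6)]
        with pytest.raises(ValueError, match="zero variance"):
            leave_one_out_rmsd(values, ids, ids[:5])

    def test_duplicated_healthy_profiles_give_near_zero_loo_sd(self):
        # two copies of each healthy profile: dropping any single subject
        # barely changes the reference, so the leave-one-out spread is a
        # small fraction of the score itself
        rng = np.random.default_rng(4)
        base = rng.normal(HEALTHY_Q, 0.05, size=(6, 4))
        values = np.vstack([base, base, [[0.45, 0.18, 0.17, 0.2]]])
        ids = [f"S{i}" for i in range(13)]
        scores = leave_one_out_rmsd(values, ids, ids[:12])
        for s in scores:
            assert s.loo_sd < 0.25 * max(s.loo_mean, 1e-9)

    def test_too_few_healthy_rejected(self):
        values, ids, _ = self._cohort(n_healthy=2, n_ipf=2)
        with pytest.raises(ValueError, match="at least 3"):
            leave_one_out_rmsd(values, ids, ids[:2])

    def test_ipf_scores_exceed_healthy_scores_on_average(self):
        values, ids, healthy = self._cohort(seed=11)
        scores = {s.subject_id: s for s in leave_one_out_rmsd(values, ids, healthy)}
        healthy_mean = np.mean([scores[i].value for i in ids[:13]])
        ipf_mean = np.mean([scores[i].value for i in ids[13:]])
        assert ipf_mean > 2 * healthy_mean


class TestSummaryTests:
    def test_welch_on_published_fvc_summary(self):
        # healthy 105±14 (n=13) vs IPF 85±16 (n=9): hand-computed Welch
        # statistic 3.03, two-sided p ≈ 0.008
        t, p = welch_t_test(105, 14, 13, 85, 16, 9)
        assert t == pytest.approx(3.032, abs=0.005)
        assert p == pytest.approx(0.0082, abs=0.001)
        # cross-check against scipy's summary-statistic Welch test
        res = stats.ttest_ind_from_stats(105, 14, 13, 85, 16, 9, equal_var=False)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_identical_groups(self):
        t, p = welch_t_test(10, 2, 8, 10, 2, 8)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_one_degenerate_group_still_finite(self):
        t, p = welch_t_test(10, 0, 8, 12, 3, 8)
        assert np.isfinite(t) and 0 < p < 1

    def test_both_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test(10, 0, 8, 12, 0, 8)

    @pytest.mark.parametrize("p,m,expected", [(0.01, 4, 0.04), (0.4, 8, 1.0), (0.2, 1, 0.2)])
    def test_bonferroni_examples(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_bonferroni_monotone_and_capped(self):
        grid = np.linspace(0, 1, 21)
        for m in (1, 2, 5, 20):
            adjusted = [bonferroni(p, m) for p in grid]
            assert all(a <= b + 1e-15 for a, b in zip(adjusted, adjusted[1:]))
            assert max(adjusted) <= 1.0

    def test_ks_normal_null_mostly_accepts(self):
        rng = np.random.default_rng(42)
        rejections = sum(ks_normality(rng.normal(size=10_000)) < 0.01 for _ in range(40))
        assert rejections <= 2  # ≥95% of seeded repeats above 0.01

    def test_ks_gross_alternative_rejected(self):
        rng = np.random.default_rng(42)
        assert ks_normality(rng.exponential(size=10_000)) < 0.01

    def test_ks_constant_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0] * 10)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref,other,direction,expected",
        [
            (-739, -596, "higher", 19),  # whole-lung HU mean, expanded
            (-578, -382, "higher", 34),  # whole-lung HU mean, contracted
            (2.33, 1.18, "lower", 49),  # skewness, expanded
            (1.49, 0.56, "lower", 62),  # skewness, contracted
            (8.93, 3.54, "lower", 60),  # kurtosis, expanded
            (5.10, 3.05, "lower", 40),  # kurtosis, contracted
            (30, 20, "lower", 33),  # lobar flow, right lower lobe
            (27, 21, "lower", 22),  # lobar flow, left lower lobe
            (10, 10, None, 0),
        ],
    )
    def test_published_group_mean_derivations(self, ref, other, direction, expected):
        assert percent_difference(ref, other, direction) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0, 5)

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            percent_difference(30, 20, "higher")


class TestGapIndex:
    def test_all_lowest_buckets(self):
        score = gap_index(Sex.FEMALE, 58, 80, 60)
        assert (score.G, score.A, score.P_FVC, score.P_DLCO, score.total) == (0, 0, 0, 0, 0)

    def test_mixed_buckets(self):
        score = gap_index("male", 71, 85, 48)
        assert (score.G, score.A, score.P_FVC, score.P_DLCO, score.total) == (1, 2, 0, 1, 4)

    def test_missing_dlco_branch(self):
        score = gap_index("male", 63, 40, None)
        assert (score.G, score.A, score.P_FVC, score.P_DLCO, score.total) == (1, 1, 2, 3, 7)

    def test_maximum_total(self):
        assert gap_index("male", 80, 40, None).total == 8

    @pytest.mark.parametrize(
        "age,expected", [(60, 0), (60.5, 1), (61, 1), (65, 1), (65.5, 2), (66, 2)]
    )
    def test_age_boundaries(self, age, expected):
        assert gap_index("female", age, 100, 80).A == expected

    @pytest.mark.parametrize("fvc,expected", [(76, 0), (75, 1), (50, 1), (49.9, 2)])
    def test_fvc_boundaries(self, fvc, expected):
        assert gap_index("female", 50, fvc, 80).P_FVC == expected

    @pytest.mark.parametrize("dlco,expected", [(56, 0), (55, 1), (36, 1), (35, 2), (35.9, 2)])
    def test_dlco_boundaries(self, dlco, expected):
        assert gap_index("female", 50, 100, dlco).P_DLCO == expected

    def test_totals_bounded(self, rng):
        for _ in range(200):
            dlco = None if rng.random() < 0.2 else float(rng.uniform(10, 120))
            score = gap_index(
                "male" if rng.random() < 0.5 else "female",
                float(rng.uniform(30, 90)),
                float(rng.uniform(20, 140)),
                dlco,
            )
            assert 0 <= score.total <= 8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gap_index("female", -1, 80, 60)
        with pytest.raises(ValueError):
            gap_index("female", 50, 80, -3)
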