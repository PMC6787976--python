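import numpy as np
import pytest

from lobarflow import (
    CohortSpec,
    LOBE_NAMES,
    PhantomSpec,
    QuantitySpec,
    calibrate_q_dispersions,
    generate_phantom_pair,
    generate_tabular_cohort,
    leave_one_out_rmsd,
    reference_stats,
    rmsd,
    sample_hu_mixture,
)
from lobarflow.published import Q_MEAN, RMSD_Q_SUMMARY

from conftest import small_spec


class TestHuMixture:
    def test_degenerate_component_constant(self):
        draws = sample_hu_mixture(100, [1.0], [-800.0], [0.0], rng=0)
        assert np.all(draws == -800.0)

    def test_component_mass_binomial_bound(self):
        n = 100_000
        draws = sample_hu_mixture(n, [0.8, 0.2], [-950, 0], [40, 60], rng=1)
        frac_air = np.mean(draws < -700)
        assert frac_air == pytest.approx(0.8, abs=3 * np.sqrt(0.8 * 0.2 / n))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            sample_hu_mixture(10, [0.5, 0.4], [-950, 0], [40, 60], rng=0)

    def test_clip_respected(self):
        draws = sample_hu_mixture(10_000, [1.0], [-1100.0], [100.0], rng=2)
        assert draws.min() >= -1024.0

    def test_fibrosis_raises_mean_and_lowers_skewness(self):
        # adding a -400 HU component shifts density up and deflates the
        # air-peak asymmetry, averaged over seeds
        from lobarflow import skewness

        deltas_mean, deltas_skew = [], []
        for seed in range(20):
            clean = sample_hu_mixture(20_000, [0.8, 0.2], [-950, 0], [40, 60], rng=seed)
            fib = sample_hu_mixture(
                20_000, [0.5, 0.2, 0.3], [-950, 0, -400], [40, 60, 150], rng=1000 + seed
            )
            deltas_mean.append(fib.mean() - clean.mean())
            deltas_skew.append(skewness(fib) - skewness(clean))
        assert np.mean(deltas_mean) > 0
        assert np.mean(deltas_skew) < 0


class TestPhantomPair:
    def test_equal_lobes_uniform_flow(self):
        spec = small_spec(
            expanded_volumes_l={n: 0.2 for n in LOBE_NAMES},
            contracted_volumes_l={n: 0.1 for n in LOBE_NAMES},
        )
        _, _, truth = generate_phantom_pair(spec)
        assert list(truth.Q.values()) == pytest.approx([0.25] * 4)

    def test_determinism(self):
        spec = small_spec(seed=9)
        (e1, l1), (c1, m1), t1 = generate_phantom_pair(spec)
        (e2, l2), (c2, m2), t2 = generate_phantom_pair(spec)
        assert np.array_equal(e1.voxels, e2.voxels)
        assert np.array_equal(c1.voxels, c2.voxels)
        assert np.array_equal(l1.labels, l2.labels)
        assert t1.Q == t2.Q

    def test_seed_changes_voxels_not_geometry(self):
        (e1, l1), _, _ = generate_phantom_pair(small_spec(seed=1))
        (e2, l2), _, _ = generate_phantom_pair(small_spec(seed=2))
        assert np.array_equal(l1.labels, l2.labels)
        assert not np.array_equal(e1.voxels, e2.voxels)

    def test_volume_targets_hit_within_half_voxel(self):
        spec = small_spec(seed=4)
        _, _, truth = generate_phantom_pair(spec)
        vox_l = float(np.prod(spec.spacing)) * 1e-6
        for state, targets in (
            ("expanded", spec.expanded_volumes_l),
            ("contracted", spec.contracted_volumes_l),
        ):
            for lobe in LOBE_NAMES:
                assert abs(truth.volumes_l[state][lobe] - targets[lobe]) <= 0.5 * vox_l

    def test_contracted_lobe_is_subset_of_expanded(self, small_phantom):
        (_, e_labels), (_, c_labels), _ = small_phantom
        for lobe in LOBE_NAMES:
            assert np.all(e_labels.mask(lobe)[c_labels.mask(lobe)])

    def test_air_conservation_under_one_percent(self, default_phantom):
        # full-size lobes: sampling noise on the lobe-mean HU is well below
        # the 1% bookkeeping tolerance
        (ev, el), (cv, cl), truth = default_phantom
        for lobe in LOBE_NAMES:
            content_e = (1000 + ev.voxels[el.mask(lobe)].mean()) * truth.volumes_l["expanded"][lobe]
            content_c = (1000 + cv.voxels[cl.mask(lobe)].mean()) * truth.volumes_l["contracted"][lobe]
            assert abs(content_e - content_c) / content_e < 0.01

    def test_unpackable_lobe_rejected(self):
        spec = small_spec()
        big = dict(spec.expanded_volumes_l, RU=10.0)
        with pytest.raises(ValueError, match="fit"):
            generate_phantom_pair(
                small_spec(expanded_volumes_l=big, contracted_volumes_l=dict(spec.contracted_volumes_l, RU=10.0))
            )

    def test_contracted_larger_than_expanded_rejected(self):
        spec = small_spec()
        with pytest.raises(ValueError, match="contracted"):
            small_spec(
                contracted_volumes_l=dict(spec.contracted_volumes_l, RU=spec.expanded_volumes_l["RU"] + 0.01)
            )


class TestDispersionCalibration:
    def test_deterministic(self):
        assert calibrate_q_dispersions() == calibrate_q_dispersions()

    def test_within_physical_bounds(self):
        sh, sd = calibrate_q_dispersions()
        assert 0.005 <= sh <= 0.12
        assert 0.01 <= sd <= 0.12

    def test_reproduces_ipf_score_mean(self):
        # cohorts drawn from the generator at the calibrated dispersions
        # reproduce the published IPF flow-score mean
        quantities = {"Q": CohortSpec().quantities["Q"]}
        means = []
        for seed in range(100):
            table = generate_tabular_cohort(
                CohortSpec(quantities=quantities, hu_summaries=False, seed=seed)
            )
            values = table[[f"Q_{n}" for n in LOBE_NAMES]].to_numpy()
            healthy = values[(table.group == "healthy").to_numpy()]
            ipf = values[(table.group == "ipf").to_numpy()]
            ref = reference_stats(healthy)
            means.append(np.mean([rmsd(x, ref) for x in ipf]))
        target_mean, _ = RMSD_Q_SUMMARY["ipf"]
        assert np.mean(means) == pytest.approx(target_mean, rel=0.05)


class TestTabularCohort:
    def test_zero_sd_healthy_exactly_at_mean(self):
        quantities = {
            "Q": QuantitySpec(
                means={g: dict(Q_MEAN[g]) for g in ("healthy", "ipf")},
                sds={"healthy": 0.0, "ipf": 0.05},
            )
        }
        table = generate_tabular_cohort(
            CohortSpec(n_healthy=4, n_ipf=2, quantities=quantities, hu_summaries=False, seed=1)
        )
        healthy = table[table.group == "healthy"]
        for lobe in LOBE_NAMES:
            assert np.allclose(healthy[f"Q_{lobe}"], Q_MEAN["healthy"][lobe])

    def test_determinism(self):
        a = generate_tabular_cohort(CohortSpec(seed=6))
        b = generate_tabular_cohort(CohortSpec(seed=6))
        assert a.equals(b)

    def test_rows_sum_to_one(self):
        table = generate_tabular_cohort(CohortSpec(seed=2))
        for prefix in ("Q", "V_expanded", "V_contracted"):
            sums = table[[f"{prefix}_{lobe}" for lobe in LOBE_NAMES]].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_healthy_flow_means_recovered(self):
        # generator parameter recovery across seeds, within 3 standard errors
        tables = [generate_tabular_cohort(CohortSpec(seed=s)) for s in range(60)]
        healthy = np.array(
            [
                t.loc[t.group == "healthy", [f"Q_{lobe}" for lobe in LOBE_NAMES]].to_numpy()
                for t in tables
            ]
        )  # (seeds, 13, 4)
        grand_mean = healthy.mean(axis=(0, 1))
        se = healthy.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(len(tables))
        target = np.array([Q_MEAN["healthy"][n] for n in LOBE_NAMES])
        assert np.all(np.abs(grand_mean - target) < 3 * se + 0.005)

    def test_ipf_ru_flow_dominates(self):
        # the fibrotic group's flow redistributes toward the right upper
        # lobe in nearly every simulated cohort
        wins = 0
        seeds = 40
        for s in range(seeds):
            t = generate_tabular_cohort(CohortSpec(seed=s))
            ipf = t[t.group == "ipf"]
            means = [ipf[f"Q_{lobe}"].mean() for lobe in LOBE_NAMES]
            wins += means[0] == max(means)
        assert wins / seeds >= 0.95

    def test_infeasible_truncation_rejected(self):
        quantities = {
            "X": QuantitySpec(
                means={"healthy": {n: 50.0 for n in LOBE_NAMES}, "ipf": {n: 50.0 for n in LOBE_NAMES}},
                sds={"healthy": 0.1, "ipf": 0.1},
                renormalize=False,
            )
        }
        with pytest.raises(ValueError, match="infeasible"):
            generate_tabular_cohort(CohortSpec(n_healthy=3, n_ipf=3, quantities=quantities, hu_summaries=False))

    def test_zero_sd_cohort_has_zero_flow_scores(self):
        quantities = {
            "Q": QuantitySpec(
                means={g: dict(Q_MEAN[g]) for g in ("healthy", "ipf")},
                sds={"healthy": 0.0, "ipf": 0.0},
            )
        }
        table = generate_tabular_cohort(
            CohortSpec(n_healthy=5, n_ipf=3, quantities=quantities, hu_summaries=False, seed=0)
        )
        values = table[[f"Q_{lobe}" for lobe in LOBE_NAMES]].to_numpy()
        ids = table.subject_id.tolist()
        healthy_ids = table.loc[table.group == "healthy", "subject_id"].tolist()
        with pytest.raises(ValueError, match="zero variance"):
            leave_one_out_rmsd(values, ids, healthy_ids)
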