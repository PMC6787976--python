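"""Reproducibility studies: end-to-end checks of the pipeline against
known ground truth and the published cohort summaries.

These routines are used by the test suite and by ``scripts/acceptance.py``
to recompute, from scratch, the quantities the package exists to produce:
the derived percent-difference claims, phantom-recovery accuracy, the
threshold-robustness check, and the behaviour of the lobar-flow
discriminant score on simulated cohorts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import published
from .cohort import leave_one_out_rmsd, percent_difference
from .io import LOBE_NAMES
from .mechanics import lobar_flow, lobe_volumes
from .segmentation import SegmentationConfig, upper_bound_sensitivity
from .synthetic import CohortSpec, PhantomSpec, default_quantities, generate_phantom_pair, generate_tabular_cohort

__all__ = [
    "derived_percent_differences",
    "phantom_recovery_study",
    "cohort_separation_study",
    "loo_structure_check",
]


def derived_percent_differences() -> dict[str, int]:
    """Percent differences between the published fibrotic and healthy group
    means, recomputed from the published summary tables.

    HU statistics are compared between groups per breath-hold state; lobar
    flow is compared for the two lower lobes, where fibrotic redistribution
    away from the lung bases is strongest.
    """
    hu = published.HU_SUMMARY
    q = published.Q_MEAN
    out = {}
    for state in ("expanded", "contracted"):
        mean_h, _, mean_d, _ = hu[state]["mean"]
        skew_h, _, skew_d, _ = hu[state]["skewness"]
        kurt_h, _, kurt_d, _ = hu[state]["kurtosis"]
        out[f"hu_mean_pct_higher_{state}"] = percent_difference(mean_h, mean_d, "higher")
        out[f"skewness_pct_lower_{state}"] = percent_difference(skew_h, skew_d, "lower")
        out[f"kurtosis_pct_lower_{state}"] = percent_difference(kurt_h, kurt_d, "lower")
    out["flow_rl_pct_lower"] = percent_difference(q["healthy"]["RL"], q["ipf"]["RL"], "lower")
    out["flow_ll_pct_lower"] = percent_difference(q["healthy"]["LL"], q["ipf"]["LL"], "lower")
    return out


def _jittered_spec(base: PhantomSpec, seed: int, rng: np.random.Generator) -> PhantomSpec:
    """Anatomical variation for a recovery-study phantom: per-lobe expanded
    volumes scaled ±5%, contracted volumes kept at the base emptying
    fraction per lobe."""
    factors = np.exp(rng.normal(0.0, 0.05, 4))
    ve = {lobe: base.expanded_volumes_l[lobe] * f for lobe, f in zip(LOBE_NAMES, factors)}
    vc = {
        lobe: ve[lobe] * (base.contracted_volumes_l[lobe] / base.expanded_volumes_l[lobe])
        for lobe in LOBE_NAMES
    }
    return dataclasses.replace(
        base, expanded_volumes_l=ve, contracted_volumes_l=vc, seed=seed
    )


def phantom_recovery_study(n_phantoms: int = 10, seed: int = 0) -> dict:
    """Generate seeded full-size phantom pairs and re-measure them.

    For each phantom the pipeline's lobe volumes are compared with the
    generator's litre targets (worst error reported in voxel volumes), the
    recovered lobar flow with the target flow (worst error, against the
    propagated voxel-rounding bound), and the threshold segmentation is
    swept over the conventional −700…−300 HU upper-bound range on the
    expanded volume.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec.healthy()
    cfg = SegmentationConfig(keep_components=4, min_component_voxels=1000)
    max_vol_err_vox = 0.0
    max_q_err = 0.0
    max_sweep = 0.0
    q_bound = 0.0
    for k in range(n_phantoms):
        spec = _jittered_spec(base, seed=int(rng.integers(0, 2**31 - 1)), rng=rng)
        (expanded, e_labels), (contracted, c_labels), truth = generate_phantom_pair(spec)
        vox_l = expanded.voxel_volume_mm3 * 1e-6
        ve = lobe_volumes(expanded, e_labels)
        vc = lobe_volumes(contracted, c_labels)
        dv_target = sum(spec.expanded_volumes_l.values()) - sum(spec.contracted_volumes_l.values())
        q_targets = {
            lobe: (spec.expanded_volumes_l[lobe] - spec.contracted_volumes_l[lobe]) / dv_target
            for lobe in LOBE_NAMES
        }
        q_measured = lobar_flow(ve, vc)
        for lobe in LOBE_NAMES:
            for measured, target in (
                (ve.volumes[lobe], spec.expanded_volumes_l[lobe]),
                (vc.volumes[lobe], spec.contracted_volumes_l[lobe]),
            ):
                max_vol_err_vox = max(max_vol_err_vox, abs(measured - target) / vox_l)
            max_q_err = max(max_q_err, abs(q_measured[lobe] - q_targets[lobe]))
        # voxel-rounding propagation: each lobe's volume difference is off
        # by ≤1 voxel, the total by ≤4
        q_bound = max(q_bound, (1 + 4 * max(q_targets.values())) * vox_l / dv_target)
        sweep = upper_bound_sensitivity(expanded, cfg)
        max_sweep = max(max_sweep, sweep["max_relative_change"])
    return {
        "n_phantoms": n_phantoms,
        "max_lobe_volume_error_voxels": max_vol_err_vox,
        "max_flow_error": max_q_err,
        "flow_error_bound": q_bound,
        "max_sweep_relative_change": max_sweep,
    }


def cohort_separation_study(n_replicates: int = 100, seed: int = 0) -> dict:
    """Discriminant-score behaviour on simulated cohorts at the published
    group structure.

    Each replicate draws a 13-healthy / 9-fibrotic cohort at the published
    flow profiles (dispersions calibrated to the published fibrotic score
    summary), scores every subject against the cohort's own healthy
    reference, and records whether the two groups' score ranges separate
    (largest healthy score below the smallest fibrotic score).
    """
    quantities = default_quantities()  # calibrate once
    rng = np.random.default_rng(seed)
    separations = 0
    healthy_means, healthy_sds, ipf_means, ipf_sds = [], [], [], []
    for _ in range(n_replicates):
        spec = CohortSpec(
            quantities=quantities, hu_summaries=False, seed=int(rng.integers(0, 2**31 - 1))
        )
        table = generate_tabular_cohort(spec)
        values = table[[f"Q_{lobe}" for lobe in LOBE_NAMES]].to_numpy()
        ids = table.subject_id.tolist()
        healthy_ids = table.loc[table.group == "healthy", "subject_id"].tolist()
        scores = {s.subject_id: s.value for s in leave_one_out_rmsd(values, ids, healthy_ids)}
        healthy = np.array([scores[i] for i in healthy_ids])
        ipf = np.array([scores[i] for i in ids if i not in set(healthy_ids)])
        separations += healthy.max() < ipf.min()
        healthy_means.append(healthy.mean())
        healthy_sds.append(healthy.std(ddof=1))
        ipf_means.append(ipf.mean())
        ipf_sds.append(ipf.std(ddof=1))
    return {
        "n_replicates": n_replicates,
        "separation_rate": float(separations / n_replicates),
        "healthy_rmsd_mean": float(np.mean(healthy_means)),
        "healthy_rmsd_sd": float(np.mean(healthy_sds)),
        "ipf_rmsd_mean": float(np.mean(ipf_means)),
        "ipf_rmsd_sd": float(np.mean(ipf_sds)),
    }


def loo_structure_check(seed: int = 0) -> dict:
    """Structural facts of the leave-one-out procedure on a default cohort:
    the number of references built and the subjects per reference."""
    from .cohort import leave_one_out_references

    table = generate_tabular_cohort(CohortSpec(seed=seed, hu_summaries=False))
    values = table[[f"Q_{lobe}" for lobe in LOBE_NAMES]].to_numpy()
    ids = table.subject_id.tolist()
    healthy_ids = table.loc[table.group == "healthy", "subject_id"].tolist()
    refs = leave_one_out_references(values, ids, healthy_ids)
    sizes = {ref.n_reference for _, ref in refs}
    return {
        "n_references": len(refs),
        "reference_sizes": sorted(sizes),
        "left_out_ids_distinct": len({lo for lo, _ in refs}) == len(refs),
    }
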