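"""End-to-end orchestration: segment → summarize → mechanics → cohort stats.

:func:`run_pipeline` drives the full analysis from a subject manifest (or
from simulated phantom subjects) and writes four CSV tables plus a
run-metadata JSON into the output directory:

* ``profiles.csv`` — per subject × lobe: absolute volumes, volume
  fractions, lobar flow Q and strain S;
* ``histograms.csv`` — per subject × state × region: HU histogram
  statistics;
* ``rmsd.csv`` — per subject × quantity: healthy-reference discriminant
  scores with leave-one-out mean/SD;
* ``comparisons.csv`` — per variable: healthy-vs-IPF group comparison
  with Bonferroni-corrected p-values.

All randomness (simulated subjects only) flows from the single config
seed, so a rerun with the same config is byte-identical apart from file
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GroupComparison, RmsdForm, compare_groups, leave_one_out_rmsd
from .histogram import summarize_lobes, summarize_region
from .io import Group, LOBE_NAMES, LungState, Sex, SubjectRecord, read_manifest
from .mechanics import build_profile
from .segmentation import SegmentationConfig
from .synthetic import PhantomSpec, generate_phantom_pair

logger = logging.getLogger("lobarflow")

__all__ = ["RunConfig", "run_pipeline", "render_tables", "simulate_subjects"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str | None = None
    output_dir: str = "lobarflow-out"
    seed: int = 0
    simulate_healthy: int = 0
    simulate_ipf: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bin_width: float = 1.0
    rmsd_form: RmsdForm = RmsdForm.LITERAL
    t_test_variant: str = "welch"
    bonferroni_family: int | None = None
    log_level: str = "INFO"

    @property
    def simulated(self) -> bool:
        return self.manifest is None


def simulate_subjects(n_healthy: int, n_ipf: int, seed: int, grid_shape=(96, 96, 96), spacing=(2.5, 2.5, 2.5)) -> list[SubjectRecord]:
    """Phantom subjects with per-subject anatomical variation.

    Whole-lung size gets ±10% lognormal variation and the per-lobe flow
    split is jittered (clipped away from paradoxical values so the
    contracted lobe stays smaller than the expanded one); demographics are
    drawn near the published group profiles.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for group, n, prefix in ((Group.HEALTHY, n_healthy, "H"), (Group.IPF, n_ipf, "D")):
        base = PhantomSpec.healthy() if group is Group.HEALTHY else PhantomSpec.ipf()
        base = dataclasses.replace(base, grid_shape=tuple(grid_shape), spacing=tuple(spacing))
        for k in range(n):
            scale = float(np.exp(rng.normal(0.0, 0.1)))
            ve = {lob: v * scale for lob, v in base.expanded_volumes_l.items()}
            dv_total = (sum(ve.values())) * (1 - sum(base.contracted_volumes_l.values()) / sum(base.expanded_volumes_l.values()))
            q = np.array([ve[lob] - base.contracted_volumes_l[lob] * scale for lob in LOBE_NAMES])
            q = q / q.sum() + rng.normal(0, 0.03, 4)
            q = np.clip(q, 0.05, 0.6)
            q /= q.sum()
            # floor keeps the contracted lobe physically positive even for
            # extreme flow draws
            vc = {lob: max(ve[lob] - qi * dv_total, 0.02 * ve[lob]) for lob, qi in zip(LOBE_NAMES, q)}
            spec = dataclasses.replace(
                base,
                expanded_volumes_l=ve,
                contracted_volumes_l=vc,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sid = f"{prefix}{k + 1}"
            expanded, contracted, _ = generate_phantom_pair(spec, subject_id=sid)
            age = float(np.clip(rng.normal(61 if group is Group.HEALTHY else 71, 10), 30, 95))
            fvc = float(np.clip(rng.normal(105 if group is Group.HEALTHY else 85, 15), 20, 160))
            dlco = float(np.clip(rng.normal(83 if group is Group.HEALTHY else 48, 14), 10, 140))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                    age=age,
                    fvc_pct=fvc,
                    dlco_pct=dlco,
                    expanded=expanded,
                    contracted=contracted,
                )
            )
    return subjects


def _histogram_rows(subject: SubjectRecord, bin_width: float) -> list[dict]:
    rows = []
    for state in (LungState.EXPANDED, LungState.CONTRACTED):
        volume, labels = getattr(subject, state.value)
        regions = {"lung": summarize_region(volume, labels.lung_mask(), bin_width)}
        regions.update(summarize_lobes(volume, labels, bin_width))
        for region, s in regions.items():
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group.value,
                    "state": state.value,
                    "region": region,
                    "n_voxels": s.n_voxels,
                    "mean": s.mean,
                    "median": s.median,
                    "sigma": s.sigma,
                    "skewness": s.skewness,
                    "kurtosis": s.kurtosis,
                }
            )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the result tables as DataFrames.

    Writes ``profiles.csv``, ``histograms.csv``, ``rmsd.csv``,
    ``comparisons.csv`` and ``run_metadata.json`` into
    ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulated:
        if config.simulate_healthy + config.simulate_ipf < 2:
            raise ValueError("simulation requires at least 2 subjects in total")
        logger.info("simulating %d healthy + %d IPF phantom subjects", config.simulate_healthy, config.simulate_ipf)
        subjects = simulate_subjects(config.simulate_healthy, config.simulate_ipf, config.seed)
    else:
        logger.info("reading manifest %s", config.manifest)
        subjects = read_manifest(config.manifest)

    logger.info("stage mechanics: lobar profiles")
    profiles = {s.subject_id: build_profile(s) for s in subjects}
    profile_rows = []
    for s in subjects:
        p = profiles[s.subject_id]
        for lobe in LOBE_NAMES:
            profile_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group.value,
                    "lobe": lobe,
                    "v_e_L": p.v_expanded.volumes[lobe],
                    "v_c_L": p.v_contracted.volumes[lobe],
                    "V_exp": p.V_expanded[lobe],
                    "V_con": p.V_contracted[lobe],
                    "Q": p.Q[lobe],
                    "S": p.S[lobe],
                }
            )
    profiles_df = pd.DataFrame(profile_rows)

    logger.info("stage histograms: HU summaries")
    histograms_df = pd.DataFrame(
        [row for s in subjects for row in _histogram_rows(s, config.bin_width)]
    )

    logger.info("stage cohort: discriminant scores")
    healthy_ids = [s.subject_id for s in subjects if s.group is Group.HEALTHY]
    subject_ids = [s.subject_id for s in subjects]
    group_of = {s.subject_id: s.group.value for s in subjects}
    rmsd_rows = []
    if len(healthy_ids) >= 3:
        for quantity, getter in (
            ("Q", lambda p: [p.Q[lob] for lob in LOBE_NAMES]),
            ("V_expanded", lambda p: [p.V_expanded[lob] for lob in LOBE_NAMES]),
            ("V_contracted", lambda p: [p.V_contracted[lob] for lob in LOBE_NAMES]),
            ("S", lambda p: [p.S[lob] for lob in LOBE_NAMES]),
        ):
            values = [getter(profiles[sid]) for sid in subject_ids]
            for score in leave_one_out_rmsd(values, subject_ids, healthy_ids, quantity, config.rmsd_form):
                rmsd_rows.append(
                    {
                        "subject_id": score.subject_id,
                        "group": group_of[score.subject_id],
                        "quantity": quantity,
                        "rmsd": score.value,
                        "loo_mean": score.loo_mean,
                        "loo_sd": score.loo_sd,
                    }
                )
    else:
        logger.warning("fewer than 3 healthy subjects: skipping discriminant scores")
    rmsd_df = pd.DataFrame(rmsd_rows)

    logger.info("stage cohort: group comparisons")
    per_subject = profiles_df.pivot_table(
        index=["subject_id", "group"], columns="lobe", values="Q"
    ).reset_index()
    per_subject = per_subject.rename(columns={lob: f"Q_{lob}" for lob in LOBE_NAMES})
    volumes = profiles_df.groupby(["subject_id", "group"], as_index=False).agg(
        v_e_L=("v_e_L", "sum"), v_c_L=("v_c_L", "sum")
    )
    per_subject = per_subject.merge(volumes, on=["subject_id", "group"])
    per_subject["dv_L"] = per_subject["v_e_L"] - per_subject["v_c_L"]
    comparison_vars = [f"Q_{lob}" for lob in LOBE_NAMES] + ["v_e_L", "v_c_L", "dv_L"]
    comparisons: list[GroupComparison] = []
    counts = per_subject.groupby("group")["subject_id"].count()
    if counts.get("healthy", 0) >= 2 and counts.get("ipf", 0) >= 2:
        comparisons = compare_groups(
            per_subject,
            comparison_vars,
            family_size=config.bonferroni_family,
            variant=config.t_test_variant,
        )
    comparisons_df = pd.DataFrame([dataclasses.asdict(c) for c in comparisons])

    results = {
        "profiles": profiles_df,
        "histograms": histograms_df,
        "rmsd": rmsd_df,
        "comparisons": comparisons_df,
    }
    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)
    metadata = {
        "lobarflow_version": __version__,
        "seed": config.seed,
        "config": {
            "manifest": config.manifest,
            "simulate_healthy": config.simulate_healthy,
            "simulate_ipf": config.simulate_ipf,
            "segmentation": dataclasses.asdict(config.segmentation),
            "bin_width": config.bin_width,
            "rmsd_form": RmsdForm(config.rmsd_form).value,
            "t_test_variant": config.t_test_variant,
            "bonferroni_family": config.bonferroni_family,
        },
        "n_subjects": len(subjects),
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    logger.info("wrote results to %s", out)
    return results


def render_tables(comparisons: list[GroupComparison], group_a: str = "Healthy", group_b: str = "IPF") -> str:
    """Plain-text comparison table in the conventional 'mean (SD)' layout.

    One row per variable with each group's mean (SD) and the corrected
    p-value; a missing p-value (degenerate comparison) renders as N/A.
    """
    header = f"{'Variable':<24}{group_a:>18}{group_b:>18}{'p-value':>12}"
    lines = [header, "-" * len(header)]
    for c in comparisons:
        cell_a = f"{c.mean_a:.3g} ({c.sd_a:.3g})"
        cell_b = f"{c.mean_b:.3g} ({c.sd_b:.3g})"
        if c.p_bonferroni is None or not np.isfinite(c.p_bonferroni):
            p_cell = "N/A"
        elif c.p_bonferroni < 0.001:
            p_cell = "< 0.001"
        else:
            p_cell = f"{c.p_bonferroni:.3f}"
        lines.append(f"{c.variable:<24}{cell_a:>18}{cell_b:>18}{p_cell:>12}")
    return "\n".join(lines)
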