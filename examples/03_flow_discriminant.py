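"""The lobar-flow discriminant score on a simulated cohort.

Simulates a 13-healthy / 9-fibrotic tabular cohort at the published
group-mean flow profiles, scores every subject against the healthy
reference (mean absolute standardized per-lobe deviation) with
leave-one-out validation, and prints the group summaries. Fibrotic
subjects redistribute flow toward the right upper lobe, which pushes
their scores far above the healthy group's.
"""

import numpy as np

from lobarflow import CohortSpec, LOBE_NAMES, generate_tabular_cohort, leave_one_out_rmsd

table = generate_tabular_cohort(CohortSpec(seed=42))
values = table[[f"Q_{lobe}" for lobe in LOBE_NAMES]].to_numpy()
ids = table.subject_id.tolist()
healthy_ids = table.loc[table.group == "healthy", "subject_id"].tolist()

scores = leave_one_out_rmsd(values, ids, healthy_ids, quantity_name="Q")
by_id = {s.subject_id: s for s in scores}
for group in ("healthy", "ipf"):
    members = table.loc[table.group == group, "subject_id"]
    vals = np.array([by_id[i].value for i in members])
    loo_sds = np.array([by_id[i].loo_sd for i in members])
    print(
        f"{group:>8}: flow score {vals.mean():.2f} ± {vals.std(ddof=1):.2f} "
        f"(range {vals.min():.2f}–{vals.max():.2f}; mean leave-one-out SD {loo_sds.mean():.3f})"
    )
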