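"""Published cohort summary statistics used as reference inputs.

The study cohort behind these numbers (13 healthy subjects, 9 with
idiopathic pulmonary fibrosis, paired inspiration/expiration HRCT) did not
release per-subject images, so downstream code works from the printed group
summaries: they calibrate the synthetic-cohort generator, seed the worked
examples, and are the inputs from which the derived percent-difference
claims are recomputed.

All values are group means with the group SD where printed. HU statistics
are whole-lung; Q and V profiles are per lobe in canonical order
(RU, RL, LL, LU).
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = [
    "N_HEALTHY",
    "N_IPF",
    "HU_SUMMARY",
    "Q_MEAN",
    "RMSD_Q_SUMMARY",
    "LUNG_VOLUMES_L",
    "PFT_SUMMARY",
]

N_HEALTHY = 13
N_IPF = 9

#: Whole-lung HU histogram statistics: (healthy mean, healthy SD, IPF mean, IPF SD)
#: per state and variable.
HU_SUMMARY = MappingProxyType(
    {
        "expanded": MappingProxyType(
            {
                "mean": (-739.0, 100.0, -596.0, 69.0),
                "median": (-869.0, 48.0, -750.0, 64.0),
                "kurtosis": (8.93, 5.74, 3.54, 1.12),
                "skewness": (2.33, 0.97, 1.18, 0.34),
            }
        ),
        "contracted": MappingProxyType(
            {
                "mean": (-578.0, 60.0, -382.0, 133.0),
                "median": (-690.0, 55.0, -429.0, 184.0),
                "kurtosis": (5.10, 1.99, 3.05, 1.01),
                "skewness": (1.49, 0.39, 0.56, 0.50),
            }
        ),
    }
)

#: Group-mean lobar flow profiles (fractions of total air breathed).
Q_MEAN = MappingProxyType(
    {
        "healthy": MappingProxyType({"RU": 0.22, "RL": 0.30, "LL": 0.27, "LU": 0.21}),
        "ipf": MappingProxyType({"RU": 0.36, "RL": 0.20, "LL": 0.21, "LU": 0.23}),
    }
)

#: Group summary of the lobar-flow RMSD discriminant: (mean, SD) per group.
RMSD_Q_SUMMARY = MappingProxyType(
    {"healthy": (0.46, 0.16), "ipf": (2.56, 1.08)}
)

#: Whole-lung volumes in litres: (healthy mean, healthy SD, IPF mean, IPF SD).
LUNG_VOLUMES_L = MappingProxyType(
    {
        "expanded": (5.56, 0.90, 4.07, 0.98),
        "contracted": (2.46, 0.56, 1.82, 0.30),
        "difference": (3.10, 0.91, 2.24, 0.71),
    }
)

#: Pulmonary-function summaries (% predicted unless noted):
#: (healthy mean, healthy SD, IPF mean, IPF SD).
PFT_SUMMARY = MappingProxyType(
    {
        "fvc_pct": (105.0, 14.0, 85.0, 16.0),
        "dlco_pct": (83.0, 12.0, 48.0, 16.0),
        "fev1_pct": (102.0, 13.0, 90.0, 21.0),
        "tlc_pct": (109.0, 18.0, 72.0, 17.0),
        "age_years": (61.0, 13.0, 71.0, 10.0),
        "gap_index": (1.3, 1.0, 3.6, 1.4),
    }
)
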