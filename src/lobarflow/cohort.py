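"""Cohort-level statistics: the healthy-reference RMSD discriminant,
leave-one-out validation, group comparisons and GAP scoring.

The discriminant score
-----------------------
For a per-lobe quantity ``X`` (lobar flow, volume fraction, or an HU
statistic evaluated per lobe), a subject's distance from the healthy
cohort is

    score = (1/4) Σ_i |X_i − X̄_i^h| / σ_i^h        (i = RU, RL, LL, LU)

with ``X̄_i^h`` and ``σ_i^h`` the healthy-group mean and SD of lobe *i*.
The quantity is conventionally called an RMSD in this literature even
though, written out, it is the mean of per-lobe absolute standardized
deviations rather than a quadratic mean; :func:`rmsd` implements the
conventional (literal) form by default and offers the quadratic form
``sqrt((1/4) Σ z_i²)`` for comparison. By the power-mean inequality the
literal score never exceeds the quadratic one.

Robustness of the score against the composition of the reference cohort is
assessed by leave-one-out: with ``n`` healthy subjects, ``n`` references
are built, each omitting a different healthy subject, and every subject is
scored against all of them; the spread across references is the
leave-one-out SD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Group, LOBE_NAMES, Sex

__all__ = [
    "RmsdForm",
    "ReferenceStats",
    "RmsdScore",
    "GapScore",
    "GroupComparison",
    "reference_stats",
    "rmsd",
    "leave_one_out_references",
    "leave_one_out_rmsd",
    "welch_t_test",
    "bonferroni",
    "ks_normality",
    "percent_difference",
    "gap_index",
    "compare_groups",
]


class RmsdForm(str, enum.Enum):
    """Aggregation form of the per-lobe standardized deviations."""

    LITERAL = "literal"  # mean of |z_i| — the conventional definition
    QUADRATIC = "quadratic"  # sqrt(mean of z_i²)


@dataclass
class ReferenceStats:
    """Healthy-cohort per-lobe mean and SD for one quantity."""

    quantity_name: str
    mean: np.ndarray  # per-lobe, canonical order
    sd: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")
        if np.any(self.sd <= 0):
            raise ValueError("degenerate reference: zero or negative SD in some lobe")
        if self.n_reference < 2:
            raise ValueError("need at least 2 reference subjects")


@dataclass
class RmsdScore:
    """A subject's discriminant score plus its leave-one-out summary."""

    subject_id: str
    quantity_name: str
    value: float
    loo_mean: float
    loo_sd: float


@dataclass(frozen=True)
class GapScore:
    """Gender–Age–Physiology composite score (0–8)."""

    G: int
    A: int
    P_FVC: int
    P_DLCO: int

    @property
    def total(self) -> int:
        return self.G + self.A + self.P_FVC + self.P_DLCO


@dataclass
class GroupComparison:
    """Two-group comparison of one variable with family-wise correction."""

    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p_raw: float
    p_bonferroni: float
    family_size: int
    normality_p_a: float | None = None
    normality_p_b: float | None = None


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(LOBE_NAMES):
        raise ValueError(f"expected {len(LOBE_NAMES)} lobes, got {arr.shape[1]}")
    return arr


def reference_stats(healthy_values, quantity_name: str = "Q") -> ReferenceStats:
    """Per-lobe sample mean and SD (n−1 denominator) over healthy subjects.

    ``healthy_values`` is an (n_subjects × 4) array-like in canonical lobe
    order. A lobe with zero variance across the reference subjects makes
    the standardization undefined and raises.
    """
    arr = _as_matrix(healthy_values)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 healthy subjects")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [LOBE_NAMES[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero variance in lobe(s) {bad}: reference SD degenerate")
    return ReferenceStats(quantity_name=quantity_name, mean=arr.mean(axis=0), sd=sd, n_reference=arr.shape[0])


def rmsd(profile_values, ref: ReferenceStats, form: RmsdForm | str = RmsdForm.LITERAL) -> float:
    """Discriminant score of one subject's per-lobe values against a reference."""
    x = np.asarray(profile_values, dtype=float)
    if x.shape != ref.mean.shape:
        raise ValueError(f"lobe count mismatch: {x.shape} vs {ref.mean.shape}")
    z = np.abs(x - ref.mean) / ref.sd
    form = RmsdForm(form)
    if form is RmsdForm.LITERAL:
        return float(z.mean())
    return float(np.sqrt(np.mean(z**2)))


def leave_one_out_references(
    cohort_values, subject_ids, healthy_ids, quantity_name: str = "Q"
) -> list[tuple[str, ReferenceStats]]:
    """One reference per left-out healthy subject.

    Returns ``[(left_out_id, ReferenceStats built from the remaining
    healthy subjects), ...]`` in the order of ``healthy_ids``.
    """
    arr = _as_matrix(cohort_values)
    subject_ids = [str(s) for s in subject_ids]
    healthy_ids = [str(s) for s in healthy_ids]
    index = {sid: k for k, sid in enumerate(subject_ids)}
    missing = [s for s in healthy_ids if s not in index]
    if missing:
        raise ValueError(f"healthy ids not in cohort: {missing}")
    h_rows = np.array([index[s] for s in healthy_ids])
    if h_rows.size < 3:
        raise ValueError("need at least 3 healthy subjects for leave-one-out")
    return [
        (healthy_ids[k], reference_stats(arr[np.delete(h_rows, k)], quantity_name))
        for k in range(h_rows.size)
    ]


def leave_one_out_rmsd(
    cohort_values,
    subject_ids,
    healthy_ids,
    quantity_name: str = "Q",
    form: RmsdForm | str = RmsdForm.LITERAL,
) -> list[RmsdScore]:
    """Score every subject against the full-healthy reference and against
    each leave-one-out reference.

    With ``n`` healthy subjects, ``n`` references are built, each from the
    remaining ``n − 1`` healthy subjects; every subject (healthy or not)
    is scored against each. ``value`` is the score against the reference
    built from all healthy subjects; ``loo_mean``/``loo_sd`` summarize the
    scores across the ``n`` leave-one-out references (SD with n−1
    denominator, 0 when the references are identical).
    """
    arr = _as_matrix(cohort_values)
    subject_ids = [str(s) for s in subject_ids]
    if arr.shape[0] != len(subject_ids):
        raise ValueError("one row of values per subject id required")
    healthy_ids = [str(s) for s in healthy_ids]
    index = {sid: k for k, sid in enumerate(subject_ids)}
    loo_refs = [
        ref for _, ref in leave_one_out_references(arr, subject_ids, healthy_ids, quantity_name)
    ]
    h_rows = np.array([index[s] for s in healthy_ids])
    full_ref = reference_stats(arr[h_rows], quantity_name)
    scores: list[RmsdScore] = []
    for sid, row in zip(subject_ids, arr):
        loo = np.array([rmsd(row, ref, form) for ref in loo_refs])
        scores.append(
            RmsdScore(
                subject_id=sid,
                quantity_name=quantity_name,
                value=rmsd(row, full_ref, form),
                loo_mean=float(loo.mean()),
                loo_sd=float(loo.std(ddof=1)) if loo.size > 1 else 0.0,
            )
        )
    return scores


def welch_t_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Two-sided Welch t-test from group summary statistics.

    Uses the unequal-variance statistic with Satterthwaite degrees of
    freedom; robust to the unequal group sizes and variances typical of
    small clinical cohorts.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        raise ValueError("both group SDs are zero")
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def pooled_t_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) t-test from summary statistics."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0:
        raise ValueError("both group SDs are zero")
    t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    p = 2 * stats.t.sf(abs(t), n_a + n_b - 2)
    return float(t), float(p)


def bonferroni(p_raw: float, family_size: int) -> float:
    """Family-wise corrected p-value: min(1, p_raw × family_size)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, p_raw * family_size)


def ks_normality(values) -> float:
    """One-sample Kolmogorov–Smirnov p-value against a fitted normal.

    The normal's mean and SD are estimated from the sample itself, which
    makes the test anti-conservative (p-values biased upward relative to
    the Lilliefors correction); adequate as the screening check it is
    used for here, but not a calibrated test.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 4:
        raise ValueError("need at least 4 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return float(stats.kstest(arr, "norm", args=(arr.mean(), sd)).pvalue)


def percent_difference(reference_value: float, other_value: float, direction: str | None = None) -> int:
    """Percent difference of ``other`` from ``reference``, as printed in
    cohort reports: ``100 × |other − reference| / |reference|``, rounded
    half away from zero to an integer.

    ``direction`` ("higher"/"lower") optionally asserts the sign of the
    change; note that for negative reference values (HU means) "higher"
    means algebraically greater, i.e. less negative.
    """
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    if direction is not None:
        if direction not in ("higher", "lower"):
            raise ValueError(f"unknown direction {direction!r}")
        actual = "higher" if other_value > reference_value else "lower"
        if other_value != reference_value and actual != direction:
            raise ValueError(f"direction mismatch: change is {actual}, expected {direction}")
    pct = 100.0 * abs(other_value - reference_value) / abs(reference_value)
    return int(np.floor(pct + 0.5))


def gap_index(
    sex: Sex | str, age_years: float, fvc_pct: float, dlco_pct: float | None
) -> GapScore:
    """Gender–Age–Physiology index for IPF risk staging.

    G: 0 for women, 1 for men. A: 0/1/2 for age ≤60, 61–65, >65.
    P_FVC: 0/1/2 for FVC >75, 50–75, <50 %predicted.
    P_DLCO: 0/1/2 for DLCO >55, 36–55, ≤35 %predicted, or 3 when DLCO
    could not be measured (``dlco_pct=None``). Total ranges 0–8.
    """
    if age_years <= 0 or fvc_pct <= 0:
        raise ValueError("age and FVC must be positive")
    if dlco_pct is not None and dlco_pct <= 0:
        raise ValueError("DLCO must be positive or None (not measurable)")
    g = 0 if Sex(sex) is Sex.FEMALE else 1
    a = 0 if age_years <= 60 else (1 if age_years <= 65 else 2)
    p_fvc = 0 if fvc_pct > 75 else (1 if fvc_pct >= 50 else 2)
    if dlco_pct is None:
        p_dlco = 3
    else:
        p_dlco = 0 if dlco_pct > 55 else (1 if dlco_pct >= 36 else 2)
    return GapScore(G=g, A=a, P_FVC=p_fvc, P_DLCO=p_dlco)


def compare_groups(
    table,
    variables: list[str],
    group_column: str = "group",
    group_a: str = Group.HEALTHY.value,
    group_b: str = Group.IPF.value,
    family_size: int | None = None,
    variant: str = "welch",
) -> list[GroupComparison]:
    """Per-variable two-group comparison table with Bonferroni correction.

    ``table`` is a pandas DataFrame with one row per subject. The family
    size defaults to the number of variables compared (the rows of the
    table being produced), mirroring per-table family-wise correction.
    """
    test = welch_t_test if variant == "welch" else pooled_t_test
    m = family_size if family_size is not None else len(variables)
    out: list[GroupComparison] = []
    for var in variables:
        a = table.loc[table[group_column] == group_a, var].dropna().to_numpy(dtype=float)
        b = table.loc[table[group_column] == group_b, var].dropna().to_numpy(dtype=float)
        t, p = test(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
        norm_a = ks_normality(a) if a.size >= 4 and a.std(ddof=1) > 0 else None
        norm_b = ks_normality(b) if b.size >= 4 and b.std(ddof=1) > 0 else None
        out.append(
            GroupComparison(
                variable=var,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                n_a=int(a.size),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                n_b=int(b.size),
                t=t,
                p_raw=p,
                p_bonferroni=bonferroni(p, m),
                family_size=m,
                normality_p_a=norm_a,
                normality_p_b=norm_b,
            )
        )
    return out
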