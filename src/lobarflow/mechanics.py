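"""Lobar volumetry and ventilation mechanics from paired breath-hold scans.

Given per-lobe absolute volumes in the expanded (full inspiration) and
contracted (full expiration) states, three normalized quantities describe
how a subject's lung empties:

* lobar volume fraction ``V_i = v_i / Σ_j v_j`` — a lobe's share of the
  lung in one state;
* lobar flow ``Q_i = (v_e,i − v_c,i) / Σ_j (v_e,j − v_c,j)`` — the share
  of the total exhaled air contributed by lobe *i* (the lung-volume
  difference between the states is the total air breathed);
* lobar strain ``S_i = (v_e,i − v_c,i) / v_e,i`` — a lobe's volumetric
  contraction relative to its expanded size.

``V`` and ``Q`` sum to one by construction; all three are invariant under
a global rescaling of the volumes. A lobe that expands during exhalation
(paradoxical motion) gives a negative ``Q_i``; the formula remains valid,
so this is reported as a warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CtVolume, LOBE_NAMES, LobeLabelMap, LungState, SubjectRecord, region_volume_liters

__all__ = [
    "LobeVolumes",
    "LobarProfile",
    "lobe_volumes",
    "volume_fractions",
    "lobar_flow",
    "lobar_strain",
    "build_profile",
]


@dataclass
class LobeVolumes:
    """Absolute per-lobe volumes (litres) for one breath-hold state."""

    volumes: dict[str, float]
    state: LungState

    def __post_init__(self) -> None:
        missing = [n for n in LOBE_NAMES if n not in self.volumes]
        if missing:
            raise ValueError(f"missing lobes: {missing}")
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("lobe volumes must be non-negative")
        if not np.any(vals > 0):
            raise ValueError("at least one lobe volume must be positive")
        self.state = LungState(self.state)

    def as_array(self) -> np.ndarray:
        return np.array([self.volumes[n] for n in LOBE_NAMES], dtype=float)

    @property
    def total(self) -> float:
        """Whole-lung volume in litres."""
        return float(self.as_array().sum())


@dataclass
class LobarProfile:
    """All per-lobe mechanics quantities for one subject."""

    subject_id: str
    v_expanded: LobeVolumes
    v_contracted: LobeVolumes
    V_expanded: dict[str, float]
    V_contracted: dict[str, float]
    Q: dict[str, float]
    S: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def lung_volume_expanded(self) -> float:
        return self.v_expanded.total

    @property
    def lung_volume_contracted(self) -> float:
        return self.v_contracted.total


def lobe_volumes(volume: CtVolume, labels: LobeLabelMap) -> LobeVolumes:
    """Per-lobe physical volumes from a label map, in litres."""
    if labels.labels.shape != volume.shape:
        raise ValueError("label map shape does not match volume")
    counts = labels.voxel_counts()
    vols: dict[str, float] = {}
    for name in LOBE_NAMES:
        if counts[name] == 0:
            warnings.warn(f"lobe {name} has no labelled voxels", stacklevel=2)
        vols[name] = region_volume_liters(counts[name], volume.spacing)
    return LobeVolumes(volumes=vols, state=volume.state)


def volume_fractions(v: LobeVolumes) -> dict[str, float]:
    """Lobar volume fractions V_i = v_i / Σ v_j (sum to 1)."""
    arr = v.as_array()
    total = arr.sum()
    if total <= 0:
        raise ValueError("total lung volume must be positive")
    return dict(zip(LOBE_NAMES, (arr / total).tolist()))


def lobar_flow(v_expanded: LobeVolumes, v_contracted: LobeVolumes) -> dict[str, float]:
    """Lobar flow fractions Q_i (sum to 1; negative = paradoxical motion)."""
    diff = v_expanded.as_array() - v_contracted.as_array()
    total = diff.sum()
    if total == 0:
        raise ValueError("zero total volume change between states")
    q = diff / total
    for name, qi in zip(LOBE_NAMES, q):
        if qi < 0:
            warnings.warn(f"negative lobar flow for {name}: paradoxical lobe motion", stacklevel=2)
    return dict(zip(LOBE_NAMES, q.tolist()))


def lobar_strain(v_expanded: LobeVolumes, v_contracted: LobeVolumes) -> dict[str, float]:
    """Per-lobe volumetric strain S_i = (v_e,i − v_c,i) / v_e,i."""
    ve = v_expanded.as_array()
    vc = v_contracted.as_array()
    if np.any(ve <= 0):
        raise ValueError("expanded lobe volumes must be positive for strain")
    return dict(zip(LOBE_NAMES, ((ve - vc) / ve).tolist()))


def build_profile(subject: SubjectRecord) -> LobarProfile:
    """Compose volumes, fractions, flow and strain for one subject."""
    if subject.expanded is None or subject.contracted is None:
        raise ValueError("both expanded and contracted scans are required")
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ve = lobe_volumes(*subject.expanded)
        vc = lobe_volumes(*subject.contracted)
        profile = LobarProfile(
            subject_id=subject.subject_id,
            v_expanded=ve,
            v_contracted=vc,
            V_expanded=volume_fractions(ve),
            V_contracted=volume_fractions(vc),
            Q=lobar_flow(ve, vc),
            S=lobar_strain(ve, vc),
        )
        collected = [str(w.message) for w in caught]
    profile.warnings = collected
    return profile
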