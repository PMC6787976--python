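"""Lobar volumes, flow and strain from a paired phantom.

Generates one expanded/contracted phantom pair at the healthy group-mean
volumes (5.56 L / 2.46 L) and prints, per lobe: absolute volumes, the
volume fraction V, the lobar flow Q (share of the total exhaled air) and
the lobar strain S (fractional emptying of the lobe). Q sums to 1 across
lobes by construction; in a healthy lung the lower lobes (RL, LL) carry
the largest share of the breath.
"""

from lobarflow import (
    Group,
    LOBE_NAMES,
    PhantomSpec,
    Sex,
    SubjectRecord,
    build_profile,
    generate_phantom_pair,
)

expanded, contracted, truth = generate_phantom_pair(PhantomSpec.healthy(seed=7))
subject = SubjectRecord(
    subject_id="H1",
    group=Group.HEALTHY,
    sex=Sex.FEMALE,
    age=61,
    fvc_pct=105,
    dlco_pct=83,
    expanded=expanded,
    contracted=contracted,
)
profile = build_profile(subject)

print(f"lung volume: expanded {profile.lung_volume_expanded:.2f} L, "
      f"contracted {profile.lung_volume_contracted:.2f} L")
print(f"{'lobe':>4}  {'v_e (L)':>8}  {'v_c (L)':>8}  {'V_exp':>6}  {'Q':>6}  {'S':>6}")
for lobe in LOBE_NAMES:
    print(
        f"{lobe:>4}  {profile.v_expanded.volumes[lobe]:8.3f}  "
        f"{profile.v_contracted.volumes[lobe]:8.3f}  "
        f"{profile.V_expanded[lobe]:6.3f}  {profile.Q[lobe]:6.3f}  {profile.S[lobe]:6.3f}"
    )
print(f"sum of Q: {sum(profile.Q.values()):.6f}")
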