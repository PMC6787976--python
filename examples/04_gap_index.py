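"""GAP (gender-age-physiology) index scoring.

The GAP index stages IPF risk on a 0-8 scale from sex, age, FVC
%predicted and DLCO %predicted (3 points when DLCO cannot be measured).
Prints the component scores for a few illustrative subjects, including
the missing-DLCO branch.
"""

from lobarflow import gap_index

subjects = [
    ("healthy woman, 58 y, FVC 80%, DLCO 60%", "female", 58, 80, 60),
    ("IPF man, 71 y, FVC 85%, DLCO 48%", "male", 71, 85, 48),
    ("IPF man, 63 y, FVC 40%, DLCO not measurable", "male", 63, 40, None),
]
for label, sex, age, fvc, dlco in subjects:
    s = gap_index(sex, age, fvc, dlco)
    print(f"{label}: G={s.G} A={s.A} P_FVC={s.P_FVC} P_DLCO={s.P_DLCO} -> total {s.total}")
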