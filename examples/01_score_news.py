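"""Score vital signs with NEWS 2.

Builds a few assessments by hand, scores each component against the
banding chart, and prints the totals.  The total (0-20) is the sum of
seven component scores; ACVPU levels other than Alert and supplemental
oxygen carry fixed penalties.
"""

from dispatchtrial import compute_news

patients = {
    "well":      dict(respiratory_rate=16, spo2=98, on_oxygen=False,
                      systolic_bp=120, pulse=75, consciousness="Alert",
                      temperature=37.0),
    "febrile":   dict(respiratory_rate=22, spo2=95, on_oxygen=False,
                      systolic_bp=100, pulse=92, consciousness="Alert",
                      temperature=38.2),
    "critical":  dict(respiratory_rate=8, spo2=91, on_oxygen=True,
                      systolic_bp=90, pulse=135, consciousness="Unresponsive",
                      temperature=35.0),
}

for label, vitals in patients.items():
    score = compute_news(vitals)
    parts = " + ".join(str(p) for p in score.component_points.values())
    print(f"{label:9s} NEWS = {score.total:2d}  ({parts})")

# A NEWS of 0 is a fully normal assessment; 5+ usually triggers an urgent
# clinical review; the febrile example's 7 comes from raised respiratory
# rate, borderline saturation and blood pressure, tachycardia and fever.
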