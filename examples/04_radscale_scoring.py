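"""Score subjects on the seven-item radiological point scale (0-12).

Items: Evans' index, mean temporal horn width, callosal angle, narrow
high-convexity sulci, periventricular hypodensities (0-2 points each),
dilated Sylvian fissures and focally enlarged sulci (0-1 each). Totals map
to Negative (0-2), Borderline (3-4) or Positive (>=5).
"""

from nphct import radscale

florid = radscale.RadscaleMeasurements(
    frontal_horn_width=42, inner_table_width=105,   # Evans 0.40
    temporal_horn_right=8, temporal_horn_left=6,    # mean 7 mm
    callosal_angle=52,
    narrow_parietal_sulci=2,
    sylvian_dilated=True, focal_sulci=True,
    periventricular="confluent",
)
healthy = radscale.RadscaleMeasurements(
    frontal_horn_width=28, inner_table_width=104,   # Evans 0.27
    temporal_horn_right=2, temporal_horn_left=2,
    callosal_angle=112,
    narrow_parietal_sulci=0,
    sylvian_dilated=False, focal_sulci=False,
    periventricular="none",
)

for name, m in (("florid NPH", florid), ("healthy", healthy)):
    s = radscale.score_subject(m)
    print(f"{name:>10}: items {list(s.item_points.values())} "
          f"total {s.total:2d} -> {s.category}")

print("\nA total of 12 is the scale's maximum; >=5 predicts NPH.")
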