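"""Generate one stimulus pair per magnitude-control condition and verify it.

For each of the six conditions (geometry control x spatial control) a
3 vs 6 pair is generated, its magnitudes are re-measured, and the relative
deviation of each controlled magnitude is printed: geometry controls are
solved in closed form (deviation ~ 0) and spatial controls are matched
within the 5% generator tolerance.
"""

from numfish import CONDITIONS, compute_magnitudes, generate_pair

for condition in CONDITIONS:
    pair = generate_pair(3, 6, condition, rng=1)
    m_s = compute_magnitudes(pair.array_small)
    m_l = compute_magnitudes(pair.array_large)
    rep = pair.constraint_report
    print(
        f"{condition.label():>16}: geometry dev {rep['geometry_rel_dev']:.2e}, "
        f"{rep['spatial_metric']} dev {rep['spatial_rel_dev']:.3f} | "
        f"areas {m_s.total_area:6.1f} vs {m_l.total_area:6.1f} mm^2, "
        f"perimeters {m_s.total_perimeter:5.1f} vs {m_l.total_perimeter:5.1f} mm"
    )

print(
    "\nEach line shows the achieved relative deviation of the two controlled "
    "magnitudes\n(geometry exact, spatial within 5%) and how the uncontrolled "
    "area/perimeter covary\nwith numerosity in that condition."
)
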