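"""Total spatial-frequency power of stimulus pairs, per control condition.

Generates a few 3 vs 6 pairs per condition, renders them, computes each
image's total power (sum of the radially averaged Fourier amplitude, DC
excluded) and prints the per-condition mean of the normalised total power
index (TP_large - TP_small)/(TP_large + TP_small).  A positive index means
the more numerous array carries more spectral energy under this convention.
"""

from numfish.pipeline import stimulus_power_indices

df = stimulus_power_indices((3, 6), n_pairs=3, seed=1, px_side=256)
summary = df.groupby("condition")["power_index"].mean()
print(summary.round(3).to_string())
print(
    "\nIndex in [-1, 1]: sign says which numerosity carries more total "
    "spectral energy;\nthe geometry control flips it between the radius-fixed "
    "and perimeter-equated\nconditions (the convention options dc_included / "
    "use_power_not_amplitude matter;\nsee SpectrumOptions)."
)
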