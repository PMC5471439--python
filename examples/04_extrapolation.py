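"""Scale the sampled neuron count to a whole-structure estimate.

The 63-neuron mean was counted in a unilateral 350 x 350 x 100 um window
at the structure's core; the structure spans ~440 um rostrocaudally and
is bilateral, so the total is 63 x (440/100) x 2 = 554.4.  The summed
per-timepoint labeling exceeding 100% of the constitutive reference
shows that adjacent tamoxifen timepoints label overlapping progenitor
pools (recombinase activity persists beyond one day).
"""

import fatemap as fm

result = fm.extrapolate_total(63, fm.ExtrapolationSpec(100, 440, 2))
print(f"estimated total neurons: {result.estimate:.1f} (~{result.display})")

neuron_sum = fm.labeling_sum_check([23, 38, 63, 26, 9], 70)
glia_sum = fm.labeling_sum_check([47, 30, 42, 38, 34], 92)
print(f"summed neuron labeling across timepoints: {neuron_sum:.1f}% "
      f"of the constitutive line")
print(f"summed glia labeling across timepoints:   {glia_sum:.1f}%")
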