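"""Pearson colocalization with the 90-degree rotation control.

Generates anisotropic two-channel images with true pixelwise correlation
0.8 for 12 cells, computes each cell's observed PCC and its PCC after
rotating channel 2 by 90 degrees (which destroys spatial registration),
then runs the paired comparison.
"""

import numpy as np

import nequant as nq

geometry = nq.SceneSpec(image_shape=(128, 128),
                        nuclei=[nq.NucleusSpec((64, 64), (52, 44))])

measurements = []
for seed in range(12):
    stack, truth = nq.make_coloc_pair(0.8, geometry, seed=seed, anisotropy=True)
    cells = nq.measure_cells(stack.channel(0), stack.channel(1),
                             truth.masks["cell"].astype(int))
    measurements.extend(cells)

obs = [m.pcc_observed for m in measurements]
rot = [m.pcc_rotated for m in measurements]
print(f"observed PCC: {np.mean(obs):.3f} ± {np.std(obs, ddof=1)/np.sqrt(len(obs)):.3f}"
      f" (s.e.m., n = {len(obs)} cells; true correlation 0.8)")
print(f"rotated  PCC: {np.mean(rot):.3f} ± {np.std(rot, ddof=1)/np.sqrt(len(rot)):.3f}")
result = nq.paired_coloc_test(measurements)
print(f"paired t test: p = {result.loc[0, 'p_raw']:.2e} {result.loc[0, 'stars']}")
print()
print("A rotated-channel PCC near zero shows the observed correlation reflects")
print("genuine spatial registration of the two channels, not shared geometry.")
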