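"""Chromocenter segmentation in 3D and PLA focus-count normalization.

Builds a z-stack with ten 20-voxel chromocenter-like foci inside an
ellipsoidal nucleus, counts them with the percentile threshold (99.5% of
the within-nucleus histogram) and the inclusive [7, 2000]-voxel filter,
then demonstrates fold-change normalization of PLA focus counts against an
antibody-only control.
"""

import numpy as np

import nequant as nq

spec = nq.SceneSpec(image_shape=(24, 96, 96),
                    nuclei=[nq.NucleusSpec((48, 48), (40, 36))],
                    foci_count=10, foci_volume_voxels=20, seed=3)
stack, truth = nq.make_foci_stack(spec)
record = nq.segment_chromocenters(stack, truth.masks["nucleus"])[0]
print(f"chromocenters detected: {record.foci_count} (10 placed)")
print(f"voxel volumes: {record.volumes}")
print(f"mean calibrated volume: {np.mean(record.calibrated_volumes):.4f} "
      "(voxel calibration 0.075 x 0.075 x 0.029)")

rng = np.random.default_rng(0)
counts = {
    "GFP antibody only": rng.poisson(2.0, 80),   # technical background
    "GFP + partner":     rng.poisson(9.0, 80),   # genuine proximity signal
}
folds = nq.normalize_foci(counts, control="GFP antibody only")
print()
print(folds[["condition", "n_cells", "mean_fold", "sem_fold"]].to_string(index=False))
print()
print("mean_fold is each cell's focus count divided by the control mean count;")
print("a fold well above 1 indicates protein proximity beyond antibody background.")
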