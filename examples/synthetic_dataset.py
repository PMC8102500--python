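"""Exporting a ground-truthed synthetic dataset to disk.

Generates a two-nucleus rim scene, writes the 16-bit TIFF, the ground-truth
masks/tables and a run manifest (spec + seed) to a directory, and reads the
image back to verify the intensity scale round-trips.
"""

import tempfile
from pathlib import Path

import numpy as np

import nequant as nq

spec = nq.SceneSpec(
    image_shape=(128, 192),
    nuclei=[nq.NucleusSpec((60, 50), (28, 22)),
            nq.NucleusSpec((64, 140), (24, 26), angle_deg=40)],
    rim_contrast=1.8, noise_sigma=5.0, seed=42)
stack, truth = nq.make_nucleus_scene(spec)

outdir = Path(tempfile.mkdtemp(prefix="nequant_demo_"))
nq.save_dataset(outdir, stack, truth, spec=spec)
print("dataset written to:", outdir)
for f in sorted(p.name for p in outdir.iterdir()):
    print("  ", f)

back = nq.read_tiff(outdir / "image.tif")
err = np.max(np.abs(back.data - stack.data))
print(f"max round-trip intensity error: {err:.4f} a.u. "
      "(16-bit quantization, scale recorded in the TIFF description)")
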