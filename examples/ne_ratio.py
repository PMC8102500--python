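"""Nuclear-envelope enrichment: rim:nucleoplasm ratio on synthetic nuclei.

Simulates two conditions — marker retained at the nuclear envelope
(rim contrast 2.0) vs redistributed into the nucleoplasm (contrast 1.05) —
segments nuclei from the DAPI channel, measures the per-nucleus rim ratio
and summarizes the fraction of nuclei called "Nuclear envelope enriched"
(ratio > 1.2) per condition.
"""

import numpy as np

import nequant as nq

rng = np.random.default_rng(7)
measurements = []
# per-cell contrast is heterogeneous around the condition mean, as in a
# real population of cells
for condition, mean_contrast in [("control", 1.7), ("displaced", 1.05)]:
    for replicate in range(1, 4):
        for _ in range(30):
            nucleus = nq.NucleusSpec(center=(32, 32),
                                     semi_axes=(rng.uniform(18, 24), rng.uniform(16, 22)),
                                     angle_deg=rng.uniform(0, 180))
            contrast = max(rng.normal(mean_contrast, 0.3), 0.6)
            spec = nq.SceneSpec(image_shape=(64, 64), nuclei=[nucleus],
                                rim_contrast=contrast, noise_sigma=10.0,
                                seed=int(rng.integers(2**31)))
            stack, _ = nq.make_nucleus_scene(spec)
            labels = nq.segment_objects(stack.channel(0),
                                        nq.SegmentationConfig(smoothing_sigma=1.5))
            if labels.max() != 1:
                continue
            part = nq.partition_rim_nucleoplasm(labels, 1, rim_width_px=3)
            m = nq.measure_ne_ratio(stack.channel(1), part,
                                    condition_label=condition, replicate=replicate)
            measurements.append(m)

summary = nq.summarize_condition(measurements)
print(summary[["condition_label", "n_cells", "fraction_enriched", "sem"]]
      .to_string(index=False))
print()
print("fraction_enriched is the share of nuclei with rim:nucleoplasm ratio > 1.2;")
print("s.e.m. is computed across the three simulated replicates, not across cells.")
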