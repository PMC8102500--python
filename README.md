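# nequant

Quantification of nuclear-envelope biology from fluorescence microscopy:
rim enrichment of inner-nuclear-membrane proteins, protein mobility by
FRAP, two-channel colocalization with a rotation control, and nuclear
foci counts — together with a ground-truthed synthetic-microscopy
generator that lets every estimator be validated end to end.

It is written for cell biologists and image analysts who quantify
readouts such as the redistribution of lamin B receptor (LBR) between
the nuclear envelope and the nucleoplasm during myogenic differentiation,
and who want those measurements reproducible outside commercial
acquisition software.

## What it computes

**NE : nucleoplasm ratio.** Nuclei are segmented from a DAPI channel,
each mask is split by its Euclidean distance transform into an inner rim
band (distance in `(0, w]` pixels from the boundary, default `w = 3`)
and a nucleoplasm core. The readout per nucleus is

    ratio = mean intensity(rim) / mean intensity(nucleoplasm)

with `ratio > 1.2` classified "Nuclear envelope enriched" and anything
else "diffuse in the nucleus". Summaries report the enriched fraction
per condition with s.e.m. across biological replicates.

**FRAP.** After translation drift correction, ROI traces are combined by
double normalization,

    N(t) = [(I_bleach − I_bg)/(I_bleach(t0) − I_bg(t0))]
         / [(I_total − I_bg)/(I_total(t0) − I_bg(t0))],

which removes camera offset and acquisition bleaching, and fitted with
N(t) = D + M(1 − D)(1 − e^{−kt}): mobile fraction M, rate k, half-time
ln 2 / k. Curves are averaged with s.e.m., and a flow metric verifies
that the bleached region recovers at the cost of the unbleached region.

**Colocalization.** Per-cell Pearson coefficient over a mask, compared
against the coefficient after rotating one channel by 90° about its
bounding-box center — a null that destroys spatial registration — with a
paired two-tailed test.

**Foci.** Chromocenters in 3D stacks: threshold at the 99.5th percentile
of the within-nucleus histogram, 26-connected components, inclusive
[7, 2000]-voxel volume filter. PLA foci per cell in 2D with fold-change
normalization against an antibody-only control.

**Statistics.** Welch/paired t tests, one-way ANOVA with Holm-adjusted
pairwise comparisons, Kruskal–Wallis; stars *P < 0.05, **P < 0.01,
***P < 0.001.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
python examples/frap_recovery.py
```

```
fitted mobile fraction M = 0.613   (true 0.600)
fitted rate k           = 0.0503 /s (true 0.0500)
half-time of recovery   = 13.8 s  (ln 2 / k)
mean curve: N(300 s) = 0.732 ± 0.001 (s.e.m., 8 curves)
```

Eight photobleach series are simulated for a protein with 60% mobile
fraction recovering at 0.05 /s under 2% camera noise and mild
acquisition bleaching; the fitted parameters recover the truth to a few
percent, and the averaged normalized curve plateaus at
D + M(1 − D) ≈ 0.73. The other scripts in `examples/` (`ne_ratio.py`,
`colocalization.py`, `foci_counting.py`, `group_stats.py`,
`synthetic_dataset.py`) demonstrate the remaining capabilities the same
way: build a small synthetic input, run the measurement, print what it
means.

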