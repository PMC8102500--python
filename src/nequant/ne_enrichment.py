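"""Nuclear-envelope enrichment: the rim : nucleoplasm intensity ratio.

For each nucleus, the mean marker fluorescence over the rim band is divided
by the mean over the nucleoplasm core. Nuclei with a ratio strictly above
the classification threshold (default 1.2) are called "Nuclear envelope
enriched"; all others, including a ratio of exactly 1.2, are "diffuse in
the nucleus". Per-condition summaries aggregate per replicate first, so the
reported s.e.m. is across biological replicates, not across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ImageStack
from .segmentation import RegionPartition

ENRICHED = "Nuclear envelope enriched"
DIFFUSE = "diffuse in the nucleus"

#: Default ratio cutoff separating NE-enriched from diffuse nuclei.
DEFAULT_THRESHOLD = 1.2


@dataclass
class NEMeasurement:
    object_id: int
    rim_mean: float
    nucleoplasm_mean: float
    ratio: float
    category: str
    condition_label: str = ""
    replicate: int | str = 0
    valid: bool = True


def measure_ne_ratio(intensity, partition: RegionPartition,
                     threshold: float = DEFAULT_THRESHOLD,
                     condition_label: str = "", replicate: int | str = 0,
                     background: float = 0.0) -> NEMeasurement:
    """Rim and nucleoplasm means, their ratio, and the enrichment call.

    Means are plain arithmetic means over the exact pixel sets of the
    partition. No background is subtracted unless ``background`` is given.
    A nucleoplasm mean of zero makes the ratio undefined; the measurement is
    returned flagged invalid (callers exclude and count it).
    """
    data = intensity.data if isinstance(intensity, ImageStack) else np.asarray(intensity, float)
    if data.shape != partition.rim.shape:
        raise ValueError("intensity image and partition masks are not congruent")
    if not partition.rim.any() or not partition.nucleoplasm.any():
        raise ValueError("partition regions must be non-empty")
    rim_mean = float(data[partition.rim].mean()) - background
    core_mean = float(data[partition.nucleoplasm].mean()) - background
    if core_mean <= 0:
        warnings.warn(f"object {partition.object_id}: non-positive nucleoplasm mean, "
                      "measurement flagged invalid", stacklevel=2)
        return NEMeasurement(partition.object_id, rim_mean, core_mean, float("nan"),
                             DIFFUSE, condition_label, replicate, valid=False)
    ratio = rim_mean / core_mean
    return NEMeasurement(partition.object_id, rim_mean, core_mean, ratio,
                         classify_enrichment(ratio, threshold),
                         condition_label, replicate)


def classify_enrichment(ratio: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Strictly above the threshold is enriched; ties go to diffuse."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be finite and positive, got {ratio}")
    return ENRICHED if ratio > threshold else DIFFUSE


def measurements_frame(measurements: list[NEMeasurement]) -> pd.DataFrame:
    """Tidy per-cell table from a list of measurements."""
    return pd.DataFrame([vars(m) for m in measurements])


def summarize_condition(measurements: list[NEMeasurement]) -> pd.DataFrame:
    """Per-condition enrichment summary.

    Pools cells within each (condition, replicate), then reports for every
    condition: total cell count, pooled enriched fraction, per-replicate
    fractions, and the s.e.m. of the fraction across replicates (NaN with a
    single replicate). Invalid measurements are excluded and counted.
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    df = measurements_frame(measurements)
    n_invalid = int((~df["valid"]).sum())
    df = df[df["valid"]]
    if df.empty:
        raise ValueError(f"all {n_invalid} measurements invalid (zero nucleoplasm signal)")
    if n_invalid:
        warnings.warn(f"{n_invalid} invalid measurement(s) excluded", stacklevel=2)

    df = df.assign(enriched=df["category"] == ENRICHED)
    rows = []
    for cond, sub in df.groupby("condition_label", sort=False):
        per_rep = sub.groupby("replicate")["enriched"].agg(["mean", "size"])
        fractions = per_rep["mean"].to_numpy(float)
        sem = (fractions.std(ddof=1) / np.sqrt(len(fractions))
               if len(fractions) > 1 else float("nan"))
        rows.append({
            "condition_label": cond,
            "n_cells": int(per_rep["size"].sum()),
            "n_replicates": len(per_rep),
            "fraction_enriched": float(sub["enriched"].mean()),
            "replicate_fractions": list(np.round(fractions, 6)),
            "sem": sem,
            "n_excluded_invalid": n_invalid,
        })
    return pd.DataFrame(rows)
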