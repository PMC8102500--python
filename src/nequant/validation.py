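"""End-to-end self-validation on synthetic data.

Each routine here generates ground-truthed synthetic inputs, runs the full
measurement pipeline on them, and scores the estimates against the truth.
They are the package's own evidence that the estimators recover what the
generator put in, at the problem sizes a desktop run can afford.
"""

from __future__ import annotations

import numpy as np

from . import coloc, frap, ne_enrichment, segmentation, stats_report, synth


def ne_ratio_recovery(seed: int = 0, n_per_contrast: int = 200,
                      contrasts: tuple[float, ...] = (1.0, 1.2, 1.5, 2.0, 3.0),
                      snr: float = 5.0) -> dict:
    """Rim-ratio estimation and enrichment classification on synthetic nuclei.

    For each rim contrast r, ``n_per_contrast`` single-nucleus scenes are
    generated at signal-to-noise ratio ``snr`` (marker level over noise
    sigma), segmented from the DAPI channel, partitioned, and measured.
    Returns per-contrast mean estimated ratios, the worst relative error of
    those means, and the classification accuracy at the 1.2 threshold over
    the contrasts at least 0.2 away from it.
    """
    rng = np.random.default_rng(seed)
    marker_level = 100.0
    noise_sigma = marker_level / snr
    config = segmentation.SegmentationConfig(smoothing_sigma=1.5, min_area_px=200)

    mean_ratio = {}
    correct = total_classified = 0
    for r in contrasts:
        ratios = []
        for _ in range(n_per_contrast):
            ay = rng.uniform(18, 24)
            ax = rng.uniform(16, 22)
            nucleus = synth.NucleusSpec(
                center=(32 + rng.uniform(-2, 2), 32 + rng.uniform(-2, 2)),
                semi_axes=(ay, ax), angle_deg=rng.uniform(0, 180))
            spec = synth.SceneSpec(
                image_shape=(64, 64), nuclei=[nucleus], rim_width_px=3,
                rim_contrast=r, marker_level=marker_level,
                noise_sigma=noise_sigma, seed=int(rng.integers(2**31)))
            stack, _ = synth.make_nucleus_scene(spec)
            labels = segmentation.segment_objects(stack.channel(0), config)
            if labels.max() != 1:
                continue
            try:
                part = segmentation.partition_rim_nucleoplasm(labels, 1, 0, 3)
            except segmentation.DegeneratePartitionError:
                continue
            m = ne_enrichment.measure_ne_ratio(stack.channel(1), part)
            if not m.valid:
                continue
            ratios.append(m.ratio)
            if abs(r - 1.2) >= 0.2:
                truth_cat = (ne_enrichment.ENRICHED if r > 1.2
                             else ne_enrichment.DIFFUSE)
                correct += m.category == truth_cat
                total_classified += 1
        mean_ratio[r] = float(np.mean(ratios))
    worst_rel_err = max(abs(mean_ratio[r] - r) / r for r in contrasts)
    return {
        "mean_ratio_by_contrast": mean_ratio,
        "worst_mean_relative_error": float(worst_rel_err),
        "classification_accuracy": float(correct / total_classified),
        "n_classified": total_classified,
    }


def frap_worked_identities() -> dict:
    """The two exact identities of the double normalization.

    A constant pre-bleach trace normalizes to exactly 1 at the reference
    frame, and the worked evaluation with bleach/total/background intensities
    100/1000/10 at reference and 55/910/10 at a later frame gives
    (45/90)/(900/990) = 0.55.
    """
    tr = frap.FrapTrace(np.array([-1.0, 0.0]), np.array([100.0, 55.0]),
                        np.array([1000.0, 910.0]), np.array([10.0, 10.0]), 1)
    frap.double_normalize(tr, reference="last")
    return {"N_at_reference": float(tr.N[0]), "worked_example": float(tr.N[1])}


def _frap_geometry() -> synth.SceneSpec:
    # structure large relative to the bleach square, as in the acquisitions
    return synth.SceneSpec(image_shape=(80, 80),
                           nuclei=[synth.NucleusSpec((40, 40), (30, 26))])


def frap_parameter_recovery(seed: int = 0, n_per_condition: int = 50,
                            mobile_fractions: tuple[float, ...] = (0.2, 0.5, 0.9),
                            rates: tuple[float, ...] = (0.01, 0.05, 0.2),
                            noise_frac: float = 0.02) -> dict:
    """Mobile fraction and rate recovery over a grid of kinetic conditions.

    ``n_per_condition`` image series are generated per (M, k) pair with
    camera noise at ``noise_frac`` of the pre-bleach level and acquisition
    bleaching alternating between 0 and 0.001 /s, then pushed through trace
    extraction, double normalization and recovery fitting. Returns the
    median absolute error on M and the median relative error on k.
    """
    rng = np.random.default_rng(seed)
    geometry = _frap_geometry()
    bg_roi = np.zeros((80, 80), bool)
    bg_roi[:6, :6] = True

    m_errors, k_errors = [], []
    for M in mobile_fractions:
        for k in rates:
            for i in range(n_per_condition):
                spec = synth.FrapSpec(
                    mobile_fraction=M, rate=k,
                    acquisition_bleach_rate=0.0 if i % 2 == 0 else 0.001,
                    noise_sigma=noise_frac * 200.0,
                    n_postbleach_frames=300, bleach_roi_halfwidth=3,
                    seed=int(rng.integers(2**31)))
                series, truth = synth.make_frap_series(spec, geometry)
                rois = frap.FrapROISet(truth.masks["bleach"],
                                       truth.masks["structure"], bg_roi)
                tr = frap.extract_traces(series, rois, spec.n_prebleach_frames)
                frap.double_normalize(tr)
                fit = frap.fit_recovery(tr)
                m_errors.append(abs(fit.mobile_fraction - M))
                if np.isfinite(fit.rate):
                    k_errors.append(abs(fit.rate - k) / k)
    return {
        "median_abs_M_error": float(np.median(m_errors)),
        "median_rel_k_error": float(np.median(k_errors)),
        "n_series": len(m_errors),
    }


def frap_conservation_residual(seed: int = 0) -> dict:
    """Noise-free conservation: bleached-region gain equals unbleached loss."""
    spec = synth.FrapSpec(mobile_fraction=0.6, rate=0.05, noise_sigma=0.0,
                          acquisition_bleach_rate=0.0,
                          n_postbleach_frames=150, bleach_roi_halfwidth=3,
                          seed=seed)
    series, truth = synth.make_frap_series(spec, _frap_geometry())
    bg_roi = np.zeros((80, 80), bool)
    bg_roi[:6, :6] = True
    rois = frap.FrapROISet(truth.masks["bleach"], truth.masks["structure"], bg_roi)
    tr = frap.extract_traces(series, rois, spec.n_prebleach_frames)
    fm = frap.flow_metric(tr, int(truth.masks["bleach"].sum()),
                          int(truth.masks["structure"].sum()))
    return {"max_abs_residual": float(np.abs(fm["residual"]).max()),
            "n_frames": len(fm)}


def coloc_rotation_attenuation(seed: int = 0, n_seeds: int = 50,
                               rho: float = 0.8) -> dict:
    """Median drop of the PCC under the 90-degree rotation null.

    Anisotropic correlated pairs at target correlation ``rho`` are generated
    over ``n_seeds`` seeds; for each, the observed PCC is compared with the
    rotation-null PCC and the median attenuation (observed minus |rotated|)
    reported.
    """
    geometry = synth.SceneSpec(image_shape=(128, 128),
                               nuclei=[synth.NucleusSpec((64, 64), (52, 44))])
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_seeds):
        stack, truth = synth.make_coloc_pair(rho, geometry,
                                             seed=int(rng.integers(2**31)),
                                             anisotropy=True)
        mask = truth.masks["cell"]
        obs = coloc.compute_pcc(stack.channel(0), stack.channel(1), mask)
        rot, _ = coloc.rotation_null_pcc(stack.channel(0), stack.channel(1), mask)
        deltas.append(obs - abs(rot))
    return {"median_attenuation": float(np.median(deltas)), "n_seeds": n_seeds}


def type_one_error(seed: int = 0, n_reps: int = 1000, n_per_group: int = 20,
                   alpha: float = 0.05) -> dict:
    """Empirical size of the two-group test under the null (normal samples)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        out = stats_report.compare_groups(
            {"a": rng.normal(0.0, 1.0, n_per_group),
             "b": rng.normal(0.0, 1.0, n_per_group)})
        hits += out.loc[0, "p_raw"] < alpha
    return {"rejection_rate": float(hits / n_reps), "n_reps": n_reps}
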