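"""Ground-truthed synthetic fluorescence microscopy.

Generates the image classes the quantification modules consume — elliptical
nuclei with a bright nuclear-envelope rim, photobleach-and-recovery time
series, correlated channel pairs, and punctate foci in 3D stacks — together
with exact ground truth (masks, true rim contrast, true kinetic parameters,
true channel correlation, true foci volumes), so every estimator in the
pipeline can be scored without real microscopy data.

The generator is deliberately simple optics-free plumbing: no point-spread
function, no light propagation, no chromatin texture. Intensities are
piecewise-constant structures plus additive Gaussian (optionally Poisson)
camera noise; that keeps closed-form expectations available for every
downstream check.

Determinism contract: identical (spec, seed) pairs produce bit-identical
arrays across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageStack, write_tiff


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    """One elliptical nucleus: center (y, x) px, semi-axes (y, x) px,
    orientation angle in degrees (counter-clockwise), interior intensity a.u."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0
    intensity: float = 100.0


@dataclass
class SceneSpec:
    """Parameters of a synthetic nucleus scene.

    ``rim_width_px`` and ``rim_contrast`` define the nuclear-envelope shell:
    pixels of the nucleus whose Euclidean distance to the outside lies in
    (0, rim_width_px] carry ``rim_contrast`` times the nucleoplasm marker
    level. ``rim_contrast = 1`` therefore yields a uniform marker channel.
    """

    image_shape: tuple[int, ...] = (128, 128)
    nuclei: list[NucleusSpec] = field(default_factory=list)
    rim_width_px: int = 3
    rim_contrast: float = 1.0
    marker_level: float = 100.0
    foci_count: int = 0
    foci_volume_voxels: int = 20
    foci_intensity: float = 400.0
    background_level: float = 10.0
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0
    z_semi_axis: float | None = None  # ellipsoid half-height for 3D scenes
    forbid_overlap: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.rim_contrast < 0:
            raise ValueError("rim contrast must be >= 0")
        if self.background_level < 0 or self.marker_level < 0:
            raise ValueError("intensities must be >= 0")
        if not self.nuclei:
            raise ValueError("scene needs at least one nucleus")
        for nuc in self.nuclei:
            if min(nuc.semi_axes) <= self.rim_width_px:
                raise ValueError(
                    f"rim band ({self.rim_width_px} px) must be narrower than the "
                    f"nucleus minor semi-axis ({min(nuc.semi_axes)} px)"
                )
            if nuc.intensity < 0:
                raise ValueError("nucleus intensity must be >= 0")


@dataclass
class FrapSpec:
    """Parameters of a synthetic photobleach-and-recovery experiment.

    The bleached-region true signal follows the reaction-limited single
    exponential ``S_b(t) = exp(-beta*t_acq) * [D + M*(P - D)*(1 - exp(-k t))]``
    with prebleach level ``P``, immediate post-bleach level
    ``D = postbleach_depth * P``, mobile fraction ``M`` and rate ``k``;
    the unbleached remainder of the structure loses exactly the signal the
    bleached region gains, so total structure signal is conserved up to the
    multiplicative acquisition-bleaching factor ``exp(-beta * t_acq)``
    (``t_acq`` = time since the first acquired frame).
    """

    prebleach_level: float = 200.0
    postbleach_depth: float = 0.3  # fraction of prebleach remaining at t=0+
    mobile_fraction: float = 0.5
    rate: float = 0.05  # 1/s
    acquisition_bleach_rate: float = 0.0  # 1/s
    background_level: float = 10.0
    n_prebleach_frames: int = 10
    n_postbleach_frames: int = 300  # 300 frames at 1 s, the acquisition used
    frame_interval: float = 1.0  # s
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0
    bleach_roi_halfwidth: int = 4  # px; square bleach region ~ a few µm
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.postbleach_depth <= 1.0:
            raise ValueError("postbleach_depth must be in [0, 1]")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile fraction must be in [0, 1]")
        if self.rate <= 0:
            raise ValueError("recovery rate must be > 0")
        if self.acquisition_bleach_rate < 0:
            raise ValueError("acquisition bleach rate must be >= 0")
        if self.n_prebleach_frames < 1 or self.n_postbleach_frames < 1:
            raise ValueError("need at least one pre- and one post-bleach frame")


@dataclass
class GroundTruth:
    """Exact per-dataset truth, sufficient to score every estimator."""

    seed: int
    masks: dict = field(default_factory=dict)  # name -> bool/int ndarray
    rim_contrast: float | None = None
    per_nucleus: pd.DataFrame | None = None  # nucleus table (areas, true ratio)
    foci_table: pd.DataFrame | None = None  # focus_id, nucleus_id, volume...
    frap: dict | None = None  # M, k, beta, P, D, traces
    channel_correlation: float | None = None

    def save(self, directory) -> None:
        """Serialize truth next to a generated dataset (CSV tables + manifest)."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": self.seed, "rim_contrast": self.rim_contrast,
                    "channel_correlation": self.channel_correlation,
                    "masks": sorted(self.masks)}
        if self.frap is not None:
            manifest["frap"] = {k: v for k, v in self.frap.items()
                                if np.isscalar(v)}
        (directory / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
        if self.per_nucleus is not None:
            self.per_nucleus.to_csv(directory / "truth_nuclei.csv", index=False)
        if self.foci_table is not None:
            self.foci_table.to_csv(directory / "truth_foci.csv", index=False)
        for name, mask in self.masks.items():
            np.savetxt(directory / f"mask_{name}.csv", np.asarray(mask, dtype=int),
                       fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def ellipse_mask(shape: tuple[int, int], nucleus: NucleusSpec) -> np.ndarray:
    """Boolean mask of a rotated filled ellipse on a (y, x) grid."""
    cy, cx = nucleus.center
    ay, ax = nucleus.semi_axes
    theta = np.deg2rad(nucleus.angle_deg)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def rim_core_split(mask: np.ndarray, rim_width_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Inner rim band (distance-to-outside in (0, width]) and core (> width)."""
    dist = ndimage.distance_transform_edt(mask)
    rim = mask & (dist <= rim_width_px)
    core = mask & (dist > rim_width_px)
    return rim, core


def _apply_noise(data: np.ndarray, rng: np.random.Generator,
                 noise_sigma: float, poisson_scale: float) -> np.ndarray:
    if poisson_scale > 0:
        data = rng.poisson(np.clip(data, 0, None) * poisson_scale) / poisson_scale
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return np.clip(data, 0.0, None)


# ---------------------------------------------------------------------------
# Nucleus scenes (rim-ratio inputs)
# ---------------------------------------------------------------------------

def make_nucleus_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Two-channel scene: DAPI-like nuclei plus an NE-marker channel.

    The marker channel is ``background`` outside nuclei and
    ``background + marker_level`` in the nucleoplasm core; the rim shell
    carries ``rim_contrast`` times that interior level, so on the true masks
    mean(rim)/mean(core) equals ``rim_contrast`` exactly before noise.
    """
    spec.validate()
    if len(spec.image_shape) != 2:
        raise ValueError("nucleus scenes are 2D (y, x)")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)

    labels = np.zeros(shape, dtype=np.int32)
    dapi = np.full(shape, spec.background_level, dtype=float)
    marker = np.full(shape, spec.background_level, dtype=float)
    rows = []
    for i, nuc in enumerate(spec.nuclei, start=1):
        mask = ellipse_mask(shape, nuc)
        if spec.forbid_overlap and np.any(labels[mask] > 0):
            raise ValueError(f"nucleus {i} overlaps a previous nucleus")
        labels[mask] = i
        rim, core = rim_core_split(mask, spec.rim_width_px)
        dapi[mask] = spec.background_level + nuc.intensity
        interior = spec.background_level + spec.marker_level
        marker[core] = interior
        marker[rim] = spec.rim_contrast * interior  # rim:core ratio is exactly r
        rows.append({"nucleus_id": i, "area_px": int(mask.sum()),
                     "rim_px": int(rim.sum()), "core_px": int(core.sum()),
                     "true_ratio": spec.rim_contrast})

    data = np.stack([dapi, marker])
    data = _apply_noise(data, rng, spec.noise_sigma, spec.poisson_scale)
    stack = ImageStack(data, ("channel", "y", "x"))
    rim_all, core_all = rim_core_split(labels > 0, spec.rim_width_px)
    truth = GroundTruth(
        seed=spec.seed,
        masks={"labels": labels, "rim": rim_all, "nucleoplasm": core_all},
        rim_contrast=spec.rim_contrast,
        per_nucleus=pd.DataFrame(rows),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP time series
# ---------------------------------------------------------------------------

def frap_bleach_trace(t: np.ndarray, P: float, D: float, M: float, k: float) -> np.ndarray:
    """Noise- and bleaching-free bleached-ROI signal for post-bleach times t >= 0."""
    return D + M * (P - D) * (1.0 - np.exp(-k * t))


def make_frap_series(spec: FrapSpec, geometry: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse of one structure photobleached at t = 0.

    The first nucleus of ``geometry`` is the bleachable structure; a square
    bleach ROI sits at its center. Signal lost from the bleached region at
    the bleach is gone; subsequent recovery of the bleached region is fed by
    an equal loss spread over the unbleached remainder (conservation), all
    scaled by the acquisition-bleaching factor. Drift, background and noise
    are applied on top.
    """
    spec.validate()
    geometry.validate()
    shape = tuple(geometry.image_shape)
    nuc = geometry.nuclei[0]
    structure = ellipse_mask(shape, nuc)

    cy, cx = int(round(nuc.center[0])), int(round(nuc.center[1]))
    h = spec.bleach_roi_halfwidth
    bleach = np.zeros(shape, dtype=bool)
    bleach[cy - h : cy + h + 1, cx - h : cx + h + 1] = True
    bleach &= structure
    unbleached = structure & ~bleach
    n_b, n_u = int(bleach.sum()), int(unbleached.sum())
    if n_b == 0 or n_u == 0:
        raise ValueError("bleach ROI must be a proper sub-region of the structure")

    P = spec.prebleach_level
    D = spec.postbleach_depth * P
    M, k, beta = spec.mobile_fraction, spec.rate, spec.acquisition_bleach_rate
    dt = spec.frame_interval
    n_pre, n_post = spec.n_prebleach_frames, spec.n_postbleach_frames

    # time relative to bleach; acquisition clock starts at the first frame
    t_rel = np.concatenate([(np.arange(n_pre) - n_pre) * dt, np.arange(n_post) * dt])
    t_acq = t_rel - t_rel[0]
    fade = np.exp(-beta * t_acq)

    s_b = np.where(t_rel < 0, P, frap_bleach_trace(np.clip(t_rel, 0, None), P, D, M, k))
    # conservation: unbleached pixels surrender what the bleached region regains
    s_u = np.where(t_rel < 0, P, P - (n_b / n_u) * (s_b - D))
    s_b, s_u = s_b * fade, s_u * fade

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((len(t_rel),) + shape, dtype=float)
    dy, dx = spec.drift_per_frame
    for i in range(len(t_rel)):
        frame = np.full(shape, spec.background_level, dtype=float)
        frame[unbleached] = spec.background_level + s_u[i]
        frame[bleach] = spec.background_level + s_b[i]
        sy, sx = dy * i, dx * i
        if sy or sx:
            if float(sy).is_integer() and float(sx).is_integer():
                frame = np.roll(frame, (int(sy), int(sx)), axis=(0, 1))
            else:
                frame = ndimage.shift(frame, (sy, sx), order=1,
                                      mode="constant", cval=spec.background_level)
        frames[i] = frame
    frames = _apply_noise(frames, rng, spec.noise_sigma, spec.poisson_scale)

    stack = ImageStack(frames, ("time", "y", "x"))
    truth = GroundTruth(
        seed=spec.seed,
        masks={"structure": structure, "bleach": bleach, "unbleached": unbleached},
        frap={"mobile_fraction": M, "rate": k, "beta": beta,
              "prebleach_level": P, "postbleach_level": D,
              "t": t_rel, "true_bleach_trace": s_b, "true_unbleached_trace": s_u,
              "n_prebleach": n_pre, "frame_interval": dt,
              "drift_per_frame": spec.drift_per_frame},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Correlated channel pairs (colocalization inputs)
# ---------------------------------------------------------------------------

def make_coloc_pair(rho: float, geometry: SceneSpec, seed: int | None = None,
                    *, anisotropy: bool = False,
                    smoothing_sigma: float = 2.0) -> tuple[ImageStack, GroundTruth]:
    """Two-channel image with target Pearson correlation ``rho`` inside the cell mask.

    Within the mask (union of the scene's nuclei), channel 2 is the mixture
    ``rho * z1 + sqrt(1 - rho^2) * z2`` of the standardized channel-1 field
    and an independent field, then affinely rescaled to non-negative
    intensities — an affine map that leaves the Pearson coefficient intact.
    With ``anisotropy`` the underlying texture is elongated along y, so a 90
    degree rotation destroys spatial registration and the rotation null is
    informative.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    geometry.validate()
    if seed is None:
        seed = geometry.seed
    shape = tuple(geometry.image_shape)
    mask = np.zeros(shape, dtype=bool)
    for nuc in geometry.nuclei:
        mask |= ellipse_mask(shape, nuc)
    if mask.sum() < 10:
        raise ValueError("degenerate mask: fewer than 10 pixels")

    rng = np.random.default_rng(seed)
    sigma = (4.0 * smoothing_sigma, smoothing_sigma * 0.5) if anisotropy \
        else (smoothing_sigma, smoothing_sigma)

    def _field() -> np.ndarray:
        f = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
        mu, sd = f[mask].mean(), f[mask].std()
        return (f - mu) / sd

    z1 = _field()
    if abs(rho) == 1.0:
        z2_mix = np.sign(rho) * z1  # independent field unused: exact correlation
    else:
        z2_mix = rho * z1 + np.sqrt(1.0 - rho**2) * _field()

    level, gain = geometry.marker_level, geometry.marker_level / 4.0
    ch1 = np.where(mask, level + gain * z1, geometry.background_level)
    ch2 = np.where(mask, level + gain * z2_mix, geometry.background_level)
    offset = min(ch1.min(), ch2.min())
    if offset < 0:  # shift, not clip: clipping would perturb the correlation
        ch1, ch2 = ch1 - offset, ch2 - offset

    data = _apply_noise(np.stack([ch1, ch2]), rng,
                        geometry.noise_sigma, geometry.poisson_scale)
    stack = ImageStack(data, ("channel", "y", "x"))
    truth = GroundTruth(seed=seed, masks={"cell": mask}, channel_correlation=rho)
    return stack, truth


# ---------------------------------------------------------------------------
# Punctate foci in 3D stacks (chromocenter / PLA inputs)
# ---------------------------------------------------------------------------

def grow_component(allowed: np.ndarray, seed_point: tuple[int, ...],
                   volume: int) -> np.ndarray:
    """Connected component of exactly ``volume`` voxels grown around a seed.

    Voxels of ``allowed`` are added in order of Euclidean distance from the
    seed (ties broken lexicographically), producing a compact ball-like blob
    that is 26-connected (2D: 8-connected) by construction.
    """
    if volume <= 0:
        raise ValueError("requested component volume must be > 0")
    if not allowed[seed_point]:
        raise ValueError("seed point outside the allowed region")
    coords = np.argwhere(allowed)
    d2 = ((coords - np.asarray(seed_point)) ** 2).sum(axis=1)
    order = np.lexsort(tuple(coords.T[::-1]) + (d2,))
    if len(order) < volume:
        raise ValueError("allowed region smaller than requested volume")
    chosen = coords[order[:volume]]
    out = np.zeros(allowed.shape, dtype=bool)
    out[tuple(chosen.T)] = True
    return out


def make_foci_stack(spec: SceneSpec,
                    volumes: list[int] | None = None) -> tuple[ImageStack, GroundTruth]:
    """3D stack (z, y, x) with bright foci of prescribed voxel volumes.

    The nucleus is the ellipsoid extruded from the first nucleus of ``spec``
    (half-height ``z_semi_axis``, default half the stack depth minus one).
    ``volumes`` overrides the per-focus volume list; by default
    ``foci_count`` foci of ``foci_volume_voxels`` voxels each are placed at
    random non-adjacent seeds inside the nucleus. The truth table lists each
    placed component's exact voxel volume.
    """
    spec.validate()
    if len(spec.image_shape) != 3:
        raise ValueError("foci stacks are 3D (z, y, x)")
    if volumes is None:
        volumes = [spec.foci_volume_voxels] * spec.foci_count
    if any(v <= 0 for v in volumes):
        raise ValueError("foci volumes must be > 0 voxels")

    nz, ny, nx = spec.image_shape
    nuc = spec.nuclei[0]
    plane = ellipse_mask((ny, nx), nuc)
    az = spec.z_semi_axis if spec.z_semi_axis is not None else max(nz / 2.0 - 1.0, 1.0)
    cz = (nz - 1) / 2.0
    zz = ((np.arange(nz) - cz) / az) ** 2
    cy, cx = nuc.center
    ay, ax = nuc.semi_axes
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    nucleus = (zz[:, None, None] + r2[None]) <= 1.0
    nucleus &= plane[None]

    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.image_shape, spec.background_level, dtype=float)
    data[nucleus] = spec.background_level + spec.marker_level
    foci_labels = np.zeros(spec.image_shape, dtype=np.int32)
    free = nucleus.copy()
    rows = []
    for fid, vol in enumerate(volumes, start=1):
        placed = False
        for _ in range(200):  # rejection-sample a seed whose blob fits untouched
            candidates = np.argwhere(free)
            if len(candidates) == 0:
                break
            seed_pt = tuple(candidates[rng.integers(len(candidates))])
            try:
                blob = grow_component(free, seed_pt, vol)
            except ValueError:
                break
            foci_labels[blob] = fid
            # keep a 1-voxel moat so separate foci never merge
            free &= ~ndimage.binary_dilation(blob, ndimage.generate_binary_structure(3, 3))
            zc, yc, xc = np.argwhere(blob).mean(axis=0)
            rows.append({"focus_id": fid, "nucleus_id": 1, "volume_voxels": int(vol),
                         "centroid_z": zc, "centroid_y": yc, "centroid_x": xc})
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place focus of {vol} voxels inside the nucleus")
    data[foci_labels > 0] = spec.background_level + spec.marker_level + spec.foci_intensity
    data = _apply_noise(data, rng, spec.noise_sigma, spec.poisson_scale)

    stack = ImageStack(data, ("z", "y", "x"))
    truth = GroundTruth(
        seed=spec.seed,
        masks={"nucleus": nucleus, "foci_labels": foci_labels},
        foci_table=pd.DataFrame(rows, columns=["focus_id", "nucleus_id", "volume_voxels",
                                               "centroid_z", "centroid_y", "centroid_x"]),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def save_dataset(directory, stack: ImageStack, truth: GroundTruth,
                 spec=None) -> None:
    """Write a generated dataset: 16-bit TIFF + truth CSVs + run manifest."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = write_tiff(directory / "image.tif", stack)
    truth.save(directory)
    manifest = {"axes": list(stack.axes), "intensity_scale": scale}
    if spec is not None:
        manifest["spec"] = json.loads(json.dumps(asdict(spec), default=str))
    (directory / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
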