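"""Synthetic laser-ablation procedures for end-to-end pipeline testing.

A procedure is emulated as a radially spreading Gaussian temperature field on
a liver surface: during heating the field's spatial maximum is driven to the
scheduled step targets (60..110 degC after a 36 degC baseline step), and
after laser-off it decays exponentially toward baseline.  Reflectance spectra
at each pixel are a deterministic, injective function of the peak temperature
reached there (coagulation whitening followed by carbonization darkening),
plus i.i.d. band noise.  Fiducial markers, specular highlights and a small
inter-modality affine misalignment complete the scene.

Every ground truth the downstream pipeline is supposed to recover is stored
on the generated object: per-step peak maps, damage label maps, the true
HS->IR affine per step, the specularity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EXCLUDED, NO_DAMAGE, RING, THERMO, Hypercube, MarkerSet, TemperatureMap
from .registration import ROI, AffineTransform2D

# Histology severity grades per damage class (mean, sd) for the two assessed
# compartments, used as the synthetic histology-score generator's defaults.
HISTOLOGY_SCORE_DEFAULTS = {
    "glisson": {"no_damage": (0.133, 0.103), "ring": (1.050, 0.4195), "thermo": (1.975, 0.3738)},
    "parenchyma": {"no_damage": (0.1667, 0.1291), "ring": (0.1583, 0.2582), "thermo": (1.000, 0.1581)},
}

CLASS_NAMES = {NO_DAMAGE: "no_damage", RING: "ring", THERMO: "thermo"}


@dataclass
class SceneParams:
    """Study conditions for one synthetic ablation procedure.

    Defaults give a desk-scale scene: 64x64 frames, a 30 px ROI, the full
    10-step acquisition schedule (baseline 36 degC, heating thresholds
    60..110 degC, three post-treatment decay steps at 1/3/5 min).
    """

    shape: tuple[int, int] = (64, 64)  # (height, width)
    n_bands: int = 100
    wavelength_range: tuple[float, float] = (500.0, 995.0)
    center: tuple[float, float] | None = None  # (x, y); None = image centre
    sigma: float = 6.0  # Gaussian heat-spread, px
    heating_targets: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0, 100.0, 110.0)
    baseline: float = 36.0
    post_times_s: tuple[float, ...] = (60.0, 180.0, 300.0)
    decay_tau_s: float = 120.0
    step_interval_s: float = 60.0
    n_frames: int = 5
    frame_noise_sd: float = 0.2  # degC, per IR frame
    noise_sd: float = 0.01  # reflectance units, per band
    n_markers: int = 6
    marker_radius: float = 2.0
    marker_ring_radius: float = 24.0
    n_specularities: int = 3
    specular_level: float = 1.2
    misalignment: float = 1.0  # scale factor on the HS->IR affine perturbation
    roi_diameter: float = 30.0
    damage_threshold: float = 50.6  # T*, degC
    char_threshold: float = 100.0  # T_char, degC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not self.damage_threshold < self.char_threshold:
            raise ValueError("damage threshold must be below carbonization threshold")
        if any(b <= a for a, b in zip(self.heating_targets, self.heating_targets[1:])):
            raise ValueError("heating schedule must be strictly increasing")
        if self.heating_targets[0] <= self.baseline:
            raise ValueError("heating targets must exceed baseline")

    @property
    def n_steps(self) -> int:
        return 1 + len(self.heating_targets) + len(self.post_times_s)

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class SyntheticStep:
    """One acquisition step of a synthetic procedure."""

    step_id: int
    cube: Hypercube
    rgb: np.ndarray
    ir_frames: list[TemperatureMap]
    markers_hs: MarkerSet
    markers_ir: MarkerSet
    true_affine: AffineTransform2D  # reference (HS) frame -> IR frame
    gt_current: np.ndarray  # noiseless field in the reference frame, degC
    gt_peak: np.ndarray  # ground-truth running peak, reference frame, degC
    gt_labels: np.ndarray  # damage classes from gt_peak


@dataclass
class SyntheticAblation:
    """A complete synthetic procedure with all ground truths."""

    ablation_id: int
    params: SceneParams
    steps: list[SyntheticStep]
    roi: ROI
    specular_mask: np.ndarray
    histology: pd.DataFrame

    @property
    def wavelengths(self) -> np.ndarray:
        return self.params.wavelengths


# ---------------------------------------------------------------------------
# Temperature fields
# ---------------------------------------------------------------------------


def _step_targets(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-step spatial-maximum temperatures and event timestamps (s)."""
    heat = list(params.heating_targets)
    t_heat = [params.step_interval_s * (i + 1) for i in range(len(heat))]
    t_off = t_heat[-1]
    post = [
        params.baseline
        + (heat[-1] - params.baseline) * np.exp(-dt / params.decay_tau_s)
        for dt in params.post_times_s
    ]
    t_post = [t_off + dt for dt in params.post_times_s]
    targets = np.array([params.baseline] + heat + post)
    times = np.array([0.0] + t_heat + t_post)
    return targets, times


def _gaussian_kernel(params: SceneParams) -> np.ndarray:
    """Radial Gaussian on the pixel grid, normalised to an on-grid maximum of
    1 so that scheduled step targets are met exactly at the hottest pixel."""
    h, w = params.shape
    cx, cy = params.resolved_center()
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    # subtracting the on-grid minimum keeps the normalisation stable as
    # sigma -> 0 (plain g / g.max() underflows to 0/0)
    return np.exp(-(r2 - r2.min()) / (2.0 * params.sigma**2))


def _radial_field(params: SceneParams, target: float) -> np.ndarray:
    """Noiseless surface temperature field whose maximum equals *target*."""
    return params.baseline + (target - params.baseline) * _gaussian_kernel(params)


def generate_temperature_sequence(
    params: SceneParams, rng: np.random.Generator | None = None
) -> list[list[TemperatureMap]]:
    """Reference-frame IR frame bursts for every acquisition step.

    Each step yields ``params.n_frames`` frames: the step's characteristic
    field plus i.i.d. Gaussian frame noise (to exercise frame averaging).
    The characteristic (noiseless) field's spatial maximum equals the step's
    scheduled target exactly.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    targets, times = _step_targets(params)
    bursts: list[list[TemperatureMap]] = []
    for target, t_event in zip(targets, times):
        f = _radial_field(params, target)
        frames = []
        for j in range(params.n_frames):
            noisy = f + rng.normal(0.0, params.frame_noise_sd, size=f.shape)
            ts = t_event - 0.1 * (params.n_frames - 1 - j)
            frames.append(TemperatureMap(np.clip(noisy, 0.0, None), timestamp=ts))
        bursts.append(frames)
    return bursts


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------


def _base_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Healthy liver: dark in the visible, rising past ~590 nm."""
    return 0.05 + 0.40 / (1.0 + np.exp(-(wavelengths - 590.0) / 25.0))


def _coagulated_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Fully coagulated tissue: brighter and flatter (scattering increase)."""
    return 0.30 + 0.35 / (1.0 + np.exp(-(wavelengths - 560.0) / 40.0))


def spectrum_from_peak_temperature(
    peak: float | np.ndarray,
    wavelengths: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline: float = 36.0,
    char_threshold: float = 100.0,
) -> np.ndarray:
    """Noiseless-injective map from peak temperature to a reflectance spectrum.

    Coagulation mixes the healthy spectrum toward a brighter, flatter one as
    the peak rises from *baseline* to *char_threshold*; above that,
    carbonization darkens the spectrum broadband.  Because the two regimes
    change the spectral *shape* differently, the noiseless map is injective
    over [36, 120] degC, which makes per-pixel regression well-posed.

    *peak* may be a scalar or an array; the band axis is appended last.
    """
    p = np.asarray(peak, dtype=np.float64)
    if np.any(p < baseline - 1e-9):
        raise ValueError(f"peak temperature below baseline {baseline} degC")
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    b = _base_spectrum(wavelengths)
    d = _coagulated_spectrum(wavelengths)
    u = np.clip((p - baseline) / (char_threshold - baseline), 0.0, 1.0)
    v = np.clip((p - char_threshold) / 20.0, 0.0, 1.0)
    spec = (1.0 - u[..., None]) * b + u[..., None] * d
    spec = spec * (1.0 - 0.55 * v[..., None])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        spec = spec + rng.normal(0.0, noise_sd, size=spec.shape)
    return spec


def labels_from_peak(
    peak: np.ndarray, damage_threshold: float, char_threshold: float
) -> np.ndarray:
    """Damage classes as a deterministic function of the peak map."""
    labels = np.full(peak.shape, NO_DAMAGE, dtype=np.uint8)
    labels[peak >= damage_threshold] = RING
    labels[peak >= char_threshold] = THERMO
    return labels


# ---------------------------------------------------------------------------
# Scene composition
# ---------------------------------------------------------------------------


def _random_affine(
    rng: np.random.Generator, magnitude: float
) -> AffineTransform2D:
    """A small rigid-ish perturbation: rotation, isotropic scale, translation."""
    angle = rng.uniform(-2.0, 2.0) * np.pi / 180.0 * magnitude
    scale = 1.0 + rng.uniform(-0.02, 0.02) * magnitude
    tx, ty = rng.uniform(-2.0, 2.0, size=2) * magnitude
    c, s = np.cos(angle) * scale, np.sin(angle) * scale
    return AffineTransform2D(np.array([[c, -s, tx], [s, c, ty]]))


def _marker_positions(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    cx, cy = params.resolved_center()
    # evenly spaced with jitter: guarantees marker disks never merge
    n = params.n_markers
    angles = (
        rng.uniform(0, 2 * np.pi)
        + np.arange(n) * 2 * np.pi / n
        + rng.uniform(-0.15, 0.15, n)
    )
    radii = params.marker_ring_radius * (1.0 + rng.uniform(-0.05, 0.05, n))
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def _paint_disks(
    img: np.ndarray, points: np.ndarray, radius: float, value: float
) -> None:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for x, y in points:
        img[(xx - x) ** 2 + (yy - y) ** 2 <= radius**2] = value


def generate_ablation(params: SceneParams, ablation_id: int = 0) -> SyntheticAblation:
    """Compose one complete synthetic procedure.

    Hypercube pixels are synthesized from the ground-truth running peak map;
    markers are rendered as bright broadband disks at affine-consistent
    positions in both modalities; specular highlights are near-saturating
    broadband pixels inside the ROI.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    wl = params.wavelengths
    cx, cy = params.resolved_center()
    roi = ROI((cx, cy), params.roi_diameter)

    markers_ref = _marker_positions(params, rng)
    base_affine = _random_affine(rng, params.misalignment)

    # Specular highlights: small clusters inside the ROI.
    specular = np.zeros((h, w), dtype=bool)
    r_roi = params.roi_diameter / 2.0
    for _ in range(params.n_specularities):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.9) * r_roi
        px = int(round(cx + rad * np.cos(ang)))
        py = int(round(cy + rad * np.sin(ang)))
        specular[max(py - 1, 0) : py + 1, max(px - 1, 0) : px + 1] = True

    bursts = generate_temperature_sequence(params, rng)
    targets, times = _step_targets(params)

    steps: list[SyntheticStep] = []
    running_target = -np.inf
    for i, (target, t_event, frames) in enumerate(zip(targets, times, bursts), start=1):
        running_target = max(running_target, target)
        gt_current = _radial_field(params, target)
        gt_peak = _radial_field(params, running_target)
        gt_labels = labels_from_peak(
            gt_peak, params.damage_threshold, params.char_threshold
        )

        # hypercube from the ground-truth peak map
        data = spectrum_from_peak_temperature(
            gt_peak, wl, noise_sd=params.noise_sd, rng=rng,
            baseline=params.baseline, char_threshold=params.char_threshold,
        )
        # markers: bright flat reflectors
        marker_mask = np.zeros((h, w), dtype=bool)
        _paint_disks(marker_mask, markers_ref, params.marker_radius, True)
        data[marker_mask] = 0.95 + (
            rng.normal(0.0, params.noise_sd, size=(int(marker_mask.sum()), len(wl)))
            if params.noise_sd > 0 else 0.0
        )
        data[specular] = params.specular_level
        cube = Hypercube(np.clip(data, 0.0, None), wl, step_id=i)

        # simple RGB render from three visible bands
        rgb_bands = [np.argmin(np.abs(wl - t)) for t in (610.0, 545.0, 505.0)]
        rgb = np.clip(cube.data[:, :, rgb_bands], 0.0, 1.0)

        # per-step HS->IR affine: base misalignment + tiny per-step jitter
        jitter = _random_affine(rng, 0.1 * params.misalignment)
        affine = base_affine.compose(jitter)
        markers_ir_pts = affine.apply(markers_ref)
        if params.misalignment > 0:
            pad = params.marker_radius
            out = (
                (markers_ir_pts[:, 0] < pad) | (markers_ir_pts[:, 0] > w - 1 - pad)
                | (markers_ir_pts[:, 1] < pad) | (markers_ir_pts[:, 1] > h - 1 - pad)
            )
            if np.any(out) or np.any(
                (markers_ref[:, 0] < pad) | (markers_ref[:, 0] > w - 1 - pad)
                | (markers_ref[:, 1] < pad) | (markers_ref[:, 1] > h - 1 - pad)
            ):
                raise ValueError("markers placed outside image bounds")

        # IR frames observed through the affine: IR(p) = field(affine^-1(p))
        ir_frames = []
        inv = affine.inverse()
        yy, xx = np.mgrid[0:h, 0:w]
        src = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
        # same on-grid normalisation as the reference-frame field
        r2min = ((xx - cx) ** 2 + (yy - cy) ** 2).min()
        for frame in frames:
            # evaluate the analytic field at the inverse-mapped coordinates
            r2 = (src[:, 0] - cx) ** 2 + (src[:, 1] - cy) ** 2
            fld = params.baseline + (target - params.baseline) * np.exp(
                -(r2 - r2min) / (2.0 * params.sigma**2)
            )
            noisy = fld.reshape(h, w) + (
                rng.normal(0.0, params.frame_noise_sd, size=(h, w))
                if params.frame_noise_sd > 0 else 0.0
            )
            ir_frames.append(
                TemperatureMap(np.clip(noisy, 0.0, None), timestamp=frame.timestamp)
            )

        steps.append(
            SyntheticStep(
                step_id=i,
                cube=cube,
                rgb=rgb,
                ir_frames=ir_frames,
                markers_hs=MarkerSet(markers_ref, image_ref=f"hs_step{i}"),
                markers_ir=MarkerSet(markers_ir_pts, image_ref=f"ir_step{i}"),
                true_affine=affine,
                gt_current=gt_current,
                gt_peak=gt_peak,
                gt_labels=gt_labels,
            )
        )

    histology = _histology_scores(steps[-1].gt_labels, roi, rng)
    return SyntheticAblation(
        ablation_id=ablation_id,
        params=params,
        steps=steps,
        roi=roi,
        specular_mask=specular,
        histology=histology,
    )


def _histology_scores(
    final_labels: np.ndarray, roi: ROI, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-class severity grades for the two assessed compartments, drawn
    around the default class means (clipped at 0)."""
    rows = []
    for compartment, means in HISTOLOGY_SCORE_DEFAULTS.items():
        for cls, (mu, sd) in means.items():
            rows.append(
                {
                    "class": cls,
                    "compartment": compartment,
                    "score": max(0.0, rng.normal(mu, sd)),
                }
            )
    return pd.DataFrame(rows)


def generate_study(
    params: SceneParams, n_ablations: int = 6
) -> list[SyntheticAblation]:
    """Generate *n_ablations* procedures with slight per-ablation variation
    (heat-spread sigma +-10%, ablation centre jitter +-2 px), seeded from
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    ablations = []
    for i in range(n_ablations):
        cx, cy = params.resolved_center()
        p = replace(
            params,
            sigma=params.sigma * rng.uniform(0.9, 1.1),
            center=(cx + rng.uniform(-2, 2), cy + rng.uniform(-2, 2)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ablations.append(generate_ablation(p, ablation_id=i))
    return ablations
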