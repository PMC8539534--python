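"""Per-pixel training samples, specularity exclusion and cross-validation folds.

Every pixel of the ROI at every acquisition step is a sample: an ``l x w x w``
spectral sub-volume centred on it, labelled either with a damage class (from
the annotations) or with the peak temperature reached there (from the aligned
IR pipeline).  Specular pixels and pixels lacking aligned coverage are
excluded.  Evaluation uses strict leave-one-ablation-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EXCLUDED, Hypercube
from .registration import fit_affine, warp_image
from .synthetic import SyntheticAblation
from .thermal import average_frames, build_peak_maps


@dataclass
class PatchSample:
    """One training/evaluation sample: spectral sub-volume + supervision."""

    patch: np.ndarray  # (l, w, w)
    x: int
    y: int
    step_id: int
    ablation_id: int
    label: float | int


@dataclass
class FoldSplit:
    """One leave-one-ablation-out fold."""

    fold: int
    train_ids: tuple[int, ...]
    test_id: int


def make_folds(ablation_ids: list[int], n_folds: int | None = None) -> list[FoldSplit]:
    """Strict leave-one-ablation-out folds: each ablation is the held-out
    test procedure exactly once, so ``n_folds`` must equal the number of
    ablations."""
    ids = list(ablation_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ablation ids must be unique")
    if n_folds is None:
        n_folds = len(ids)
    if n_folds != len(ids):
        raise ValueError(
            f"n_folds={n_folds} but {len(ids)} ablations; the validation "
            "scheme is strictly leave-one-ablation-out"
        )
    return [
        FoldSplit(fold=i + 1, train_ids=tuple(x for x in ids if x != held), test_id=held)
        for i, held in enumerate(ids)
    ]


def detect_specularity(
    cube: Hypercube | np.ndarray,
    tau: float = 0.95,
    min_bands: int = 50,
    rule=None,
) -> np.ndarray:
    """Flag specular-reflection pixels (they carry no usable spectral signal).

    Default rule: reflectance >= *tau* in at least *min_bands* bands, i.e.
    broadband near-saturation.  A custom ``rule(data) -> bool mask`` or an
    externally supplied mask can replace it.
    """
    data = cube.data if isinstance(cube, Hypercube) else np.asarray(cube)
    if rule is not None:
        return np.asarray(rule(data), dtype=bool)
    return (data >= tau).sum(axis=2) >= min_bands


def extract_patch(cube: Hypercube | np.ndarray, center: tuple[int, int], w: int = 5) -> np.ndarray:
    """The ``l x w x w`` sub-volume centred on pixel ``center=(x, y)``.

    Windows that exceed the image bounds are replicate-padded.  Returned axes
    are ``(band, dy, dx)``.
    """
    data = cube.data if isinstance(cube, Hypercube) else np.asarray(cube)
    h, wid = data.shape[:2]
    x, y = center
    if not (0 <= x < wid and 0 <= y < h):
        raise ValueError(f"patch centre ({x}, {y}) outside image {wid}x{h}")
    half = w // 2
    iy = np.clip(np.arange(y - half, y + half + 1), 0, h - 1)
    ix = np.clip(np.arange(x - half, x + half + 1), 0, wid - 1)
    patch = data[np.ix_(iy, ix)]  # (w, w, l)
    return np.moveaxis(patch, 2, 0)


def aligned_peak_maps(ablation: SyntheticAblation, k_frames: int = 5):
    """Run the IR half of the pipeline for one procedure.

    For each step: average the last *k_frames* IR frames into a
    characteristic map, fit the marker affine (IR -> reference), warp the map
    into the reference frame, then take running per-pixel maxima.  Returns
    ``(peak_maps, coverages)``.
    """
    aligned, coverages = [], []
    shape = ablation.params.shape
    for step in ablation.steps:
        char = average_frames(step.ir_frames, k=k_frames)
        transform = fit_affine(step.markers_ir, step.markers_hs)
        warped, cov = warp_image(
            char.data, transform, out_shape=shape, interpolation="bilinear"
        )
        aligned.append(warped)
        coverages.append(cov)
    return build_peak_maps(aligned, coverages), coverages


def build_samples(
    ablations: list[SyntheticAblation],
    mode: str = "classes",
    *,
    patch_width: int = 5,
    k_frames: int = 5,
    specularity_tau: float = 0.95,
    specularity_min_bands: int = 50,
    max_per_step: int | None = None,
    rng: np.random.Generator | int | None = None,
    min_label: float = 1.0,
) -> "SampleSet":
    """Assemble the per-pixel sample index for a set of procedures.

    ``mode='classes'`` labels each pixel with its annotated damage class;
    ``mode='peak_temp'`` labels it with the peak temperature (degC) from the
    aligned IR pipeline.  One sample per (ablation, step, ROI pixel), minus
    specular pixels and pixels without aligned coverage.  *max_per_step*
    randomly subsamples each (ablation, step) cell to bound the dataset size
    (seeded via *rng*); patches themselves are materialised lazily.
    """
    if mode not in ("classes", "peak_temp"):
        raise ValueError("mode must be 'classes' or 'peak_temp'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    cubes: dict[tuple[int, int], np.ndarray] = {}
    n_excluded = 0
    for abl in ablations:
        roi_mask = abl.roi.mask(abl.params.shape)
        peaks = None
        if mode == "peak_temp":
            peaks, _ = aligned_peak_maps(abl, k_frames=k_frames)
        for si, step in enumerate(abl.steps):
            cubes[(abl.ablation_id, step.step_id)] = step.cube.data
            specular = detect_specularity(
                step.cube, tau=specularity_tau, min_bands=specularity_min_bands
            )
            usable = roi_mask & ~specular
            if mode == "classes":
                labels = step.gt_labels
                usable &= labels != EXCLUDED
            else:
                labels = peaks[si].data
                usable &= peaks[si].valid & np.isfinite(labels) & (labels >= min_label)
            n_excluded += int(roi_mask.sum() - usable.sum())
            ys, xs = np.nonzero(usable)
            if max_per_step is not None and len(ys) > max_per_step:
                sel = rng.choice(len(ys), size=max_per_step, replace=False)
                ys, xs = ys[sel], xs[sel]
            for y, x in zip(ys, xs):
                rows.append(
                    (abl.ablation_id, step.step_id, int(x), int(y), labels[y, x])
                )
    index = pd.DataFrame(
        rows, columns=["ablation", "step", "x", "y", "label"]
    )
    if index.empty:
        warnings.warn("no usable samples (all pixels excluded?)", stacklevel=2)
    return SampleSet(index=index, cubes=cubes, patch_width=patch_width,
                     mode=mode, n_excluded=n_excluded)


@dataclass
class SampleSet:
    """Sample index plus references to the source cubes.

    ``index`` has one row per sample (ablation, step, x, y, label);
    bookkeeping invariant: ``len(index) + n_excluded`` equals the summed ROI
    pixel count over all (ablation, step) pairs when no subsampling is used.
    """

    index: pd.DataFrame
    cubes: dict[tuple[int, int], np.ndarray]
    patch_width: int
    mode: str
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.index)

    def subset(self, ablation_ids) -> "SampleSet":
        ids = set(np.atleast_1d(ablation_ids).tolist())
        return SampleSet(
            index=self.index[self.index["ablation"].isin(ids)].reset_index(drop=True),
            cubes=self.cubes, patch_width=self.patch_width, mode=self.mode,
            n_excluded=self.n_excluded,
        )

    def materialize(self) -> tuple[np.ndarray, np.ndarray]:
        """Extract all patches: returns ``(X, y)`` with X of shape
        ``(n, l, w, w)`` float32."""
        n = len(self.index)
        if n == 0:
            raise ValueError("empty sample set")
        first = next(iter(self.cubes.values()))
        l = first.shape[2]
        w = self.patch_width
        X = np.empty((n, l, w, w), dtype=np.float32)
        for i, row in enumerate(self.index.itertuples(index=False)):
            cube = self.cubes[(row.ablation, row.step)]
            X[i] = extract_patch(cube, (row.x, row.y), w)
        y = self.index["label"].to_numpy()
        return X, (y.astype(int) if self.mode == "classes" else y.astype(np.float64))

    def to_patch_samples(self) -> list[PatchSample]:
        X, y = self.materialize()
        return [
            PatchSample(patch=X[i], x=row.x, y=row.y, step_id=row.step,
                        ablation_id=row.ablation, label=y[i])
            for i, row in enumerate(self.index.itertuples(index=False))
        ]
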