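"""Readers/writers for hypercubes, temperature maps, label masks and markers.

Formats
-------
* Hypercubes: ENVI header (``.hdr`` text) + band-sequential (BSQ) float32 raw.
* Temperature maps: single-channel float32 TIFF, or a plain CSV grid.
* Damage label masks: 8-bit paletted PNG with values
  0 = no damage, 1 = ring, 2 = thermo, 255 = excluded.
* Markers: CSV with columns ``id, x, y`` (0-based, x = column, y = row,
  pixel-center convention).
* Histology scores: CSV with columns ``class, score``.

Reflectance values are deliberately *not* clipped to [0, 1]; specular pixels
may exceed 1 and are detected downstream from that signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

# Label codes used across the package.
NO_DAMAGE, RING, THERMO, EXCLUDED = 0, 1, 2, 255

_LABEL_PALETTE = {
    NO_DAMAGE: (250, 220, 80),   # yellow
    RING: (30, 30, 30),          # black
    THERMO: (200, 40, 40),       # red
    EXCLUDED: (255, 255, 255),
}


@dataclass
class Hypercube:
    """A (height, width, bands) relative-reflectance volume.

    ``wavelengths`` holds the per-band centre in nm, strictly increasing.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    step_id: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (height, width, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class TemperatureMap:
    """A 2-D grid of surface temperatures in deg C."""

    data: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("temperature map must be 2-D")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite temperature at (y={bad[0]}, x={bad[1]})"
            )


@dataclass
class MarkerSet:
    """Ordered sub-pixel fiducial coordinates for one image.

    Point order defines the correspondence across images/modalities.
    """

    points: np.ndarray  # (n, 2) array of (x, y)
    image_ref: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# ENVI hypercube I/O
# ---------------------------------------------------------------------------

def write_hypercube(cube: Hypercube, path: str | Path) -> None:
    """Write *cube* as ENVI ``path.hdr`` + raw BSQ float32 ``path.raw``."""
    path = Path(path)
    h, w, b = cube.data.shape
    wl = ", ".join(f"{v:.3f}" for v in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {relative reflectance; coordinates 0-based, "
        "x=column, y=row, pixel-center}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
        f"step id = {cube.step_id}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    # BSQ: band-major ordering on disk
    arr = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f4")
    arr.tofile(path.with_suffix(".raw"))


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI 'key = value' pairs; brace-delimited values may span lines."""
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and "}" not in value:
            buf, in_braces = [value], True
        else:
            fields[key] = value
    return fields


def read_hypercube(path: str | Path, expected_bands: int | None = None) -> Hypercube:
    """Read an ENVI hdr+raw hypercube written by :func:`write_hypercube`.

    Raises ``ValueError`` on a missing/garbled header or when the band count
    does not match *expected_bands*.
    """
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    raw_path = path.with_suffix(".raw")
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"garbled ENVI header {hdr_path}: missing {exc}") from exc
    if fields.get("data type", "4") != "4":
        raise ValueError("only float32 (ENVI data type 4) cubes are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if expected_bands is not None and b != expected_bands:
        raise ValueError(f"cube has {b} bands but configuration requires {expected_bands}")
    wl_field = fields.get("wavelength", "")
    wl = np.array(
        [float(tok) for tok in wl_field.strip(" {}").replace(",", " ").split()],
        dtype=np.float64,
    )
    if wl.size != b:
        raise ValueError(f"header lists {wl.size} wavelengths for {b} bands")
    data = np.fromfile(raw_path, dtype="<f4")
    if data.size != h * w * b:
        raise ValueError(
            f"raw file {raw_path} holds {data.size} values, expected {h * w * b}"
        )
    cube = data.reshape(b, h, w)
    step_id = int(fields.get("step id", 1))
    return Hypercube(np.moveaxis(cube, 0, 2), wl, step_id=step_id)


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(
    raw: np.ndarray, white_ref: np.ndarray, dark_ref: np.ndarray
) -> np.ndarray:
    """Radiance-to-relative-reflectance conversion ``(raw - dark)/(white - dark)``.

    The white reference is a recording of a highly diffuse reflector, the dark
    reference the closed-shutter (dark-current) signal.  All three arrays must
    share one shape.  A zero (or negative) denominator anywhere raises, naming
    the first offending element.
    """
    raw = np.asarray(raw, dtype=np.float64)
    white_ref = np.asarray(white_ref, dtype=np.float64)
    dark_ref = np.asarray(dark_ref, dtype=np.float64)
    if not (raw.shape == white_ref.shape == dark_ref.shape):
        raise ValueError("raw, white and dark references must share one shape")
    denom = white_ref - dark_ref
    bad = denom <= 0
    if np.any(bad):
        idx = tuple(int(v) for v in np.argwhere(bad)[0])
        raise ValueError(
            f"white - dark is {denom[idx]:g} <= 0 at element {idx}; "
            "calibration undefined there"
        )
    return ((raw - dark_ref) / denom).astype(np.float32)


# ---------------------------------------------------------------------------
# Temperature map I/O (float32 TIFF or CSV grid)
# ---------------------------------------------------------------------------

def write_temperature_map(tmap: TemperatureMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        # %.9g round-trips float32 exactly
        np.savetxt(path, tmap.data.astype(np.float32), delimiter=",", fmt="%.9g",
                   header=f"timestamp_s={tmap.timestamp}")
    else:
        tifffile.imwrite(
            path,
            tmap.data.astype(np.float32),
            metadata={"timestamp_s": tmap.timestamp},
        )


def read_temperature_map(path: str | Path) -> TemperatureMap:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        timestamp = 0.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "timestamp_s=" in first:
                timestamp = float(first.split("timestamp_s=")[1])
        data = np.loadtxt(path, delimiter=",", dtype=np.float32, ndmin=2)
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            timestamp = 0.0
            meta = tif.shaped_metadata
            if meta and "timestamp_s" in meta[0]:
                timestamp = float(meta[0]["timestamp_s"])
    if np.any(np.isnan(data)):
        bad = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"NaN temperature at (y={bad[0]}, x={bad[1]}) in {path}")
    return TemperatureMap(data, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Label masks (8-bit paletted PNG)
# ---------------------------------------------------------------------------

def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    codes = set(np.unique(labels).tolist())
    if not codes <= set(_LABEL_PALETTE):
        raise ValueError(f"unknown label codes: {sorted(codes - set(_LABEL_PALETTE))}")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0] * (256 * 3)
    for code, rgb in _LABEL_PALETTE.items():
        palette[3 * code : 3 * code + 3] = rgb
    img.putpalette(palette)
    img.save(Path(path))


def read_label_map(path: str | Path) -> np.ndarray:
    img = Image.open(Path(path))
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Markers / histology tables (CSV)
# ---------------------------------------------------------------------------

def write_markers(markers: MarkerSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(len(markers)),
            "x": markers.points[:, 0],
            "y": markers.points[:, 1],
        }
    )
    df.to_csv(Path(path), index=False)


def read_markers(path: str | Path, image_ref: str = "") -> MarkerSet:
    df = pd.read_csv(Path(path)).sort_values("id")
    return MarkerSet(df[["x", "y"]].to_numpy(float), image_ref=image_ref)


def read_histology_scores(path: str | Path) -> pd.DataFrame:
    """Read a histology score table with columns ``class, score`` (one row per
    assessed sample); scores are non-negative severity grades."""
    df = pd.read_csv(Path(path))
    if not {"class", "score"} <= set(df.columns):
        raise ValueError("histology table needs 'class' and 'score' columns")
    if (df["score"] < 0).any():
        raise ValueError("histology scores must be non-negative")
    return df
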