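"""imzML input/output and the in-memory spectrum-image model.

Only processed-mode (per-pixel centroid arrays) imzML 1.1 is supported,
matching centroided Orbitrap MSI data.  imzML coordinates are 1-based with
x = column and y = row; internally everything is 0-based.  Intensities are
stored as 32-bit floats and m/z as 64-bit floats, the common imzML dialect.

Acquisition metadata that imzML has no controlled vocabulary for (condition,
replicate, solvent, ice matrix) travels in a small YAML sidecar written next
to the .imzML file; :func:`read_imzml` picks it up when present and accepts
an explicit override otherwise.
"""

from __future__ import annotations

import os
import uuid as _uuid
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .ion_images import IonImage

__all__ = [
    "AcquisitionMetadata",
    "PixelSpectrum",
    "SpectrumImage",
    "UnsupportedModeError",
    "read_imzml",
    "write_imzml",
    "tic_image",
    "tissue_mask",
]


class UnsupportedModeError(ValueError):
    """Raised for continuous-mode (profile-layout) imzML files."""


@dataclass
class AcquisitionMetadata:
    """Instrument/run context carried alongside the pixel spectra."""

    spatial_resolution: float = 100.0          # µm per pixel
    scan_range: Tuple[float, float] = (200.0, 800.0)
    polarity: str = "positive"
    injection_time: float = 15.0               # ms, fixed (AGC off)
    intensity_units: str = "charges per second"
    condition: Optional[str] = None            # e.g. healthy / diseased
    replicate_id: Optional[str] = None
    solvent: str = "standard"                  # standard | doped
    ice_matrix: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.scan_range
        if not lo < hi:
            raise ValueError("scan_range low must be < high")
        if self.spatial_resolution <= 0:
            raise ValueError("spatial_resolution must be positive")
        self.scan_range = (float(lo), float(hi))


@dataclass
class PixelSpectrum:
    """One pixel's centroided spectrum at 0-based grid coordinates."""

    x: int
    y: int
    mz_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError("mz/intensity length mismatch")
        if self.mz_values.size and np.any(np.diff(self.mz_values) <= 0):
            raise ValueError("mz_values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        return float(self.intensities.sum())


class SpectrumImage:
    """Pixel-indexed centroided spectra plus acquisition metadata.

    Stores the spectra in flat arrays (per-pixel slices defined by
    ``offsets``) so that whole-image operations stay vectorised; individual
    :class:`PixelSpectrum` views are created on demand.  At most one
    spectrum per coordinate; missing pixels inside the grid are legal (thin
    or damaged sections leave holes) and are excluded from masks.
    """

    def __init__(self, pixels: Sequence[PixelSpectrum],
                 grid_shape: Tuple[int, int],
                 metadata: Optional[AcquisitionMetadata] = None):
        n_cols, n_rows = grid_shape
        coords = []
        seen = set()
        for p in pixels:
            if not (0 <= p.x < n_cols and 0 <= p.y < n_rows):
                raise ValueError(
                    f"pixel ({p.x},{p.y}) outside grid {grid_shape}"
                )
            if (p.x, p.y) in seen:
                raise ValueError(f"duplicate spectrum at ({p.x},{p.y})")
            seen.add((p.x, p.y))
            coords.append((p.x, p.y))
        self.grid_shape = (int(n_cols), int(n_rows))
        self.metadata = metadata if metadata is not None else AcquisitionMetadata()
        self.coords = np.array(coords, dtype=np.int64).reshape(-1, 2)
        lengths = [p.mz_values.size for p in pixels]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.mzs = (np.concatenate([p.mz_values for p in pixels])
                    if pixels else np.empty(0))
        self.intensities = (np.concatenate([p.intensities for p in pixels])
                            if pixels else np.empty(0))
        self._global_index = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_flat(cls, coords: np.ndarray, offsets: np.ndarray,
                  mzs: np.ndarray, intensities: np.ndarray,
                  grid_shape: Tuple[int, int],
                  metadata: Optional[AcquisitionMetadata] = None) -> "SpectrumImage":
        """Build directly from flat arrays (generator fast path)."""
        obj = cls.__new__(cls)
        obj.grid_shape = (int(grid_shape[0]), int(grid_shape[1]))
        obj.metadata = metadata if metadata is not None else AcquisitionMetadata()
        obj.coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
        obj.offsets = np.asarray(offsets, dtype=np.int64)
        obj.mzs = np.asarray(mzs, dtype=np.float64)
        obj.intensities = np.asarray(intensities, dtype=np.float64)
        obj._global_index = None
        return obj

    # -- access ------------------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def pixel(self, i: int) -> PixelSpectrum:
        o0, o1 = self.offsets[i], self.offsets[i + 1]
        x, y = self.coords[i]
        return PixelSpectrum(int(x), int(y), self.mzs[o0:o1],
                             self.intensities[o0:o1])

    def __iter__(self) -> Iterator[PixelSpectrum]:
        for i in range(self.n_pixels):
            yield self.pixel(i)

    def get(self, x: int, y: int) -> Optional[PixelSpectrum]:
        hits = np.nonzero((self.coords[:, 0] == x) & (self.coords[:, 1] == y))[0]
        return self.pixel(int(hits[0])) if hits.size else None

    def missing_grid(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) grid, True where no spectrum exists."""
        n_cols, n_rows = self.grid_shape
        miss = np.ones((n_rows, n_cols), dtype=bool)
        miss[self.coords[:, 1], self.coords[:, 0]] = False
        return miss

    def global_mz_index(self):
        """All peaks sorted by m/z: (mz, pixel_index, intensity) arrays.

        Cached; the backbone of fast repeated ion-image extraction.
        """
        if self._global_index is None:
            order = np.argsort(self.mzs, kind="stable")
            pixel_ids = np.repeat(
                np.arange(self.n_pixels), np.diff(self.offsets)
            )
            self._global_index = (self.mzs[order], pixel_ids[order],
                                  self.intensities[order])
        return self._global_index


# --------------------------------------------------------------------------
# imzML round trip
# --------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".meta.yaml"


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(str(path))
    return base + _SIDECAR_SUFFIX


def write_imzml(img: SpectrumImage, path, uuid: Optional[_uuid.UUID] = None) -> str:
    """Write processed-mode imzML/ibd (m/z float64, intensity float32).

    ``uuid`` fixes the dataset UUID so regeneration from a fixed seed is
    byte-identical; by default a random UUID is used as in plain pyimzml.
    A YAML sidecar with the acquisition metadata is written next to the
    imzML file.  Returns the imzML path.
    """
    import pyimzml.ImzMLWriter as _wmod
    from pyimzml.ImzMLWriter import ImzMLWriter

    base, _ = os.path.splitext(str(path))
    out_dir = os.path.dirname(base) or "."
    run_name = os.path.basename(base)
    old_uuid4 = _wmod.uuid.uuid4
    old_cwd = os.getcwd()
    if uuid is not None:
        _wmod.uuid.uuid4 = lambda: uuid  # the writer draws its UUID in __init__
    try:
        # write from inside the target directory so the embedded run id is
        # the bare file stem and the bytes do not depend on the output path
        os.chdir(out_dir)
        writer = ImzMLWriter(run_name, mode="processed",
                             polarity=img.metadata.polarity)
    finally:
        _wmod.uuid.uuid4 = old_uuid4
        os.chdir(old_cwd)
    with writer as w:
        for p in img:
            # empty spectra are not representable in processed imzML; such
            # pixels read back as missing.  imzML coordinates are 1-based.
            if p.mz_values.size == 0:
                continue
            w.addSpectrum(p.mz_values, p.intensities, (p.x + 1, p.y + 1, 1))
    meta = asdict(img.metadata)
    meta["grid_shape"] = list(img.grid_shape)
    meta["scan_range"] = list(meta["scan_range"])
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return base + ".imzML"


def read_imzml(path, metadata: Optional[AcquisitionMetadata] = None) -> SpectrumImage:
    """Read a processed-mode imzML/ibd pair into a :class:`SpectrumImage`.

    Metadata precedence: explicit ``metadata`` argument, else the YAML
    sidecar written by :func:`write_imzml`, else defaults.  Continuous-mode
    files raise :class:`UnsupportedModeError`.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    mode_params = parser.metadata.file_description.param_by_name
    if "continuous" in mode_params and "processed" not in mode_params:
        raise UnsupportedModeError(
            f"{path}: continuous-mode imzML is not supported; convert to "
            "processed (centroid) mode"
        )

    if metadata is None:
        sidecar = _sidecar_path(path)
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                raw = yaml.safe_load(fh)
            raw.pop("grid_shape", None)
            raw["scan_range"] = tuple(raw.get("scan_range", (200.0, 800.0)))
            metadata = AcquisitionMetadata(**raw)
        else:
            metadata = AcquisitionMetadata()

    pixels = []
    max_x = max_y = 0
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        pixels.append(PixelSpectrum(int(x) - 1, int(y) - 1,
                                    np.asarray(mzs, dtype=np.float64),
                                    np.asarray(ints, dtype=np.float64)))
        max_x, max_y = max(max_x, int(x)), max(max_y, int(y))
    grid = (max(max_x, parser.imzmldict.get("max count of pixels x", max_x)),
            max(max_y, parser.imzmldict.get("max count of pixels y", max_y)))
    if hasattr(parser, "m") and parser.m is not None:  # pragma: no cover
        parser.m.close()
    return SpectrumImage(pixels, grid, metadata)


# --------------------------------------------------------------------------
# TIC and tissue masking
# --------------------------------------------------------------------------

def tic_image(img: SpectrumImage) -> IonImage:
    """Per-pixel total ion current; missing pixels are 0 and flagged."""
    n_cols, n_rows = img.grid_shape
    values = np.zeros((n_rows, n_cols))
    csum = np.concatenate([[0.0], np.cumsum(img.intensities)])
    tic = csum[img.offsets[1:]] - csum[img.offsets[:-1]]
    if img.n_pixels:
        values[img.coords[:, 1], img.coords[:, 0]] = tic
    return IonImage(values, None, None, "TIC", img.metadata, img.missing_grid())


def tissue_mask(tic: IonImage, method: str = "otsu",
                param: float = 0.1) -> np.ndarray:
    """Boolean on-tissue mask from a TIC image.

    ``otsu`` thresholds the acquired-pixel TIC distribution; ``fraction``
    keeps pixels with TIC ≥ ``param`` × max TIC.  Only the largest connected
    component is kept; missing pixels are never on-tissue.
    """
    from skimage import measure
    from skimage.filters import threshold_otsu

    vals = tic.values[~tic.missing]
    if vals.size == 0 or vals.max() <= 0:
        raise ValueError("cannot build a tissue mask from an all-zero TIC image")
    if method == "otsu":
        thr = float(threshold_otsu(vals))
        mask = (tic.values > thr) & ~tic.missing
        if not mask.any():  # degenerate two-level case
            mask = (tic.values >= thr) & ~tic.missing & (tic.values > 0)
    elif method == "fraction":
        thr = param * float(vals.max())
        mask = (tic.values >= thr) & ~tic.missing & (tic.values > 0)
    else:
        raise ValueError("method must be 'otsu' or 'fraction'")
    if not mask.any():
        raise ValueError("tissue mask is empty after thresholding")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
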