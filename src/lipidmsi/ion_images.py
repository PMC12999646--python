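"""Ion-image extraction, summation, colocalization and rendering.

An :class:`IonImage` is the 2-D abundance map of one m/z window over a
pixel grid.  Extraction uses a half-open ppm window
``[target·(1−tol·1e−6), target·(1+tol·1e−6))`` so that adjacent windows
partition the m/z axis and a centroid can never be counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "IonImage",
    "extract_ion_image",
    "summed_ion_image",
    "colocalization_score",
    "render_heatmap",
    "render_overlay",
]


@dataclass
class IonImage:
    """2-D abundance grid for one target m/z window.

    ``values`` has shape ``(n_rows, n_cols)`` in charges/s; ``missing`` marks
    grid positions with no acquired spectrum (distinct from a true zero).
    """

    values: np.ndarray
    target_mz: float | None = None
    tol_ppm: float | None = None
    label: str = ""
    metadata: object | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("IonImage values must be 2-D")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("IonImage values must be non-negative")
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape mismatch")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def observed_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Values at acquired pixels, optionally restricted to ``mask``."""
        keep = ~self.missing
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        return self.values[keep]

    def mean(self, mask: np.ndarray | None = None) -> float:
        v = self.observed_values(mask)
        return float(v.mean()) if v.size else float("nan")


def ppm_window(target_mz: float, tol_ppm: float) -> Tuple[float, float]:
    """Half-open window bounds ``[lo, hi)`` around ``target_mz``."""
    return (target_mz * (1.0 - tol_ppm * 1e-6),
            target_mz * (1.0 + tol_ppm * 1e-6))


def extract_ion_image(img, target_mz: float, tol_ppm: float = 5.0,
                      reducer: str = "sum", label: str | None = None) -> IonImage:
    """Extract the abundance map of one m/z window from a spectrum image.

    Parameters
    ----------
    img : SpectrumImage
        Pixel-indexed centroided spectra.
    target_mz, tol_ppm
        Window centre and half-width in ppm (default ±5 ppm, twice the
        instrument's stated ±2.5 ppm mass accuracy).
    reducer : {"sum", "max"}
        How multiple in-window centroids in one pixel combine; ``sum``
        matches abundance semantics in charges/s.

    A target outside the acquisition scan range yields an all-zero image
    with a warning rather than an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if reducer not in ("sum", "max"):
        raise ValueError("reducer must be 'sum' or 'max'")
    n_cols, n_rows = img.grid_shape
    values = np.zeros((n_rows, n_cols), dtype=float)
    missing = img.missing_grid()
    lab = label if label is not None else f"m/z {target_mz:.4f}"

    lo_mz, hi_mz = ppm_window(target_mz, tol_ppm)
    scan_lo, scan_hi = (img.metadata.scan_range
                        if img.metadata is not None else (None, None))
    if scan_lo is not None and (target_mz < scan_lo or target_mz > scan_hi):
        warnings.warn(
            f"target m/z {target_mz} outside scan range {scan_lo}-{scan_hi}; "
            "returning zero image"
        )
        return IonImage(values, target_mz, tol_ppm, lab, img.metadata, missing)

    # one global m/z sort per SpectrumImage is cached and reused across
    # targets; comparisons happen on the raw m/z values so the result is
    # bitwise identical to a per-pixel linear scan
    mz_sorted, px_sorted, int_sorted = img.global_mz_index()
    i0, i1 = np.searchsorted(mz_sorted, (lo_mz, hi_mz), side="left")
    if i1 > i0:
        px = px_sorted[i0:i1]
        inten = int_sorted[i0:i1]
        n_px = img.n_pixels
        if reducer == "sum":
            acc = np.bincount(px, weights=inten, minlength=n_px)
        else:
            acc = np.zeros(n_px)
            np.maximum.at(acc, px, inten)
        xs, ys = img.coords[:, 0], img.coords[:, 1]
        values[ys, xs] = acc
    return IonImage(values, target_mz, tol_ppm, lab, img.metadata, missing)


def summed_ion_image(images: Sequence[IonImage]) -> IonImage:
    """Elementwise sum of ion images on identical grids (e.g. adduct set)."""
    images = list(images)
    if not images:
        raise ValueError("summed_ion_image requires at least one image")
    shape = images[0].shape
    for im in images[1:]:
        if im.shape != shape:
            raise ValueError("ion images have mismatched grid shapes")
    total = np.sum([im.values for im in images], axis=0)
    missing = images[0].missing.copy()
    for im in images[1:]:
        missing &= im.missing
    label = " + ".join(im.label for im in images)
    return IonImage(total, None, None, label,
                    images[0].metadata, missing)


def _otsu_threshold(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def colocalization_score(a: IonImage, b: IonImage,
                         mask: np.ndarray | None = None) -> dict:
    """Pearson correlation and Otsu-overlap fraction of two ion images.

    ``overlap_fraction`` is |pixels above each image's own Otsu threshold in
    both| / |above threshold in either| over the masked acquired pixels.
    A zero-variance image yields ``pearson_r = nan`` with a warning.
    """
    if a.shape != b.shape:
        raise ValueError("ion images have mismatched shapes")
    keep = ~(a.missing | b.missing)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("empty mask")
    va, vb = a.values[keep], b.values[keep]
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("zero-variance image; Pearson r undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(va, vb)[0, 1])
    try:
        ta, tb = _otsu_threshold(va), _otsu_threshold(vb)
        ha, hb = va > ta, vb > tb
        union = int(np.count_nonzero(ha | hb))
        overlap = (np.count_nonzero(ha & hb) / union) if union else float("nan")
    except ValueError:
        overlap = float("nan")
    return {"pearson_r": r, "overlap_fraction": overlap, "n_pixels": int(keep.sum())}


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _to_rgb(values: np.ndarray, colormap: str) -> np.ndarray:
    import matplotlib

    vmax = values.max()
    norm = values / vmax if vmax > 0 else np.zeros_like(values)
    cmap = matplotlib.colormaps[colormap]
    return cmap(norm)[..., :3]


def render_heatmap(image: IonImage, path, normalization: str = "linear",
                   colormap: str = "viridis") -> None:
    """Write a deterministic PNG heat map of one ion image."""
    from PIL import Image

    if normalization not in ("linear", "per-channel-max"):
        raise ValueError("normalization must be 'linear' or 'per-channel-max'")
    rgb = _to_rgb(image.values, colormap)
    rgb[image.missing] = 0.0
    arr = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


_DEFAULT_COLORS = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def render_overlay(images: Sequence[IonImage], path,
                   colors: Sequence[Tuple[float, float, float]] | None = None) -> None:
    """Additively blend per-channel-max-normalised ion images into a PNG.

    Each channel is scaled to its own maximum, multiplied by its colour and
    summed, so coincident red and green signal blends toward yellow.
    """
    from PIL import Image

    images = list(images)
    if not images:
        raise ValueError("render_overlay requires at least one image")
    colors = list(colors) if colors is not None else list(_DEFAULT_COLORS[: len(images)])
    if len(colors) != len(images):
        raise ValueError("one color per image required")
    shape = images[0].shape
    out = np.zeros(shape + (3,), dtype=float)
    for im, col in zip(images, colors):
        if im.shape != shape:
            raise ValueError("ion images have mismatched grid shapes")
        vmax = im.values.max()
        norm = im.values / vmax if vmax > 0 else np.zeros(shape)
        out += norm[..., None] * np.asarray(col, dtype=float)
    arr = (np.clip(out, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


def export_pixels(image: IonImage, path) -> None:
    """Delimited per-pixel export (x, y, value) of acquired pixels."""
    import pandas as pd

    ys, xs = np.nonzero(~image.missing)
    pd.DataFrame({"x": xs, "y": ys, "value": image.values[ys, xs]}).to_csv(
        path, sep="\t", index=False
    )
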