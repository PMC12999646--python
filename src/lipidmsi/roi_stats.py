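"""Square-ROI sampling per brain quadrant and z-score normalization.

Forty square regions of interest — ten per quadrant — act as
pseudo-technical replicates of each region.  Per-ROI species abundances
(means of the species' summed-adduct ion image) are log10-transformed and
z-scored under three stratification schemes:

* ``replicate``     — within each (replicate, species): removes
  per-replicate systematic offsets.
* ``global``        — within each (condition, species) across all
  replicates and regions: an offset replicate shows up as a shifted mean.
* ``region_global`` — within each (condition, region, species): regional
  structure is absorbed, replicate offsets remain visible in every region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ion_images import IonImage

__all__ = [
    "Roi",
    "RoiSet",
    "RoiPlacementError",
    "place_rois",
    "extract_roi_abundances",
    "znormalize",
    "summarize_region_boxplots",
    "Z_SCHEMES",
]

Z_SCHEMES = ("replicate", "global", "region_global")

_STRATA: Dict[str, Tuple[str, ...]] = {
    "replicate": ("replicate_id", "species"),
    "global": ("condition", "species"),
    "region_global": ("condition", "region", "species"),
}

_ZCOL = {"replicate": "z_replicate", "global": "z_global",
         "region_global": "z_region_global"}


class RoiPlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class Roi:
    region: str
    x: int          # top-left column
    y: int          # top-left row
    side: int

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.y:self.y + self.side, self.x:self.x + self.side] = True
        return m


@dataclass
class RoiSet:
    rois: List[Roi]
    side: int

    def __len__(self) -> int:
        return len(self.rois)

    def by_region(self) -> Dict[str, List[Roi]]:
        out: Dict[str, List[Roi]] = {}
        for r in self.rois:
            out.setdefault(r.region, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"region": r.region, "x": r.x, "y": r.y, "side": r.side}
             for r in self.rois]
        )


def place_rois(
    mask: np.ndarray,
    region_map: Mapping[str, np.ndarray],
    n_per_region: int = 10,
    side: int = 3,
    seed: int | None = 0,
    max_attempts: int = 20000,
) -> RoiSet:
    """Place ``n_per_region`` disjoint squares inside each region.

    Uniform-random rejection sampling over the top-left corners whose full
    ``side × side`` footprint lies inside both the tissue mask and the
    region; deterministic for a fixed seed.  Raises
    :class:`RoiPlacementError` naming the region if placement is infeasible
    within ``max_attempts`` draws.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    occupied = np.zeros_like(mask)
    rois: List[Roi] = []
    for region, rmask in region_map.items():
        inside = np.asarray(rmask, dtype=bool) & mask
        # valid[y, x] <=> the side×side square at (x, y) fits in the region
        if side <= n_rows and side <= n_cols:
            window = np.lib.stride_tricks.sliding_window_view(
                inside, (side, side))
            cand = np.argwhere(window.all(axis=(2, 3)))
        else:
            cand = np.empty((0, 2), dtype=int)
        if cand.shape[0] < n_per_region:
            raise RoiPlacementError(
                f"region {region!r} cannot fit {n_per_region} squares of "
                f"side {side}"
            )
        placed = 0
        attempts = 0
        while placed < n_per_region:
            if attempts >= max_attempts:
                raise RoiPlacementError(
                    f"could not place {n_per_region} disjoint ROIs in region "
                    f"{region!r} after {max_attempts} attempts "
                    f"(placed {placed})"
                )
            attempts += 1
            y, x = cand[rng.integers(cand.shape[0])]
            if occupied[y:y + side, x:x + side].any():
                continue
            occupied[y:y + side, x:x + side] = True
            rois.append(Roi(region, int(x), int(y), side))
            placed += 1
    return RoiSet(rois, side)


def extract_roi_abundances(
    images: Mapping[str, Mapping[str, IonImage]],
    rois: RoiSet,
    floor: float = 5.0,
) -> pd.DataFrame:
    """Long-format ROI × species abundance table.

    ``images`` maps replicate_id -> species -> IonImage (typically the
    summed-adduct image).  ``mean_abundance`` is the mean over the ROI's
    acquired pixels; ``log_abundance`` is log10(mean + floor), the additive
    floor keeping zero ROIs finite.
    """
    rows = []
    for rep_id, spec_imgs in images.items():
        for species, img in spec_imgs.items():
            cond = (img.metadata.condition
                    if img.metadata is not None else None)
            for i, roi in enumerate(rois.rois):
                sl_y = slice(roi.y, roi.y + roi.side)
                sl_x = slice(roi.x, roi.x + roi.side)
                vals = img.values[sl_y, sl_x]
                miss = img.missing[sl_y, sl_x]
                vals = vals[~miss]
                mean = float(vals.mean()) if vals.size else 0.0
                rows.append({
                    "condition": cond,
                    "replicate_id": rep_id,
                    "region": roi.region,
                    "roi_index": i,
                    "species": species,
                    "mean_abundance": mean,
                    "log_abundance": float(np.log10(mean + floor)),
                })
    return pd.DataFrame(rows)


def znormalize(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Add the z-score column for one normalization scheme.

    z = (log_abundance − μ) / σ with μ and the sample SD computed over the
    scheme's stratum.  A zero-SD stratum yields z = 0 with a warning; a
    stratum with fewer than two rows is an error naming the stratum.
    """
    if scheme not in _STRATA:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of "
                         f"{Z_SCHEMES}")
    keys = list(_STRATA[scheme])
    out = table.copy()
    grouped = out.groupby(keys, sort=False, dropna=False)["log_abundance"]
    sizes = grouped.transform("size")
    if (sizes < 2).any():
        bad = out.loc[sizes < 2, keys].iloc[0].to_dict()
        raise ValueError(
            f"stratum {bad} has fewer than 2 rows under scheme {scheme!r}"
        )
    mu = grouped.transform("mean")
    sd = grouped.transform(lambda s: s.std(ddof=1))
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} rows in zero-variance strata; "
                      "z set to 0")
    z = np.where(zero, 0.0, (out["log_abundance"] - mu) / sd.replace(0, np.nan))
    out[_ZCOL[scheme]] = z
    return out


def summarize_region_boxplots(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Tukey boxplot statistics of z per (condition, replicate, region).

    Whiskers extend to the most extreme points within 1.5 IQR of the
    quartiles.  One row per condition × replicate × region.
    """
    zcol = _ZCOL[scheme]
    if zcol not in table.columns:
        raise ValueError(f"table lacks {zcol!r}; run znormalize first")
    rows = []
    for (cond, rep, region), grp in table.groupby(
            ["condition", "replicate_id", "region"], sort=True, dropna=False):
        z = grp[zcol].to_numpy()
        q1, med, q3 = np.percentile(z, [25, 50, 75])
        iqr = q3 - q1
        in_lo = z[z >= q1 - 1.5 * iqr]
        in_hi = z[z <= q3 + 1.5 * iqr]
        rows.append({
            "condition": cond, "replicate_id": rep, "region": region,
            "n": z.size, "mean": float(z.mean()), "median": float(med),
            "q1": float(q1), "q3": float(q3),
            "whisker_low": float(in_lo.min()) if in_lo.size else float(z.min()),
            "whisker_high": float(in_hi.max()) if in_hi.size else float(z.max()),
        })
    return pd.DataFrame(rows)
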