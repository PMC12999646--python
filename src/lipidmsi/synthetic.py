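"""Synthetic brain-phantom MSI cohorts and PRM ramp data with known truth.

The phantom emulates the structure of a sagittal mouse-brain MSI study of a
demyelinating disease model: a brain-like silhouette on a 100–150 µm pixel
grid partitioned into four anatomical quadrants (cerebrum, midbrain,
cerebellum, brain stem) plus a small visual-cortex hotspot inside the
cerebrum; per-lipid per-region baseline abundances; condition fold changes
(psychosine strongly enriched in the posterior regions of the diseased
condition only); per-replicate multiplicative systematic offsets; mean-one
log-normal pixel noise; mass jitter bounded at ±2.5 ppm; adduct splitting;
decoy background peaks; and a detection floor.

Everything is driven by a single integer seed: fixing the seed fixes every
output byte, including serialized imzML files.
"""

from __future__ import annotations

import copy
import uuid as _uuid
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .msi_io import AcquisitionMetadata, SpectrumImage, write_imzml
from .panel import PanelEntry, default_panel

__all__ = [
    "PhantomConfig",
    "NoiseModel",
    "FragmentationModel",
    "RegionMaps",
    "CohortTruth",
    "build_region_maps",
    "generate_phantom",
    "generate_cohort",
    "generate_breakdown_data",
    "generate_prm_image",
    "PSYCHOSINE_MH",
    "FRAGMENT_282",
    "FRAGMENT_264",
]

# theoretical ion m/z of the PRM system: protonated psychosine and its two
# quantitative fragments (neutral loss of galactose, then of water)
_PSY = chem.parse_formula("C24H47NO7")
_GALACTOSE = chem.parse_formula("C6H12O6")
_H2O = chem.parse_formula("H2O")
PSYCHOSINE_MH = chem.adduct_mz(_PSY, chem.get_adduct("[M+H]+"))
FRAGMENT_282 = chem.neutral_loss_mz(PSYCHOSINE_MH, _GALACTOSE)
FRAGMENT_264 = chem.neutral_loss_mz(FRAGMENT_282, _H2O)

QUADRANTS = ("cerebrum", "midbrain", "cerebellum", "brain_stem")


@dataclass
class NoiseModel:
    """Stochastic components of the phantom.

    ``lognormal_sigma`` is the natural-log SD of mean-one multiplicative
    pixel noise; ``ppm_jitter_sd`` the SD of the per-peak mass error
    (truncated at ``ppm_jitter_max``, the instrument's stated accuracy);
    ``replicate_offset_sd`` the SD (log2) of per-replicate global
    multiplicative offsets; ``detection_floor`` the minimum reportable
    intensity in charges/s; ``baseline_peak_density`` the expected decoy
    peaks per pixel per 100 Th.
    """

    lognormal_sigma: float = 0.5
    ppm_jitter_sd: float = 1.0
    ppm_jitter_max: float = 2.5
    replicate_offset_sd: float = 0.3
    detection_floor: float = 5.0
    baseline_peak_density: float = 2.0

    def __post_init__(self) -> None:
        for name in ("lognormal_sigma", "ppm_jitter_sd", "ppm_jitter_max",
                     "replicate_offset_sd", "detection_floor",
                     "baseline_peak_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PhantomConfig:
    """Geometry, panel and cohort design of the phantom."""

    grid_shape: Tuple[int, int] = (120, 80)     # (n_cols, n_rows)
    spatial_resolution: float = 100.0           # µm per pixel
    scan_range: Tuple[float, float] = (200.0, 800.0)
    panel: List[PanelEntry] = field(default_factory=default_panel)
    n_replicates: Dict[str, int] = field(
        default_factory=lambda: {"healthy": 3, "diseased": 4})
    diseased_condition: str = "diseased"
    solvent: str = "standard"
    #: shared latent field giving cholesterol/psychosine spatial
    #: anti-correlation in diseased posterior regions (0 disables)
    anticorr_sigma: float = 0.6
    #: explicit per-condition replicate offsets (log2); None -> drawn
    replicate_offsets: Optional[Dict[str, Sequence[float]]] = None
    missing_pixel_fraction: float = 0.0

    def conditions(self) -> List[str]:
        return list(self.n_replicates)


@dataclass
class RegionMaps:
    """Painted anatomy of the phantom.

    ``abundance_ids`` labels five abundance regions (the four quadrants with
    the visual-cortex hotspot carved out of the cerebrum); ``quadrant_ids``
    merges the hotspot back into the cerebrum, giving the four disjoint
    quadrants whose union is the tissue mask.
    """

    tissue: np.ndarray
    abundance_ids: np.ndarray
    abundance_labels: Tuple[str, ...]
    quadrant_ids: np.ndarray
    quadrant_labels: Tuple[str, ...]

    def quadrant_mask(self, label: str) -> np.ndarray:
        return self.quadrant_ids == self.quadrant_labels.index(label)

    def abundance_mask(self, label: str) -> np.ndarray:
        return self.abundance_ids == self.abundance_labels.index(label)


def _ellipse(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
             ax: float, ay: float) -> np.ndarray:
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def build_region_maps(grid_shape: Tuple[int, int]) -> RegionMaps:
    """Paint the parametric brain silhouette and its quadrant partition.

    The silhouette is a large cerebral ellipse plus a cerebellar lobe and a
    brain-stem lobe; quadrant boundaries are vertical/horizontal cuts in
    fractional grid coordinates so any grid size yields the same topology.
    """
    n_cols, n_rows = grid_shape
    xx, yy = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    fx, fy = xx / n_cols, yy / n_rows

    main = _ellipse(fx, fy, 0.42, 0.48, 0.36, 0.38)
    lobe = _ellipse(fx, fy, 0.80, 0.42, 0.16, 0.24)
    stem = _ellipse(fx, fy, 0.78, 0.72, 0.20, 0.16)
    tissue = main | lobe | stem

    quad = np.full(tissue.shape, -1, dtype=np.int64)
    quad[tissue & (fx < 0.52)] = 0                                # cerebrum
    quad[tissue & (fx >= 0.52) & (fx < 0.66)] = 1                 # midbrain
    quad[tissue & (fx >= 0.66) & (fy < 0.56)] = 2                 # cerebellum
    quad[tissue & (fx >= 0.66) & (fy >= 0.56)] = 3                # brain_stem

    hotspot = _ellipse(fx, fy, 0.44, 0.22, 0.06, 0.09) & (quad == 0)
    # five-region abundance scheme: hotspot carved out of the cerebrum
    abund = np.full(tissue.shape, -1, dtype=np.int64)
    abund[quad == 0] = 0
    abund[hotspot] = 1
    abund[quad == 1] = 2
    abund[quad == 2] = 3
    abund[quad == 3] = 4
    return RegionMaps(
        tissue=tissue,
        abundance_ids=abund,
        abundance_labels=("cerebrum", "visual_cortex", "midbrain",
                          "cerebellum", "brain_stem"),
        quadrant_ids=quad,
        quadrant_labels=QUADRANTS,
    )


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

def _mean_one_lognormal(rng: np.random.Generator, sigma: float,
                        size) -> np.ndarray:
    """exp(N(-sigma^2/2, sigma)): multiplicative noise with expectation 1."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _jitter_mz(rng: np.random.Generator, mz: float, noise: NoiseModel,
               size) -> np.ndarray:
    ppm = rng.normal(0.0, noise.ppm_jitter_sd, size=size) if noise.ppm_jitter_sd else np.zeros(size)
    ppm = np.clip(ppm, -noise.ppm_jitter_max, noise.ppm_jitter_max)
    return mz * (1.0 + ppm * 1e-6)


def generate_phantom(
    cfg: PhantomConfig,
    noise: NoiseModel,
    condition: str,
    replicate_idx: int,
    seed,
    replicate_offset_log2: Optional[float] = None,
) -> SpectrumImage:
    """Generate one replicate's spectrum image.

    Per tissue pixel and panel species the expected abundance is
    ``baseline(region) × 2^log2fc(region) (diseased only) ×
    2^replicate_offset × 2^suppression (doped solvent only)``, multiplied by
    mean-one log-normal pixel noise, split across the species' adducts, each
    peak mass-jittered; decoy background peaks cover the whole grid and the
    detection floor censors everything below it.  Deterministic for a fixed
    seed.
    """
    if condition not in cfg.n_replicates:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{list(cfg.n_replicates)}"
        )
    rng = np.random.default_rng(seed)
    maps = build_region_maps(cfg.grid_shape)
    n_cols, n_rows = cfg.grid_shape
    lo, hi = cfg.scan_range

    if replicate_offset_log2 is None:
        replicate_offset_log2 = float(
            rng.normal(0.0, noise.replicate_offset_sd))
    offset_factor = 2.0 ** replicate_offset_log2
    diseased = condition == cfg.diseased_condition
    doped = cfg.solvent == "doped"

    # flat pixel order: row-major over the full grid
    ys, xs = np.mgrid[0:n_rows, 0:n_cols]
    xs, ys = xs.ravel(), ys.ravel()
    n_px = xs.size
    tissue_flat = maps.tissue.ravel()
    abund_flat = maps.abundance_ids.ravel()
    t_idx = np.nonzero(tissue_flat)[0]
    t_regions = abund_flat[t_idx]

    # shared latent field for the cholesterol/psychosine anti-correlation,
    # active in the diseased posterior regions only
    latent = rng.normal(0.0, 1.0, size=t_idx.size)
    posterior = np.isin(t_regions,
                        [maps.abundance_labels.index("cerebellum"),
                         maps.abundance_labels.index("brain_stem")])
    anti_on = diseased and cfg.anticorr_sigma > 0

    px_parts: List[np.ndarray] = []
    mz_parts: List[np.ndarray] = []
    int_parts: List[np.ndarray] = []

    for entry in cfg.panel:
        base = np.array([entry.baseline(lab) for lab in maps.abundance_labels])
        expected = base[t_regions].astype(float)
        if diseased:
            fc = np.array([entry.log2fc(lab) for lab in maps.abundance_labels])
            expected = expected * 2.0 ** fc[t_regions]
        if doped:
            expected = expected * 2.0 ** entry.solvent_suppression_log2
        expected = expected * offset_factor
        if anti_on and entry.name == "psychosine":
            expected = expected * np.where(
                posterior, np.exp(cfg.anticorr_sigma * latent
                                  - 0.5 * cfg.anticorr_sigma ** 2), 1.0)
        elif anti_on and entry.name == "cholesterol":
            expected = expected * np.where(
                posterior, np.exp(-cfg.anticorr_sigma * latent
                                  - 0.5 * cfg.anticorr_sigma ** 2), 1.0)
        # one noise draw per species-pixel, shared by all its adducts
        abundance = expected * _mean_one_lognormal(
            rng, noise.lognormal_sigma, expected.shape)
        fractions = entry.ion_fraction_map()
        for adduct, mz in entry.ion_mz_map().items():
            if not (lo <= mz <= hi):
                continue
            amp = abundance * fractions[adduct]
            keep = amp >= noise.detection_floor
            if not keep.any():
                continue
            px_parts.append(t_idx[keep])
            mz_parts.append(_jitter_mz(rng, mz, noise, int(keep.sum())))
            int_parts.append(amp[keep])

    # decoy background peaks over the whole grid (off-tissue included)
    lam = noise.baseline_peak_density * (hi - lo) / 100.0
    counts = rng.poisson(lam, size=n_px)
    n_decoy = int(counts.sum())
    if n_decoy:
        px_parts.append(np.repeat(np.arange(n_px), counts))
        mz_parts.append(rng.uniform(lo, hi, size=n_decoy))
        int_parts.append(noise.detection_floor *
                         np.exp(np.abs(rng.normal(0.0, 0.8, size=n_decoy))))

    if px_parts:
        px = np.concatenate(px_parts)
        mzs = np.concatenate(mz_parts)
        ints = np.concatenate(int_parts)
    else:  # degenerate: nothing detectable
        px = np.empty(0, dtype=np.int64)
        mzs = np.empty(0)
        ints = np.empty(0)

    order = np.lexsort((mzs, px))
    px, mzs, ints = px[order], mzs[order], ints[order]
    # merge (vanishingly rare) exact m/z ties within a pixel
    if px.size > 1:
        dup = (np.diff(px) == 0) & (np.diff(mzs) == 0)
        if dup.any():
            keep = np.concatenate([[True], ~dup])
            grp = np.cumsum(keep) - 1
            ints = np.bincount(grp, weights=ints)
            px, mzs = px[keep], mzs[keep]

    keep_px = np.ones(n_px, dtype=bool)
    if cfg.missing_pixel_fraction > 0:
        drop = rng.random(n_px) < cfg.missing_pixel_fraction
        keep_px = ~drop
        sel = keep_px[px]
        px, mzs, ints = px[sel], mzs[sel], ints[sel]

    kept = np.nonzero(keep_px)[0]
    remap = np.full(n_px, -1, dtype=np.int64)
    remap[kept] = np.arange(kept.size)
    px = remap[px]
    coords = np.column_stack([xs[kept], ys[kept]])
    offsets = np.concatenate([[0], np.cumsum(np.bincount(px, minlength=kept.size))])

    meta = AcquisitionMetadata(
        spatial_resolution=cfg.spatial_resolution,
        scan_range=cfg.scan_range,
        condition=condition,
        replicate_id=f"{condition}_{replicate_idx + 1}",
        solvent=cfg.solvent,
    )
    return SpectrumImage.from_flat(coords, offsets, mzs, ints,
                                   cfg.grid_shape, meta)


@dataclass
class CohortTruth:
    """Generated cohort plus the ground truth that produced it."""

    images: List[SpectrumImage]
    true_log2fc: pd.DataFrame        # species × region long table
    replicate_offsets: Dict[str, float]
    region_maps: RegionMaps
    config: PhantomConfig
    noise: NoiseModel
    seed: int

    def by_condition(self, condition: str) -> List[SpectrumImage]:
        return [im for im in self.images
                if im.metadata.condition == condition]


def generate_cohort(cfg: PhantomConfig, noise: NoiseModel,
                    seed: int) -> CohortTruth:
    """Generate the full two-condition cohort (default 3 healthy + 4 diseased).

    Per-replicate sub-seeds and offsets all derive from ``seed``; the
    returned :class:`CohortTruth` echoes the injected fold changes and the
    drawn replicate offsets for parameter-recovery checks.
    """
    children = np.random.SeedSequence(seed).spawn(
        1 + sum(cfg.n_replicates.values()))
    master = np.random.default_rng(children[0])   # replicate offset draws
    child_seeds = iter(children[1:])              # one stream per replicate
    maps = build_region_maps(cfg.grid_shape)

    images: List[SpectrumImage] = []
    offsets: Dict[str, float] = {}
    for condition, n_rep in cfg.n_replicates.items():
        given = (cfg.replicate_offsets or {}).get(condition)
        for r in range(n_rep):
            off = (float(given[r]) if given is not None
                   else float(master.normal(0.0, noise.replicate_offset_sd)))
            img = generate_phantom(cfg, noise, condition, r,
                                   next(child_seeds),
                                   replicate_offset_log2=off)
            offsets[img.metadata.replicate_id] = off
            images.append(img)

    rows = []
    for entry in cfg.panel:
        for lab in maps.abundance_labels:
            rows.append({"species": entry.name, "region": lab,
                         "log2fc": entry.log2fc(lab)})
    truth = pd.DataFrame(rows)
    return CohortTruth(images, truth, offsets, maps, cfg, noise, int(seed))


def write_cohort(cohort: CohortTruth, out_dir) -> List[str]:
    """Serialize a cohort to imzML with seed-derived UUIDs (byte-stable)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, img in enumerate(cohort.images):
        rid = img.metadata.replicate_id
        uid = _uuid.uuid5(_uuid.NAMESPACE_URL,
                          f"lipidmsi/{cohort.seed}/{rid}")
        paths.append(write_imzml(img, os.path.join(out_dir, f"{rid}.imzML"),
                                 uuid=uid))
    truth_path = os.path.join(out_dir, "ground_truth.tsv")
    truth = cohort.true_log2fc.copy()
    truth.to_csv(truth_path, sep="\t", index=False)
    offs = pd.DataFrame(
        sorted(cohort.replicate_offsets.items()),
        columns=["replicate_id", "offset_log2"],
    )
    offs.to_csv(os.path.join(out_dir, "replicate_offsets.tsv"),
                sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# PRM fragmentation
# --------------------------------------------------------------------------

def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class FragmentationModel:
    """NCE-dependent fragmentation of protonated psychosine.

    The precursor survives with logistic decay in NCE; the fragment pool
    splits between the galactose-loss fragment (m/z 282) and the
    galactose-plus-water-loss fragment (m/z 264) by a logistic conversion
    curve centred at ``crossover_nce``, where the two fragments are exactly
    equal.  Above ``secondary_onset`` the 282 series is non-increasing while
    264 keeps rising, reproducing the observed high-NCE behaviour.
    """

    crossover_nce: float = 16.0
    precursor_midpoint: Optional[float] = None   # default crossover + 2
    precursor_slope: float = 4.0
    conversion_slope: float = 8.0
    secondary_onset: float = 35.0
    total_abundance: float = 1000.0

    def __post_init__(self) -> None:
        if self.precursor_midpoint is None:
            self.precursor_midpoint = self.crossover_nce + 2.0

    def survival(self, nce) -> np.ndarray | float:
        return _logistic((self.precursor_midpoint - np.asarray(nce, float))
                         / self.precursor_slope)

    def fragment_fractions(self, nce):
        """(fraction_282, fraction_264) of the total ion population."""
        nce = np.asarray(nce, dtype=float)
        f = 1.0 - self.survival(nce)
        g = _logistic((nce - self.crossover_nce) / self.conversion_slope)
        return f * (1.0 - g), f * g

    def expected_abundances(self, nce) -> Dict[float, np.ndarray | float]:
        f282, f264 = self.fragment_fractions(nce)
        t = self.total_abundance
        return {PSYCHOSINE_MH: self.survival(nce) * t,
                FRAGMENT_282: f282 * t,
                FRAGMENT_264: f264 * t}


def generate_breakdown_data(
    fm: FragmentationModel,
    nce_grid: Sequence[float],
    n_scans: int = 10,
    seed: int | None = 0,
    noise_sigma: float = 0.1,
    ppm_jitter_sd: float = 1.0,
) -> Dict[float, List[Tuple[np.ndarray, np.ndarray]]]:
    """Per-NCE lists of centroided scans (mz, intensity arrays).

    Each scan carries the precursor and the two quantitative fragments at
    model-expected abundances under mean-one log-normal noise with
    mass jitter.  ``noise_sigma = 0`` gives the model expectations exactly.
    """
    if len(nce_grid) == 0:
        raise ValueError("nce_grid must be non-empty")
    rng = np.random.default_rng(seed)
    jitter = NoiseModel(ppm_jitter_sd=ppm_jitter_sd, detection_floor=0.0,
                        baseline_peak_density=0.0)
    out: Dict[float, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for nce in nce_grid:
        expect = fm.expected_abundances(float(nce))
        scans = []
        for _ in range(n_scans):
            mzs, ints = [], []
            for mz, a in sorted(expect.items()):
                amp = float(a) * float(
                    _mean_one_lognormal(rng, noise_sigma, ()))
                mzs.append(float(_jitter_mz(rng, mz, jitter, ())))
                ints.append(max(amp, 0.0))
            scans.append((np.array(mzs), np.array(ints)))
        out[float(nce)] = scans
    return out


def generate_prm_image(
    cfg: PhantomConfig,
    fm: FragmentationModel,
    nce: float,
    noise: NoiseModel,
    seed: int | None = 0,
    n_isotope_peaks: int = 4,
) -> SpectrumImage:
    """PRM-mode spectrum image: precursor envelope plus fragments per pixel.

    The psychosine spatial pattern follows the panel's diseased psychosine
    abundances; pixel noise multiplies the per-pixel total before the
    precursor/fragment split, so fragment maps are deterministic fractions
    of the precursor map and colocalize by construction.  The precursor is
    emitted with its theoretical isotope envelope.
    """
    rng = np.random.default_rng(seed)
    maps = build_region_maps(cfg.grid_shape)
    n_cols, n_rows = cfg.grid_shape
    entry = next(e for e in cfg.panel if e.name == "psychosine")

    ys, xs = np.mgrid[0:n_rows, 0:n_cols]
    xs, ys = xs.ravel(), ys.ravel()
    tissue_flat = maps.tissue.ravel()
    t_idx = np.nonzero(tissue_flat)[0]
    regions = maps.abundance_ids.ravel()[t_idx]
    base = np.array([entry.baseline(lab) * 2.0 ** entry.log2fc(lab)
                     for lab in maps.abundance_labels])
    total = base[regions] * _mean_one_lognormal(
        rng, noise.lognormal_sigma, t_idx.shape) * 20.0

    surv = float(fm.survival(nce))
    f282, f264 = (float(v) for v in fm.fragment_fractions(nce))
    env = chem.isotope_pattern(chem.ion_composition(_PSY, chem.get_adduct("[M+H]+")),
                               n_peaks=n_isotope_peaks, charge=1)

    ion_mzs = [FRAGMENT_264, FRAGMENT_282] + list(env.mz)
    ion_fracs = [f264, f282] + list(surv * env.abundance)

    px_parts, mz_parts, int_parts = [], [], []
    for mz, frac in zip(ion_mzs, ion_fracs):
        amp = total * frac
        keep = amp >= noise.detection_floor
        if not keep.any():
            continue
        px_parts.append(t_idx[keep])
        mz_parts.append(_jitter_mz(rng, mz, noise, int(keep.sum())))
        int_parts.append(amp[keep])

    px = np.concatenate(px_parts) if px_parts else np.empty(0, dtype=np.int64)
    mzs = np.concatenate(mz_parts) if mz_parts else np.empty(0)
    ints = np.concatenate(int_parts) if int_parts else np.empty(0)
    order = np.lexsort((mzs, px))
    px, mzs, ints = px[order], mzs[order], ints[order]
    n_px = xs.size
    coords = np.column_stack([xs, ys])
    offsets = np.concatenate([[0], np.cumsum(np.bincount(px, minlength=n_px))])
    meta = AcquisitionMetadata(
        spatial_resolution=cfg.spatial_resolution, scan_range=(40.0, 500.0),
        condition=cfg.diseased_condition, replicate_id="prm_1",
        solvent=cfg.solvent,
    )
    return SpectrumImage.from_flat(coords, offsets, mzs, ints,
                                   cfg.grid_shape, meta)
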