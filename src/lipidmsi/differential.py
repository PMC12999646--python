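"""Between-condition volcano analysis and the two-solvent comparison.

Whole-tissue species abundances are per-replicate means of the species'
summed-adduct ion image over the tissue mask.  The volcano statistic is the
difference of mean log2 abundances between conditions with a Welch
two-sample t-test, Benjamini-Hochberg adjusted across the panel; a species
is significant when |log2fc| exceeds the fold-change threshold (default
0.6) and its adjusted p falls below alpha (default 0.05).  Effect-size
bands are reported as labels: small_moderate for 0.6 < |log2fc| <= 1.5,
large for |log2fc| > 2.0.

The standard vs NH4F-doped solvent comparison is descriptive: per-species
log2(doped/standard) on-tissue abundance ratios summarised by LMSD
category, plus summed abundances of three configured mass-range ion groups
and the fraction of evaluated ions preferring the standard solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .ion_images import IonImage, extract_ion_image, summed_ion_image
from .msi_io import SpectrumImage, tic_image, tissue_mask
from .panel import DEFAULT_MASS_GROUPS, PanelEntry

__all__ = [
    "species_image",
    "whole_tissue_abundances",
    "benjamini_hochberg",
    "volcano",
    "regional_volcano",
    "solvent_compare",
    "reflection_data",
    "classify_effect",
]


def species_image(img: SpectrumImage, entry: PanelEntry,
                  tol_ppm: float = 5.0,
                  adducts: str = "summed") -> IonImage:
    """Per-species abundance image: summed adducts (default) or [M+H]+ only."""
    mz_map = entry.ion_mz_map()
    if adducts == "summed":
        targets = list(mz_map.items())
    elif adducts in mz_map:
        targets = [(adducts, mz_map[adducts])]
    else:
        raise ValueError(f"{entry.name}: no adduct {adducts!r}")
    parts = [extract_ion_image(img, mz, tol_ppm,
                               label=f"{entry.name} {name}")
             for name, mz in targets]
    out = summed_ion_image(parts) if len(parts) > 1 else parts[0]
    out.label = entry.name
    return out


def cohort_species_images(
    images: Sequence[SpectrumImage],
    panel: Sequence[PanelEntry],
    tol_ppm: float = 5.0,
    adducts: str = "summed",
) -> Dict[str, Dict[str, IonImage]]:
    """replicate_id -> species -> summed-adduct IonImage for a cohort."""
    out: Dict[str, Dict[str, IonImage]] = {}
    for img in images:
        rid = img.metadata.replicate_id or f"replicate_{len(out)}"
        out[rid] = {e.name: species_image(img, e, tol_ppm, adducts)
                    for e in panel}
    return out


def whole_tissue_abundances(
    cohort: Sequence[SpectrumImage],
    panel: Sequence[PanelEntry],
    mask_method: str = "otsu",
    mask_param: float = 0.1,
    tol_ppm: float = 5.0,
    adducts: str = "summed",
) -> pd.DataFrame:
    """Per-replicate mean on-tissue abundance of every panel species.

    Long table with columns (species, lmsd_category, condition,
    replicate_id, abundance); the tissue mask is derived from each
    replicate's own TIC image.
    """
    rows = []
    for img in cohort:
        mask = tissue_mask(tic_image(img), method=mask_method,
                           param=mask_param)
        for entry in panel:
            im = species_image(img, entry, tol_ppm, adducts)
            rows.append({
                "species": entry.name,
                "lmsd_category": entry.lmsd_category,
                "condition": img.metadata.condition,
                "replicate_id": img.metadata.replicate_id,
                "abundance": im.mean(mask),
            })
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def classify_effect(log2fc: float) -> str:
    """Effect-size band label for a log2 fold change."""
    a = abs(log2fc)
    if a > 2.0:
        return "large"
    if a > 1.5:
        return "intermediate"
    if a > 0.6:
        return "small_moderate"
    return "none"


def _log2_groups(values_a: np.ndarray, values_b: np.ndarray,
                 species: str) -> Tuple[np.ndarray, np.ndarray]:
    bad_a, bad_b = values_a <= 0, values_b <= 0
    if bad_a.any() or bad_b.any():
        warnings.warn(
            f"{species}: {int(bad_a.sum() + bad_b.sum())} non-positive "
            "abundances excluded before log transform"
        )
    return np.log2(values_a[~bad_a]), np.log2(values_b[~bad_b])


def volcano(
    abundances: pd.DataFrame,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 0.6,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Differential table (one row per species) between two conditions.

    log2fc = mean log2 abundance in ``group_a`` − mean in ``group_b``; p
    from a Welch two-sample t-test on the log2 values (``test="mannwhitney"``
    swaps in the exact Mann-Whitney U); Benjamini-Hochberg adjustment across
    all tested species.
    """
    rows = []
    for species, grp in abundances.groupby("species", sort=False):
        a = grp.loc[grp["condition"] == group_a, "abundance"].to_numpy(float)
        b = grp.loc[grp["condition"] == group_b, "abundance"].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"species {species!r}: need >=2 replicates per condition "
                f"(got {a.size} vs {b.size})"
            )
        la, lb = _log2_groups(a, b, species)
        if la.size < 2 or lb.size < 2:
            warnings.warn(f"{species}: insufficient positive abundances; "
                          "skipped")
            continue
        lfc = float(la.mean() - lb.mean())
        if np.allclose(la.var(ddof=1) + lb.var(ddof=1), 0.0):
            p = 1.0 if np.isclose(lfc, 0.0) else 0.0
        elif test == "welch":
            p = float(_stats.ttest_ind(la, lb, equal_var=False).pvalue)
        elif test == "mannwhitney":
            p = float(_stats.mannwhitneyu(la, lb,
                                          alternative="two-sided").pvalue)
        else:
            raise ValueError("test must be 'welch' or 'mannwhitney'")
        cat = grp["lmsd_category"].iloc[0] if "lmsd_category" in grp else ""
        rows.append({"species": species, "lmsd_category": cat,
                     "log2fc": lfc, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no species could be tested")
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = (out["log2fc"].abs() > lfc_threshold) & \
                         (out["p_adjusted"] < alpha)
    out["effect_class"] = out["log2fc"].map(classify_effect)
    return out


def regional_volcano(
    roi_table: pd.DataFrame,
    region: str,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 0.6,
    alpha: float = 0.05,
    test: str = "welch",
    floor: float = 5.0,
) -> pd.DataFrame:
    """Volcano restricted to one quadrant using ROI-derived abundances.

    Each replicate contributes its regional mean over that replicate's ROIs
    (mean of ``mean_abundance``); those replicate-level values then run
    through the same test as :func:`volcano`.  ``floor`` (the detection
    floor, charges/s) is added before the log so regions where a species is
    fully censored stay testable — a sub-floor mean is treated as "at the
    floor", which also shrinks fold changes toward zero rather than letting
    censored zeros explode them.
    """
    sub = roi_table[roi_table["region"] == region]
    if sub.empty:
        raise ValueError(f"ROI table has no rows for region {region!r}")
    agg = (sub.groupby(["species", "condition", "replicate_id"],
                       sort=False)["mean_abundance"]
           .mean().reset_index().rename(columns={"mean_abundance": "abundance"}))
    agg["abundance"] = agg["abundance"] + floor
    counts = agg.groupby(["species", "condition"])["abundance"].size()
    for cond in (group_a, group_b):
        n = counts.xs(cond, level="condition", drop_level=True).min() \
            if cond in counts.index.get_level_values("condition") else 0
        if n < 2:
            raise ValueError(
                f"region {region!r}: condition {cond!r} has fewer than 2 "
                "replicates"
            )
    return volcano(agg, group_a, group_b, lfc_threshold, alpha, test)


# --------------------------------------------------------------------------
# two-solvent comparison
# --------------------------------------------------------------------------

@dataclass
class SolventComparison:
    """Descriptive standard vs NH4F-doped solvent comparison."""

    per_species: pd.DataFrame      # species, category, means, log2_ratio
    per_category: pd.DataFrame     # category box statistics of log2_ratio
    mass_groups: pd.DataFrame      # group, window, member sums, fold ratio
    per_ion: pd.DataFrame          # member ion-level preference
    preference_fraction: float     # share of evaluated ions with standard > doped


def solvent_compare(
    img_standard: SpectrumImage,
    img_doped: SpectrumImage,
    panel: Sequence[PanelEntry],
    groups: Mapping[str, Tuple[float, float]] | None = None,
    tol_ppm: float = 5.0,
    mask_method: str = "otsu",
) -> SolventComparison:
    """Compare lipid detection between the two electrospray solvents.

    Per species: on-tissue mean of the summed-adduct image in each image
    and log2(doped/standard), defined only where both are positive.
    Each configured mass-range group carries an explicit list of member ion
    m/z; every member contributes its on-tissue window mean, and the group
    reports summed member abundance per condition and the standard/doped
    fold ratio.
    """
    groups = dict(groups) if groups is not None else dict(DEFAULT_MASS_GROUPS)
    mask_s = tissue_mask(tic_image(img_standard), method=mask_method)
    mask_d = tissue_mask(tic_image(img_doped), method=mask_method)

    sp_rows = []
    for entry in panel:
        im_s = species_image(img_standard, entry, tol_ppm)
        im_d = species_image(img_doped, entry, tol_ppm)
        mean_s, mean_d = im_s.mean(mask_s), im_d.mean(mask_d)
        defined = mean_s > 0 and mean_d > 0
        sp_rows.append({
            "species": entry.name, "lmsd_category": entry.lmsd_category,
            "mean_standard": mean_s, "mean_doped": mean_d,
            "log2_ratio": float(np.log2(mean_d / mean_s)) if defined
            else float("nan"),
            "defined": defined,
        })
    per_species = pd.DataFrame(sp_rows)

    ion_rows = []
    for gname, gdef in groups.items():
        for mz in gdef["members"]:
            s = extract_ion_image(img_standard, mz, tol_ppm).mean(mask_s)
            d = extract_ion_image(img_doped, mz, tol_ppm).mean(mask_d)
            ion_rows.append({
                "group": gname, "mz": mz,
                "mean_standard": s, "mean_doped": d,
                "prefers_standard": bool(s > d),
            })

    cat_rows = []
    for cat, grp in per_species[per_species["defined"]].groupby(
            "lmsd_category", sort=True):
        r = grp["log2_ratio"].to_numpy()
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        cat_rows.append({"lmsd_category": cat, "n": r.size,
                         "mean": float(r.mean()), "median": float(med),
                         "q1": float(q1), "q3": float(q3)})
    per_category = pd.DataFrame(cat_rows)

    per_ion = pd.DataFrame(ion_rows)
    grp_rows = []
    for gname, gdef in groups.items():
        glo, ghi = gdef["window"]
        sub = per_ion[per_ion["group"] == gname] if not per_ion.empty \
            else per_ion
        sum_s = float(sub["mean_standard"].sum()) if not sub.empty else 0.0
        sum_d = float(sub["mean_doped"].sum()) if not sub.empty else 0.0
        grp_rows.append({
            "group": gname, "window_low": glo, "window_high": ghi,
            "n_members": int(len(sub)),
            "member_mzs": ";".join(f"{m:.4f}" for m in sub["mz"]) if not
            sub.empty else "",
            "sum_standard": sum_s, "sum_doped": sum_d,
            "fold_standard_over_doped": (sum_s / sum_d) if sum_d > 0
            else float("nan"),
        })
    mass_groups = pd.DataFrame(grp_rows)
    pref = (float(per_ion["prefers_standard"].mean())
            if not per_ion.empty else float("nan"))
    return SolventComparison(per_species, per_category, mass_groups,
                             per_ion, pref)


def reflection_data(
    img_a: SpectrumImage,
    img_b: SpectrumImage,
    bin_width: float = 1.0,
    mask_method: str = "otsu",
) -> pd.DataFrame:
    """Paired binned mean on-tissue spectra for a mirror (reflection) plot.

    Each condition's spectrum is the intensity histogram of its on-tissue
    peaks divided by the number of on-tissue pixels, binned at ``bin_width``
    over the overlapping scan range.  The table carries both sides positive;
    plotting negates side b.  Total bin content equals the mean on-tissue
    TIC of each image.
    """
    lo = max(img_a.metadata.scan_range[0], img_b.metadata.scan_range[0])
    hi = min(img_a.metadata.scan_range[1], img_b.metadata.scan_range[1])
    if not lo < hi:
        raise ValueError("scan ranges do not overlap")
    edges = np.arange(lo, hi + bin_width, bin_width)

    def _binned(img: SpectrumImage) -> np.ndarray:
        mask = tissue_mask(tic_image(img), method=mask_method)
        on = mask[img.coords[:, 1], img.coords[:, 0]]
        keep = np.repeat(on, np.diff(img.offsets))
        mzs, ints = img.mzs[keep], img.intensities[keep]
        inside = (mzs >= lo) & (mzs < edges[-1])
        hist, _ = np.histogram(mzs[inside], bins=edges,
                               weights=ints[inside])
        n_on = int(on.sum())
        return hist / max(n_on, 1)

    ha, hb = _binned(img_a), _binned(img_b)
    return pd.DataFrame({
        "mz_low": edges[:-1], "mz_high": edges[1:],
        "mean_a": ha, "mean_b": hb,
    })
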