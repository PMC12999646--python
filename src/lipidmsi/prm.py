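"""Parallel-reaction-monitoring confirmation of the psychosine precursor.

Breakdown-curve construction over a collision-energy (NCE) ramp, selection
of the optimal NCE, ion-abundance-ratio analysis, isotope-envelope cosine
matching, and precursor/fragment image colocalization.  The quantitative
fragments are the galactose-loss ion (nominal m/z 282) and the
galactose-plus-water-loss ion (nominal m/z 264); both form independently
below ~35% NCE, so both are treated as quantitative.

The "optimal" NCE is formalised as the grid point where the two
quantitative fragments are closest to equal abundance subject to a minimum
total fragment yield (default 25% of the ion population); ties break to the
lower collision energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .ion_images import colocalization_score, extract_ion_image, ppm_window
from .msi_io import SpectrumImage
from .synthetic import FRAGMENT_264, FRAGMENT_282, PSYCHOSINE_MH

__all__ = [
    "PrmSettings",
    "BreakdownCurve",
    "IonRatioResult",
    "build_breakdown_curve",
    "optimal_nce",
    "ion_ratio_analysis",
    "isotope_match_score",
    "fragment_coloc",
    "read_nce_ramp_table",
]


@dataclass(frozen=True)
class FragmentDef:
    label: str
    mz: float
    quantitative: bool = True


@dataclass
class PrmSettings:
    """Acquisition/extraction settings of the PRM experiment."""

    precursor_mz: float = PSYCHOSINE_MH
    isolation_width: float = 5.0                 # Th
    scan_range: Tuple[float, float] = (40.0, 500.0)
    fragments: Tuple[FragmentDef, ...] = (
        FragmentDef("frag_264", FRAGMENT_264, True),
        FragmentDef("frag_282", FRAGMENT_282, True),
    )
    tol_ppm: float = 5.0
    min_fragment_yield: float = 0.25

    def __post_init__(self) -> None:
        if self.isolation_width <= 0:
            raise ValueError("isolation_width must be positive")
        lo, hi = self.scan_range
        for f in self.fragments:
            if not lo <= f.mz <= hi:
                raise ValueError(
                    f"fragment {f.label} m/z {f.mz} outside scan range")

    def quantitative_fragments(self) -> List[FragmentDef]:
        return [f for f in self.fragments if f.quantitative]

    def ion_labels(self) -> List[str]:
        return ["precursor"] + [f.label for f in self.fragments]

    def ion_mzs(self) -> Dict[str, float]:
        out = {"precursor": self.precursor_mz}
        out.update({f.label: f.mz for f in self.fragments})
        return out


@dataclass
class BreakdownCurve:
    """Per-NCE abundances of the precursor and each fragment."""

    nce_grid: np.ndarray
    abundances: pd.DataFrame        # index = NCE, columns = ion labels
    settings: PrmSettings

    def __post_init__(self) -> None:
        self.nce_grid = np.asarray(self.nce_grid, dtype=float)
        if np.any(np.diff(self.nce_grid) <= 0):
            raise ValueError("NCE grid must be strictly ascending")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    def fractions(self) -> pd.DataFrame:
        """Fraction-of-total per NCE (rows sum to 1 where total > 0)."""
        total = self.abundances.sum(axis=1)
        return self.abundances.div(total.replace(0, np.nan), axis=0)


def _window_sum(mzs: np.ndarray, ints: np.ndarray, target: float,
                tol_ppm: float) -> float:
    lo, hi = ppm_window(target, tol_ppm)
    i0, i1 = np.searchsorted(mzs, (lo, hi), side="left")
    return float(ints[i0:i1].sum())


def build_breakdown_curve(
    spectra_by_nce: Mapping[float, Sequence[Tuple[np.ndarray, np.ndarray]]],
    settings: PrmSettings | None = None,
) -> BreakdownCurve:
    """Average each ion's ppm-window abundance over the scans at each NCE.

    ``spectra_by_nce`` maps NCE (%) to a sequence of centroided scans, each
    an ``(mz, intensity)`` array pair with m/z sorted ascending.  The same
    half-open ppm window convention as ion-image extraction applies.
    """
    settings = settings if settings is not None else PrmSettings()
    if len(spectra_by_nce) < 3:
        raise ValueError("need at least 3 NCE points for a breakdown curve")
    grid = sorted(float(n) for n in spectra_by_nce)
    targets = settings.ion_mzs()
    rows = []
    for nce in grid:
        scans = spectra_by_nce[nce]
        acc = {lab: 0.0 for lab in targets}
        for mzs, ints in scans:
            mzs = np.asarray(mzs, float)
            ints = np.asarray(ints, float)
            for lab, mz in targets.items():
                acc[lab] += _window_sum(mzs, ints, mz, settings.tol_ppm)
        rows.append({lab: v / max(len(scans), 1) for lab, v in acc.items()})
    df = pd.DataFrame(rows, index=pd.Index(grid, name="nce"))
    return BreakdownCurve(np.array(grid), df, settings)


def optimal_nce(curve: BreakdownCurve) -> float:
    """NCE grid point with the most balanced quantitative fragments.

    Minimises |fraction(264) − fraction(282)| over grid points whose total
    quantitative-fragment fraction meets ``min_fragment_yield``; ties go to
    the lower NCE.  If no point meets the yield constraint, raises with the
    best candidate listed.
    """
    quant = [f.label for f in curve.settings.quantitative_fragments()]
    if len(quant) != 2:
        raise ValueError("optimal_nce needs exactly 2 quantitative fragments")
    frac = curve.fractions()
    f_a, f_b = frac[quant[0]].to_numpy(), frac[quant[1]].to_numpy()
    yield_total = f_a + f_b
    diff = np.abs(f_a - f_b)
    feasible = yield_total >= curve.settings.min_fragment_yield
    if not feasible.any():
        best = int(np.nanargmax(yield_total))
        raise ValueError(
            "no NCE reaches the minimum fragment yield "
            f"{curve.settings.min_fragment_yield:.2f}; best candidate "
            f"NCE {curve.nce_grid[best]:g} with yield {yield_total[best]:.3f}"
        )
    diff = np.where(feasible, diff, np.inf)
    return float(curve.nce_grid[int(np.argmin(diff))])   # argmin takes first


@dataclass
class IonRatioResult:
    """Abundances and fractions of precursor + quantitative fragments."""

    abundances: Dict[str, float]
    fractions: Dict[str, float]
    equality_ratio: float          # min/max of the two quantitative fragments


def ion_ratio_analysis(
    source,
    settings: PrmSettings | None = None,
    mask: np.ndarray | None = None,
) -> IonRatioResult:
    """Ion-abundance-ratio analysis of a spectrum or a PRM image.

    ``source`` is either an ``(mz, intensity)`` array pair or a
    :class:`SpectrumImage` (abundances are then summed over on-grid pixels,
    optionally restricted to ``mask``).  Fractions are of the summed
    precursor + quantitative fragment abundances; ``equality_ratio`` is the
    min/max ratio of the two quantitative fragments (1 = perfectly equal).
    """
    settings = settings if settings is not None else PrmSettings()
    labels = ["precursor"] + [f.label for f in
                              settings.quantitative_fragments()]
    targets = settings.ion_mzs()
    # windows must not overlap or an ion could be counted twice
    spans = sorted(ppm_window(targets[lab], settings.tol_ppm)
                   for lab in labels)
    for (l0, h0), (l1, h1) in zip(spans, spans[1:]):
        if l1 < h0:
            raise ValueError("extraction windows overlap")

    abund: Dict[str, float] = {}
    if isinstance(source, SpectrumImage):
        for lab in labels:
            im = extract_ion_image(source, targets[lab], settings.tol_ppm)
            v = im.observed_values(mask)
            abund[lab] = float(v.sum())
    else:
        mzs, ints = (np.asarray(a, float) for a in source)
        for lab in labels:
            abund[lab] = _window_sum(mzs, ints, targets[lab],
                                     settings.tol_ppm)

    total = sum(abund.values())
    fractions = {k: (v / total if total > 0 else 0.0)
                 for k, v in abund.items()}
    quant = [f.label for f in settings.quantitative_fragments()]
    fa, fb = abund[quant[0]], abund[quant[1]]
    hi = max(fa, fb)
    equality = (min(fa, fb) / hi) if hi > 0 else 0.0
    return IonRatioResult(abund, fractions, equality)


def isotope_match_score(
    observed: Tuple[np.ndarray, np.ndarray],
    theoretical: chem.IsotopePattern,
    tol_ppm: float = 5.0,
) -> float:
    """Cosine similarity between observed and theoretical isotope envelopes.

    Observed peaks are matched to theoretical entries by nearest m/z within
    ``tol_ppm`` (intensities of multiple matches summed); unmatched
    theoretical entries contribute zero.  Requires at least two observed
    isotopologue peaks.
    """
    mzs, ints = (np.asarray(a, float) for a in observed)
    if mzs.size < 2:
        raise ValueError("need at least 2 observed isotopologue peaks")
    theo_mz = theoretical.mz
    theo_ab = theoretical.abundance
    obs_vec = np.zeros_like(theo_ab)
    for mz, inten in zip(mzs, ints):
        ppm = np.abs((mz - theo_mz) / theo_mz) * 1e6
        j = int(np.argmin(ppm))
        if ppm[j] <= tol_ppm:
            obs_vec[j] += inten
    denom = np.linalg.norm(obs_vec) * np.linalg.norm(theo_ab)
    if denom == 0:
        return 0.0
    return float(np.dot(obs_vec, theo_ab) / denom)


def observed_envelope(img: SpectrumImage, theoretical: chem.IsotopePattern,
                      tol_ppm: float = 5.0) -> Tuple[np.ndarray, np.ndarray]:
    """Summed per-isotopologue abundances of a PRM image's precursor."""
    mzs, ints = [], []
    for mz in theoretical.mz:
        im = extract_ion_image(img, float(mz), tol_ppm)
        mzs.append(float(mz))
        ints.append(float(im.observed_values().sum()))
    return np.array(mzs), np.array(ints)


def fragment_coloc(
    img: SpectrumImage,
    settings: PrmSettings | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise colocalization among precursor and fragment ion images."""
    settings = settings if settings is not None else PrmSettings()
    targets = settings.ion_mzs()
    images = {lab: extract_ion_image(img, mz, settings.tol_ppm, label=lab)
              for lab, mz in targets.items()}
    labels = list(images)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            score = colocalization_score(images[a], images[b], mask)
            rows.append({"ion_a": a, "ion_b": b, **score})
    return pd.DataFrame(rows)


def read_nce_ramp_table(path) -> Dict[float, List[Tuple[np.ndarray, np.ndarray]]]:
    """Read a delimited NCE-ramp table (columns nce, scan, mz, intensity).

    The ``scan`` column is optional; without it each NCE's rows form one
    scan.  Returns the mapping :func:`build_breakdown_curve` consumes.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"nce", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"ramp table needs columns {sorted(required)}")
    if "scan" not in df.columns:
        df = df.assign(scan=0)
    out: Dict[float, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for (nce, _scan), grp in df.groupby(["nce", "scan"], sort=True):
        grp = grp.sort_values("mz")
        out.setdefault(float(nce), []).append(
            (grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float)))
    return out
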