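"""Lipid panel: the species the pipeline targets and their ion chemistry.

A :class:`PanelEntry` describes one analyte either by molecular formula plus
a set of adducts with abundance fractions, or (for putative annotations
known only by their observed ion) by a single explicit ion m/z.  The default
panel covers the study analytes — psychosine, cholesterol, two
galactosylceramides, a sphingomyelin, five free fatty acids — plus the 14
solvent-comparison ions in three mass-range groups, each tagged with its
LIPID MAPS (LMSD) category.

Per-region baselines and condition fold-changes on each entry drive the
synthetic phantom; they are ignored when the panel is only used for
extraction from real data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import chem
from .chem import Formula, get_adduct, parse_formula

__all__ = [
    "LMSD_CATEGORIES",
    "PanelEntry",
    "default_panel",
    "read_panel",
    "write_panel",
    "panel_ion_mzs",
    "null_panel",
    "with_uniform_suppression",
]

LMSD_CATEGORIES = ("FA", "GL", "GP", "SP", "ST", "PR", "SL", "PK")

REGIONS = ("cerebrum", "visual_cortex", "midbrain", "cerebellum", "brain_stem")


@dataclass
class PanelEntry:
    """One target species.

    ``baseline_abundance`` maps region name -> expected healthy abundance in
    charges/s (key ``"default"`` fills unlisted regions).
    ``condition_log2fc`` maps region -> log2 fold change applied in the
    diseased condition.  ``adduct_fractions`` (formula entries only) split
    the species abundance across adduct ions and must sum to 1.
    ``solvent_suppression_log2`` is the log2 change of this species under
    the NH4F-doped electrospray solvent relative to standard.
    """

    name: str
    formula: Optional[Formula] = None
    ion_mz: Optional[float] = None
    lmsd_category: str = "SP"
    baseline_abundance: Dict[str, float] = field(default_factory=lambda: {"default": 100.0})
    condition_log2fc: Dict[str, float] = field(default_factory=dict)
    adduct_fractions: Dict[str, float] = field(default_factory=lambda: {"[M+H]+": 1.0})
    solvent_suppression_log2: float = 0.0

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.ion_mz is None):
            raise ValueError(
                f"panel entry {self.name!r}: exactly one of formula or ion_mz "
                "must be given"
            )
        if self.lmsd_category not in LMSD_CATEGORIES:
            raise ValueError(
                f"panel entry {self.name!r}: unknown LMSD category "
                f"{self.lmsd_category!r}"
            )
        if any(v < 0 for v in self.baseline_abundance.values()):
            raise ValueError(f"panel entry {self.name!r}: negative baseline")
        if self.formula is not None:
            total = sum(self.adduct_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"panel entry {self.name!r}: adduct fractions sum to {total}"
                )

    # -- ion chemistry -----------------------------------------------------
    def ion_mz_map(self) -> Dict[str, float]:
        """adduct label -> theoretical ion m/z (single pseudo-ion for
        m/z-only entries)."""
        if self.formula is None:
            return {"[ion]": float(self.ion_mz)}
        return {
            name: chem.adduct_mz(self.formula, get_adduct(name))
            for name in self.adduct_fractions
        }

    def ion_fraction_map(self) -> Dict[str, float]:
        if self.formula is None:
            return {"[ion]": 1.0}
        return dict(self.adduct_fractions)

    def baseline(self, region: str) -> float:
        if region in self.baseline_abundance:
            return self.baseline_abundance[region]
        return self.baseline_abundance.get("default", 0.0)

    def log2fc(self, region: str) -> float:
        if region in self.condition_log2fc:
            return self.condition_log2fc[region]
        return self.condition_log2fc.get("default", 0.0)


def _fa(name: str, formula: str, fc: float, baseline: float) -> PanelEntry:
    return PanelEntry(
        name=name, formula=parse_formula(formula), lmsd_category="FA",
        baseline_abundance={"default": baseline},
        condition_log2fc={"default": fc},
        adduct_fractions={"[M+H]+": 1.0},
        solvent_suppression_log2=-1.0,
    )


#: the 14 ions of the three solvent-comparison mass-range groups
#: (lower 300–325, central 545–570, upper 745–770 Th)
SOLVENT_GROUP_IONS = (
    ("PR01_305.2475", 305.2475, "PR"),
    ("FA01_313.2737", 313.2737, "FA"),
    ("FA01_315.2530", 315.2530, "FA"),
    ("FA07_548.5401", 548.5401, "FA"),
    ("SP01_566.5506", 566.5506, "SP"),
    ("GP01_758.5694", 758.5694, "GP"),
    ("GP01_760.5851", 760.5851, "GP"),
    ("SP01_761.5886", 761.5886, "SP"),
    ("GP01_762.6007", 762.6007, "GP"),
    ("GP10_764.5225", 764.5225, "GP"),
    ("GP10_766.5381", 766.5381, "GP"),
    ("GP01_768.5514", 768.5514, "GP"),
    ("GP01_768.5538", 768.5538, "GP"),
    ("GP01_772.5851", 772.5851, "GP"),
)

#: default mass-range groups for the two-solvent comparison: nominal Th
#: window plus the explicit member ion m/z evaluated for it (3 + 2 + 9 = 14
#: ions; the windows are descriptive labels — the upper group's heaviest
#: member sits nominally just above its window)
DEFAULT_MASS_GROUPS = {
    "lower": {
        "window": (300.0, 325.0),
        "members": [mz for _, mz, _ in SOLVENT_GROUP_IONS if mz < 500.0],
    },
    "central": {
        "window": (545.0, 570.0),
        "members": [mz for _, mz, _ in SOLVENT_GROUP_IONS if 500.0 < mz < 700.0],
    },
    "upper": {
        "window": (745.0, 770.0),
        "members": [mz for _, mz, _ in SOLVENT_GROUP_IONS if mz > 700.0],
    },
}


def default_panel() -> List[PanelEntry]:
    """The built-in ~25-species panel used by the phantom and the pipeline.

    Psychosine carries the disease signature: scarce near the detection
    floor in the healthy brain and log2fc = 2.5 in cerebellum, brain stem
    and the visual-cortex hotspot of the diseased brain.  The free fatty
    acids carry small-to-moderate (0.6–1.5) fold changes; cholesterol is
    abundant everywhere with no condition effect but a −1 log2 suppression
    under the doped solvent.
    """
    panel: List[PanelEntry] = []
    panel.append(PanelEntry(
        name="psychosine",
        formula=parse_formula("C24H47NO7"),
        lmsd_category="SP",
        baseline_abundance={
            "cerebrum": 2.0, "midbrain": 2.0,
            "visual_cortex": 12.0, "cerebellum": 12.0, "brain_stem": 12.0,
        },
        condition_log2fc={
            "visual_cortex": 2.5, "cerebellum": 2.5, "brain_stem": 2.5,
        },
        adduct_fractions={"[M+H]+": 0.7, "[M+H-H2O]+": 0.1,
                          "[M+NH4]+": 0.1, "[M+Na]+": 0.1},
        solvent_suppression_log2=0.0,
    ))
    panel.append(PanelEntry(
        name="cholesterol",
        formula=parse_formula("C27H46O"),
        lmsd_category="ST",
        baseline_abundance={"default": 600.0, "cerebellum": 800.0,
                            "brain_stem": 800.0},
        condition_log2fc={},
        adduct_fractions={"[M+H-H2O]+": 0.7, "[M+H]+": 0.1,
                          "[M+NH4]+": 0.1, "[M+Na]+": 0.1},
        solvent_suppression_log2=-1.0,
    ))
    panel.append(PanelEntry(
        name="GalCer(d18:1/18:0)",
        formula=parse_formula("C42H81NO8"),
        lmsd_category="SP",
        baseline_abundance={"default": 300.0},
        condition_log2fc={"default": 0.8},
        adduct_fractions={"[M+H]+": 0.6, "[M+Na]+": 0.2, "[M+H-H2O]+": 0.2},
        solvent_suppression_log2=-0.8,
    ))
    panel.append(PanelEntry(
        name="GalCer(d18:1/22:0)",
        formula=parse_formula("C46H89NO8"),
        lmsd_category="SP",
        baseline_abundance={"default": 250.0},
        condition_log2fc={"default": 0.7},
        # no [M+Na]+: 806.6 Th sits outside the default 200-800 scan range
        adduct_fractions={"[M+H]+": 0.7, "[M+H-H2O]+": 0.3},
        solvent_suppression_log2=-0.8,
    ))
    panel.append(PanelEntry(
        name="SM(d18:1/16:0)",
        formula=parse_formula("C39H79N2O6P"),
        lmsd_category="SP",
        baseline_abundance={"default": 200.0},
        condition_log2fc={"default": 0.3},
        adduct_fractions={"[M+H]+": 0.8, "[M+Na]+": 0.2},
        solvent_suppression_log2=-0.6,
    ))
    # essential free fatty acids: small-to-moderate effect sizes
    panel.append(_fa("oleic acid", "C18H34O2", 0.9, 400.0))
    panel.append(_fa("DHA", "C22H32O2", 1.1, 350.0))
    panel.append(_fa("EPA", "C20H30O2", 0.8, 250.0))
    panel.append(_fa("linoleic acid", "C18H32O2", 1.0, 300.0))
    panel.append(_fa("arachidonic acid", "C20H32O2", 0.7, 450.0))
    # the 14 solvent-comparison ions as m/z-only putative annotations
    for name, mz, cat in SOLVENT_GROUP_IONS:
        panel.append(PanelEntry(
            name=name, ion_mz=mz, lmsd_category=cat,
            baseline_abundance={"default": 150.0},
            condition_log2fc={},
            solvent_suppression_log2=-1.0,
        ))
    return panel


def null_panel() -> List[PanelEntry]:
    """The default panel with every condition fold change zeroed."""
    panel = copy.deepcopy(default_panel())
    for e in panel:
        e.condition_log2fc = {}
    return panel


def with_uniform_suppression(panel: Sequence[PanelEntry],
                             log2: float) -> List[PanelEntry]:
    """Copy of ``panel`` with one doped-solvent suppression for all species."""
    out = copy.deepcopy(list(panel))
    for e in out:
        e.solvent_suppression_log2 = log2
    return out


# --------------------------------------------------------------------------
# panel files
# --------------------------------------------------------------------------

def write_panel(panel: Sequence[PanelEntry], path) -> None:
    """Write the panel as tab-delimited text.

    Columns: name, formula (empty for m/z-only entries), ion_mz,
    lmsd_category, adducts (``name:fraction`` separated by ``;``),
    suppression_log2.
    """
    rows = []
    for e in panel:
        rows.append({
            "name": e.name,
            "formula": e.formula.hill() if e.formula is not None else "",
            "ion_mz": "" if e.ion_mz is None else f"{e.ion_mz:.4f}",
            "lmsd_category": e.lmsd_category,
            "adducts": ";".join(f"{k}:{v:g}" for k, v in
                                e.adduct_fractions.items())
            if e.formula is not None else "",
            "suppression_log2": e.solvent_suppression_log2,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path) -> List[PanelEntry]:
    """Read a tab-delimited panel file written by :func:`write_panel`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: List[PanelEntry] = []
    for _, row in df.iterrows():
        formula = parse_formula(row["formula"]) if row.get("formula") else None
        ion_mz = float(row["ion_mz"]) if row.get("ion_mz") else None
        adducts: Dict[str, float] = {}
        if row.get("adducts"):
            for tok in row["adducts"].split(";"):
                k, _, v = tok.rpartition(":")
                adducts[get_adduct(k).name] = float(v)
        kwargs = {}
        if formula is not None and adducts:
            kwargs["adduct_fractions"] = adducts
        out.append(PanelEntry(
            name=row["name"], formula=formula, ion_mz=ion_mz,
            lmsd_category=row.get("lmsd_category", "SP") or "SP",
            solvent_suppression_log2=float(row.get("suppression_log2") or 0.0),
            **kwargs,
        ))
    return out


def panel_ion_mzs(panel: Sequence[PanelEntry]) -> pd.DataFrame:
    """Long table (species, adduct, mz) of every target ion in the panel."""
    rows = []
    for e in panel:
        for adduct, mz in e.ion_mz_map().items():
            rows.append({"species": e.name, "adduct": adduct, "mz": mz,
                         "lmsd_category": e.lmsd_category})
    return pd.DataFrame(rows)
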