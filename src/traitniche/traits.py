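"""Functional-trait calculation from raw greenhouse measurement records.

The calculators reproduce the standard plant-ecology definitions for leaf,
fine-root, taproot and whole-root-system traits of pot-grown individuals.
Inputs arrive in the units they are measured in (cm2, g, mm, m, cm3) and
outputs are returned in the units conventionally reported for each trait:

=====================================  =================
specific leaf area (SLA)               m2.kg-1
leaf dry matter content (LDMC)         mg.g-1
mean root diameter (D)                 mm
specific root length (SRL)             m.g-1
root tissue density (RTD)              mg.cm-3
specific root area (SRA)               dm2.g-1
very fine root percentage              % of root length
root P use efficiency (RPUE)           m.mg-1
investment in nodules                  g.m-1
specific taproot length (STRL)         m.g-1
taproot tissue density (TRTD)          g.cm-3
taproot percentage                     % of root mass
depth of 95% root length (depth95)     cm
root length density (RLD)              cm.cm-3
mycorrhization rate                    %
=====================================  =================

Two definitional choices deserve note. Taproot tissue density is mass /
volume (g.cm-3) — the density convention the reported units imply.
Investment in nodules is nodule dry mass per unit root length (g.m-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, UndefinedTraitError

__all__ = [
    "TRAIT_COLUMNS",
    "TRAIT_UNITS",
    "RecordBundle",
    "compute_trait_row",
    "write_trait_table",
    "read_trait_table",
    "LeafRecord",
    "RootSampleRecord",
    "DepthProfile",
    "IntersectCount",
    "compute_leaf_traits",
    "compute_fine_root_traits",
    "compute_taproot_traits",
    "compute_depth95",
    "compute_rld",
    "compute_mycorrhization_rate",
    "summarize_traits",
    "VERY_FINE_DIAMETER_MM",
]

# fine roots with diameter below this are "very fine" (field convention)
VERY_FINE_DIAMETER_MM = 0.2

# canonical trait-table column names (ASCII) and reporting units
TRAIT_UNITS = {
    "Aerenchyma": "%",
    "Diameter": "mm",
    "Hairs": "um",
    "Investment in nodules": "g.m-1",
    "Mycorrhizal rate": "%",
    "Root phosphorus use efficiency": "m.mg-1",
    "Root-surface phosphatase activity": "ug.m-1.h-1",
    "Root tissue density": "mg.cm-3",
    "Specific root area": "dm2.g-1",
    "Specific root length": "m.g-1",
    "Stele percentage": "%",
    "Very fine root percentage": "%",
    "Specific taproot length": "m.g-1",
    "Taproot tissue density": "g.cm-3",
    "Depth of 95% root length": "cm",
    "Fine root biomass": "g",
    "Root system biomass": "g",
    "Root length density": "cm.cm-3",
    "Taproot biomass": "g",
    "Taproot percentage": "%",
    "Specific leaf area": "m2.kg-1",
    "Leaf dry matter content": "mg.g-1",
    "Aboveground biomass": "g",
    "Root:shoot ratio": "",
    "Total biomass": "g",
}
TRAIT_COLUMNS = list(TRAIT_UNITS)


@dataclass(frozen=True)
class LeafRecord:
    """One individual's leaf sample: area (cm2), fresh and dry mass (g)."""

    individual_id: str
    leaf_area: float  # cm2
    leaf_fresh_mass: float  # g
    leaf_dry_mass: float  # g

    def __post_init__(self):
        if self.leaf_area <= 0:
            raise InvalidRecordError(f"{self.individual_id}: leaf area must be > 0")
        if self.leaf_dry_mass <= 0:
            raise InvalidRecordError(f"{self.individual_id}: dry mass must be > 0")
        if self.leaf_dry_mass > self.leaf_fresh_mass:
            raise InvalidRecordError(
                f"{self.individual_id}: dry mass exceeds fresh mass"
            )


@dataclass(frozen=True)
class RootSampleRecord:
    """A scanned nodule-free fine-root sample.

    ``length_by_diameter_class`` holds (class median diameter in mm, length
    in m) pairs as produced by root-scan image analysis. ``total_length``
    must equal the sum of class lengths. ``phosphatase_activity`` is carried
    through unchanged (it is measured, not derived).
    """

    individual_id: str
    length_by_diameter_class: tuple  # ((mm, m), ...)
    total_length: float  # m
    dry_mass: float  # g
    volume: float  # cm3
    p_concentration: float = float("nan")  # mg P per g
    nodule_dry_mass: float = 0.0  # g
    phosphatase_activity: float = float("nan")  # ug.m-1.h-1

    def __post_init__(self):
        classes = tuple((float(d), float(l)) for d, l in self.length_by_diameter_class)
        object.__setattr__(self, "length_by_diameter_class", classes)
        if not classes:
            raise InvalidRecordError(f"{self.individual_id}: empty diameter-class list")
        if any(l < 0 for _, l in classes) or any(d <= 0 for d, _ in classes):
            raise InvalidRecordError(f"{self.individual_id}: invalid class entries")
        total = sum(l for _, l in classes)
        if total <= 0:
            raise InvalidRecordError(f"{self.individual_id}: zero total root length")
        if abs(total - self.total_length) > 1e-9 * max(total, 1.0):
            raise InvalidRecordError(
                f"{self.individual_id}: total_length inconsistent with classes"
            )
        if self.dry_mass <= 0 or self.volume <= 0:
            raise InvalidRecordError(
                f"{self.individual_id}: dry mass and volume must be > 0"
            )
        if self.nodule_dry_mass < 0:
            raise InvalidRecordError(f"{self.individual_id}: negative nodule mass")


@dataclass(frozen=True)
class DepthProfile:
    """Per-segment root distribution down a pot (20-cm segments by default)."""

    individual_id: str
    fine_root_length_per_segment: tuple  # m, top to bottom
    segment_boundaries: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)  # cm
    fine_root_mass_per_segment: tuple = ()  # g
    coarse_root_mass_per_segment: tuple = ()  # g
    taproot_length: float = 0.0  # cm
    pot_volume: float = float("nan")  # cm3

    def __post_init__(self):
        b = tuple(float(x) for x in self.segment_boundaries)
        object.__setattr__(self, "segment_boundaries", b)
        if b[0] != 0.0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise InvalidRecordError(
                f"{self.individual_id}: boundaries must strictly increase from 0"
            )
        lengths = tuple(float(x) for x in self.fine_root_length_per_segment)
        object.__setattr__(self, "fine_root_length_per_segment", lengths)
        if len(lengths) != len(b) - 1:
            raise InvalidRecordError(
                f"{self.individual_id}: one length per segment required"
            )
        if any(x < 0 for x in lengths) or self.taproot_length < 0:
            raise InvalidRecordError(f"{self.individual_id}: negative length")
        for name in ("fine_root_mass_per_segment", "coarse_root_mass_per_segment"):
            masses = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, masses)
            if masses and (len(masses) != len(b) - 1 or any(m < 0 for m in masses)):
                raise InvalidRecordError(f"{self.individual_id}: bad {name}")


@dataclass(frozen=True)
class IntersectCount:
    """Grid-line intersect counts for mycorrhizal colonization."""

    individual_id: str
    amf_intersects: int
    total_intersects: int

    def __post_init__(self):
        if self.total_intersects <= 0:
            raise InvalidRecordError(f"{self.individual_id}: no intersects counted")
        if not 0 <= self.amf_intersects <= self.total_intersects:
            raise InvalidRecordError(
                f"{self.individual_id}: AMF intersects outside [0, total]"
            )


def compute_leaf_traits(rec: LeafRecord):
    """SLA (m2.kg-1) and LDMC (mg.g-1) from one leaf record.

    SLA is leaf area over leaf dry mass; LDMC is dry over fresh mass.
    cm2/g converts to m2/kg by the factor 0.1; g/g to mg/g by 1000.
    """
    sla = 0.1 * rec.leaf_area / rec.leaf_dry_mass
    ldmc = 1000.0 * rec.leaf_dry_mass / rec.leaf_fresh_mass
    return sla, ldmc


def compute_fine_root_traits(rec: RootSampleRecord):
    """Fine-root trait bundle from a scanned sample.

    Returns a dict with mean diameter D (length-weighted mean of class
    median diameters, mm), SRL (m.g-1), RTD (mg.cm-3), SRA (cylinder
    lateral surface per dry mass, dm2.g-1), very fine root percentage
    (% of length with class median < 0.2 mm), RPUE (SRL / root P
    concentration, m.mg-1) and nodule investment (g nodules per m, g.m-1).
    RPUE is NaN when P concentration was not measured; a measured zero P
    concentration raises :class:`UndefinedTraitError`.
    """
    total = sum(l for _, l in rec.length_by_diameter_class)
    d_mean = sum(d * l for d, l in rec.length_by_diameter_class) / total
    srl = total / rec.dry_mass
    rtd = 1000.0 * rec.dry_mass / rec.volume
    # 1 mm * 1 m = 1e-3 m2 = 0.1 dm2 of cylinder surface
    sra = 0.1 * math.pi * sum(d * l for d, l in rec.length_by_diameter_class) / rec.dry_mass
    very_fine = 100.0 * sum(
        l for d, l in rec.length_by_diameter_class if d < VERY_FINE_DIAMETER_MM
    ) / total
    if math.isnan(rec.p_concentration):
        rpue = float("nan")
    elif rec.p_concentration <= 0:
        raise UndefinedTraitError(
            f"{rec.individual_id}: RPUE undefined at zero P concentration"
        )
    else:
        rpue = srl / rec.p_concentration
    nodule_investment = rec.nodule_dry_mass / total
    return {
        "D": d_mean,
        "SRL": srl,
        "RTD": rtd,
        "SRA": sra,
        "very_fine_pct": very_fine,
        "RPUE": rpue,
        "nodule_investment": nodule_investment,
    }


def compute_taproot_traits(taproot_length, taproot_dry_mass, taproot_volume,
                           coarse_mass, total_root_mass):
    """STRL (m.g-1), TRTD (g.cm-3) and taproot percentage of root mass.

    Taproot length in m, masses in g, volume in cm3.
    """
    if taproot_dry_mass <= 0 or taproot_volume <= 0 or total_root_mass <= 0:
        raise InvalidRecordError("taproot mass, volume and total root mass must be > 0")
    if coarse_mass < 0 or coarse_mass > total_root_mass:
        raise InvalidRecordError("coarse root mass must lie in [0, total root mass]")
    strl = taproot_length / taproot_dry_mass
    trtd = taproot_dry_mass / taproot_volume
    taproot_pct = 100.0 * coarse_mass / total_root_mass
    return strl, trtd, taproot_pct


def compute_depth95(profile: DepthProfile) -> float:
    """Depth (cm) at which a linear fit to the cumulative fine-root-length
    profile reaches 95% of total fine root length.

    An ordinary least-squares line (with intercept) is fitted to the points
    (segment lower-boundary depth, cumulative length down to that boundary)
    and solved for 0.95 x total length. Undefined for an all-zero profile or
    a zero fitted slope.
    """
    lengths = np.asarray(profile.fine_root_length_per_segment, dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise UndefinedTraitError(f"{profile.individual_id}: zero total root length")
    if lengths.size < 2:
        raise UndefinedTraitError(f"{profile.individual_id}: need >= 2 segments")
    depths = np.asarray(profile.segment_boundaries[1:], dtype=float)
    cumulative = np.cumsum(lengths)
    slope, intercept = np.polyfit(depths, cumulative, 1)
    if abs(slope) < 1e-12 * total:
        raise UndefinedTraitError(f"{profile.individual_id}: degenerate flat profile")
    return float((0.95 * total - intercept) / slope)


def compute_rld(profile: DepthProfile, srl: float) -> float:
    """Root length density (cm.cm-3): total fine root length (segment fine
    root masses x SRL) plus taproot length, over pot volume."""
    if not profile.pot_volume > 0:
        raise InvalidRecordError(f"{profile.individual_id}: pot volume must be > 0")
    if not profile.fine_root_mass_per_segment:
        raise InvalidRecordError(f"{profile.individual_id}: fine root masses required")
    fine_mass = float(np.sum(profile.fine_root_mass_per_segment))
    fine_length_cm = fine_mass * srl * 100.0
    return (fine_length_cm + profile.taproot_length) / profile.pot_volume


def compute_mycorrhization_rate(c: IntersectCount) -> float:
    """Percentage of root-gridline intersects showing AMF structures."""
    return 100.0 * c.amf_intersects / c.total_intersects


@dataclass(frozen=True)
class RecordBundle:
    """Every raw measurement for one species' individual, grouped.

    Traits that are measured rather than derived (aerenchyma %, stele %,
    root hair length, aboveground biomass; phosphatase activity sits on the
    root sample) pass through :func:`compute_trait_row` unchanged.
    """

    species: str
    leaf: LeafRecord
    root_sample: RootSampleRecord
    profile: DepthProfile
    intersects: IntersectCount
    taproot_length: float  # m
    taproot_dry_mass: float  # g
    taproot_volume: float  # cm3
    aboveground_biomass: float  # g
    passthrough: dict = field(default_factory=dict)  # aerenchyma/hairs/stele


def compute_trait_row(bundle: RecordBundle) -> dict:
    """The full trait row (all reported traits) for one species."""
    sla, ldmc = compute_leaf_traits(bundle.leaf)
    fine = compute_fine_root_traits(bundle.root_sample)
    fine_biomass = float(np.sum(bundle.profile.fine_root_mass_per_segment))
    taproot_biomass = float(np.sum(bundle.profile.coarse_root_mass_per_segment))
    root_system = fine_biomass + taproot_biomass
    strl, trtd, taproot_pct = compute_taproot_traits(
        bundle.taproot_length, bundle.taproot_dry_mass, bundle.taproot_volume,
        taproot_biomass, root_system,
    )
    return {
        "Aerenchyma": bundle.passthrough.get("Aerenchyma", float("nan")),
        "Diameter": fine["D"],
        "Hairs": bundle.passthrough.get("Hairs", float("nan")),
        "Investment in nodules": fine["nodule_investment"],
        "Mycorrhizal rate": compute_mycorrhization_rate(bundle.intersects),
        "Root phosphorus use efficiency": fine["RPUE"],
        "Root-surface phosphatase activity": bundle.root_sample.phosphatase_activity,
        "Root tissue density": fine["RTD"],
        "Specific root area": fine["SRA"],
        "Specific root length": fine["SRL"],
        "Stele percentage": bundle.passthrough.get("Stele percentage", float("nan")),
        "Very fine root percentage": fine["very_fine_pct"],
        "Specific taproot length": strl,
        "Taproot tissue density": trtd,
        "Depth of 95% root length": compute_depth95(bundle.profile),
        "Fine root biomass": fine_biomass,
        "Root system biomass": root_system,
        "Root length density": compute_rld(bundle.profile, fine["SRL"]),
        "Taproot biomass": taproot_biomass,
        "Taproot percentage": taproot_pct,
        "Specific leaf area": sla,
        "Leaf dry matter content": ldmc,
        "Aboveground biomass": bundle.aboveground_biomass,
        "Root:shoot ratio": root_system / bundle.aboveground_biomass,
        "Total biomass": root_system + bundle.aboveground_biomass,
    }


def write_trait_table(table: pd.DataFrame, path):
    """Species x trait CSV with a units row beneath the header."""
    units = pd.DataFrame(
        [[TRAIT_UNITS.get(c, "") for c in table.columns]],
        index=pd.Index(["unit"], name=table.index.name or "species"),
        columns=table.columns,
    )
    pd.concat([units, table.astype(object)]).to_csv(path, na_rep="NA")


def read_trait_table(path) -> pd.DataFrame:
    """Read a species x variable CSV, tolerating an optional units row."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    if len(df) and str(df.index[0]).lower() == "unit":
        df = df.iloc[1:]
    return df.apply(pd.to_numeric, errors="coerce")


def summarize_traits(table: pd.DataFrame):
    """Per-trait min / mean / max / CV% summary across species.

    CV is 100 x sample standard deviation (n-1 denominator) over the mean,
    computed on non-NA entries. Columns that are entirely NA (or have fewer
    than 2 usable values) are flagged and excluded from the summary.

    Returns (summary DataFrame indexed by trait, list of flagged columns).
    """
    rows, flagged = {}, []
    for col in table.columns:
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if len(vals) < 2:
            flagged.append(col)
            continue
        mean = vals.mean()
        cv = float("nan") if mean == 0 else 100.0 * vals.std(ddof=1) / mean
        rows[col] = {
            "min": vals.min(),
            "mean": mean,
            "max": vals.max(),
            "cv_pct": cv,
            "n": len(vals),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "trait"
    return summary, flagged
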