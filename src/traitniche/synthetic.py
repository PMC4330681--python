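"""Synthetic data with the statistical structure the analysis assumes.

The generators emulate the study design this package targets: a modest set
of grassland species (13 by default) with

* an ultrametric phylogeny from a Yule (pure-birth) process,
* quantitative traits evolving on that tree under Brownian motion (signal
  present) or drawn as white noise (signal absent),
* ecological-indicator values linearly coupled to a trait with additive
  Gaussian noise (a planted hierarchical trait-indicator correlation),
* missing-at-random indicator cells, and
* raw measurement records constructed to invert *exactly* (1e-9 relative)
  to a target trait table, exercising every trait calculator.

A single integer seed drives a hierarchical random stream (tree, traits,
indicators, missingness), so each stage is independently reproducible.

The packaged ecological-indicator reference table (:func:`fixture_table1`)
lists the 13 wild Fabaceae species with their Ellenberg indicator values for
continentality (C), edaphic humidity (HE), nitrogen (N), pH and salinity (S)
plus a 0-10 phosphorus requirement score (P), NA cells included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .traits import (
    DepthProfile,
    IntersectCount,
    LeafRecord,
    RecordBundle,
    RootSampleRecord,
    TRAIT_COLUMNS,
    VERY_FINE_DIAMETER_MM,
    compute_trait_row,
)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_trait",
    "plant_indicator",
    "inject_missing",
    "generate_trait_targets",
    "generate_measurement_records",
    "fixture_table1",
    "INDICATOR_COLUMNS",
]

INDICATOR_COLUMNS = ["C", "HE", "N", "P", "pH", "S"]

# Ellenberg / P-requirement indicator reference for the 13 study species.
# Verbatim values, NA cells included (10 in total: C 3, N 4, P 2, pH 1).
_TABLE1_ROWS = [
    ("Anthyllis vulneraria", 3, 3, 2, 2.9, 7, 0),
    ("Lotus corniculatus", 3, 7, 4, 0.0, 7, 4),
    ("Medicago lupulina", None, 4, None, 3.8, 8, 0),
    ("Medicago sativa", 7, 3, None, 10.0, 9, 0),
    ("Melilotus albus", 6, 3, 4, None, 7, 0),
    ("Onobrychis viciifolia", 6, 3, 3, 4.0, 8, 0),
    ("Securigera varia", 5, 4, 3, None, 9, 0),
    ("Trifolium campestre", 3, 4, 3, 4.6, 6, 0),
    ("Trifolium fragiferum", 5, 7, 7, 8.2, 8, 4),
    ("Trifolium pratense", 3, 5, None, 0.0, 6, 0),
    ("Trifolium repens", None, 5, 6, 0.0, 6, 1),
    ("Vicia cracca", None, 6, None, 3.8, None, 1),
    ("Vicia tenuifolia", 6, 3, 2, 8.3, 8, 0),
]


def fixture_table1() -> pd.DataFrame:
    """The packaged species x ecological-indicator table (13 x 6, with NA)."""
    df = pd.DataFrame(
        [row[1:] for row in _TABLE1_ROWS],
        index=pd.Index([row[0] for row in _TABLE1_ROWS], name="species"),
        columns=INDICATOR_COLUMNS,
        dtype=float,
    )
    return df


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale simulation settings.

    Defaults mirror the emulated design: 13 species; unit-rate Yule tree;
    unit-variance Brownian traits; indicator = slope x trait + N(0, noise).
    The default noise_sd of 0.75 puts the population correlation between
    hierarchical (signed pairwise-difference) trait and indicator distances
    at slope/sqrt(slope^2 + noise_sd^2) = 0.8 for a unit-variance trait.
    """

    n_species: int = 13
    tree_model: str = "yule"
    birth_rate: float = 1.0
    trait_model: str = "brownian"
    bm_variance: float = 1.0
    indicator_slope: float = 1.0
    indicator_noise_sd: float = 0.75
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValidationError("n_species must be >= 4")
        if self.tree_model != "yule":
            raise ValidationError(f"unknown tree model: {self.tree_model!r}")
        if self.trait_model not in ("brownian", "white"):
            raise ValidationError(f"unknown trait model: {self.trait_model!r}")
        if self.birth_rate <= 0 or self.bm_variance <= 0:
            raise ValidationError("rates and variances must be positive")
        if self.indicator_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must lie in [0, 1)")

    def streams(self):
        """Independent child RNGs: (tree, traits, indicators, missingness)."""
        kids = np.random.SeedSequence(self.seed).spawn(4)
        return tuple(np.random.default_rng(k) for k in kids)


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_tree(n_species, birth_rate=1.0, seed=None) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with ``n_species`` leaves.

    Lineages split at rate ``birth_rate`` each; the process starts from a
    root with two lineages and is stopped one exponential waiting time after
    the last split, so every tip sits at the same depth. Leaves are labelled
    s01, s02, ... in traversal order.
    """
    if n_species < 2:
        raise ValidationError("need at least 2 species")
    rng = _rng(seed)
    root = dendropy.Node()
    start = {}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        start[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - start[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    for node in active:
        node.edge.length = t_end - start[node]

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    width = max(2, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.require_taxon(f"s{i:0{width}d}")
    tree.is_rooted = True
    return tree


def simulate_trait(tree, model="brownian", bm_variance=1.0, seed=None) -> pd.Series:
    """One quantitative trait over the tree's leaves.

    ``brownian``: root value 0, each branch adds an independent normal
    increment with variance bm_variance x branch length, so tip covariance
    equals bm_variance x shared path length from the root. ``white``:
    independent N(0, bm_variance) per leaf, ignoring the tree.
    """
    rng = _rng(seed)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if model == "white":
        vals = rng.normal(0.0, math.sqrt(bm_variance), size=len(leaves))
        return pd.Series(vals, index=labels)
    if model != "brownian":
        raise ValidationError(f"unknown trait model: {model!r}")
    value = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        if bl is None:
            raise ValidationError("branch lengths required for Brownian traits")
        value[node] = value[node.parent_node] + rng.normal(
            0.0, math.sqrt(bm_variance * bl)
        )
    return pd.Series([value[lf] for lf in leaves], index=labels)


def plant_indicator(trait: pd.Series, slope=1.0, noise_sd=0.75,
                    seed=None) -> pd.Series:
    """Indicator linearly coupled to a trait: slope x trait + N(0, noise_sd)."""
    if not math.isfinite(slope):
        raise ValidationError("slope must be finite")
    rng = _rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(trait)) if noise_sd > 0 else 0.0
    return trait * slope + noise


def inject_missing(table: pd.DataFrame, fraction, seed=None) -> pd.DataFrame:
    """Set a Bernoulli(fraction) random subset of cells to NA.

    Refuses (raises) if any column would be left with fewer than 3 non-NA
    species — the minimum for a usable distance matrix.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must lie in [0, 1)")
    rng = _rng(seed)
    out = table.copy().astype(float)
    if fraction == 0:
        return out
    mask = rng.random(out.shape) < fraction
    out[mask] = np.nan
    short = [c for c in out.columns if out[c].notna().sum() < 3]
    if short:
        raise ValidationError(
            f"missingness leaves fewer than 3 usable species in column(s) {short}"
        )
    return out


# --- feasible trait targets and exactly-inverting measurement records -----

# sampling ranges for the independently chosen target traits (units as in
# the trait registry); the remaining columns are derived for consistency
_FREE_RANGES = {
    "Aerenchyma": (0.0, 12.9),
    "Hairs": (7.9, 39.6),
    "Investment in nodules": (0.02, 0.34),
    "Root phosphorus use efficiency": (20.5, 424.4),
    "Root-surface phosphatase activity": (140.0, 740.0),
    "Root tissue density": (54.9, 209.6),
    "Specific root length": (38.0, 655.6),
    "Stele percentage": (9.3, 38.0),
    "Specific taproot length": (0.24, 2.24),
    "Taproot tissue density": (1.61, 5.35),
    "Depth of 95% root length": (81.8, 99.7),
    "Fine root biomass": (0.42, 10.55),
    "Root length density": (1.23, 9.94),
    "Taproot biomass": (0.25, 13.53),
    "Specific leaf area": (19.2, 31.1),
    "Leaf dry matter content": (138.0, 288.0),
    "Aboveground biomass": (4.0, 19.07),
}


def generate_trait_targets(n_species, seed=None) -> pd.DataFrame:
    """A random, physically consistent species x trait target table.

    Independent traits are drawn uniformly within realistic ranges; traits
    that are arithmetically tied to them (specific root area, root-system
    biomass, taproot percentage, root:shoot ratio, total biomass) are
    derived, and the mycorrhization rate is drawn as an integer intersect
    count out of 300 so the grid-count record inverts exactly.
    """
    rng = _rng(seed)
    width = max(2, len(str(n_species)))
    species = [f"s{i:0{width}d}" for i in range(1, n_species + 1)]
    rows = []
    for _ in species:
        row = {k: rng.uniform(*v) for k, v in _FREE_RANGES.items()}
        d = rng.uniform(0.13, 0.37)
        f_lo = 0.15 if d >= VERY_FINE_DIAMETER_MM else max(
            0.15, 1.0 - d / VERY_FINE_DIAMETER_MM + 0.05
        )
        f = rng.uniform(f_lo, 0.91)
        row["Diameter"] = d
        row["Very fine root percentage"] = 100.0 * f
        row["Mycorrhizal rate"] = 100.0 * int(rng.integers(3, 79)) / 300.0
        row["Specific root area"] = (
            0.1 * math.pi * d * row["Specific root length"]
        )
        root_system = row["Fine root biomass"] + row["Taproot biomass"]
        row["Root system biomass"] = root_system
        row["Taproot percentage"] = 100.0 * row["Taproot biomass"] / root_system
        row["Root:shoot ratio"] = root_system / row["Aboveground biomass"]
        row["Total biomass"] = root_system + row["Aboveground biomass"]
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(species, name="species"))
    return df[TRAIT_COLUMNS]


def _diameter_classes(d_target, very_fine_frac, total_length):
    """Two (or one) diameter classes realising a mean diameter and very-fine
    length fraction exactly."""
    f = very_fine_frac
    thr = VERY_FINE_DIAMETER_MM
    if not 0.0 <= f <= 1.0:
        raise ValidationError("very_fine_pct must lie in [0, 100]")
    if f == 1.0:
        if d_target >= thr:
            raise ValidationError(
                "very_fine_pct 100 requires mean diameter < 0.2 mm"
            )
        return ((d_target, total_length),)
    if f == 0.0:
        if d_target < thr:
            raise ValidationError(
                "very_fine_pct 0 requires mean diameter >= 0.2 mm"
            )
        return ((d_target, total_length),)
    if d_target >= thr:
        d1 = 0.75 * thr
        d2 = (d_target - d1 * f) / (1.0 - f)
    else:
        d1 = (d_target - thr * (1.0 - f)) / f
        d2 = thr
        if d1 <= 0:
            raise ValidationError(
                f"mean diameter {d_target} too small for very-fine fraction {f}"
            )
    return ((d1, f * total_length), (d2, (1.0 - f) * total_length))


def _depth_profile_points(depth95, total_length):
    """Five cumulative fine-root-length points whose OLS fit reaches 95% of
    the total at the requested depth; pattern (u, u, u, u, T)."""
    z = depth95
    if not 0 < z < 135.0:
        raise ValidationError(f"depth95 target {z} not realisable on a 0-100 cm pot")
    u = total_length * (135.0 - z) / (140.0 - z)
    cumulative = np.array([u, u, u, u, total_length])
    return np.diff(np.concatenate([[0.0], cumulative]))


def generate_measurement_records(targets: pd.DataFrame, seed=None) -> dict:
    """Raw measurement records whose computed traits equal ``targets``.

    Returns {species: RecordBundle}. Free scale choices (sample lengths,
    masses) are fixed constants; everything else is solved from the target
    row. Infeasible targets raise :class:`ValidationError` naming the
    constraint. ``seed`` is accepted for interface symmetry (the inversion
    is deterministic).
    """
    del seed
    bundles = {}
    for species, row in targets.iterrows():
        ldmc, sla = row["Leaf dry matter content"], row["Specific leaf area"]
        if not (0 < ldmc <= 1000) or sla <= 0:
            raise ValidationError(f"{species}: infeasible leaf targets")
        leaf_dry = 0.2
        leaf = LeafRecord(
            individual_id=f"{species}-leaf",
            leaf_area=10.0 * sla * leaf_dry,
            leaf_fresh_mass=1000.0 * leaf_dry / ldmc,
            leaf_dry_mass=leaf_dry,
        )
        srl = row["Specific root length"]
        if srl <= 0:
            raise ValidationError(f"{species}: SRL must be positive")
        sample_length = 10.0  # m of scanned fine root
        classes = _diameter_classes(
            row["Diameter"], row["Very fine root percentage"] / 100.0, sample_length
        )
        expected_sra = 0.1 * math.pi * row["Diameter"] * srl
        if not math.isclose(expected_sra, row["Specific root area"],
                            rel_tol=1e-9):
            raise ValidationError(
                f"{species}: specific root area inconsistent with diameter x SRL "
                "under the cylinder-surface definition"
            )
        dry_mass = sample_length / srl
        root_sample = RootSampleRecord(
            individual_id=f"{species}-fine",
            length_by_diameter_class=classes,
            total_length=sample_length,
            dry_mass=dry_mass,
            volume=1000.0 * dry_mass / row["Root tissue density"],
            p_concentration=srl / row["Root phosphorus use efficiency"],
            nodule_dry_mass=row["Investment in nodules"] * sample_length,
            phosphatase_activity=row["Root-surface phosphatase activity"],
        )
        fine_biomass = row["Fine root biomass"]
        taproot_biomass = row["Taproot biomass"]
        if fine_biomass <= 0 or taproot_biomass <= 0:
            raise ValidationError(f"{species}: biomasses must be positive")
        for col, expect in (
            ("Root system biomass", fine_biomass + taproot_biomass),
            ("Taproot percentage",
             100.0 * taproot_biomass / (fine_biomass + taproot_biomass)),
            ("Root:shoot ratio",
             (fine_biomass + taproot_biomass) / row["Aboveground biomass"]),
            ("Total biomass",
             fine_biomass + taproot_biomass + row["Aboveground biomass"]),
        ):
            if not math.isclose(row[col], expect, rel_tol=1e-9):
                raise ValidationError(f"{species}: {col} inconsistent with parts")
        taproot_length_m = row["Specific taproot length"] * taproot_biomass
        taproot_volume = taproot_biomass / row["Taproot tissue density"]
        total_fine_length = fine_biomass * srl  # m, whole plant
        seg_lengths = _depth_profile_points(
            row["Depth of 95% root length"], total_fine_length
        )
        seg_masses = tuple(seg_lengths / srl)
        taproot_length_cm = 100.0 * taproot_length_m
        rld = row["Root length density"]
        if rld <= 0:
            raise ValidationError(f"{species}: RLD must be positive")
        pot_volume = (100.0 * total_fine_length + taproot_length_cm) / rld
        profile = DepthProfile(
            individual_id=f"{species}-profile",
            fine_root_length_per_segment=tuple(seg_lengths),
            fine_root_mass_per_segment=seg_masses,
            coarse_root_mass_per_segment=(taproot_biomass, 0.0, 0.0, 0.0, 0.0),
            taproot_length=taproot_length_cm,
            pot_volume=pot_volume,
        )
        amf = round(row["Mycorrhizal rate"] * 3.0)
        if not math.isclose(100.0 * amf / 300.0, row["Mycorrhizal rate"],
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                f"{species}: mycorrhization rate not realisable as an integer "
                "count out of 300 intersects"
            )
        intersects = IntersectCount(
            individual_id=f"{species}-amf", amf_intersects=int(amf),
            total_intersects=300,
        )
        bundles[species] = RecordBundle(
            species=str(species),
            leaf=leaf,
            root_sample=root_sample,
            profile=profile,
            intersects=intersects,
            taproot_length=taproot_length_m,
            taproot_dry_mass=taproot_biomass,
            taproot_volume=taproot_volume,
            aboveground_biomass=row["Aboveground biomass"],
            passthrough={
                "Aerenchyma": row["Aerenchyma"],
                "Hairs": row["Hairs"],
                "Stele percentage": row["Stele percentage"],
            },
        )
    return bundles


def trait_table_from_records(bundles: dict) -> pd.DataFrame:
    """Forward computation: {species: RecordBundle} -> species x trait table."""
    rows = {sp: compute_trait_row(b) for sp, b in bundles.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df[TRAIT_COLUMNS]
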