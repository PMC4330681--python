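"""End-to-end analysis: traits + indicators + phylogeny -> Mantel report.

The entry point is :class:`TraitNicheAnalysis`, a model object built from a
species x trait table, a species x ecological-indicator table and a
phylogeny (a tree, or an alignment from which a neighbor-joining tree is
built). Its :meth:`~TraitNicheAnalysis.fit` runs the full procedure:

1. trait summary statistics (min / mean / max / CV);
2. patristic phylogenetic distance matrix and PCoA eigenvectors;
3. phylogenetic-signal F-test per trait (eigenvector regression);
4. Mantel tests of *absolute* trait distances against phylogenetic distance
   and against each indicator's absolute distance (one-sided, greater);
5. Mantel tests of *hierarchical* (signed) trait distances against each
   indicator's hierarchical distance (two-sided);

and returns a :class:`TraitNicheResults` carrying every cell of the grids
(r, p, number of pairs used) with significance stars at 0.05 / 0.01 / 0.001.
Cells whose statistic is undefined (constant trait, too few complete pairs)
are reported with a note, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .comparative import pcoa, phylo_signal_anova, select_axes
from .distances import absolute_matrix, hierarchical_matrix
from .errors import SpeciesMismatchError, TraitNicheError, ValidationError
from .mantel import mantel_test
from .phylo import neighbor_joining, pairwise_distance, patristic_matrix
from .traits import summarize_traits

__all__ = ["TraitNicheAnalysis", "TraitNicheResults", "stars"]

PHYLO_COLUMN = "phylogeny"


def stars(p) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _holm(pvals):
    """Holm step-down adjustment; NaNs passed through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    adj = np.maximum.accumulate(ps[order] * (m - np.arange(m)))
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


class TraitNicheAnalysis:
    """Model object tying together traits, indicators and a phylogeny.

    Parameters
    ----------
    traits : DataFrame, species x trait (NA allowed)
    indicators : DataFrame, species x ecological indicator (NA allowed)
    tree : dendropy.Tree, optional — phylogeny with branch lengths
    alignment : Alignment, optional — sequences to build an NJ tree from
    distance_model : {'p-distance', 'K2P'} — used when building from an
        alignment
    na_policy : {'pairwise', 'listwise'} — pairwise-complete deletion per
        test (default) or up-front removal of species with any NA indicator
    """

    def __init__(self, traits, indicators, tree=None, alignment=None,
                 distance_model="p-distance", na_policy="pairwise"):
        if tree is None and alignment is None:
            raise ValidationError("provide a tree or an alignment")
        if na_policy not in ("pairwise", "listwise"):
            raise ValueError(f"unknown na_policy: {na_policy!r}")
        traits = traits.apply(pd.to_numeric, errors="coerce")
        indicators = indicators.apply(pd.to_numeric, errors="coerce")
        if na_policy == "listwise":
            traits = traits.loc[indicators.notna().all(axis=1)]
            indicators = indicators.loc[traits.index]
        if len(traits) < 4:
            raise ValidationError("need at least 4 species")
        if tree is None:
            tree = neighbor_joining(pairwise_distance(alignment, distance_model))
        leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        sets = {
            "traits": set(traits.index),
            "indicators": set(indicators.index),
            "tree": leaf_labels,
        }
        union = set.union(*sets.values())
        inter = set.intersection(*sets.values())
        if na_policy == "listwise" and sets["traits"] < leaf_labels:
            # listwise deletion legitimately shrinks the species set
            tree = tree.extract_tree_with_taxa_labels(sets["traits"])
            inter = set.intersection(sets["traits"], sets["indicators"])
            union = inter
        if union != inter:
            raise SpeciesMismatchError(
                f"species IDs inconsistent across inputs: {sorted(union - inter)}",
                offending=union - inter,
            )
        self.species = list(traits.index)
        self.traits = traits
        self.indicators = indicators.loc[self.species]
        self.tree = tree
        self.na_policy = na_policy

    @classmethod
    def from_csv(cls, traits_path, indicators_path, tree_path=None,
                 alignment_path=None, **kwargs):
        from .phylo import Alignment, read_newick
        from .traits import read_trait_table

        tree = read_newick(tree_path) if tree_path else None
        aln = Alignment.from_fasta(alignment_path) if alignment_path else None
        return cls(read_trait_table(traits_path), read_trait_table(indicators_path),
                   tree=tree, alignment=aln, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, n_permutations=999, seed=0, tail_absolute="greater",
            tail_hierarchical="two_sided", axis_rule="broken-stick",
            k_axes=None, holm=False, alpha=0.05):
        """Run the whole analysis; returns :class:`TraitNicheResults`."""
        log = []
        rng = np.random.default_rng(seed)

        summary, flagged = summarize_traits(self.traits)
        for col in flagged:
            log.append(f"trait {col!r}: too few values; excluded from summary")

        phylo_d = patristic_matrix(self.tree).reindex(self.species)
        basis = pcoa(phylo_d)
        axes = select_axes(basis, rule=axis_rule, k=k_axes)
        if not axes:
            axes = [basis.positive_axes[0]]
            log.append("axis selection retained nothing; fell back to axis 1")

        signal_rows = []
        for col in self.traits.columns:
            try:
                res = phylo_signal_anova(self.traits[col], basis, axes, name=col)
                signal_rows.append({
                    "trait": col, "F": res.F, "df1": res.df_model,
                    "df2": res.df_residual, "p": res.p,
                    "r_squared": res.r_squared, "n": res.n_species,
                    "stars": stars(res.p), "note": res.note,
                })
            except TraitNicheError as exc:
                log.append(f"signal test failed for {col!r}: {exc}")
                signal_rows.append({"trait": col, "F": np.nan, "df1": np.nan,
                                    "df2": np.nan, "p": np.nan,
                                    "r_squared": np.nan, "n": np.nan,
                                    "stars": "", "note": str(exc)})
        signal = pd.DataFrame(signal_rows).set_index("trait")

        abs_trait = {}
        hier_trait = {}
        for col in self.traits.columns:
            try:
                abs_trait[col] = absolute_matrix(self.traits[col])
                hier_trait[col] = hierarchical_matrix(self.traits[col])
            except TraitNicheError as exc:
                log.append(f"distance matrices unavailable for trait {col!r}: {exc}")
        abs_ind = {}
        hier_ind = {}
        for col in self.indicators.columns:
            try:
                abs_ind[col] = absolute_matrix(self.indicators[col])
                hier_ind[col] = hierarchical_matrix(self.indicators[col])
            except TraitNicheError as exc:
                log.append(f"distance matrices unavailable for indicator "
                           f"{col!r}: {exc}")

        def run_cell(x, y, tail, rows, trait, comparator):
            cell_seed = int(rng.integers(2 ** 31))
            try:
                res = mantel_test(x, y, n_perm=n_permutations, tail=tail,
                                  seed=cell_seed)
                rows.append({"trait": trait, "comparator": comparator,
                             "r": res.r, "p": res.p,
                             "n_pairs": res.n_pairs_used, "tail": res.tail,
                             "seed": cell_seed, "note": ""})
            except TraitNicheError as exc:
                log.append(f"Mantel {trait!r} vs {comparator!r} unavailable: {exc}")
                rows.append({"trait": trait, "comparator": comparator,
                             "r": np.nan, "p": np.nan, "n_pairs": 0,
                             "tail": tail, "seed": cell_seed,
                             "note": str(exc)})

        abs_rows = []
        for col in self.traits.columns:
            if col not in abs_trait:
                continue
            run_cell(abs_trait[col], phylo_d, tail_absolute, abs_rows,
                     col, PHYLO_COLUMN)
            for ind in self.indicators.columns:
                if ind in abs_ind:
                    run_cell(abs_trait[col], abs_ind[ind], tail_absolute,
                             abs_rows, col, ind)
        hier_rows = []
        for col in self.traits.columns:
            if col not in hier_trait:
                continue
            for ind in self.indicators.columns:
                if ind in hier_ind:
                    run_cell(hier_trait[col], hier_ind[ind], tail_hierarchical,
                             hier_rows, col, ind)

        mantel_absolute = pd.DataFrame(abs_rows)
        mantel_hierarchical = pd.DataFrame(hier_rows)
        if holm:
            for df in (mantel_absolute, mantel_hierarchical):
                df["p_adjusted"] = _holm(df["p"].to_numpy())

        metadata = {
            "package_version": _version,
            "n_species": len(self.species),
            "n_traits": int(self.traits.shape[1]),
            "n_indicators": int(self.indicators.shape[1]),
            "seed": int(seed),
            "n_permutations": int(n_permutations),
            "tail_absolute": tail_absolute,
            "tail_hierarchical": tail_hierarchical,
            "axis_rule": axis_rule,
            "k_axes": k_axes,
            "retained_axes": [int(a) for a in axes],
            "na_policy": self.na_policy,
            "holm": bool(holm),
            "alpha": alpha,
        }
        return TraitNicheResults(
            trait_summary=summary, signal=signal,
            mantel_absolute=mantel_absolute,
            mantel_hierarchical=mantel_hierarchical,
            basis=basis, phylo_distances=phylo_d, metadata=metadata,
            log=log, alpha=alpha, holm=holm,
        )


@dataclass
class TraitNicheResults:
    """Fitted analysis: summary tables, Mantel grids and run metadata."""

    trait_summary: pd.DataFrame
    signal: pd.DataFrame
    mantel_absolute: pd.DataFrame
    mantel_hierarchical: pd.DataFrame
    basis: object
    phylo_distances: object
    metadata: dict
    log: list = field(default_factory=list)
    alpha: float = 0.05
    holm: bool = False

    def _p_column(self):
        return "p_adjusted" if self.holm else "p"

    def wide_grid(self, long_df) -> pd.DataFrame:
        """Wide trait x comparator grid of starred r values (strings)."""
        pcol = self._p_column()
        cells = {}
        for _, row in long_df.iterrows():
            if np.isfinite(row["r"]):
                cell = f"{row['r']:.2f}{stars(row[pcol])}"
            else:
                cell = "NA"
            cells.setdefault(row["trait"], {})[row["comparator"]] = cell
        traits_order = list(dict.fromkeys(long_df["trait"]))
        comp_order = list(dict.fromkeys(long_df["comparator"]))
        grid = pd.DataFrame.from_dict(cells, orient="index")
        grid = grid.reindex(index=traits_order, columns=comp_order)
        grid.index.name = "trait"
        return grid

    def summary(self) -> str:
        """Human-readable run overview."""
        pcol = self._p_column()
        lines = []
        md = self.metadata
        lines.append("Trait-niche distance analysis")
        lines.append("=" * 64)
        lines.append(
            f"species: {md['n_species']}  traits: {md['n_traits']}  "
            f"indicators: {md['n_indicators']}"
        )
        lines.append(
            f"permutations: {md['n_permutations']}  seed: {md['seed']}  "
            f"alpha: {md['alpha']}  NA policy: {md['na_policy']}"
        )
        lines.append(f"retained phylogenetic axes: {md['retained_axes']}")
        sig = self.signal[self.signal["p"] < self.alpha]
        lines.append("")
        lines.append(f"phylogenetic signal (p < {self.alpha}): "
                     f"{len(sig)}/{len(self.signal)} traits")
        for trait, row in sig.iterrows():
            lines.append(f"  {trait}: F({row['df1']:.0f},{row['df2']:.0f}) = "
                         f"{row['F']:.2f}{row['stars']}")
        for label, df in (("absolute", self.mantel_absolute),
                          ("hierarchical", self.mantel_hierarchical)):
            ok = df[np.isfinite(df["r"])]
            hits = ok[ok[pcol] < self.alpha]
            lines.append("")
            lines.append(f"{label} Mantel tests: {len(hits)}/{len(df)} "
                         f"significant at alpha = {self.alpha}")
            for _, row in hits.iterrows():
                lines.append(
                    f"  {row['trait']} vs {row['comparator']}: "
                    f"r = {row['r']:+.2f}{stars(row[pcol])} "
                    f"(p = {row[pcol]:.3f}, pairs = {row['n_pairs']})"
                )
        return "\n".join(lines)

    def to_csv(self, out_dir):
        """Write the full report (CSV grids + metadata + log) to a directory."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.12g"
        self.trait_summary.to_csv(out / "summary.csv", na_rep="NA",
                                  float_format=fmt)
        self.signal.to_csv(out / "signal.csv", na_rep="NA", float_format=fmt)
        self.wide_grid(self.mantel_absolute).to_csv(
            out / "mantel_absolute.csv", na_rep="NA")
        self.wide_grid(self.mantel_hierarchical).to_csv(
            out / "mantel_hierarchical.csv", na_rep="NA")
        long = pd.concat([
            self.mantel_absolute.assign(kind="absolute"),
            self.mantel_hierarchical.assign(kind="hierarchical"),
        ], ignore_index=True)
        long.to_csv(out / "mantel_long.csv", index=False, na_rep="NA",
                    float_format=fmt)
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "run.log", "w") as fh:
            for line in self.log:
                fh.write(line + "\n")
        return out
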