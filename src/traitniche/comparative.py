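"""Phylogenetic-signal analysis by phylogenetic eigenvector regression (PVR).

The phylogenetic distance matrix is embedded by principal coordinates
analysis (Gower double-centering of -d^2/2 followed by eigendecomposition);
a trait is then regressed on a retained subset of the eigenvectors and the
overall regression F-statistic measures how much trait variance the tree
structure explains — significant F means phylogenetic signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = ["EigenBasis", "SignalResult", "pcoa", "select_axes",
           "phylo_signal_anova", "broken_stick_expectations"]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class EigenBasis:
    """PCoA eigendecomposition of a phylogenetic distance matrix.

    ``eigenvectors`` columns are orthonormal; ``eigenvalues`` are sorted in
    descending order; ``positive_axes`` indexes the axes usable for
    regression (eigenvalue > 0 up to tolerance). Negative-eigenvalue axes
    are retained in the record for diagnostics but never selectable.
    """

    species: tuple
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # species x axis
    positive_axes: tuple

    @property
    def n_positive(self):
        return len(self.positive_axes)

    def coordinates(self, axes=None):
        """Classical-scaling coordinates (eigenvectors scaled by sqrt(eigenvalue))."""
        axes = list(self.positive_axes if axes is None else axes)
        return self.eigenvectors[:, axes] * np.sqrt(self.eigenvalues[axes])


@dataclass(frozen=True)
class SignalResult:
    """Overall regression F-test of one trait on retained eigenvectors."""

    trait: str
    F: float
    df_model: int
    df_residual: int
    p: float
    r_squared: float
    n_species: int
    flagged: bool = False
    note: str = ""


def pcoa(d) -> EigenBasis:
    """Principal coordinates analysis of a symmetric distance matrix.

    Applies Gower double-centering B = -1/2 J d^2 J (J the centering
    matrix), eigendecomposes B, and returns unit-norm eigenvectors sorted by
    descending eigenvalue. Axes with negative eigenvalues (non-Euclidean
    input) are excluded from ``positive_axes``.
    """
    if np.isnan(d.values).any():
        raise ValidationError("PCoA input must be complete (no NA)")
    n = d.n_species
    if n < 3:
        raise ValidationError("PCoA needs at least 3 species")
    a = -0.5 * d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = 0.5 * (b + b.T)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.abs(vals).max() if vals.size else 1.0
    positive = tuple(int(i) for i, v in enumerate(vals)
                     if v > _EIG_TOL * max(scale, 1.0))
    return EigenBasis(species=tuple(d.species), eigenvalues=vals,
                      eigenvectors=vecs, positive_axes=positive)


def broken_stick_expectations(n: int) -> np.ndarray:
    """Expected relative eigenvalue sizes under the broken-stick null:
    b_k = (1/n) * sum_{i=k..n} 1/i for k = 1..n."""
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1] / n


def select_axes(basis: EigenBasis, rule="broken-stick", k=None):
    """Indices of eigenvector axes to retain for the signal regression.

    ``broken-stick`` keeps the leading positive axes whose share of the
    positive eigenvalue total exceeds the broken-stick expectation, stopping
    at the first axis that falls below its stick; ``first-k`` keeps the k
    leading positive axes.
    """
    if basis.n_positive < 1:
        raise ValidationError("no positive eigenvalues to select from")
    pos = list(basis.positive_axes)
    if rule == "first-k":
        if k is None or k < 1:
            raise ValueError("first-k rule requires k >= 1")
        if k > len(pos):
            raise ValidationError(
                f"k={k} exceeds the {len(pos)} positive axes available"
            )
        return pos[:k]
    if rule != "broken-stick":
        raise ValueError(f"unknown selection rule: {rule!r}")
    vals = basis.eigenvalues[pos]
    rel = vals / vals.sum()
    expect = broken_stick_expectations(len(pos))
    kept = []
    for axis, r, e in zip(pos, rel, expect):
        if r <= e:  # sequential rule: stop at the first axis below its stick
            break
        kept.append(axis)
    return kept


def phylo_signal_anova(trait: pd.Series, basis: EigenBasis, axes,
                       name=None) -> SignalResult:
    """Regression F-test of a species trait on retained phylogenetic axes.

    Fits trait ~ intercept + eigenvectors[axes] by least squares over the
    non-NA species and reports the overall F with (|axes|, n - |axes| - 1)
    degrees of freedom. A perfect fit reports F = +inf (p = 0); a constant
    trait yields a flagged result with no signal claim.
    """
    axes = list(axes)
    if not axes:
        raise ValidationError("at least one axis required")
    name = name if name is not None else str(trait.name)
    trait = trait.reindex(list(basis.species))
    mask = trait.notna().to_numpy()
    y = trait.to_numpy(dtype=float)[mask]
    n = int(mask.sum())
    k = len(axes)
    if n < k + 2:
        raise ValidationError(
            f"{name}: {n} usable species cannot support {k} axes (+ intercept)"
        )
    if np.ptp(y) == 0:
        return SignalResult(trait=name, F=float("nan"), df_model=k,
                            df_residual=n - k - 1, p=float("nan"),
                            r_squared=float("nan"), n_species=n, flagged=True,
                            note="constant trait; F undefined")
    x = np.column_stack([np.ones(n), basis.eigenvectors[mask][:, axes]])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    df1, df2 = k, n - k - 1
    if sse <= 1e-12 * sst:
        return SignalResult(trait=name, F=math.inf, df_model=df1,
                            df_residual=df2, p=0.0, r_squared=1.0,
                            n_species=n, note="perfect fit")
    f = (ssr / df1) / (sse / df2)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df1, df2))
    return SignalResult(trait=name, F=f, df_model=df1, df_residual=df2, p=p,
                        r_squared=max(ssr, 0.0) / sst, n_species=n)
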